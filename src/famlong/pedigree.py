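"""Pedigree data model, PED-style I/O, validation, and kinship computation.

A pedigree is a directed acyclic graph of parent links within one family.
Kinship coefficients phi(i, j) -- the probability that a randomly drawn
allele from i and one from j are identical by descent -- are computed by
the standard recursive algorithm in a topological (parents-first) order:

    phi(i, i) = 1/2 * (1 + phi(p, q))              (p, q parents of i)
    phi(i, j) = 1/2 * (phi(p, j) + phi(q, j))      (j already processed)

with phi = 1/2 on the diagonal and 0 off-diagonal for founders.  The
additive genetic relationship matrix used by the heritability module is
2 * Phi.  Families are treated as independent sampling units: kinship
across families is identically zero and the matrix is block diagonal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "load_pedigree",
    "load_pedigrees",
    "kinship",
    "kinship_all",
]

MISSING_PARENT = "0"

SEX_CODES = {"1": "male", "2": "female", "M": "male", "F": "female",
             "male": "male", "female": "female"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree file or object."""


@dataclass
class Individual:
    person_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female"
    generation: str | None = None  # proband | offspring | spouse-control | ...
    birth_year: int | None = None
    vital_status: str | None = None  # "alive" | "dead"
    age_years: float | None = None
    annotations: dict = field(default_factory=dict)

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise PedigreeError(
                f"individual {self.person_id}: negative age {self.age_years}")


@dataclass(eq=False)  # identity semantics; hashable for caches
class Pedigree:
    """One family's individuals with validated parent links."""

    family_id: str
    individuals: dict[str, Individual]

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals.values())

    @property
    def ids(self) -> list[str]:
        return list(self.individuals)

    @property
    def founders(self) -> list[str]:
        return [i.person_id for i in self if i.is_founder]

    def members(self, generation: str) -> list[Individual]:
        return [i for i in self if i.generation == generation]

    def parents_of(self, person_id: str) -> tuple[str | None, str | None]:
        ind = self.individuals[person_id]
        return ind.father_id, ind.mother_id

    def graph(self) -> nx.DiGraph:
        """Directed graph with edges parent -> child."""
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self:
            for par in (ind.father_id, ind.mother_id):
                if par is not None:
                    g.add_edge(par, ind.person_id)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.graph()))

    def validate(self) -> None:
        for ind in self:
            if (ind.father_id is None) != (ind.mother_id is None):
                raise PedigreeError(
                    f"individual {ind.person_id} in family {self.family_id} "
                    "has exactly one known parent; both-or-neither required "
                    "(use add_dummy_parents to auto-complete)")
            for par, want in ((ind.father_id, "male"), (ind.mother_id, "female")):
                if par is None:
                    continue
                if par not in self.individuals:
                    raise PedigreeError(
                        f"individual {ind.person_id} in family {self.family_id} "
                        f"references unknown parent {par!r}")
                if self.individuals[par].sex != want:
                    raise PedigreeError(
                        f"parent {par} of {ind.person_id} has sex "
                        f"{self.individuals[par].sex}, expected {want}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise PedigreeError(
                f"family {self.family_id}: parent links contain a cycle: "
                + " -> ".join(str(e[0]) for e in cycle))
        if not self.founders:
            raise PedigreeError(f"family {self.family_id} has no founder")


@dataclass
class KinshipMatrix:
    """Kinship coefficients for an ordered set of individuals.

    ``phi`` is symmetric with phi(i,i) = (1 + f_i)/2; the relationship
    matrix 2*phi is positive semidefinite.  ``families`` records each
    individual's family so downstream code can exploit the block
    structure.
    """

    ids: list[str]
    phi: np.ndarray
    families: list[str]

    def __post_init__(self) -> None:
        self.index = {pid: k for k, pid in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.phi[self.index[a], self.index[b]])

    @property
    def relationship(self) -> np.ndarray:
        return 2.0 * self.phi

    def family_blocks(self):
        """Yield (family_id, ids, 2*phi block) per family, in id order."""
        fams = pd.Series(self.families)
        for fam in fams.unique():
            idx = np.flatnonzero(fams.to_numpy() == fam)
            yield fam, [self.ids[k] for k in idx], 2.0 * self.phi[np.ix_(idx, idx)]

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i, n):
                if self.families[i] == self.families[j]:
                    rows.append((self.ids[i], self.ids[j], self.phi[i, j]))
        return pd.DataFrame(rows, columns=["id1", "id2", "phi"])

    def to_square_csv(self, path) -> None:
        pd.DataFrame(self.phi, index=self.ids, columns=self.ids).to_csv(path)


def _classify_sex(raw, person_id) -> str:
    s = str(raw).strip()
    if s not in SEX_CODES:
        raise PedigreeError(f"individual {person_id}: unknown sex code {raw!r}")
    return SEX_CODES[s]


def _rows_to_pedigrees(df: pd.DataFrame, missing: str,
                       add_dummy_parents: bool) -> dict[str, Pedigree]:
    extra = [c for c in df.columns
             if c not in ("family", "individual", "father", "mother", "sex")]
    peds: dict[str, Pedigree] = {}
    for fam, sub in df.groupby("family", sort=False):
        inds: dict[str, Individual] = {}
        dummy_n = 0
        for _, row in sub.iterrows():
            pid = str(row["individual"])
            if pid in inds:
                raise PedigreeError(f"duplicate person_id {pid} in family {fam}")
            fa = None if str(row["father"]) == missing else str(row["father"])
            mo = None if str(row["mother"]) == missing else str(row["mother"])
            ann = {}
            for c in extra:
                v = row[c]
                if pd.notna(v):
                    ann[c] = v
            kw = {}
            if "generation" in ann:
                kw["generation"] = str(ann.pop("generation"))
            if "birth_year" in ann:
                kw["birth_year"] = int(ann.pop("birth_year"))
            if "vital_status" in ann:
                kw["vital_status"] = str(ann.pop("vital_status"))
            if "age_years" in ann:
                kw["age_years"] = float(ann.pop("age_years"))
            inds[pid] = Individual(pid, str(fam), fa, mo,
                                   _classify_sex(row["sex"], pid),
                                   annotations=ann, **kw)
        if add_dummy_parents:
            for ind in list(inds.values()):
                if (ind.father_id is None) != (ind.mother_id is None):
                    dummy_n += 1
                    did = f"__dummy{dummy_n}"
                    want = "male" if ind.father_id is None else "female"
                    inds[did] = Individual(did, str(fam), None, None, want,
                                           generation="dummy")
                    if ind.father_id is None:
                        ind.father_id = did
                    else:
                        ind.mother_id = did
        peds[str(fam)] = Pedigree(str(fam), inds)
    return peds


def load_pedigrees(path, *, missing: str = MISSING_PARENT, sep: str | None = None,
                   add_dummy_parents: bool = False) -> dict[str, Pedigree]:
    """Read a PED/FAM-style whitespace- or tab-delimited file.

    The first five columns are FID IID PAT MAT SEX.  A header line
    starting with ``#`` or with the literal column names may name extra
    columns (generation, birth_year, vital_status, age_years, ...),
    which are attached to individuals as typed fields or annotations.
    """
    with open(path) as fh:
        text = fh.read()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    tokens = first.lstrip("#").split()
    has_header = bool(tokens) and tokens[0].lower() in ("fid", "family")
    base = ["family", "individual", "father", "mother", "sex"]
    if has_header:
        names = base + [t.lower() for t in tokens[5:]]
        df = pd.read_csv(io.StringIO(text), sep=sep or r"\s+", skiprows=1,
                         names=names, dtype=str, comment=None)
    else:
        df = pd.read_csv(io.StringIO(text), sep=sep or r"\s+", header=None,
                         dtype=str)
        if df.shape[1] < 5:
            raise PedigreeError(
                f"{path}: expected at least 5 columns (FID IID PAT MAT SEX)")
        df.columns = base + [f"col{i}" for i in range(5, df.shape[1])]
    return _rows_to_pedigrees(df, missing, add_dummy_parents)


def load_pedigree(path, **kwargs) -> Pedigree:
    """Read a single-family PED file (error if several families present)."""
    peds = load_pedigrees(path, **kwargs)
    if len(peds) != 1:
        raise PedigreeError(
            f"{path}: expected one family, found {len(peds)}")
    return next(iter(peds.values()))


def write_ped(pedigrees, path) -> None:
    """Write pedigrees to a headered PED-style file (round-trips loaders)."""
    if isinstance(pedigrees, Pedigree):
        pedigrees = {pedigrees.family_id: pedigrees}
    rows = []
    for ped in pedigrees.values():
        for ind in ped:
            rows.append({
                "FID": ped.family_id,
                "IID": ind.person_id,
                "PAT": ind.father_id or MISSING_PARENT,
                "MAT": ind.mother_id or MISSING_PARENT,
                "SEX": "1" if ind.sex == "male" else "2",
                "generation": ind.generation or "NA",
                "birth_year": ind.birth_year if ind.birth_year is not None else "NA",
                "vital_status": ind.vital_status or "NA",
                "age_years": f"{ind.age_years:.4f}" if ind.age_years is not None else "NA",
            })
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def kinship(pedigree: Pedigree) -> KinshipMatrix:
    """Kinship coefficients for one family by the recursive algorithm."""
    order = pedigree.topological_order()
    pos = {pid: k for k, pid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k, pid in enumerate(order):
        fa, mo = pedigree.parents_of(pid)
        if fa is None:
            phi[k, k] = 0.5
        else:
            p, q = pos[fa], pos[mo]
            phi[k, :k] = 0.5 * (phi[p, :k] + phi[q, :k])
            phi[:k, k] = phi[k, :k]
            phi[k, k] = 0.5 * (1.0 + phi[p, q])
    # re-order rows/cols to the pedigree's input id order
    want = pedigree.ids
    perm = np.array([pos[pid] for pid in want])
    phi = phi[np.ix_(perm, perm)]
    return KinshipMatrix(want, phi, [pedigree.family_id] * n)


def kinship_all(pedigrees: dict[str, Pedigree]) -> KinshipMatrix:
    """Block-diagonal kinship across families (cross-family phi = 0)."""
    parts = [kinship(p) for p in pedigrees.values()]
    ids = [pid for p in parts for pid in p.ids]
    fams = [f for p in parts for f in p.families]
    n = len(ids)
    phi = np.zeros((n, n))
    at = 0
    for p in parts:
        m = len(p.ids)
        phi[at:at + m, at:at + m] = p.phi
        at += m
    return KinshipMatrix(ids, phi, fams)
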