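"""Seeded generator of longevity-study families, lifespans and phenotypes.

The generator stands in for the restricted cohort data.  It emulates the
study's sampling design: two-generation families built around a
long-lived proband sibship, with spouses as genetically unrelated
in-family controls, enrolled family sizes averaging about 9 members
(range 3-79); proband-generation lifespans drawn from a life table
(optionally with a reduced hazard to mimic survival exceptionality); and
two phenotype visits 8-10 years apart with heritable, kinship-correlated
person-specific intercepts and slopes plus independent per-visit
measurement error.

Every family uses an independent deterministic random substream derived
from (seed, family index), so outputs are reproducible and independent
of iteration order.  An unphenotyped ancestral founder couple (generation
"ancestor") links the proband siblings genetically; enrolled-size
statistics exclude them, matching how the study counts enrolled members.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .lifetables import LifeTable, default_cohort_table
from .pedigree import Individual, Pedigree, kinship, write_ped

__all__ = ["SimConfig", "family_rng", "simulate_pedigrees",
           "simulate_lifespans", "simulate_phenotypes",
           "simulate_polygenic_trait", "random_sibship", "write_sim_output",
           "ENROLLED_GENERATIONS"]

ENROLLED_GENERATIONS = ("proband", "spouse-control", "offspring")

SITE_EFFECTS = {"site1": 1.0, "site2": -0.5, "site3": 0.0, "site4": 0.5}


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Family-structure defaults were calibrated once so that 500 default
    families give a mean enrolled size near the study's 9.1 (range
    bounded to [3, 79]).  Trait defaults describe a generic aging
    phenotype: person-level intercept variance 10, slope variance 0.01
    per year^2, intercept-slope correlation 0.6 (level predicts rate of
    change), heritability 0.5 for both components, and per-visit
    measurement-error variance 4 -- large relative to the slope signal
    accrued over the 8-10 year inter-visit window, which is exactly the
    regime where naive OLS change scores lose their heritability.
    """

    n_families: int = 150
    seed: int = 0
    # pedigree structure
    sibship_extra_mean: float = 1.1      # sibship size = 2 + NegBin(mean, disp)
    sibship_dispersion: float = 2.0
    offspring_rate: float = 1.0          # Poisson offspring per sibling
    include_spouses: bool = True
    spouse_prob_childless: float = 0.3   # spouse for a childless sibling
    offspring_spouse_prob: float = 0.2
    min_family_size: int = 3             # enrolled members
    max_family_size: int = 79
    # demographics / lifespans
    proband_birth_year: tuple[float, float] = (1916.0, 4.0)   # mean, sd
    offspring_birth_year: tuple[float, float] = (1946.0, 6.0)
    hazard_multiplier: float = 1.0       # < 1 enriches survival exceptionality
    censor_age: tuple[float, float] = (93.0, 4.0)             # mean, sd
    # visit layout
    visit1_age: dict = field(default_factory=lambda: {
        "proband": (91.0, 5.0), "offspring": (61.0, 8.0),
        "spouse-control": (75.0, 14.0)})
    inter_visit_years: tuple[float, float] = (8.0, 10.0)      # uniform support
    visit2_dropout: float = 0.0
    # phenotype model
    beta: tuple[float, float] = (50.0, -0.4)
    sigma2_int: float = 10.0
    sigma2_slope: float = 0.01
    rho_g: float = 0.6                   # genetic intercept-slope correlation
    rho_e: float = 0.6                   # environmental counterpart
    h2_intercept: float = 0.5
    h2_slope: float = 0.5
    sigma2_e: float = 4.0                # per-visit measurement-error variance
    sex_effect: float = 2.0              # added to male intercepts
    n_sites: int = 4

    def __post_init__(self) -> None:
        for name in ("sigma2_int", "sigma2_slope", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("h2_intercept", "h2_slope"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(self.rho_g) > 1 or abs(self.rho_e) > 1:
            raise ValueError("correlations must be in [-1, 1]")
        if not self.min_family_size <= self.max_family_size:
            raise ValueError("family size bounds inverted")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def family_rng(seed: int, family_index: int) -> np.random.Generator:
    """Deterministic per-family substream, independent of iteration order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), 7919, int(family_index)]))


def _negbin(rng, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _draw_structure(cfg: SimConfig, rng) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Sibship size, offspring counts, spouse flags; resampled to size bounds."""
    for _ in range(1000):
        s = 2 + _negbin(rng, cfg.sibship_extra_mean, cfg.sibship_dispersion)
        offs = rng.poisson(cfg.offspring_rate, size=s)
        if cfg.include_spouses:
            spouse = (offs > 0) | (rng.random(s) < cfg.spouse_prob_childless)
        else:
            spouse = offs > 0  # parents of offspring must exist in the file
        off_spouse = rng.random(int(offs.sum())) < (
            cfg.offspring_spouse_prob if cfg.include_spouses else 0.0)
        total = s + int(spouse.sum()) + int(offs.sum()) + int(off_spouse.sum())
        if cfg.min_family_size <= total <= cfg.max_family_size:
            return s, offs, spouse, off_spouse
    raise ValueError("family-size configuration cannot satisfy the size bounds")


def _birth_year(rng, mean_sd) -> int:
    return int(round(rng.normal(*mean_sd)))


def simulate_pedigrees(config: SimConfig) -> dict[str, Pedigree]:
    """Generate two-generation families around long-lived proband sibships."""
    peds: dict[str, Pedigree] = {}
    for f in range(config.n_families):
        rng = family_rng(config.seed, f)
        fam = f"F{f + 1:04d}"
        s, offs, spouse, off_spouse = _draw_structure(config, rng)
        inds: dict[str, Individual] = {}

        def add(pid, father, mother, sex, gen, by):
            inds[pid] = Individual(pid, fam, father, mother, sex,
                                   generation=gen, birth_year=by)

        fa, mo = f"{fam}-A1", f"{fam}-A2"
        add(fa, None, None, "male", "ancestor", _birth_year(rng, (1888, 3)))
        add(mo, None, None, "female", "ancestor", _birth_year(rng, (1890, 3)))
        osp_iter = iter(off_spouse)
        for k in range(s):
            sid = f"{fam}-S{k + 1}"
            sex = "male" if rng.random() < 0.5 else "female"
            add(sid, fa, mo, sex, "proband",
                _birth_year(rng, config.proband_birth_year))
            partner = None
            if spouse[k]:
                partner = f"{fam}-P{k + 1}"
                add(partner, None, None,
                    "female" if sex == "male" else "male", "spouse-control",
                    inds[sid].birth_year + int(round(rng.normal(0, 3))))
            for j in range(int(offs[k])):
                oid = f"{fam}-O{k + 1}.{j + 1}"
                osex = "male" if rng.random() < 0.5 else "female"
                par_f = sid if sex == "male" else partner
                par_m = partner if sex == "male" else sid
                add(oid, par_f, par_m, osex, "offspring",
                    _birth_year(rng, config.offspring_birth_year))
                if next(osp_iter):
                    qid = f"{fam}-Q{k + 1}.{j + 1}"
                    add(qid, None, None,
                        "female" if osex == "male" else "male",
                        "spouse-control",
                        inds[oid].birth_year + int(round(rng.normal(0, 3))))
        peds[fam] = Pedigree(fam, inds)
    return peds


def enrolled_members(ped: Pedigree) -> list[Individual]:
    return [i for i in ped if i.generation in ENROLLED_GENERATIONS]


def enrolled_size(ped: Pedigree) -> int:
    return len(enrolled_members(ped))


def simulate_lifespans(pedigrees: dict[str, Pedigree], table: LifeTable,
                       config: SimConfig) -> None:
    """Draw proband-generation ages and vital status in place.

    Death ages come from the life table by inverse transform of the
    cumulative hazard, scaled by ``hazard_multiplier`` (< 1 = protective
    familial effect).  A per-person censoring age converts the survivors
    to "alive at age c"; other enrolled generations are marked alive.
    """
    for f, ped in enumerate(pedigrees.values()):
        rng = family_rng(config.seed, f).spawn(1)[0]
        for ind in ped:
            if ind.generation == "proband":
                t_death = float(table.sample_age_at_death(
                    ind.sex, ind.birth_year, rng,
                    hazard_multiplier=config.hazard_multiplier))
                censor = float(np.clip(rng.normal(*config.censor_age),
                                       85.0, 110.0))
                if t_death > censor:
                    ind.vital_status, ind.age_years = "alive", censor
                else:
                    ind.vital_status, ind.age_years = "dead", t_death
            elif ind.generation == "ancestor":
                ind.vital_status = "dead"
            else:
                ind.vital_status = "alive"


def random_sibship(n: int, table: LifeTable, rng: np.random.Generator,
                   birth_year: int = 1915, hazard_multiplier: float = 1.0,
                   censor_age: float | None = None,
                   family_id: str = "sib") -> list[Individual]:
    """A standalone sibship with table-distributed lifespans (calibration aid)."""
    out = []
    for k in range(n):
        sex = "male" if rng.random() < 0.5 else "female"
        t = float(table.sample_age_at_death(sex, birth_year, rng,
                                            hazard_multiplier=hazard_multiplier))
        if censor_age is not None and t > censor_age:
            status, age = "alive", censor_age
        else:
            status, age = "dead", t
        out.append(Individual(f"{family_id}-{k + 1}", family_id, None, None,
                              sex, generation="proband", birth_year=birth_year,
                              vital_status=status, age_years=age))
    return out


def _sqrt_psd(M: np.ndarray) -> np.ndarray:
    d, U = np.linalg.eigh(M)
    return U @ np.diag(np.sqrt(np.clip(d, 0.0, None))) @ U.T


def _component_chol(var_i, var_s, rho) -> np.ndarray:
    cov = rho * np.sqrt(var_i * var_s)
    return _sqrt_psd(np.array([[var_i, cov], [cov, var_s]]))


def simulate_phenotypes(pedigrees: dict[str, Pedigree], config: SimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-visit phenotype table plus the per-person truth table.

    True intercepts/slopes are beta plus genetic deviations correlated
    2*phi within a family (via the matrix square root of the kinship
    block) and independent environmental deviations; observed values add
    N(0, sigma2_e) measurement error at each visit.
    """
    A_g = _component_chol(config.h2_intercept * config.sigma2_int,
                          config.h2_slope * config.sigma2_slope, config.rho_g)
    A_e = _component_chol((1 - config.h2_intercept) * config.sigma2_int,
                          (1 - config.h2_slope) * config.sigma2_slope,
                          config.rho_e)
    pheno_rows, truth_rows = [], []
    for f, (fam, ped) in enumerate(pedigrees.items()):
        rng = family_rng(config.seed, f).spawn(2)[1]
        site = f"site{(f % config.n_sites) + 1}"
        members = enrolled_members(ped)
        if not members:
            continue
        kin = kinship(ped)
        idx = [kin.index[m.person_id] for m in members]
        L = _sqrt_psd(kin.relationship[np.ix_(idx, idx)])
        n = len(members)
        dev_g = L @ rng.standard_normal((n, 2)) @ A_g.T
        dev_e = rng.standard_normal((n, 2)) @ A_e.T
        for i, ind in enumerate(members):
            gen = ind.generation
            mean_sd = config.visit1_age.get(gen, (70.0, 10.0))
            age1 = float(np.clip(rng.normal(*mean_sd), 30.0, 107.0))
            d1 = date(2006, 1, 1) + timedelta(days=int(rng.integers(0, 1096)))
            gap_years = float(rng.uniform(*config.inter_visit_years))
            gap_days = int(round(gap_years * 365.25))
            d2 = d1 + timedelta(days=gap_days)
            t2 = gap_days / 365.25
            sex_term = config.sex_effect if ind.sex == "male" else 0.0
            base = config.beta[0] + sex_term + SITE_EFFECTS.get(
                site, 0.0) if config.n_sites else config.beta[0]
            intercept = base + dev_g[i, 0] + dev_e[i, 0]
            slope = config.beta[1] + dev_g[i, 1] + dev_e[i, 1]
            e1, e2 = rng.normal(0.0, np.sqrt(config.sigma2_e), size=2)
            truth_rows.append({
                "person_id": ind.person_id, "family_id": fam,
                "generation": gen, "true_intercept": intercept,
                "true_slope": slope, "genetic_intercept": dev_g[i, 0],
                "genetic_slope": dev_g[i, 1]})
            common = {"person_id": ind.person_id, "family_id": fam,
                      "sex": ind.sex, "field_site": site, "generation": gen}
            pheno_rows.append({**common, "visit": 1, "visit_date": d1,
                               "age_at_visit": age1, "value": intercept + e1})
            v2 = intercept + slope * t2 + e2
            if rng.random() < config.visit2_dropout:
                v2 = np.nan
            pheno_rows.append({**common, "visit": 2, "visit_date": d2,
                               "age_at_visit": age1 + t2, "value": v2})
    pheno = pd.DataFrame(pheno_rows)
    truth = pd.DataFrame(truth_rows)
    return pheno, truth


def simulate_polygenic_trait(pedigrees: dict[str, Pedigree], h2: float,
                             sigma2_total: float = 1.0, seed: int = 0,
                             generations=ENROLLED_GENERATIONS) -> pd.Series:
    """Direct person-level trait with y = g + e, Var(g) = h2 * sigma2 * 2Phi."""
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    vals: dict[str, float] = {}
    for f, ped in enumerate(pedigrees.values()):
        rng = family_rng(seed, f).spawn(3)[2]
        members = [i for i in ped if i.generation in generations]
        if not members:
            continue
        kin = kinship(ped)
        idx = [kin.index[m.person_id] for m in members]
        L = _sqrt_psd(kin.relationship[np.ix_(idx, idx)])
        n = len(members)
        g = np.sqrt(h2 * sigma2_total) * (L @ rng.standard_normal(n))
        e = np.sqrt((1 - h2) * sigma2_total) * rng.standard_normal(n)
        for m, v in zip(members, g + e):
            vals[m.person_id] = float(v)
    return pd.Series(vals, name="trait")


def _sha(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def write_sim_output(outdir, pedigrees, pheno: pd.DataFrame,
                     truth: pd.DataFrame, table: LifeTable,
                     config: SimConfig) -> dict:
    """Write PED, phenotype, truth and life-table files plus a manifest."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_ped(pedigrees, out / "families.ped")
    pheno.to_csv(out / "phenotypes.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    table.to_csv(out / "lifetable.csv")
    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": config.as_dict(),
        "files": {p.name: _sha(p) for p in sorted(out.glob("*"))
                  if p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
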