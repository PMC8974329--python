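"""Gene-dropping simulation, variance-component linkage LODs, and HLOD.

The demonstration this module supports: clusters of rare, nearly
lineage-specific causal variants segregating in large pedigrees can
collectively produce a strong linkage peak while every single variant is
too rare for a pooled single-variant association scan to detect.

Gene dropping assigns each founder two uniquely labelled alleles at an
abstract locus and transmits one allele from each parent to each child
uniformly at random, yielding simulation-true identity-by-descent (IBD)
and carrier status.  Per family, the variance-component linkage model is

    y ~ N(mu, Pi*sigma2_q + 2*Phi*sigma2_g + I*sigma2_e)

with Pi the locus IBD-proportion matrix; the family LOD is the log10
likelihood ratio of this model against sigma2_q = 0.  Heterogeneity is
handled by the standard admixture HLOD,

    HLOD = max_alpha sum_f log10( alpha*10^lod_f + (1 - alpha) ),

with families whose LOD exceeds 0.2 flagged as the driving families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .pedigree import Pedigree

__all__ = ["GeneDropResult", "FamilyLod", "HlodResult", "gene_drop",
           "gene_drop_ibd", "ibd_matrix", "family_vc_lod", "study_vc_lods",
           "hlod",
           "single_variant_association", "DRIVING_LOD_THRESHOLD"]

DRIVING_LOD_THRESHOLD = 0.2


@dataclass
class GeneDropResult:
    family_id: str
    ids: list[str]
    alleles: np.ndarray                  # (n, 2) int founder-allele labels
    causal_labels: dict[str, set[int]] = field(default_factory=dict)

    def dosage(self, variant: str) -> np.ndarray:
        labs = self.causal_labels[variant]
        if not labs:
            return np.zeros(len(self.ids))
        mask = np.isin(self.alleles, list(labs))
        return mask.sum(axis=1).astype(float)

    def carriers(self, variant: str) -> np.ndarray:
        return self.dosage(variant) > 0


_ORDER_CACHE: "weakref.WeakKeyDictionary" = None


def _drop_order(ped: Pedigree):
    global _ORDER_CACHE
    if _ORDER_CACHE is None:
        import weakref
        _ORDER_CACHE = weakref.WeakKeyDictionary()
    try:
        return _ORDER_CACHE[ped]
    except (KeyError, TypeError):
        pass
    res = _drop_order_compute(ped)
    try:
        _ORDER_CACHE[ped] = res
    except TypeError:
        pass
    return res


def _drop_order_compute(ped: Pedigree):
    order = ped.topological_order()
    pos = {pid: k for k, pid in enumerate(order)}
    steps = []
    for pid in order:
        fa, mo = ped.parents_of(pid)
        if fa is not None:
            steps.append((pos[pid], pos[fa], pos[mo]))
    return order, pos, steps


def gene_drop(pedigree: Pedigree, founder_carriers=None,
              rng: np.random.Generator | None = None,
              seed: int | None = None,
              mutations: dict[str, str] | None = None) -> GeneDropResult:
    """One gene-dropping replicate at an abstract locus.

    ``founder_carriers`` defines causal variants present in founders:
    either a mapping ``{variant_name: {founder_id: n_copies}}``, or a
    single allele frequency in [0, 1] applied independently to every
    founder allele (variant name "v").  ``mutations`` maps variant names
    to a person in whom a new causal allele arises (a recent,
    lineage-founding mutation on that person's first allele copy); the
    fresh label is transmitted to descendants like any other allele, so
    the variant is private to that person's lineage.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    order, pos, steps = _drop_order(pedigree)
    n = len(order)
    alleles = np.zeros((n, 2), dtype=np.int64)
    label = 0
    founder_allele_labels: dict[str, tuple[int, int]] = {}
    for pid in order:
        if pedigree.individuals[pid].is_founder:
            alleles[pos[pid]] = (label, label + 1)
            founder_allele_labels[pid] = (label, label + 1)
            label += 2
    causal: dict[str, set[int]] = {}
    mut_at: dict[str, list[str]] = {}
    for variant, pid in (mutations or {}).items():
        if pid not in pedigree.individuals:
            raise ValueError(f"mutation carrier {pid} not in family "
                             f"{pedigree.family_id}")
        mut_at.setdefault(pid, []).append(variant)
    parent_step = {k: (f, m) for k, f, m in steps}
    for pid in order:
        k = pos[pid]
        if k in parent_step:
            f, m = parent_step[k]
            alleles[k, 0] = alleles[f, rng.integers(0, 2)]
            alleles[k, 1] = alleles[m, rng.integers(0, 2)]
        for variant in mut_at.get(pid, ()):
            alleles[k, 0] = label
            causal.setdefault(variant, set()).add(label)
            label += 1
    if founder_carriers is None:
        pass
    elif np.isscalar(founder_carriers):
        freq = float(founder_carriers)
        if not 0.0 <= freq <= 1.0:
            raise ValueError(f"allele frequency {freq} outside [0, 1]")
        labs = set()
        for a, b in founder_allele_labels.values():
            if rng.random() < freq:
                labs.add(a)
            if rng.random() < freq:
                labs.add(b)
        causal["v"] = labs
    else:
        for variant, assignment in founder_carriers.items():
            labs = set()
            for fid, copies in assignment.items():
                if fid not in founder_allele_labels:
                    raise ValueError(f"{fid} is not a founder of family "
                                     f"{pedigree.family_id}")
                pair = founder_allele_labels[fid]
                if copies not in (0, 1, 2):
                    raise ValueError("founder copies must be 0, 1 or 2")
                labs.update(pair[:copies])
            causal[variant] = labs
    # reorder rows to pedigree id order
    perm = np.array([pos[pid] for pid in pedigree.ids])
    return GeneDropResult(pedigree.family_id, pedigree.ids, alleles[perm],
                          causal)


def ibd_matrix(drop: GeneDropResult) -> np.ndarray:
    """Pairwise IBD proportions pi-hat in {0, 0.5, 1}; pi-hat(i,i) = 1."""
    a = drop.alleles
    a0, a1 = a[:, 0], a[:, 1]
    m_same = ((a0[:, None] == a0[None, :]).astype(np.int8)
              + (a1[:, None] == a1[None, :]).astype(np.int8))
    m_cross = ((a0[:, None] == a1[None, :]).astype(np.int8)
               + (a1[:, None] == a0[None, :]).astype(np.int8))
    pi = np.maximum(m_same, m_cross) / 2.0
    np.fill_diagonal(pi, 1.0)
    return pi


def gene_drop_ibd(pedigree: Pedigree, n_reps: int,
                  rng: np.random.Generator | None = None,
                  seed: int | None = None):
    """Monte-Carlo mean and SE of pairwise IBD proportions over many drops.

    Vectorized over replicates; the mean/2 is the gene-dropping estimate
    of the kinship coefficient (oracle for the recursive algorithm).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    order, pos, steps = _drop_order(pedigree)
    n = len(order)
    alleles = np.zeros((n_reps, n, 2), dtype=np.int32)
    label = 0
    for pid in order:
        if pedigree.individuals[pid].is_founder:
            alleles[:, pos[pid], 0] = label
            alleles[:, pos[pid], 1] = label + 1
            label += 2
    for k, f, m in steps:
        pick_f = rng.integers(0, 2, size=n_reps)
        pick_m = rng.integers(0, 2, size=n_reps)
        rows = np.arange(n_reps)
        alleles[:, k, 0] = alleles[rows, f, pick_f]
        alleles[:, k, 1] = alleles[rows, m, pick_m]
    perm = np.array([pos[pid] for pid in pedigree.ids])
    alleles = alleles[:, perm, :]
    mean = np.ones((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        ai0, ai1 = alleles[:, i, 0], alleles[:, i, 1]
        for j in range(i + 1, n):
            bj0, bj1 = alleles[:, j, 0], alleles[:, j, 1]
            straight = (ai0 == bj0).astype(np.int8) + (ai1 == bj1).astype(np.int8)
            crossed = (ai0 == bj1).astype(np.int8) + (ai1 == bj0).astype(np.int8)
            pi = np.maximum(straight, crossed) / 2.0
            mean[i, j] = mean[j, i] = pi.mean()
            se[i, j] = se[j, i] = pi.std(ddof=1) / np.sqrt(n_reps)
    return mean, se


# ---------------------------------------------------------------------------
# variance-component linkage


@dataclass
class FamilyLod:
    family_id: str
    lod: float
    sigma2_q: float = 0.0
    converged: bool = True
    message: str = ""


def _profile_ll(V: np.ndarray, y: np.ndarray) -> float:
    """Restricted Gaussian log-likelihood with the family mean profiled out.

    The REML term -0.5*log(1' V^-1 1) accounts for the degree of freedom
    the per-family mean absorbs; without it the many small-family means
    make variance-ratio LODs anti-conservative.
    """
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    n = len(y)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    one = np.ones(n)
    a = np.linalg.solve(L, np.column_stack([y, one]))
    yy = a[:, 0] @ a[:, 0]
    oy = a[:, 1] @ a[:, 0]
    oo = a[:, 1] @ a[:, 1]
    quad = yy - oy * oy / oo
    return -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet + quad + np.log(oo))


def _fit_vc(y, mats, x0, bounds):
    def neg(theta):
        V = sum(t * M for t, M in zip(theta, mats))
        ll = _profile_ll(V, y)
        return np.inf if not np.isfinite(ll) else -ll

    best = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                             options={"maxiter": 300, "ftol": 1e-11})
    for x_alt in (np.array(x0) * 0.2 + 1e-3, np.array(x0) * 3.0):
        r = optimize.minimize(neg, np.clip(x_alt, [b[0] for b in bounds],
                                           [b[1] for b in bounds]),
                              method="L-BFGS-B", bounds=bounds,
                              options={"maxiter": 300, "ftol": 1e-11})
        if r.fun < best.fun - 1e-10:
            best = r
    return best


def family_vc_lod(y: np.ndarray, ibd: np.ndarray, kin2: np.ndarray,
                  family_id: str = "fam") -> FamilyLod:
    """Variance-component linkage LOD for one family.

    ``ibd`` is the locus IBD-proportion matrix Pi, ``kin2`` the additive
    relationship matrix 2*Phi restricted to the same phenotyped members.
    """
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        return FamilyLod(family_id, float("nan"), converged=False,
                         message="fewer than 3 phenotyped members")
    vy = max(float(np.var(y, ddof=1)), 1e-12)
    I = np.eye(n)
    hi = 20.0 * vy
    floor_e = 1e-8 * vy
    null = _fit_vc(y, [kin2, I], [0.3 * vy, 0.7 * vy],
                   [(0.0, hi), (floor_e, hi)])
    full = _fit_vc(y, [ibd, kin2, I],
                   [1e-6 * vy, *np.clip(null.x, floor_e, hi)],
                   [(0.0, hi), (0.0, hi), (floor_e, hi)])
    if not (np.isfinite(null.fun) and np.isfinite(full.fun)):
        return FamilyLod(family_id, float("nan"), converged=False,
                         message="variance-component fit failed")
    lod = (null.fun - full.fun) / np.log(10.0)  # both are negative lls
    if lod < 0:
        lod = 0.0 if lod > -1e-6 else lod
    if full.x[0] <= 1e-10 * vy or lod < 1e-6:
        lod = 0.0
    return FamilyLod(family_id, float(lod), sigma2_q=float(full.x[0]))


def study_vc_lods(families: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]]
                  ) -> tuple[float, list[FamilyLod]]:
    """Admixture-aware joint linkage scan: per-family LOD scores under a
    shared QTL variance chosen to maximize the heterogeneity likelihood.

    ``families`` holds (family_id, y, Pi, 2*Phi) tuples.  Background
    components (sigma2_g, sigma2_e) are ML-fitted jointly under no
    linkage; per-family LOD curves over the locus variance sigma2_q are
    then combined in the admixture likelihood

        sum_f log10( alpha * 10^lod_f(sq) + (1 - alpha) ),

    maximized over both alpha and sq.  Per-family LODs are reported at
    the maximizing sq; they can be negative for families whose
    phenotype covariance argues against linkage -- the behaviour
    family-specific heterogeneity LOD scores rely on.  At the sq = 0
    boundary every LOD is exactly 0.  Returns (homogeneity LOD = sum of
    per-family LODs at sq-hat, per-family LODs).
    """
    if not families:
        raise ValueError("no families supplied")
    data = []
    vtot = []
    for fam, y, pi, kin2 in families:
        y = np.asarray(y, float)
        data.append((fam, y, np.asarray(pi, float), np.asarray(kin2, float),
                     np.eye(len(y))))
        vtot.append(np.var(y, ddof=1))
    vy = max(float(np.mean(vtot)), 1e-12)
    hi = 20.0 * vy
    floor_e = 1e-8 * vy

    sg, se = fit_polygenic_background(
        [(y, kin2) for _, y, _, kin2, _ in data])
    ll0 = np.array([_profile_ll(sg * kin2 + se * I, y)
                    for _, y, _, kin2, I in data])

    def lod_curve(sq: float) -> np.ndarray:
        ll = np.array([_profile_ll(sq * pi + sg * kin2 + se * I, y)
                       for _, y, pi, kin2, I in data])
        return (ll - ll0) / np.log(10.0)

    def admixture_max(lods: np.ndarray) -> float:
        a = np.linspace(0.0, 1.0, 201)[:, None]
        terms = a * np.power(10.0, lods)[None, :] + (1.0 - a)
        return float(np.max(np.sum(np.log10(np.maximum(terms, 1e-300)),
                                   axis=1)))

    sq_grid = np.concatenate([[0.0], np.geomspace(0.01 * vy, hi, 30)])
    best_sq, best_val = 0.0, 0.0
    for sq in sq_grid:
        val = admixture_max(lod_curve(sq)) if sq > 0 else 0.0
        if val > best_val + 1e-12:
            best_sq, best_val = float(sq), val
    if best_sq > 0:  # local refinement around the best grid point
        k = int(np.argmin(np.abs(sq_grid - best_sq)))
        lo = sq_grid[max(k - 1, 0)]
        hi_b = sq_grid[min(k + 1, len(sq_grid) - 1)]
        res = optimize.minimize_scalar(
            lambda s: -admixture_max(lod_curve(s)), bounds=(max(lo, 1e-12), hi_b),
            method="bounded", options={"xatol": 1e-4 * vy})
        if -res.fun > best_val:
            best_sq, best_val = float(res.x), float(-res.fun)
    if best_sq <= 0 or best_val <= 1e-9:
        lods = [FamilyLod(fam, 0.0, sigma2_q=0.0) for fam, *_ in data]
        return 0.0, lods
    per = lod_curve(best_sq)
    lods = [FamilyLod(fam, float(l), sigma2_q=best_sq)
            for (fam, *_), l in zip(data, per)]
    return float(per.sum()), lods


# ---------------------------------------------------------------------------
# admixture HLOD


@dataclass
class HlodResult:
    alpha_hat: float
    hlod: float
    per_family: list[FamilyLod]
    driving_families: list[str]

    def summary(self) -> dict:
        return {"alpha_hat": self.alpha_hat, "hlod": self.hlod,
                "n_families": len(self.per_family),
                "driving_families": self.driving_families}


def hlod(per_family, alpha_grid: np.ndarray | None = None,
         refine: bool = False) -> HlodResult:
    """Admixture heterogeneity LOD over a grid of alpha values.

    The default 1001-point grid is evaluated exactly; ties resolve to the
    smallest alpha.  ``refine=True`` adds a bounded local polish around
    the grid argmax (off by default so the reported maximum is the exact
    grid maximum).
    """
    fams = [f if isinstance(f, FamilyLod) else FamilyLod(str(i), float(f))
            for i, f in enumerate(per_family)]
    lods = np.array([f.lod for f in fams if np.isfinite(f.lod)])
    if lods.size == 0:
        raise ValueError("no finite family LODs")
    if alpha_grid is None:
        alpha_grid = np.linspace(0.0, 1.0, 1001)
    ratios = np.power(10.0, lods)

    def objective(alpha):
        a = np.atleast_1d(np.asarray(alpha, float))[:, None]
        terms = a * ratios[None, :] + (1.0 - a)
        return np.sum(np.log10(np.maximum(terms, 1e-300)), axis=1)

    vals = objective(alpha_grid)
    k = int(np.argmax(vals))  # argmax returns first (= smallest alpha) on ties
    alpha_hat, best = float(alpha_grid[k]), float(vals[k])
    if refine:
        lo = alpha_grid[max(k - 1, 0)]
        hi = alpha_grid[min(k + 1, len(alpha_grid) - 1)]
        res = optimize.minimize_scalar(lambda a: -objective(a)[0],
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-12})
        if -res.fun > best:
            alpha_hat, best = float(res.x), float(-res.fun)
    hl = max(best, 0.0)
    driving = [f.family_id for f in fams
               if np.isfinite(f.lod) and f.lod > DRIVING_LOD_THRESHOLD]
    return HlodResult(alpha_hat, hl, fams, driving)


# ---------------------------------------------------------------------------
# pooled single-variant association comparator


def single_variant_association(y: np.ndarray, dosage: np.ndarray):
    """Linear score test of a phenotype on carrier dosage, pooled sample.

    Returns (chi2 statistic, p value); (nan, nan) for a monomorphic
    variant.  This is the standard one-variant GWAS-style test that the
    rare lineage-specific scenario defeats.
    """
    y = np.asarray(y, float)
    x = np.asarray(dosage, float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3 or np.ptp(x) == 0:
        return float("nan"), float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    u = xc @ yc
    v = (yc @ yc / len(y)) * (xc @ xc)
    if v <= 0:
        return float("nan"), float("nan")
    stat = u * u / v
    return float(stat), float(chi2.sf(stat, 1))


def min_association_p(y: np.ndarray, dosages: pd.DataFrame):
    """Minimum single-variant p across a set of variants (pooled sample)."""
    best_p, best_v = float("nan"), None
    for var in dosages.columns:
        _, p = single_variant_association(y, dosages[var].to_numpy())
        if np.isfinite(p) and (not np.isfinite(best_p) or p < best_p):
            best_p, best_v = p, var
    return best_p, best_v


def fit_polygenic_background(blocks: list[tuple[np.ndarray, np.ndarray]]
                             ) -> tuple[float, float]:
    """Joint ML fit of (sigma2_g, sigma2_e) for y ~ N(mu, 2*Phi*sg + I*se)
    over independent family blocks (mu profiled per block)."""
    vy = max(float(np.mean([np.var(y, ddof=1) for y, _ in blocks])), 1e-12)
    hi = 20.0 * vy
    floor_e = 1e-8 * vy

    def neg(theta):
        tot = 0.0
        for y, kin2 in blocks:
            ll = _profile_ll(theta[0] * kin2 + theta[1] * np.eye(len(y)), y)
            if not np.isfinite(ll):
                return np.inf
            tot -= ll
        return tot

    res = optimize.minimize(neg, [0.3 * vy, 0.7 * vy], method="L-BFGS-B",
                            bounds=[(0.0, hi), (floor_e, hi)],
                            options={"maxiter": 300, "ftol": 1e-11})
    sg, se = res.x
    return float(max(sg, 0.0)), float(max(se, floor_e))


def kinship_adjusted_association(
        families: list[tuple[str, np.ndarray, np.ndarray]],
        dosages: dict[str, tuple[str, np.ndarray]],
        background: tuple[float, float] | None = None) -> pd.DataFrame:
    """Mixed-model single-variant score tests in a family cohort.

    The standard association analysis for related samples: a polygenic
    background y ~ N(mu, 2*Phi*sigma2_g + I*sigma2_e) is fitted once
    (or supplied), and each variant's dosage is score-tested under the
    fitted covariance by generalized least squares.  ``families`` holds
    (family_id, y, 2*Phi) blocks; ``dosages`` maps variant name ->
    (family_id, dosage vector within that family) for family-private
    variants (zero dosage elsewhere).  Returns a DataFrame with the
    chi-square statistic and p value per variant.
    """
    empty = pd.DataFrame(columns=["stat", "p"],
                         index=pd.Index([], name="variant"))
    if not dosages:
        return empty
    if background is None:
        background = fit_polygenic_background([(y, k) for _, y, k in families])
    sg, se = background
    Vinv = {}
    o_sum = 0.0
    oy_sum = 0.0
    for fam, y, kin2 in families:
        Vi = np.linalg.inv(sg * kin2 + se * np.eye(len(y)))
        Vinv[fam] = Vi
        one = np.ones(len(y))
        o_sum += one @ Vi @ one
        oy_sum += one @ Vi @ y
    mu = oy_sum / o_sum
    ydict = {fam: y for fam, y, _ in families}
    rows = []
    for var, (fam, dose) in sorted(dosages.items()):
        if fam not in Vinv or np.ptp(dose) == 0:
            rows.append({"variant": var, "stat": np.nan, "p": np.nan})
            continue
        Vi = Vinv[fam]
        one = np.ones(len(dose))
        xc = dose - (one @ Vi @ dose) / (one @ Vi @ one) * one
        r = ydict[fam] - mu
        u = xc @ Vi @ r
        v = xc @ Vi @ xc
        if v <= 0:
            rows.append({"variant": var, "stat": np.nan, "p": np.nan})
            continue
        stat = u * u / v
        rows.append({"variant": var, "stat": float(stat),
                     "p": float(chi2.sf(stat, 1))})
    return pd.DataFrame(rows).set_index("variant")
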