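"""Polygenic variance-component heritability under the kinship model.

The model for an adjusted person-level phenotype y (a visit value, an
OLS slope, or a growth-curve slope) is

    y ~ N(mu 1, 2*Phi*sigma2_g + I*sigma2_e),       h2 = sigma2_g / (sigma2_g + sigma2_e)

with Phi the pedigree kinship matrix.  Because families are independent,
2*Phi is block diagonal; each family block is eigendecomposed once, the
likelihood becomes a weighted sum over eigenvalues, and the REML
objective is profiled down to a one-dimensional search over h2 in [0, 1]
(the total variance has a closed-form profile).  Mortality/ascertainment
selection is ignored, and estimates are conditional on having both
visits when the caller applies that restriction -- both deliberate
assumptions of the source workflow.  The likelihood-ratio test against
sigma2_g = 0 uses the 1/2 chi2_0 + 1/2 chi2_1 boundary mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .pedigree import KinshipMatrix

__all__ = ["HeritabilityEstimate", "polygenic_reml", "reml_profile",
           "heritability_table", "HeritabilityError"]

EIG_FLOOR = 1e-10


class HeritabilityError(ValueError):
    pass


@dataclass
class HeritabilityEstimate:
    trait_name: str
    n_used: int
    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    loglik: float
    lrt_p: float

    def as_dict(self) -> dict:
        return {"trait": self.trait_name, "n": self.n_used,
                "sigma2_g": self.sigma2_g, "sigma2_e": self.sigma2_e,
                "h2": self.h2, "se_h2": self.se_h2,
                "loglik": self.loglik, "lrt_p": self.lrt_p}


class _Spectral:
    """Eigen-transformed data: per-family U'y, U'1 and eigenvalues of 2*Phi."""

    def __init__(self, values: pd.Series, kin: KinshipMatrix):
        ids = [i for i in kin.ids if i in values.index and pd.notna(values[i])]
        if len(ids) < 2:
            raise HeritabilityError("fewer than 2 phenotyped individuals")
        keep = set(ids)
        lam, yt, xt = [], [], []
        fam_count = 0
        for fam, fids, A in kin.family_blocks():
            sel = [k for k, fid in enumerate(fids) if fid in keep]
            if not sel:
                continue
            fam_count += 1
            Af = A[np.ix_(sel, sel)]
            yf = values[[fids[k] for k in sel]].to_numpy(float)
            d, U = np.linalg.eigh(Af)
            d = np.clip(d, EIG_FLOOR, None)
            lam.append(d)
            yt.append(U.T @ yf)
            xt.append(U.T @ np.ones(len(sel)))
        self.lam = np.concatenate(lam)
        self.yt = np.concatenate(yt)
        self.xt = np.concatenate(xt)
        self.n = len(self.lam)
        self.n_families = fam_count
        if np.max(np.abs(self.lam - 1.0)) < 1e-6:
            raise HeritabilityError(
                "sigma2_g and sigma2_e are confounded: all individuals are "
                "mutually unrelated (2*Phi = I)")

    def loglik(self, h2: float) -> float:
        """Profiled REML log-likelihood at heritability h2."""
        w = h2 * self.lam + (1.0 - h2)
        w = np.maximum(w, EIG_FLOOR)
        sxx = np.sum(self.xt ** 2 / w)
        mu = np.sum(self.xt * self.yt / w) / sxx
        r = self.yt - mu * self.xt
        rss = np.sum(r * r / w)
        n1 = self.n - 1
        s2 = max(rss / n1, 1e-300)
        return -0.5 * (n1 * (np.log(2 * np.pi) + np.log(s2) + 1.0)
                       + np.sum(np.log(w)) + np.log(sxx))

    def total_var(self, h2: float) -> float:
        w = np.maximum(h2 * self.lam + (1.0 - h2), EIG_FLOOR)
        sxx = np.sum(self.xt ** 2 / w)
        mu = np.sum(self.xt * self.yt / w) / sxx
        r = self.yt - mu * self.xt
        return float(np.sum(r * r / w) / (self.n - 1))


def reml_profile(values: pd.Series, kinship: KinshipMatrix,
                 grid: np.ndarray) -> np.ndarray:
    """Profiled REML log-likelihood over a grid of h2 values (oracle hook)."""
    sp = _Spectral(values, kinship)
    return np.array([sp.loglik(float(h)) for h in grid])


def polygenic_reml(values: pd.Series, kinship: KinshipMatrix,
                   trait_name: str = "trait", min_n: int = 30,
                   tol: float = 1e-8) -> HeritabilityEstimate:
    """REML heritability of a person-level phenotype.

    ``values`` is indexed by person id; missing values and persons absent
    from the kinship matrix are dropped.  Requires >= ``min_n``
    phenotyped individuals spanning >= 2 families.
    """
    sp = _Spectral(values.dropna(), kinship)
    if sp.n < min_n:
        raise HeritabilityError(
            f"{trait_name}: only {sp.n} phenotyped individuals (< {min_n})")
    if sp.n_families < 2:
        raise HeritabilityError(f"{trait_name}: phenotypes span < 2 families")

    neg = lambda h: -sp.loglik(float(h))
    # coarse grid to localize, then bounded refinement; endpoints checked
    hs = np.linspace(0.0, 1.0, 21)
    vals = np.array([neg(h) for h in hs])
    k = int(np.argmin(vals))
    lo, hi = max(0.0, hs[k] - 0.05), min(1.0, hs[k] + 0.05)
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    h_hat, best = float(res.x), float(res.fun)
    for h_end in (0.0, 1.0):
        if neg(h_end) <= best + 1e-12:
            h_hat, best = h_end, neg(h_end)
    if h_hat < 1e-6:
        h_hat = 0.0
    elif h_hat > 1 - 1e-6:
        h_hat = 1.0
    ll = sp.loglik(h_hat)
    s2 = sp.total_var(h_hat)
    lrt = 2.0 * (ll - sp.loglik(0.0))
    lrt_p = 1.0 if lrt <= 0 else float(0.5 * chi2.sf(lrt, 1))
    if 1e-4 < h_hat < 1 - 1e-4:
        eps = 1e-4
        d2 = (sp.loglik(h_hat + eps) - 2.0 * ll + sp.loglik(h_hat - eps)) / eps ** 2
        se = float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("nan")
    else:
        se = float("nan")
    return HeritabilityEstimate(
        trait_name=trait_name, n_used=sp.n, sigma2_g=float(h_hat * s2),
        sigma2_e=float((1.0 - h_hat) * s2), h2=float(h_hat), se_h2=se,
        loglik=float(ll), lrt_p=lrt_p)


def heritability_table(phenotypes: dict[str, pd.Series], kinship: KinshipMatrix,
                       require_both_visits: bool = True,
                       gc_correlations: dict[int, float] | None = None,
                       min_n: int = 30) -> pd.DataFrame:
    """Heritability of each phenotype in the cross-sectional/longitudinal layout.

    ``phenotypes`` maps column names (e.g. visit1, visit2, gc_slope,
    ols_slope) to person-indexed adjusted values.  With
    ``require_both_visits`` every estimate is restricted to persons
    non-missing for *all* supplied phenotypes, mirroring the
    conditional-heritability convention; measured-vs-GC correlations are
    attached as columns when supplied.
    """
    if require_both_visits:
        common = None
        for s in phenotypes.values():
            idx = set(s.dropna().index)
            common = idx if common is None else (common & idx)
        common = sorted(common)
    rows = []
    for name, s in phenotypes.items():
        s_use = s[s.index.isin(common)] if require_both_visits else s
        try:
            est = polygenic_reml(s_use, kinship, trait_name=name, min_n=min_n)
            row = est.as_dict()
            row["status"] = "ok"
        except HeritabilityError as e:
            row = {"trait": name, "n": int(s_use.notna().sum()),
                   "sigma2_g": np.nan, "sigma2_e": np.nan, "h2": np.nan,
                   "se_h2": np.nan, "loglik": np.nan, "lrt_p": np.nan,
                   "status": f"failed: {e}"}
        rows.append(row)
    out = pd.DataFrame(rows).set_index("trait")
    if gc_correlations:
        for visit, corr in gc_correlations.items():
            out[f"corr_measured_gc_visit{visit}"] = np.nan
            key = f"visit{visit}"
            if key in out.index:
                out.loc[key, f"corr_measured_gc_visit{visit}"] = corr
    return out
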