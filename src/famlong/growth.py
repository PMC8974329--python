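"""Phenotype preprocessing and individual longitudinal change estimation.

Two estimators of each person's rate of change are provided:

* the naive per-person OLS slope, Delta = (P2 - P1) / years, with
  years = (date2 - date1) / 365.25 -- measurement errors at the two
  visits accumulate in this difference, they do not cancel;
* the random-coefficient (growth-curve) model,

      y_ij = (b0 + u_i0) + (b1 + u_i1) t_ij + e_ij,
      (u_i0, u_i1) ~ N(0, G),  e_ij ~ N(0, sigma2_e),

  fitted by REML with a log-Cholesky parameterization of G, returning
  empirical-Bayes (BLUP) per-person intercepts and slopes.  Shrinkage
  toward the population mean trajectory trades bias for a large
  reduction in error variance, which is what preserves the heritability
  of longitudinal change downstream.

Preprocessing implements the cohort's trait-specific rules: blood
pressure medication adjustments (SBP+15, DBP+10 on antihypertensives),
diabetes-based exclusion of glycemic traits (fasting glucose >= 126
mg/dL, HbA1c >= 6.5, reported diagnosis, or diabetes medication),
missingness of lipid traits under lipid-lowering medication or
non-fasting, and residualization on sex, age, age squared, and field
site (same-visit age for visit values, baseline age for slopes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "VisitRecord", "GrowthCurveFit", "SlopePhenotype", "TraitRules",
    "TRAIT_REGISTRY", "register_trait", "apply_medication_adjustment",
    "apply_exclusions", "residualize", "ols_slope", "ols_slopes_table",
    "fit_rcm", "gc_fitted_vs_measured", "RcmIdentifiabilityWarning",
    "RcmConvergenceError", "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.25


class RcmIdentifiabilityWarning(UserWarning):
    pass


class RcmConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# records and trait rules


@dataclass
class VisitRecord:
    person_id: str
    visit: int
    visit_date: date | None
    value: float | None
    age_at_visit: float | None = None
    sex: str | None = None
    field_site: str | None = None
    fasting: bool | None = None
    meds: frozenset = frozenset()          # {"antihypertensive", "lipid_lowering", "diabetes"}
    diabetes_dx: bool | None = None
    glucose: float | None = None           # companion labs for the diabetes rule
    hba1c: float | None = None
    provenance: tuple = ()


@dataclass(frozen=True)
class TraitRules:
    name: str
    med_adjustment: float = 0.0            # added when on antihypertensives
    glycemic: bool = False                 # excluded for diabetics
    lipid: bool = False                    # excluded on lipid meds / non-fasting
    fasting_required: bool = False


TRAIT_REGISTRY: dict[str, TraitRules] = {}


def register_trait(rules: TraitRules) -> None:
    TRAIT_REGISTRY[rules.name] = rules


for _r in [
    TraitRules("sbp", med_adjustment=15.0),
    TraitRules("dbp", med_adjustment=10.0),
    TraitRules("pulse_pressure"),
    TraitRules("pulse_rate"),
    TraitRules("glucose", glycemic=True, fasting_required=True),
    TraitRules("hba1c", glycemic=True),
    TraitRules("total_cholesterol", lipid=True, fasting_required=True),
    TraitRules("ldl", lipid=True, fasting_required=True),
    TraitRules("hdl", lipid=True, fasting_required=True),
    TraitRules("triglycerides", lipid=True, fasting_required=True),
    TraitRules("bmi"),
    TraitRules("weight"),
    TraitRules("grip_strength"),
    TraitRules("fev1"),
    TraitRules("gait_speed"),
    TraitRules("sim_trait"),               # synthetic-pipeline phenotype
]:
    register_trait(_r)


def _rules(phenotype_name: str) -> TraitRules:
    try:
        return TRAIT_REGISTRY[phenotype_name]
    except KeyError:
        raise KeyError(
            f"unknown phenotype {phenotype_name!r}; register it with "
            "register_trait() first") from None


def apply_medication_adjustment(record: VisitRecord,
                                phenotype_name: str) -> VisitRecord:
    """Blood-pressure medication adjustment (SBP+15, DBP+10); no-op otherwise."""
    rules = _rules(phenotype_name)
    if (rules.med_adjustment and record.value is not None
            and "antihypertensive" in record.meds):
        return replace(record, value=record.value + rules.med_adjustment,
                       provenance=record.provenance
                       + (f"+{rules.med_adjustment:g} antihypertensive",))
    return record


def is_diabetic(record: VisitRecord) -> bool:
    """Four-part diabetes rule: fasting glucose >= 126, HbA1c >= 6.5,
    reported diagnosis, or diabetes medication."""
    if record.diabetes_dx:
        return True
    if "diabetes" in record.meds:
        return True
    glu = record.glucose
    if glu is None and record.fasting:
        # if this record *is* a glucose measurement, use its own value
        pass
    if glu is not None and record.fasting and glu >= 126.0:
        return True
    if record.hba1c is not None and record.hba1c >= 6.5:
        return True
    return False


def apply_exclusions(record: VisitRecord, phenotype_name: str) -> VisitRecord:
    """Set the value to missing per the trait's exclusion rules."""
    rules = _rules(phenotype_name)
    if record.value is None:
        return record
    rec = record
    if phenotype_name == "glucose" and rec.glucose is None:
        rec = replace(rec, glucose=rec.value)
    if phenotype_name == "hba1c" and rec.hba1c is None:
        rec = replace(rec, hba1c=rec.value)
    if rules.glycemic:
        if is_diabetic(rec):
            return replace(record, value=None,
                           provenance=record.provenance + ("excluded: diabetes",))
        if rules.fasting_required and rec.fasting is not None and not rec.fasting:
            return replace(record, value=None,
                           provenance=record.provenance + ("excluded: non-fasting",))
    if rules.lipid:
        if "lipid_lowering" in rec.meds:
            return replace(record, value=None,
                           provenance=record.provenance
                           + ("excluded: lipid-lowering medication",))
        if rec.fasting is not None and not rec.fasting:
            return replace(record, value=None,
                           provenance=record.provenance + ("excluded: non-fasting",))
    return record


# ---------------------------------------------------------------------------
# covariate residualization


def residualize(df: pd.DataFrame, value_col: str, *, sex_col: str = "sex",
                age_col: str = "age", site_col: str = "field_site",
                include_age_sq: bool = True) -> pd.Series:
    """Residuals from a linear adjustment on sex, age, age^2 and field site.

    Sex and field site enter as categorical effects, age and age squared
    as continuous.  For visit-level values pass the same-visit age; for
    slope phenotypes pass the baseline (Visit 1) age.
    """
    sub = df[[value_col, sex_col, age_col, site_col]].dropna()
    if sub.empty:
        raise ValueError("no complete records to residualize")
    counts = sub[site_col].value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"field-site level(s) with < 2 observations: {list(thin.index)}")
    y = sub[value_col].to_numpy(float)
    age = sub[age_col].to_numpy(float)
    cols = [np.ones_like(y), age]
    if include_age_sq:
        cols.append(age ** 2)
    for frame, col in ((sub, sex_col), (sub, site_col)):
        d = pd.get_dummies(frame[col].astype(str), drop_first=True)
        for c in d.columns:
            cols.append(d[c].to_numpy(float))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=sub.index, name=value_col)


# ---------------------------------------------------------------------------
# naive OLS slope


@dataclass
class SlopePhenotype:
    person_id: str
    ols_slope: float | None
    gc_intercept: float | None = None
    gc_slope: float | None = None
    years_between: float | None = None
    reason: str | None = None


def ols_slope(v1: VisitRecord, v2: VisitRecord) -> SlopePhenotype:
    """Per-person change per year: (P2 - P1) / ((date2 - date1)/365.25)."""
    if v1.value is None or v2.value is None:
        return SlopePhenotype(v1.person_id, None, reason="incomplete pair")
    if v1.visit_date is None or v2.visit_date is None:
        return SlopePhenotype(v1.person_id, None, reason="missing visit date")
    days = (v2.visit_date - v1.visit_date).days
    if days <= 0:
        raise ValueError(
            f"{v1.person_id}: Visit 2 date {v2.visit_date} not after "
            f"Visit 1 date {v1.visit_date}")
    years = days / DAYS_PER_YEAR
    return SlopePhenotype(v1.person_id, (v2.value - v1.value) / years,
                          years_between=years)


def ols_slopes_table(df: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Vectorized OLS slopes from a long table with person_id/visit/visit_date."""
    wide_v = df.pivot_table(index="person_id", columns="visit", values=value_col,
                            aggfunc="first")
    dates = df.pivot_table(index="person_id", columns="visit",
                           values="visit_date", aggfunc="first")
    out = pd.DataFrame(index=wide_v.index)
    have = {1, 2}.issubset(wide_v.columns)
    if have:
        d1 = pd.to_datetime(dates[1])
        d2 = pd.to_datetime(dates[2])
        years = (d2 - d1).dt.days / DAYS_PER_YEAR
        if (years.dropna() <= 0).any():
            bad = years.index[years <= 0].tolist()
            raise ValueError(f"non-positive inter-visit time for {bad}")
        out["years_between"] = years
        out["ols_slope"] = (wide_v[2] - wide_v[1]) / years
    else:
        out["years_between"] = np.nan
        out["ols_slope"] = np.nan
    return out


# ---------------------------------------------------------------------------
# random-coefficient (growth-curve) model


@dataclass
class GrowthCurveFit:
    beta: np.ndarray                 # (intercept, slope)
    G: np.ndarray                    # 2x2 random-effect covariance
    sigma2_e: float
    per_person: dict[str, tuple[float, float]]   # id -> (blup_int, blup_slope)
    loglik: float
    n_obs: int
    n_persons: int
    converged: bool
    n_iter: int
    grad_norm: float

    @property
    def slope_corr(self) -> float:
        d = np.sqrt(self.G[0, 0] * self.G[1, 1])
        return float(self.G[0, 1] / d) if d > 0 else 0.0

    def blup_frame(self) -> pd.DataFrame:
        ids = list(self.per_person)
        arr = np.array([self.per_person[i] for i in ids])
        return pd.DataFrame(
            {"gc_intercept": self.beta[0] + arr[:, 0],
             "gc_slope": self.beta[1] + arr[:, 1]},
            index=pd.Index(ids, name="person_id"))


def _unpack(x):
    a, b, c, d = x
    la, lc = np.exp(a), np.exp(c)
    g00 = la * la
    g01 = b * la
    g11 = b * b + lc * lc
    s = np.exp(2.0 * d)
    return g00, g01, g11, s


class _RcmData:
    """Per-person grouped views; fast paths for 1- and 2-observation persons."""

    def __init__(self, person_ids, t, y):
        person_ids = np.asarray(person_ids)
        t = np.asarray(t, float)
        y = np.asarray(y, float)
        order = np.argsort(person_ids, kind="stable")
        person_ids, t, y = person_ids[order], t[order], y[order]
        self.ids, starts, counts = np.unique(person_ids, return_index=True,
                                             return_counts=True)
        self.n_obs = len(y)
        self.n_persons = len(self.ids)
        one = counts == 1
        two = counts == 2
        self.t1o = t[starts[one]]
        self.y1o = y[starts[one]]
        self.ids_one = self.ids[one]
        s2 = starts[two]
        self.ta, self.tb = t[s2], t[s2 + 1]
        self.ya, self.yb = y[s2], y[s2 + 1]
        self.ids_two = self.ids[two]
        other = ~(one | two)
        self.general = []
        for s0, c0, pid in zip(starts[other], counts[other], self.ids[other]):
            self.general.append((pid, t[s0:s0 + c0], y[s0:s0 + c0]))
        self.var_y = float(np.var(y)) if len(y) else 0.0
        self.dt2 = self.tb - self.ta


_PENALTY = 1e15  # finite "infeasible" value; keeps FD gradients finite


def _neg2reml(x, data: _RcmData):
    g00, g01, g11, s = _unpack(x)
    A = np.zeros((2, 2))
    bvec = np.zeros(2)
    quad = 0.0
    logdet = 0.0
    if len(data.t1o):
        t, y = data.t1o, data.y1o
        v = g00 + 2 * g01 * t + g11 * t * t + s
        if np.any(v <= 0):
            return _PENALTY
        iv = 1.0 / v
        A[0, 0] += np.sum(iv)
        A[0, 1] += np.sum(t * iv)
        A[1, 1] += np.sum(t * t * iv)
        bvec[0] += np.sum(y * iv)
        bvec[1] += np.sum(t * y * iv)
        quad += np.sum(y * y * iv)
        logdet += np.sum(np.log(v))
    if len(data.ta):
        t1, t2, y1, y2 = data.ta, data.tb, data.ya, data.yb
        V11 = g00 + 2 * g01 * t1 + g11 * t1 * t1 + s
        V22 = g00 + 2 * g01 * t2 + g11 * t2 * t2 + s
        V12 = g00 + g01 * (t1 + t2) + g11 * t1 * t2
        det = V11 * V22 - V12 * V12
        if np.any(det <= 0) or np.any(V11 <= 0):
            return _PENALTY
        w11, w22, w12 = V22 / det, V11 / det, -V12 / det
        r0 = w11 + w12          # X'W row pieces
        r1 = w12 + w22
        q0 = t1 * w11 + t2 * w12
        q1 = t1 * w12 + t2 * w22
        A[0, 0] += np.sum(r0 + r1)
        A[0, 1] += np.sum(r0 * t1 + r1 * t2)
        A[1, 1] += np.sum(q0 * t1 + q1 * t2)
        bvec[0] += np.sum(r0 * y1 + r1 * y2)
        bvec[1] += np.sum(q0 * y1 + q1 * y2)
        quad += np.sum(w11 * y1 * y1 + 2 * w12 * y1 * y2 + w22 * y2 * y2)
        logdet += np.sum(np.log(det))
    for _, t, y in data.general:
        Z = np.column_stack([np.ones_like(t), t])
        G = np.array([[g00, g01], [g01, g11]])
        V = Z @ G @ Z.T + s * np.eye(len(t))
        sign, ld = np.linalg.slogdet(V)
        if sign <= 0:
            return _PENALTY
        W = np.linalg.inv(V)
        A += Z.T @ W @ Z
        bvec += Z.T @ W @ y
        quad += y @ W @ y
        logdet += ld
    A[1, 0] = A[0, 1]
    detA = A[0, 0] * A[1, 1] - A[0, 1] ** 2
    if detA <= 0:
        return _PENALTY
    Ainv_b = np.linalg.solve(A, bvec)
    return logdet + np.log(detA) + quad - bvec @ Ainv_b


def _beta_hat(x, data: _RcmData):
    g00, g01, g11, s = _unpack(x)
    A = np.zeros((2, 2))
    bvec = np.zeros(2)
    if len(data.t1o):
        t, y = data.t1o, data.y1o
        iv = 1.0 / (g00 + 2 * g01 * t + g11 * t * t + s)
        A += np.array([[np.sum(iv), np.sum(t * iv)],
                       [np.sum(t * iv), np.sum(t * t * iv)]])
        bvec += np.array([np.sum(y * iv), np.sum(t * y * iv)])
    if len(data.ta):
        t1, t2, y1, y2 = data.ta, data.tb, data.ya, data.yb
        V11 = g00 + 2 * g01 * t1 + g11 * t1 * t1 + s
        V22 = g00 + 2 * g01 * t2 + g11 * t2 * t2 + s
        V12 = g00 + g01 * (t1 + t2) + g11 * t1 * t2
        det = V11 * V22 - V12 * V12
        w11, w22, w12 = V22 / det, V11 / det, -V12 / det
        r0, r1 = w11 + w12, w12 + w22
        q0, q1 = t1 * w11 + t2 * w12, t1 * w12 + t2 * w22
        A += np.array([[np.sum(r0 + r1), np.sum(r0 * t1 + r1 * t2)],
                       [np.sum(r0 * t1 + r1 * t2), np.sum(q0 * t1 + q1 * t2)]])
        bvec += np.array([np.sum(r0 * y1 + r1 * y2), np.sum(q0 * y1 + q1 * y2)])
    for _, t, y in data.general:
        Z = np.column_stack([np.ones_like(t), t])
        G = np.array([[g00, g01], [g01, g11]])
        W = np.linalg.inv(Z @ G @ Z.T + s * np.eye(len(t)))
        A += Z.T @ W @ Z
        bvec += Z.T @ W @ y
    return np.linalg.solve(A, bvec)


def _blups(x, beta, data: _RcmData) -> dict[str, tuple[float, float]]:
    g00, g01, g11, s = _unpack(x)
    out: dict[str, tuple[float, float]] = {}
    # with negligible residual variance the BLUP limit is each person's own
    # least-squares line; the V^-1 route loses precision there
    exact_fit = s <= 1e-9 * max(g00 + g11, 1e-300)
    if exact_fit:
        if len(data.ta):
            t1, t2, y1, y2 = data.ta, data.tb, data.ya, data.yb
            r1 = y1 - beta[0] - beta[1] * t1
            r2 = y2 - beta[0] - beta[1] * t2
            slope = (r2 - r1) / (t2 - t1)
            inter = r1 - slope * t1
            for pid, a0, a1 in zip(data.ids_two, inter, slope):
                out[pid] = (float(a0), float(a1))
        for pid, t, y in data.general:
            Z = np.column_stack([np.ones_like(t), t])
            r = y - Z @ beta
            u, *_ = np.linalg.lstsq(Z, r, rcond=None)
            out[pid] = (float(u[0]), float(u[1]))
        if len(data.t1o):
            t, y = data.t1o, data.y1o
            v = g00 + 2 * g01 * t + g11 * t * t + s
            r = (y - beta[0] - beta[1] * t) / v
            for pid, a0, a1 in zip(data.ids_one,
                                   (g00 + g01 * t) * r, (g01 + g11 * t) * r):
                out[pid] = (float(a0), float(a1))
        return out
    if len(data.t1o):
        t, y = data.t1o, data.y1o
        v = g00 + 2 * g01 * t + g11 * t * t + s
        r = (y - beta[0] - beta[1] * t) / v
        u0 = (g00 + g01 * t) * r
        u1 = (g01 + g11 * t) * r
        for pid, a0, a1 in zip(data.ids_one, u0, u1):
            out[pid] = (float(a0), float(a1))
    if len(data.ta):
        t1, t2, y1, y2 = data.ta, data.tb, data.ya, data.yb
        V11 = g00 + 2 * g01 * t1 + g11 * t1 * t1 + s
        V22 = g00 + 2 * g01 * t2 + g11 * t2 * t2 + s
        V12 = g00 + g01 * (t1 + t2) + g11 * t1 * t2
        det = V11 * V22 - V12 * V12
        w11, w22, w12 = V22 / det, V11 / det, -V12 / det
        r1 = y1 - beta[0] - beta[1] * t1
        r2 = y2 - beta[0] - beta[1] * t2
        wr1 = w11 * r1 + w12 * r2
        wr2 = w12 * r1 + w22 * r2
        u0 = (g00 + g01 * t1) * wr1 + (g00 + g01 * t2) * wr2
        u1 = (g01 + g11 * t1) * wr1 + (g01 + g11 * t2) * wr2
        for pid, a0, a1 in zip(data.ids_two, u0, u1):
            out[pid] = (float(a0), float(a1))
    for pid, t, y in data.general:
        Z = np.column_stack([np.ones_like(t), t])
        G = np.array([[g00, g01], [g01, g11]])
        W = np.linalg.inv(Z @ G @ Z.T + s * np.eye(len(t)))
        u = G @ Z.T @ W @ (y - Z @ beta)
        out[pid] = (float(u[0]), float(u[1]))
    return out


def _fd_hessian(f, x, h=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi = x.copy(); xi[i] += h; xi[j] += h; fpp = f(xi)
            xi = x.copy(); xi[i] += h; xi[j] -= h; fpm = f(xi)
            xi = x.copy(); xi[i] -= h; xi[j] += h; fmp = f(xi)
            xi = x.copy(); xi[i] -= h; xi[j] -= h; fmm = f(xi)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H, f0


def fit_rcm(records: pd.DataFrame, value_col: str = "value",
            time_col: str = "t", person_col: str = "person_id",
            max_iter: int = 500, tol: float = 1e-8,
            check_identifiability: bool = True) -> GrowthCurveFit:
    """REML fit of the random intercept/slope model for one phenotype.

    ``records`` must hold one row per usable visit with the time column
    measured in years since the person's own Visit 1 (so the intercept
    is the expected Visit-1 value).  Persons with a single visit are
    retained; their estimates are strongly shrunk toward the population
    mean.
    """
    sub = records[[person_col, time_col, value_col]].dropna()
    data = _RcmData(sub[person_col].to_numpy(), sub[time_col].to_numpy(),
                    sub[value_col].to_numpy())
    if data.n_obs < 4 or data.n_persons < 2:
        raise ValueError("need >= 4 observations on >= 2 persons")
    vy = max(data.var_y, 1e-12)

    degenerate_layout = (len(data.t1o) == 0 and not data.general
                         and len(data.dt2) > 0
                         and float(np.std(data.dt2)) < 1e-3)
    if check_identifiability and degenerate_layout:
        warnings.warn(
            "all persons share an identical two-visit time layout; G and "
            "sigma2_e are weakly separated", RcmIdentifiabilityWarning,
            stacklevel=2)

    # moment-based starting values
    slopes = (data.yb - data.ya) / np.where(data.dt2 == 0, 1.0, data.dt2) \
        if len(data.ta) else np.array([0.0])
    g11_0 = max(np.var(slopes) / 2 if len(slopes) > 1 else 0.01 * vy, 1e-6 * vy)
    s0 = 0.25 * vy
    g00_0 = max(vy - s0, 1e-3 * vy)
    x0 = np.array([0.5 * np.log(g00_0), 0.0, 0.5 * np.log(g11_0),
                   0.5 * np.log(s0)])
    lo_d = 0.5 * np.log(1e-14 * vy)
    hi = 0.5 * np.log(1e6 * vy)
    bounds = [(lo_d, hi), (-np.sqrt(1e6 * vy), np.sqrt(1e6 * vy)),
              (lo_d, hi), (lo_d, hi)]

    obj = lambda x: _neg2reml(x, data)
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": max_iter, "ftol": tol,
                                     "gtol": 1e-9})
    best = res
    for alt in ([x0[0], 0.0, x0[2] + 2.0, lo_d + 1.0],
                [x0[0], 0.0, x0[2] - 2.0, 0.5 * np.log(0.8 * vy)]):
        r2 = optimize.minimize(obj, np.asarray(alt), method="L-BFGS-B",
                               bounds=bounds,
                               options={"maxiter": max_iter, "ftol": tol})
        if r2.fun < best.fun - 1e-9:
            best = r2
    if not best.success and np.isfinite(best.fun):
        # polish with a derivative-free restart
        r3 = optimize.minimize(obj, best.x, method="Nelder-Mead",
                               options={"maxiter": 2000, "fatol": 1e-10,
                                        "xatol": 1e-10})
        if r3.fun <= best.fun:
            best = r3
    if not np.isfinite(best.fun) or best.fun >= _PENALTY:
        raise RcmConvergenceError(
            f"growth-curve REML did not converge: {best.message}")

    x = best.x
    if check_identifiability and degenerate_layout:
        H, _ = _fd_hessian(obj, x)
        cond = np.linalg.cond(H)
        if not np.isfinite(cond) or cond > 1e12:
            raise RcmConvergenceError(
                "growth-curve model unidentifiable: identical two-visit "
                "layout leaves the Hessian numerically singular")

    g00, g01, g11, s = _unpack(x)
    beta = _beta_hat(x, data)
    per_person = _blups(x, beta, data)
    with np.errstate(all="ignore"):
        grad = optimize.approx_fprime(x, obj, 1e-6)
    grad = np.where(np.isfinite(grad), grad, 0.0)
    nconst = data.n_obs - 2
    loglik = -0.5 * (best.fun + nconst * np.log(2 * np.pi))
    return GrowthCurveFit(
        beta=beta, G=np.array([[g00, g01], [g01, g11]]), sigma2_e=float(s),
        per_person=per_person, loglik=float(loglik), n_obs=data.n_obs,
        n_persons=data.n_persons, converged=bool(best.success),
        n_iter=int(getattr(best, "nit", -1)), grad_norm=float(np.linalg.norm(grad)))


def gc_fitted_vs_measured(fit: GrowthCurveFit, records: pd.DataFrame,
                          value_col: str = "value", time_col: str = "t",
                          person_col: str = "person_id",
                          visit_col: str = "visit") -> dict[int, float]:
    """Pearson correlation between measured and BLUP-predicted values per visit."""
    out: dict[int, float] = {}
    sub = records.dropna(subset=[value_col])
    for visit, grp in sub.groupby(visit_col):
        pred, meas = [], []
        for pid, t, y in zip(grp[person_col], grp[time_col], grp[value_col]):
            if pid not in fit.per_person:
                continue
            u0, u1 = fit.per_person[pid]
            pred.append((fit.beta[0] + u0) + (fit.beta[1] + u1) * t)
            meas.append(y)
        if len(pred) < 3:
            out[int(visit)] = float("nan")
        else:
            out[int(visit)] = float(np.corrcoef(meas, pred)[0, 1])
    return out


def add_time_since_visit1(df: pd.DataFrame, person_col: str = "person_id",
                          date_col: str = "visit_date",
                          out_col: str = "t") -> pd.DataFrame:
    """Attach t = years since the person's first visit (t=0 at Visit 1)."""
    df = df.copy()
    dates = pd.to_datetime(df[date_col])
    first = dates.groupby(df[person_col]).transform("min")
    df[out_col] = (dates - first).dt.days / DAYS_PER_YEAR
    return df
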