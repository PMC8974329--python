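"""Preprocessing rules, OLS slopes, and the growth-curve REML fitter."""

import subprocess
import sys
import textwrap
import warnings
from datetime import date

import numpy as np
import pandas as pd
import pytest

from famlong import growth
from famlong.growth import (RcmIdentifiabilityWarning, VisitRecord,
                            apply_exclusions, apply_medication_adjustment,
                            fit_rcm, gc_fitted_vs_measured, ols_slope,
                            residualize)


def rec(value, *, meds=(), fasting=None, dx=None, glucose=None, hba1c=None,
        visit_date=None, visit=1):
    return VisitRecord("p1", visit, visit_date, value, fasting=fasting,
                       meds=frozenset(meds), diabetes_dx=dx, glucose=glucose,
                       hba1c=hba1c)


class TestMedicationAdjustment:
    @pytest.mark.parametrize("trait,value,want", [
        ("sbp", 130.0, 145.0),     # +15 on antihypertensives
        ("dbp", 80.0, 90.0),       # +10
    ])
    def test_antihypertensive_shift(self, trait, value, want):
        out = apply_medication_adjustment(
            rec(value, meds={"antihypertensive"}), trait)
        assert out.value == pytest.approx(want)
        assert out.provenance

    def test_no_medication_no_change(self):
        out = apply_medication_adjustment(rec(130.0), "sbp")
        assert out.value == 130.0 and not out.provenance

    def test_other_trait_untouched(self):
        out = apply_medication_adjustment(
            rec(27.0, meds={"antihypertensive"}), "bmi")
        assert out.value == 27.0


class TestExclusions:
    def test_high_fasting_glucose_defines_diabetes(self):
        out = apply_exclusions(rec(140.0, fasting=True), "glucose")
        assert out.value is None and "diabetes" in out.provenance[0]

    def test_glucose_just_below_threshold_kept(self):
        out = apply_exclusions(rec(125.9, fasting=True), "glucose")
        assert out.value == 125.9

    def test_hba1c_boundary_inclusive(self):
        assert apply_exclusions(rec(6.5), "hba1c").value is None
        assert apply_exclusions(rec(6.4), "hba1c").value == 6.4

    def test_reported_diagnosis_and_medication(self):
        assert apply_exclusions(rec(100.0, fasting=True, dx=True),
                                "glucose").value is None
        assert apply_exclusions(rec(100.0, fasting=True, meds={"diabetes"}),
                                "glucose").value is None

    def test_nonfasting_glucose_missing_but_hba1c_kept(self):
        assert apply_exclusions(rec(100.0, fasting=False), "glucose").value is None
        assert apply_exclusions(rec(5.5, fasting=False), "hba1c").value == 5.5

    def test_lipids_on_medication_or_nonfasting(self):
        assert apply_exclusions(rec(200.0, fasting=True,
                                    meds={"lipid_lowering"}),
                                "total_cholesterol").value is None
        assert apply_exclusions(rec(200.0, fasting=False),
                                "total_cholesterol").value is None
        assert apply_exclusions(rec(200.0, fasting=True),
                                "total_cholesterol").value == 200.0

    def test_passthrough_trait(self):
        out = apply_exclusions(rec(30.0, fasting=False, meds={"diabetes"}),
                               "bmi")
        assert out.value == 30.0

    def test_unknown_trait_errors(self):
        with pytest.raises(KeyError, match="mystery"):
            apply_exclusions(rec(1.0), "mystery")


class TestOlsSlope:
    def test_no_change_zero_slope(self):
        s = ols_slope(rec(100.0, visit_date=date(2006, 6, 1)),
                      rec(100.0, visit_date=date(2014, 6, 1), visit=2))
        assert s.ols_slope == 0.0

    def test_days_over_365_25_rule(self):
        s = ols_slope(rec(100.0, visit_date=date(2006, 6, 1)),
                      rec(110.0, visit_date=date(2008, 5, 31), visit=2))
        days = (date(2008, 5, 31) - date(2006, 6, 1)).days
        assert s.years_between == pytest.approx(days / 365.25)
        assert s.ols_slope == pytest.approx(10.0 / (days / 365.25))
        assert s.ols_slope == pytest.approx(5.0, abs=0.01)

    def test_missing_visit_gives_reason(self):
        s = ols_slope(rec(100.0, visit_date=date(2006, 6, 1)),
                      rec(None, visit_date=date(2014, 6, 1), visit=2))
        assert s.ols_slope is None and s.reason == "incomplete pair"

    def test_reversed_dates_error(self):
        with pytest.raises(ValueError, match="not after"):
            ols_slope(rec(1.0, visit_date=date(2010, 1, 1)),
                      rec(2.0, visit_date=date(2009, 1, 1), visit=2))


class TestResidualize:
    def frame(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "sex": rng.choice(["male", "female"], n),
            "age": rng.uniform(50, 90, n),
            "field_site": rng.choice(["s1", "s2", "s3"], n),
        })

    def test_projection_removes_age(self):
        df = self.frame()
        df["value"] = 2.0 * df["age"] + np.random.default_rng(1).normal(0, 1, len(df))
        res = residualize(df, "value")
        r = np.corrcoef(res, df.loc[res.index, "age"])[0, 1]
        assert abs(r) < 1e-10

    def test_constant_phenotype_zero_residuals(self):
        df = self.frame()
        df["value"] = 5.0
        assert np.allclose(residualize(df, "value"), 0.0, atol=1e-10)

    def test_thin_site_level_errors(self):
        df = self.frame(n=30)
        df.loc[df.index[0], "field_site"] = "lonely"
        df["value"] = 1.0 * df["age"]
        with pytest.raises(ValueError, match="lonely"):
            residualize(df, "value")


def simulate_two_visit(seed, n=600, s0=1.0, s1=0.04, s01=0.0, se=1.0,
                       beta=(5.0, 0.1)):
    rng = np.random.default_rng(seed)
    G = np.array([[s0, s01], [s01, s1]])
    w, V = np.linalg.eigh(G)
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    rows = []
    truth = {}
    for i in range(n):
        u = L @ rng.standard_normal(2)
        truth[f"p{i:04d}"] = (beta[0] + u[0], beta[1] + u[1])
        dt = rng.uniform(8, 10)
        for t in (0.0, dt):
            rows.append((f"p{i:04d}", t,
                         (beta[0] + u[0]) + (beta[1] + u[1]) * t
                         + rng.normal(0, np.sqrt(se))))
    return pd.DataFrame(rows, columns=["person_id", "t", "value"]), truth


class TestFitRcm:
    def test_noise_free_three_visits_recovers_exact_lines(self):
        rng = np.random.default_rng(0)
        rows = []
        slopes = {}
        for i in range(40):
            b0, b1 = rng.normal(10, 2), rng.normal(-0.3, 0.3)
            slopes[f"p{i:02d}"] = b1
            for t in (0.0, 4.5, rng.uniform(8, 10)):
                rows.append((f"p{i:02d}", t, b0 + b1 * t))
        df = pd.DataFrame(rows, columns=["person_id", "t", "value"])
        fit = fit_rcm(df)
        assert fit.sigma2_e <= 1e-8 * df["value"].var()
        bl = fit.blup_frame()
        for pid, b1 in slopes.items():
            assert bl.loc[pid, "gc_slope"] == pytest.approx(b1, abs=1e-6)
        corr = gc_fitted_vs_measured(fit, df.assign(visit=1))
        assert corr[1] == pytest.approx(1.0, abs=1e-9)

    def test_total_shrinkage_when_slopes_homogeneous(self):
        # three visits per person so sigma2_slope separates cleanly from
        # residual noise; all true slopes equal -> BLUP slopes collapse
        rng = np.random.default_rng(1)
        rows = []
        for i in range(400):
            b0 = rng.normal(5, 1)
            for t in (0.0, 4.5, rng.uniform(8, 10)):
                rows.append((f"p{i:04d}", t, b0 + 0.1 * t + rng.normal()))
        df = pd.DataFrame(rows, columns=["person_id", "t", "value"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RcmIdentifiabilityWarning)
            fit = fit_rcm(df)
        ols = (df.groupby("person_id")
                 .apply(lambda g: np.polyfit(g["t"], g["value"], 1)[0],
                        include_groups=False))
        bl = fit.blup_frame()["gc_slope"]
        assert bl.std() < 0.10 * ols.std()

    def test_identifiable_covariance_functionals_recovered(self):
        """Var(V1), Cov(V1,V2) and Var(V2) at the mean gap: 25% rel. error
        (median over 20 seeds).  The individual G entries are only weakly
        identified with two visits and gaps confined to 8-10 years."""
        errs = []
        for seed in range(20):
            df, _ = simulate_two_visit(seed)
            fit = fit_rcm(df)
            g00, g01 = fit.G[0, 0], fit.G[0, 1]
            g11, s = fit.G[1, 1], fit.sigma2_e
            d = 9.0
            got = np.array([g00 + s, g00 + g01 * d,
                            g00 + 2 * g01 * d + g11 * d * d + s])
            want = np.array([2.0, 1.0, 1.0 + 0.04 * 81 + 1.0])
            errs.append(np.abs(got - want) / want)
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.25), med

    def test_matches_lme4_reference(self, tmp_path):
        """Dual-route check: REML optimum agrees with lme4 on shared data."""
        df, _ = simulate_two_visit(123)
        fit = fit_rcm(df)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(value ~ t + (1 + t | person_id), data=d, REML=TRUE,
                      control=lmerControl(check.nobs.vs.nRE="ignore",
                                          calc.derivs=FALSE))
            vc <- VarCorr(m)$person_id
            cat(vc[1,1], vc[1,2], vc[2,2], sigma(m)^2,
                as.numeric(logLik(m)), sep=",")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        g00, g01, g11, s, ll = map(float, out.stdout.strip().split(","))
        assert fit.loglik == pytest.approx(ll, abs=0.05)
        assert fit.G[0, 0] + fit.sigma2_e == pytest.approx(g00 + s, rel=0.02)
        assert fit.G[0, 1] == pytest.approx(g01, abs=0.02)

    def test_blup_between_mean_and_ols_slope(self):
        # three visits per person identify a near-diagonal G, in which case
        # shrinkage is scalar: every BLUP lies between the person's OLS
        # slope and the population mean slope
        # per-person centered times decouple intercepts from slopes, so with
        # a near-diagonal fitted G the shrinkage is (almost) scalar
        rng = np.random.default_rng(7)
        rows = []
        for i in range(300):
            b0, b1 = rng.normal(5, 1), rng.normal(0.1, 0.2)
            for t in (-4.5, 0.0, 4.5):
                rows.append((f"p{i:04d}", t, b0 + b1 * t + rng.normal()))
        df = pd.DataFrame(rows, columns=["person_id", "t", "value"])
        fit = fit_rcm(df, check_identifiability=False)
        assert abs(fit.slope_corr) < 0.3
        ols = (df.groupby("person_id")
                 .apply(lambda g: np.polyfit(g["t"], g["value"], 1)[0],
                        include_groups=False))
        bl = fit.blup_frame()["gc_slope"]
        beta1 = fit.beta[1]
        between = [(min(o, beta1) - 1e-8 <= b <= max(o, beta1) + 1e-8)
                   for o, b in zip(ols.reindex(bl.index), bl)]
        assert np.mean(between) >= 0.95   # ghat_01 != 0 leaks a few percent

    def test_blup_mse_beats_ols_mse(self):
        """The core argument: with measurement error, shrunken slopes are
        closer to the truth than the naive change scores."""
        wins = 0
        for seed in range(5):
            # the study regime: large level variance, small slope variance,
            # correlated components, heavy per-visit error
            df, truth = simulate_two_visit(seed + 50, n=400, s0=10.0,
                                           s1=0.01, s01=0.6 * np.sqrt(0.1),
                                           se=4.0)
            fit = fit_rcm(df)
            ols = (df.groupby("person_id")
                     .apply(lambda g: np.polyfit(g["t"], g["value"], 1)[0],
                            include_groups=False))
            bl = fit.blup_frame()["gc_slope"]
            ts = pd.Series({p: v[1] for p, v in truth.items()})
            mse_blup = ((bl - ts.reindex(bl.index)) ** 2).mean()
            mse_ols = ((ols - ts.reindex(ols.index)) ** 2).mean()
            wins += mse_blup < mse_ols
        assert wins == 5

    def test_single_visit_persons_are_shrunken_and_retained(self):
        df, _ = simulate_two_visit(3, n=200)
        df = df.drop(df[(df["person_id"] == "p0000") & (df["t"] > 0)].index)
        fit = fit_rcm(df)
        assert "p0000" in fit.per_person
        assert fit.n_persons == 200

    def test_identical_layout_warns(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(60):
            u = rng.standard_normal(2) * [1.0, 0.2]
            for t in (0.0, 9.0):          # same gap for everyone
                rows.append((f"p{i}", t, 5 + u[0] + u[1] * t + rng.normal()))
        df = pd.DataFrame(rows, columns=["person_id", "t", "value"])
        with pytest.warns(RcmIdentifiabilityWarning):
            fit_rcm(df)

    def test_local_optimality_of_reml_solution(self):
        """Perturbing any parameter from the optimum does not lower the
        restricted objective (beyond numerical tolerance)."""
        from famlong.growth import _RcmData, _neg2reml
        df, _ = simulate_two_visit(11)
        fit = fit_rcm(df)
        data = _RcmData(df["person_id"].to_numpy(), df["t"].to_numpy(),
                        df["value"].to_numpy())
        la = np.sqrt(fit.G[0, 0])
        b = fit.G[0, 1] / la
        c2 = max(fit.G[1, 1] - b * b, 1e-14)
        x = np.array([np.log(la), b, 0.5 * np.log(c2),
                      0.5 * np.log(fit.sigma2_e)])
        f0 = _neg2reml(x, data)
        for k in range(4):
            for h in (-1e-3, 1e-3):
                xp = x.copy()
                xp[k] += h
                assert _neg2reml(xp, data) >= f0 - 1e-6

    def test_correlation_bounds(self):
        df, _ = simulate_two_visit(13, s01=0.1)
        fit = fit_rcm(df)
        assert -1.0 <= fit.slope_corr <= 1.0
        ev = np.linalg.eigvalsh(fit.G)
        assert ev.min() >= -1e-12


class TestTimeSinceVisit1:
    def test_origin_at_first_visit(self):
        df = pd.DataFrame({
            "person_id": ["a", "a", "b", "b"],
            "visit_date": ["2006-03-01", "2015-03-01", "2007-01-01",
                           "2016-07-02"],
            "value": [1.0, 2.0, 3.0, 4.0],
        })
        out = growth.add_time_since_visit1(df)
        assert out.loc[0, "t"] == 0.0
        assert out.loc[1, "t"] == pytest.approx(
            (pd.Timestamp("2015-03-01") - pd.Timestamp("2006-03-01")).days
            / 365.25)
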