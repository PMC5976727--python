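import numpy as np
import pandas as pd
import pytest

import fetgrowth as fg
from fetgrowth.biometry import classify_sga_lga
from fetgrowth.periods import (
    assign_period_weights,
    fit_period,
    fit_sga_lga,
)


def toy_weights(n=12, seed=0, grs_effect=0.0):
    """Hand-sized cohort with one scan per window plus a birth record."""
    rng = np.random.default_rng(seed)
    ids = [f"f{i}" for i in range(n)]
    grs = rng.normal(55, 4, n)
    rows = []
    for i, fid in enumerate(ids):
        for ga, base, src in (
            (140 + rng.uniform(-3, 3), 330, "ultrasound"),
            (175 + rng.uniform(-3, 3), 890, "ultrasound"),
            (224 + rng.uniform(-3, 3), 2090, "ultrasound"),
            (279 + rng.uniform(-5, 5), 3580, "birth"),
        ):
            w = base + rng.normal(0, base * 0.05) + grs_effect * (grs[i] - 55)
            rows.append({"fetus_id": fid, "ga_days": ga, "weight_g": w,
                         "source": src})
    return pd.DataFrame(rows), pd.Series(grs, index=ids)


class TestAssignment:
    def test_wide_table_shape(self):
        w, _ = toy_weights()
        wide = assign_period_weights(w)
        assert set(wide.columns) >= {
            "weight_20w", "weight_25w", "weight_32w", "weight_birth",
            "ga_20w", "ga_25w", "ga_32w", "ga_birth",
        }
        assert len(wide) == 12

    def test_ambiguous_assignment_raises(self):
        w, _ = toy_weights()
        dup = pd.concat(
            [w, pd.DataFrame([{"fetus_id": "f0", "ga_days": 141.0,
                               "weight_g": 340.0, "source": "ultrasound"}])],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="f0"):
            assign_period_weights(dup)


class TestFitPeriod:
    def test_matches_normal_equations(self):
        """OLS via the period model equals the closed-form solution of
        the normal equations on the same design."""
        w, grs = toy_weights(n=12, seed=3)
        pf = fit_period("20-25", w, grs)
        wide = assign_period_weights(w)
        df = pd.DataFrame(
            {
                "grs": grs,
                "w_start": wide["weight_20w"],
                "ga_start": wide["ga_20w"],
                "ga_end": wide["ga_25w"],
            }
        )
        X = np.column_stack([np.ones(len(df)), df.to_numpy()])
        y = wide["weight_25w"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert pf.coef_g_per_allele == pytest.approx(beta[1], rel=1e-10)

    def test_per_day_scaling_uses_mean_interval(self):
        w, grs = toy_weights(n=15, seed=4)
        pf = fit_period("25-32", w, grs)
        assert pf.coef_g_per_day_per_allele == pytest.approx(
            pf.coef_g_per_allele / pf.mean_interval_days
        )
        assert 40 < pf.mean_interval_days < 60

    def test_null_grs_effect_centered_at_zero(self):
        zs = []
        for seed in range(30):
            w, grs = toy_weights(n=40, seed=seed)
            pf = fit_period("32-birth", w, grs)
            zs.append(pf.coef_g_per_allele / pf.se_g_per_allele)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 3 / np.sqrt(len(zs))

    def test_positive_effect_detected_and_ordering(self, small_cohort, small_grs):
        """On the default generative truth the score's period effects are
        positive and largest in the 32w-birth window."""
        coefs = {}
        for period in ("20-25", "25-32", "32-birth"):
            pf = fit_period(
                period, small_cohort.weights, small_grs,
                covariates=small_cohort.covariates, adjusted=True,
            )
            coefs[period] = pf.coef_g_per_day_per_allele
        assert coefs["32-birth"] > max(coefs["20-25"], coefs["25-32"]) - 1e-9

    def test_adjusted_close_to_unadjusted_on_balanced_data(
        self, small_cohort, small_grs
    ):
        un = fit_period("25-32", small_cohort.weights, small_grs)
        ad = fit_period(
            "25-32", small_cohort.weights, small_grs,
            covariates=small_cohort.covariates, adjusted=True,
        )
        assert abs(un.coef_g_per_allele - ad.coef_g_per_allele) < un.se_g_per_allele

    def test_residuals_orthogonal_to_design(self):
        w, grs = toy_weights(n=20, seed=6)
        wide = assign_period_weights(w)
        df = pd.DataFrame(
            {
                "grs": grs,
                "w_start": wide["weight_20w"],
                "ga_start": wide["ga_20w"],
                "ga_end": wide["ga_25w"],
            }
        )
        X = np.column_stack([np.ones(len(df)), df.to_numpy()])
        y = wide["weight_25w"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-6)

    def test_unknown_period_rejected(self):
        w, grs = toy_weights()
        with pytest.raises(ValueError):
            fit_period("10-20", w, grs)


class TestSgaLga:
    @staticmethod
    def make_categories(n, rng, p_case=0.12, outcome="SGA"):
        labels = np.where(rng.random(n) < p_case, outcome, "AGA")
        return pd.Series(labels, index=[f"f{i}" for i in range(n)])

    def test_null_or_near_one(self, rng):
        n = 2000
        grs = pd.Series(rng.normal(55, 4.5, n), index=[f"f{i}" for i in range(n)])
        cats = self.make_categories(n, rng)
        fit = fit_sga_lga(grs, cats, "SGA")
        assert fit.odds_ratio == pytest.approx(1.0, abs=0.05)
        assert fit.ci_low < 1.0 < fit.ci_high

    def test_doubling_preserves_or_and_narrows_ci(self, rng):
        n = 800
        idx = [f"f{i}" for i in range(n)]
        grs = pd.Series(rng.normal(55, 4.5, n), index=idx)
        cats = self.make_categories(n, rng, outcome="LGA")
        single = fit_sga_lga(grs, cats, "LGA")
        grs2 = pd.concat([grs, grs.set_axis([f"{i}_b" for i in idx])])
        cats2 = pd.concat([cats, cats.set_axis([f"{i}_b" for i in idx])])
        double = fit_sga_lga(grs2, cats2, "LGA")
        assert double.odds_ratio == pytest.approx(single.odds_ratio, rel=1e-6)
        assert (double.ci_high - double.ci_low) < (single.ci_high - single.ci_low)

    def test_dichotomized_grs_equals_contingency_cross_product(self, rng):
        n = 1000
        idx = [f"f{i}" for i in range(n)]
        g = rng.integers(0, 2, n).astype(float)  # 0/1 "score"
        p = np.where(g == 1, 0.25, 0.10)
        case = rng.random(n) < p
        grs = pd.Series(g, index=idx)
        cats = pd.Series(np.where(case, "SGA", "AGA"), index=idx)
        fit = fit_sga_lga(grs, cats, "SGA")
        a = ((g == 1) & case).sum()
        b = ((g == 1) & ~case).sum()
        c = ((g == 0) & case).sum()
        d = ((g == 0) & ~case).sum()
        assert fit.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-5)

    def test_too_few_cases_rejected(self, rng):
        grs = pd.Series(rng.normal(55, 4, 100), index=[f"f{i}" for i in range(100)])
        cats = pd.Series(["AGA"] * 99 + ["SGA"], index=grs.index)
        with pytest.raises(ValueError, match="cases"):
            fit_sga_lga(grs, cats, "SGA")

    def test_integration_with_fitted_reference(self, small_cohort, small_grs,
                                               unconditional_fit):
        """End-to-end: classify births against the fitted growth curve,
        then test GRS association (null-ish on this small cohort)."""
        cov = small_cohort.covariates
        cats = {
            row["fetus_id"]: classify_sga_lga(
                row["birth_weight"], row["birth_ga"],
                unconditional_fit.predict_weight,
            )
            for _, row in cov.iterrows()
        }
        labels = pd.Series({k: v.label for k, v in cats.items()})
        counts = labels.value_counts()
        assert counts.get("AGA", 0) > counts.get("SGA", 0)
        assert counts.get("AGA", 0) > counts.get("LGA", 0)
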