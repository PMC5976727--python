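import math

import numpy as np
import pandas as pd
import pytest

import fetgrowth as fg
from fetgrowth.growth import (
    GrowthModelSpec,
    anchored_term_difference,
    per_variant_scan,
    transform_intercept,
    transform_linear,
    transform_quadratic,
)

from conftest import FAST_FIT

# Published unconditional growth estimates (raw log-scale coefficient,
# printed transformed value, printed decimals) for each outcome; the
# transformed column must be reproduced from the raw column by the
# scale maps. Raw values are themselves rounded in print, so agreement
# is required to within one unit in the last printed digit.
UNCONDITIONAL_CELLS = [
    # (raw, half-ulp of printed raw, printed transformed, its decimals)
    # for intercept / GA / GA^2 per outcome
    ("weight_incl_birth", (0.774, 5e-4, 2.17, 2), (0.0456, 5e-5, 4.67, 2),
     (-6.82e-5, 5e-8, -0.0136, 4)),
    ("weight_excl_birth", (1.30, 5e-3, 3.68, 2), (0.0395, 5e-5, 4.03, 2),
     (-5.12e-5, 5e-8, -0.0102, 4)),
    ("ofd", (2.04, 5e-3, 7.69, 2), (0.0198, 5e-5, 2.00, 2),
     (-3.62e-5, 5e-8, -0.00724, 5)),
    ("ac", (2.95, 5e-3, 19.1, 1), (0.019, 5e-4, 1.92, 2),
     (-3.1e-5, 5e-7, -0.0062, 4)),
    ("fl", (0.861, 5e-4, 2.37, 2), (0.0249, 5e-5, 2.52, 2),
     (-4.64e-5, 5e-8, -0.00928, 5)),
    ("bpd", (1.89, 5e-3, 6.62, 2), (0.0187, 5e-5, 1.89, 2),
     (-3.28e-5, 5e-8, -0.00657, 5)),
]

# Adjusted conditional (GA^2 x covariate) cells: raw curvature shift and
# its printed %-points-per-day transform. Two printed cells whose
# transformed value contradicts their own raw estimate (and their own
# CI under the x200 rule) are excluded as misprints.
CONDITIONAL_CELLS = [
    (4.46e-8, 8.92e-6),  # weight incl. birth, GRS
    (4.10e-8, 8.20e-6),  # weight incl. birth, BMI
    (-4.99e-7, -9.98e-5),  # weight incl. birth, sex
    (4.21e-8, 8.42e-6),  # weight excl. birth, BMI
    (-4.53e-7, -9.06e-5),  # weight excl. birth, sex
    (4.29e-9, 8.58e-7),  # OFD, GRS
    (1.20e-8, 2.40e-6),  # OFD, BMI
    (-3.27e-7, -6.54e-5),  # OFD, sex
    (1.61e-8, 3.22e-6),  # AC, GRS
    (1.30e-8, 2.60e-6),  # AC, BMI
    (5.95e-9, 1.19e-6),  # BPD, GRS
    (9.64e-9, 1.93e-6),  # BPD, BMI
    (-3.14e-7, -6.28e-5),  # BPD, sex
]


class TestScaleTransforms:
    def test_identity_cases(self):
        assert transform_intercept(0.0) == 1.0
        assert transform_linear(0.0) == 0.0
        assert transform_quadratic(0.0) == 0.0

    def test_quadratic_is_linear_map(self):
        x = 3.7e-8
        for a in (-2.0, 0.5, 1000.0):
            assert transform_quadratic(a * x) == pytest.approx(
                a * transform_quadratic(x), rel=1e-15
            )

    @pytest.mark.parametrize(
        "row", UNCONDITIONAL_CELLS, ids=[r[0] for r in UNCONDITIONAL_CELLS]
    )
    def test_unconditional_round_trip(self, row):
        """The raw->interpretable maps reproduce every printed
        transformed cell, allowing for the rounding already present in
        the printed raw value (propagated through the map's derivative)
        plus half a unit in the transformed cell's last digit."""
        _, icell, gcell, qcell = row
        derivs = (
            lambda r: math.exp(r),  # d exp / dr
            lambda r: 100.0 * math.exp(r),  # d 100(e^r - 1) / dr
            lambda r: 200.0,
        )
        for (raw, half_ulp, printed, dec), f, df in zip(
            (icell, gcell, qcell),
            (transform_intercept, transform_linear, transform_quadratic),
            derivs,
        ):
            tol = 0.5 * 10.0**-dec + df(raw) * half_ulp + 1e-12
            assert abs(f(raw) - printed) <= tol

    @pytest.mark.parametrize("raw,printed", CONDITIONAL_CELLS)
    def test_conditional_round_trip(self, raw, printed):
        assert transform_quadratic(raw) == pytest.approx(printed, rel=5e-3)


class TestModelSpec:
    def test_threeway_requires_grs(self):
        with pytest.raises(ValueError, match="GRS"):
            GrowthModelSpec(ga2_interactions=("Sex",), threeway="BMI")

    def test_unknown_outcome(self):
        with pytest.raises(ValueError):
            GrowthModelSpec(outcome="crl")

    def test_biometry_outcome_never_includes_birth(self):
        spec = GrowthModelSpec(outcome="ac_mm", include_birth=True)
        assert spec.include_birth is False


class TestFittedGrowthCurve:
    def test_recovers_generative_curve(self, unconditional_fit):
        te = unconditional_fit.transformed_effects()
        assert te.loc["ga", "transformed"] == pytest.approx(4.67, rel=0.03)
        assert te.loc["ga2", "transformed"] == pytest.approx(-0.0136, rel=0.05)
        assert te.loc["const", "transformed"] == pytest.approx(2.17, rel=0.25)

    def test_predict_weight_is_geometric_mean_curve(self, unconditional_fit):
        w0 = unconditional_fit.predict_weight(0.0)
        assert w0 == pytest.approx(math.exp(unconditional_fit.params["const"]))
        # term prediction lands near the observed birth-weight mean
        assert unconditional_fit.predict_weight(280.0) == pytest.approx(3580, rel=0.1)

    def test_predicted_curve_monotone_to_term(self, unconditional_fit):
        grid = np.arange(0.0, 281.0, 7.0)
        w = np.array([unconditional_fit.predict_weight(t) for t in grid])
        assert np.all(np.diff(w) > 0)

    def test_conditional_fit_recovers_interactions(self, small_cohort, small_grs):
        spec = GrowthModelSpec(ga2_interactions=("GRS", "Sex", "BMI"))
        res = fg.GrowthCurveModel.from_cohort(small_cohort, spec).fit(**FAST_FIT)
        truth = small_cohort.truth
        for term, true_val in (
            ("ga2_x_GRS", truth.gamma_grs),
            ("ga2_x_Sex", truth.gamma_sex),
            ("ga2_x_BMI", truth.gamma_bmi),
        ):
            est, se = res.params[term], res.bse[term]
            assert abs(est - true_val) < 3 * se, term

    def test_adjustment_shifts_grs_estimate_only_moderately(
        self, small_cohort, small_grs
    ):
        unadj = fg.GrowthCurveModel.from_cohort(
            small_cohort, GrowthModelSpec(ga2_interactions=("GRS",))
        ).fit(**FAST_FIT)
        adj = fg.GrowthCurveModel.from_cohort(
            small_cohort, GrowthModelSpec(ga2_interactions=("GRS", "Sex", "BMI"))
        ).fit(**FAST_FIT)
        a, b = unadj.params["ga2_x_GRS"], adj.params["ga2_x_GRS"]
        assert abs(a - b) < 3 * unadj.bse["ga2_x_GRS"]

    def test_excluding_birth_records_drops_observations(self, small_cohort):
        full = fg.GrowthCurveModel.from_cohort(small_cohort, GrowthModelSpec())
        no_birth = fg.GrowthCurveModel.from_cohort(
            small_cohort, GrowthModelSpec(include_birth=False)
        )
        assert full.n_obs == no_birth.n_obs + small_cohort.truth.n_fetuses


class TestThreeWayInteraction:
    def test_glucose_subset_fit_reports_n(self, small_cohort, small_grs):
        res = fg.fit_threeway(
            "glucose", small_cohort.weights, small_cohort.covariates, small_grs,
            **FAST_FIT,
        )
        n_glucose = small_cohort.covariates["glucose_2h"].notna().sum()
        # listwise deletion keeps only the glucose (and sex-known) subset
        assert res.lmm.n_groups <= n_glucose
        assert "ga2_x_GRS_x_glucose" in res.params.index
        assert np.isfinite(res.pvalues["ga2_x_GRS_x_glucose"])

    def test_smoking_modifier_runs(self, small_cohort, small_grs):
        res = fg.fit_threeway(
            "smoking", small_cohort.weights, small_cohort.covariates, small_grs,
            **FAST_FIT,
        )
        assert "ga2_x_GRS_x_smoking" in res.params.index
        assert 0.0 <= res.pvalues["ga2_x_GRS_x_smoking"] <= 1.0

    def test_constant_modifier_rejected(self, small_cohort, small_grs):
        cov = small_cohort.covariates.copy()
        cov["smoking"] = 0
        with pytest.raises(ValueError, match="constant"):
            fg.fit_threeway("smoking", small_cohort.weights, cov, small_grs)


class TestTermDifference:
    def test_zero_interaction_gives_zero(self):
        assert anchored_term_difference(
            0.774, 0.0456, -6.82e-5, 0.0, 47.5, 78.8, 55.0
        ) == 0.0

    def test_reversed_grs_order_rejected(self):
        with pytest.raises(ValueError):
            anchored_term_difference(0.774, 0.0456, -6.82e-5, 4.46e-8, 78.8, 47.5, 55.0)

    def test_published_magnitude(self):
        """Low-vs-high score gap at term: ~410 g for the published
        curvature shift on the published anchor curve."""
        diff = anchored_term_difference(
            0.774, 0.0456, -6.82e-5, 4.46e-8, 47.5, 78.8,
            grs_mean=(53.1 + 56.6) / 2.0, ga_days=280.0,
        )
        assert diff == pytest.approx(410.0, rel=0.10)
        assert 115.0 < diff < 798.0

    def test_first_order_linearity_in_grs_gap(self):
        f = lambda hi: anchored_term_difference(
            0.774, 0.0456, -6.82e-5, 4.46e-8, 55.0, hi, 55.0
        )
        d1, d2 = f(56.0), f(57.0)
        assert d2 == pytest.approx(2 * d1, rel=0.01)

    def test_fitted_model_term_difference(self, small_cohort, small_grs):
        spec = GrowthModelSpec(ga2_interactions=("GRS", "Sex", "BMI"))
        res = fg.GrowthCurveModel.from_cohort(small_cohort, spec).fit(**FAST_FIT)
        diff = res.term_difference(47.5, 78.8, ga_days=280.0)
        implied = anchored_term_difference(
            res.params["const"], res.params["ga"], res.params["ga2"],
            res.params["ga2_x_GRS"], 47.5, 78.8,
            grs_mean=res.centers["GRS"], ga_days=280.0,
        )
        assert diff == pytest.approx(implied, rel=1e-10)


class TestPerVariantScan:
    def test_grs_substitution_reproduces_grs_fit(self, small_cohort, small_grs):
        panel = fg.VariantPanel(("vGRS",), ("A",), (0.5,))
        doses = pd.DataFrame({"vGRS": small_grs})
        scan = per_variant_scan(
            panel, small_cohort.weights, small_cohort.covariates, doses,
            adjusted=True, **FAST_FIT,
        )
        ref = fg.GrowthCurveModel.from_cohort(
            small_cohort, GrowthModelSpec(ga2_interactions=("GRS", "Sex", "BMI"))
        ).fit(**FAST_FIT)
        assert scan.loc["vGRS", "estimate"] == pytest.approx(
            ref.params["ga2_x_GRS"], rel=1e-6
        )

    def test_causal_variant_ranks_first(self, small_cohort):
        """A variant given a real curvature effect out-z-scores null ones."""
        rng = np.random.default_rng(21)
        n = small_cohort.truth.n_fetuses
        ids = small_cohort.covariates["fetus_id"]
        doses = pd.DataFrame(
            rng.binomial(2, 0.5, size=(n, 10)).astype(float),
            index=pd.Index(ids, name="fetus_id"),
            columns=[f"v{i}" for i in range(10)],
        )
        causal = "v0"
        gamma_v = 6e-7
        w = small_cohort.weights.copy()
        dose_c = doses[causal] - doses[causal].mean()
        shift = dose_c.reindex(w["fetus_id"]).to_numpy() * gamma_v * w["ga_days"] ** 2
        w["weight_g"] = w["weight_g"] * np.exp(shift)
        panel = fg.VariantPanel(
            tuple(doses.columns), ("A",) * 10, (0.5,) * 10
        )
        scan = per_variant_scan(
            panel, w, small_cohort.covariates, doses, adjusted=False, **FAST_FIT
        )
        assert scan["z"].abs().idxmax() == causal

    def test_monomorphic_variant_flagged(self, small_cohort):
        ids = small_cohort.covariates["fetus_id"]
        doses = pd.DataFrame(
            {"vM": np.ones(len(ids)), "vP": np.arange(len(ids)) % 3 / 1.0},
            index=pd.Index(ids, name="fetus_id"),
        )
        panel = fg.VariantPanel(("vM", "vP"), ("A", "C"), (0.5, 0.5))
        scan = per_variant_scan(
            panel, small_cohort.weights, small_cohort.covariates, doses,
            adjusted=False, **FAST_FIT,
        )
        assert scan.loc["vM", "status"] == "monomorphic"
        assert np.isnan(scan.loc["vM", "estimate"])
        assert scan.loc["vP", "status"] == "ok"
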