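"""Simulation-based validation studies.

Parameter-recovery, confidence-interval coverage and test-calibration
experiments run against the synthetic-cohort generator. These are the
quantitative checks that the modelling stack estimates what the
generator put in; they are exercised by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .growth import GrowthCurveModel, GrowthModelSpec, fit_threeway, per_variant_scan
from .grs import compute_grs
from .simulate import DEFAULT_TRUTH, SimulationTruth, simulate_cohort

__all__ = [
    "recovery_study",
    "coverage_study",
    "threeway_type1_study",
    "null_variant_scan_study",
]

log = logging.getLogger(__name__)

#: optimizer settings for large simulation studies: GLS coefficients are
#: insensitive to the final digits of the variance components, so one
#: start and a loose tolerance suffice.
FAST_FIT = dict(xtol=1e-3, restarts=1, polish=False)


def _rep_seed(base_seed: int, rep: int) -> int:
    return (base_seed * 1000 + rep) % (2**31 - 1)


def recovery_study(
    n_reps: int = 25,
    truth: SimulationTruth = DEFAULT_TRUTH,
    base_seed: int = 1,
    conditional: bool = True,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Simulate cohorts and refit, returning per-replicate transformed
    effects.

    Each replicate draws a fresh cohort under ``truth``, fits the
    unconditional growth model (and, when ``conditional``, the
    sex/BMI-adjusted GRS-conditional model) and records the
    interpretable-scale estimates: ``ga_pct_per_day``,
    ``ga2_pctpts_per_day`` and — conditionally — ``grs_pctpts_per_day``.
    """
    fk = dict(FAST_FIT if fit_kwargs is None else fit_kwargs)
    rows = []
    for rep in range(1, n_reps + 1):
        cohort = simulate_cohort(truth, seed=_rep_seed(base_seed, rep),
                                 with_biometry=False)
        uncond = GrowthCurveModel.from_cohort(cohort, GrowthModelSpec()).fit(**fk)
        te = uncond.transformed_effects()
        row = {
            "rep": rep,
            "ga_pct_per_day": te.loc["ga", "transformed"],
            "ga2_pctpts_per_day": te.loc["ga2", "transformed"],
            "converged": uncond.converged,
        }
        if conditional:
            cond = GrowthCurveModel.from_cohort(
                cohort, GrowthModelSpec(ga2_interactions=("GRS", "Sex", "BMI"))
            ).fit(**fk)
            cte = cond.transformed_effects()
            row["grs_pctpts_per_day"] = cte.loc["ga2_x_GRS", "transformed"]
            row["converged"] = row["converged"] and cond.converged
        rows.append(row)
    return pd.DataFrame(rows).set_index("rep")


def coverage_study(
    n_reps: int = 200,
    truth: SimulationTruth | None = None,
    base_seed: int = 2,
    term: str = "ga2",
    fit_kwargs: dict | None = None,
) -> float:
    """Fraction of replicate 95% Wald intervals covering the true
    quadratic GA coefficient."""
    if truth is None:
        truth = DEFAULT_TRUTH.replace(n_fetuses=120)
    fk = dict(FAST_FIT if fit_kwargs is None else fit_kwargs)
    true_val = {"const": truth.b0, "ga": truth.b1, "ga2": truth.b2}[term]
    hits = 0
    for rep in range(1, n_reps + 1):
        cohort = simulate_cohort(truth, seed=_rep_seed(base_seed, rep),
                                 with_biometry=False)
        res = GrowthCurveModel.from_cohort(cohort, GrowthModelSpec()).fit(**fk)
        ci = res.conf_int().loc[term]
        hits += ci["lower"] <= true_val <= ci["upper"]
    return hits / n_reps


def threeway_type1_study(
    n_reps: int = 500,
    modifier: str = "smoking",
    truth: SimulationTruth | None = None,
    base_seed: int = 3,
    fit_kwargs: dict | None = None,
) -> np.ndarray:
    """Null p-values of the GA^2 x GRS x modifier Wald test.

    The generative truth carries no three-way effect, so the returned
    p-values are draws from the test's null distribution.
    """
    if truth is None:
        truth = DEFAULT_TRUTH.replace(n_fetuses=120)
    fk = dict(FAST_FIT if fit_kwargs is None else fit_kwargs)
    pvals = np.empty(n_reps)
    for rep in range(1, n_reps + 1):
        cohort = simulate_cohort(truth, seed=_rep_seed(base_seed, rep),
                                 with_biometry=False)
        grs = compute_grs(cohort.dosages, cohort.panel)["score"]
        res = fit_threeway(modifier, cohort.weights, cohort.covariates, grs, **fk)
        pvals[rep - 1] = res.pvalues[f"ga2_x_GRS_x_{modifier}"]
    return pvals


def null_variant_scan_study(
    n_cohorts: int = 5,
    truth: SimulationTruth | None = None,
    base_seed: int = 4,
    fit_kwargs: dict | None = None,
) -> np.ndarray:
    """Per-variant scan p-values on cohorts generated with no genetic
    effect at all (every variant is null)."""
    if truth is None:
        truth = DEFAULT_TRUTH.replace(n_fetuses=120, gamma_grs=0.0)
    else:
        truth = truth.replace(gamma_grs=0.0)
    fk = dict(FAST_FIT if fit_kwargs is None else fit_kwargs)
    all_p = []
    for rep in range(1, n_cohorts + 1):
        cohort = simulate_cohort(truth, seed=_rep_seed(base_seed, rep),
                                 with_biometry=False)
        scan = per_variant_scan(
            cohort.panel, cohort.weights, cohort.covariates, cohort.dosages,
            adjusted=False, **fk,
        )
        all_p.append(scan["p_value"].dropna().to_numpy())
    return np.concatenate(all_p)
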