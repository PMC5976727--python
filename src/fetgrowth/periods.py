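"""Period-specific conditional growth and birth-size association models.

Growth inside a gestational window (20-25, 25-32, or 32 weeks-birth) is
analyzed by conditional linear regression: the weight at the end of the
period is regressed on the GRS while adjusting for the weight at the
start of the period and the exact gestational ages of both measurements
(and, optionally, fetal sex and maternal BMI):

    W_end ~ GRS + W_start + GA_start + GA_end [+ Sex + BMI]

Conditioning on the start weight turns the end-weight coefficient into
a within-period growth effect. Because the published effects are per
day, the end-weight coefficient (g per allele) is also rescaled by the
cohort-mean interval length into g per day per allele; both scales are
reported.

SGA/LGA association uses per-allele logistic regression of the binary
birth-size category on the GRS.

Ordinary least squares and logistic fits are delegated to statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .biometry import GrowthCategory

__all__ = ["PeriodFit", "assign_period_weights", "fit_period", "fit_sga_lga",
           "DEFAULT_PERIOD_WINDOWS", "SgaLgaFit"]

log = logging.getLogger(__name__)

#: GA windows (days) used to assign a scan to a period endpoint; the
#: fourth endpoint is always the birth record itself.
DEFAULT_PERIOD_WINDOWS: dict[str, tuple[float, float]] = {
    "20w": (130.0, 150.0),
    "25w": (165.0, 185.0),
    "32w": (215.0, 235.0),
}

#: period name -> (start endpoint, end endpoint)
PERIODS: dict[str, tuple[str, str]] = {
    "20-25": ("20w", "25w"),
    "25-32": ("25w", "32w"),
    "32-birth": ("32w", "birth"),
}


@dataclass(frozen=True)
class PeriodFit:
    """GRS effect on growth within one gestational window."""

    period: str
    coef_g_per_allele: float  # on end-of-period weight
    coef_g_per_day_per_allele: float  # divided by mean interval length
    se_g_per_allele: float
    se_g_per_day_per_allele: float
    p_value: float
    n: int
    mean_interval_days: float


@dataclass(frozen=True)
class SgaLgaFit:
    """Per-allele odds ratio of a birth-size category on the GRS."""

    outcome: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int
    n: int


def assign_period_weights(
    weights: pd.DataFrame,
    windows: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Pivot long weight records to one row per fetus with columns
    ``weight_<endpoint>`` / ``ga_<endpoint>`` for 20w/25w/32w/birth.

    A fetus with two scans falling in the same window is ambiguous and
    raises (listing the offenders); a fetus simply missing an endpoint
    gets NaN there and drops out of fits that need it.
    """
    if windows is None:
        windows = DEFAULT_PERIOD_WINDOWS
    rows: dict[str, dict[str, float]] = {}
    ambiguous: list[str] = []
    if "source" in weights.columns:
        scans = weights[weights["source"] != "birth"]
        births = weights[weights["source"] == "birth"]
    else:
        scans = weights
        births = weights.iloc[0:0]
    for endpoint, (lo, hi) in windows.items():
        hit = scans[(scans["ga_days"] >= lo) & (scans["ga_days"] <= hi)]
        counts = hit.groupby("fetus_id").size()
        ambiguous.extend(str(f) for f in counts.index[counts > 1])
        for _, r in hit.iterrows():
            rows.setdefault(r["fetus_id"], {})[f"weight_{endpoint}"] = r["weight_g"]
            rows[r["fetus_id"]][f"ga_{endpoint}"] = r["ga_days"]
    for _, r in births.iterrows():
        rows.setdefault(r["fetus_id"], {})["weight_birth"] = r["weight_g"]
        rows[r["fetus_id"]]["ga_birth"] = r["ga_days"]
    if ambiguous:
        raise ValueError(
            "ambiguous scan-to-period assignment for fetuses: "
            f"{sorted(set(ambiguous))}"
        )
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("fetus_id")


def fit_period(
    period: str,
    weights: pd.DataFrame,
    grs: pd.Series,
    covariates: pd.DataFrame | None = None,
    adjusted: bool = False,
    windows: dict[str, tuple[float, float]] | None = None,
) -> PeriodFit:
    """Conditional OLS of end-of-period weight on the GRS.

    ``period`` is one of '20-25', '25-32', '32-birth'. With
    ``adjusted=True``, female sex (0/1) and maternal BMI join the
    design. ``grs`` may equally be a single variant's dosage column,
    giving a per-variant period effect.
    """
    if period not in PERIODS:
        raise ValueError(f"period must be one of {sorted(PERIODS)}")
    start, end = PERIODS[period]
    wide = assign_period_weights(weights, windows)
    df = wide[[f"weight_{end}", f"weight_{start}", f"ga_{start}", f"ga_{end}"]].copy()
    df.columns = ["w_end", "w_start", "ga_start", "ga_end"]
    df["grs"] = pd.Series(grs).astype(float).reindex(df.index)
    if adjusted:
        if covariates is None:
            raise ValueError("adjusted fit requires the covariates table")
        cov = covariates.set_index("fetus_id") \
            if "fetus_id" in covariates.columns else covariates
        sex = cov["sex"].replace("", np.nan).map({"female": 1.0, "male": 0.0})
        df["female"] = sex.reindex(df.index)
        df["bmi"] = cov["bmi"].astype(float).reindex(df.index)
    df = df.dropna()
    n = len(df)
    if n < 10:
        raise ValueError(f"only {n} fetuses have both endpoints for period {period}")
    xcols = ["grs", "w_start", "ga_start", "ga_end"] + (
        ["female", "bmi"] if adjusted else []
    )
    X = sm.add_constant(df[xcols])
    res = sm.OLS(df["w_end"], X).fit()
    interval = float((df["ga_end"] - df["ga_start"]).mean())
    return PeriodFit(
        period=period,
        coef_g_per_allele=float(res.params["grs"]),
        coef_g_per_day_per_allele=float(res.params["grs"]) / interval,
        se_g_per_allele=float(res.bse["grs"]),
        se_g_per_day_per_allele=float(res.bse["grs"]) / interval,
        p_value=float(res.pvalues["grs"]),
        n=n,
        mean_interval_days=interval,
    )


def fit_sga_lga(
    grs: pd.Series,
    categories: pd.Series | dict[str, GrowthCategory],
    outcome: str,
) -> SgaLgaFit:
    """Logistic regression of an SGA or LGA indicator on the GRS.

    ``categories`` maps fetus id to a label ('SGA'/'AGA'/'LGA') or a
    :class:`GrowthCategory`. Returns the per-allele odds ratio with a
    Wald 95% CI. Complete separation raises with a diagnostic.
    """
    if outcome not in ("SGA", "LGA"):
        raise ValueError("outcome must be 'SGA' or 'LGA'")
    if isinstance(categories, dict):
        labels = pd.Series(
            {k: v.label if isinstance(v, GrowthCategory) else v
             for k, v in categories.items()}
        )
    else:
        labels = pd.Series(categories).map(
            lambda v: v.label if isinstance(v, GrowthCategory) else v
        )
    df = pd.DataFrame({"grs": pd.Series(grs).astype(float)})
    df["y"] = (labels.reindex(df.index) == outcome).astype(float)
    df = df.dropna()
    n_cases = int(df["y"].sum())
    if n_cases < 10:
        raise ValueError(f"only {n_cases} {outcome} cases; need at least 10")
    X = sm.add_constant(df[["grs"]])
    try:
        res = sm.Logit(df["y"], X).fit(disp=0)
    except Exception as exc:  # pragma: no cover - separation is data-dependent
        raise RuntimeError(
            f"logistic fit failed (possible complete separation): {exc}"
        ) from exc
    if not np.all(np.isfinite(res.bse)):
        raise RuntimeError("logistic fit unstable: infinite standard errors "
                           "(complete separation?)")
    ci = res.conf_int().loc["grs"]
    return SgaLgaFit(
        outcome=outcome,
        odds_ratio=float(np.exp(res.params["grs"])),
        ci_low=float(np.exp(ci.iloc[0])),
        ci_high=float(np.exp(ci.iloc[1])),
        p_value=float(res.pvalues["grs"]),
        n_cases=n_cases,
        n=len(df),
    )
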