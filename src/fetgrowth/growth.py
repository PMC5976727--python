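"""Quadratic growth-curve models of log fetal size, conditioned on
genetic risk and maternal covariates.

The unconditional model for any log outcome (estimated fetal weight,
or a raw biometry measure) is

    log y ~ GA + GA^2                                    (unconditional)

and conditioning enters only through the curvature, because at GA 0 a
fetal genotype or maternal trait cannot yet have acted on size:

    log y ~ GA + GA^2 + GA^2 x GRS [+ GA^2 x Sex + GA^2 x BMI]

GRS and BMI are centered at realized cohort means, so main effects are
absorbed in the intercept; female sex is coded 0/1. Three-way
gene-environment tests add GA^2 x GRS x modifier together with the
constituent GA^2 x modifier term.

Raw log-scale estimates are re-expressed on interpretable scales:

* intercept -> geometric mean size at GA 0 (grams or mm): exp(b)
* linear GA -> daily proportional gain in % per day: (exp(b) - 1) * 100
* quadratic GA^2 and every GA^2 interaction -> change in the daily
  proportional gain, in percentage points per day: b * 2 * 100
  (d/dt of the t^2 term's contribution to the daily log-gain is 2*b*t,
  so 2*b is the per-day change of the daily rate; x100 for percent)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import SpatialGrowthLMM, SpatialLMMResults
from .panel import VariantPanel

__all__ = [
    "GrowthModelSpec",
    "GrowthCurveModel",
    "GrowthCurveResults",
    "transform_intercept",
    "transform_linear",
    "transform_quadratic",
    "anchored_term_difference",
    "fit_growth",
    "fit_threeway",
    "per_variant_scan",
]

log = logging.getLogger(__name__)

_BIOMETRY_OUTCOMES = ("ac_mm", "fl_mm", "bpd_mm", "ofd_mm")
_MODIFIERS = ("BMI", "glucose", "smoking")


# ----------------------------------------------------------------------
# scale transformations
# ----------------------------------------------------------------------
def transform_intercept(raw):
    """Log-scale intercept -> geometric-mean size at GA 0 (g or mm)."""
    return np.exp(raw)


def transform_linear(raw):
    """Linear GA coefficient -> daily proportional gain, % per day."""
    return (np.exp(raw) - 1.0) * 100.0


def transform_quadratic(raw):
    """GA^2 (or GA^2-interaction) coefficient -> change in daily
    proportional gain, percentage points per day."""
    return np.asarray(raw, dtype=float) * 200.0 if np.ndim(raw) else raw * 200.0


@dataclass(frozen=True)
class GrowthModelSpec:
    """What to model: outcome, birth-record inclusion, and conditioning.

    ga2_interactions entries are "GRS", "Sex", "BMI" or a variant id
    present in a supplied dosage column. Interactions with the *linear*
    GA term are never specified: the linear coefficient is the growth
    rate at GA 0, before genotype or environment can plausibly act.
    """

    outcome: str = "weight"
    include_birth: bool = True
    ga2_interactions: tuple[str, ...] = ()
    threeway: str | None = None

    def __post_init__(self) -> None:
        if self.outcome != "weight" and self.outcome not in _BIOMETRY_OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome != "weight" and self.include_birth:
            object.__setattr__(self, "include_birth", False)
        if self.threeway is not None:
            if self.threeway not in _MODIFIERS:
                raise ValueError(f"three-way modifier must be one of {_MODIFIERS}")
            if "GRS" not in self.ga2_interactions:
                raise ValueError("three-way interaction requires GRS among "
                                 "ga2_interactions")


class GrowthCurveModel:
    """Growth-curve LMM assembled from cohort tables.

    Build with :meth:`from_dataframes` (or :meth:`from_cohort` for a
    simulated cohort); ``fit()`` runs the REML spatial mixed model and
    returns :class:`GrowthCurveResults`.
    """

    def __init__(self, endog, exog, groups, times, exog_names, spec, centers):
        self.spec = spec
        self.centers = centers  # covariate centering used in the design
        self._lmm = SpatialGrowthLMM(endog, exog, groups, times, exog_names=exog_names)

    @property
    def n_obs(self) -> int:
        return self._lmm.n_obs

    @property
    def n_fetuses(self) -> int:
        return self._lmm.n_groups

    @classmethod
    def from_cohort(cls, cohort, spec: GrowthModelSpec | None = None,
                    grs: pd.Series | None = None, dosages: pd.DataFrame | None = None):
        from .grs import compute_grs

        if spec is None:
            spec = GrowthModelSpec()
        if grs is None:
            grs = compute_grs(cohort.dosages, cohort.panel)["score"]
        return cls.from_dataframes(
            weights=cohort.weights,
            covariates=cohort.covariates,
            grs=grs,
            spec=spec,
            scans=cohort.scans,
            dosages=dosages if dosages is not None else cohort.dosages,
        )

    @classmethod
    def from_dataframes(
        cls,
        weights: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        grs: pd.Series | None = None,
        spec: GrowthModelSpec | None = None,
        scans: pd.DataFrame | None = None,
        dosages: pd.DataFrame | None = None,
    ) -> "GrowthCurveModel":
        """Assemble the design from long-format tables.

        ``weights`` needs fetus_id, ga_days, weight_g and (for birth
        filtering) source; biometry outcomes are read from ``scans``.
        ``grs`` is indexed by fetus id; ``dosages`` supplies per-variant
        columns when a variant id appears in the interactions.
        Fetuses missing a modeled covariate are dropped listwise.
        """
        if spec is None:
            spec = GrowthModelSpec()

        if spec.outcome == "weight":
            df = weights.copy()
            if not spec.include_birth and "source" in df.columns:
                df = df[df["source"] != "birth"]
            value_col = "weight_g"
        else:
            if scans is None:
                raise ValueError(f"outcome {spec.outcome!r} requires the scans table")
            df = scans.copy()
            value_col = spec.outcome
        df = df[np.isfinite(df[value_col]) & (df[value_col] > 0)]

        cov = None
        if covariates is not None:
            cov = covariates.set_index("fetus_id") \
                if "fetus_id" in covariates.columns else covariates

        # per-fetus covariate lookup for the interaction terms
        per_fetus: dict[str, pd.Series] = {}
        centers: dict[str, float] = {}
        n_before = df["fetus_id"].nunique()
        keep = pd.Series(True, index=df["fetus_id"].unique())

        def need(name: str, series: pd.Series, center: bool):
            series = series.reindex(keep.index)
            ok = series.notna()
            keep[~ok] = False
            if center:
                centers[name] = float(series[ok].mean())
                series = series - centers[name]
            per_fetus[name] = series

        terms = list(spec.ga2_interactions)
        if spec.threeway is not None:
            pass  # modifier handled below
        for term in terms:
            if term == "GRS":
                if grs is None:
                    raise ValueError("spec includes GRS but no scores were supplied")
                need("GRS", pd.Series(grs).astype(float), center=True)
            elif term == "Sex":
                if cov is None or "sex" not in cov.columns:
                    raise ValueError("spec includes Sex but covariates lack 'sex'")
                sex = cov["sex"].replace("", np.nan)
                female = sex.map({"female": 1.0, "male": 0.0})
                need("Sex", female, center=False)
            elif term == "BMI":
                if cov is None or "bmi" not in cov.columns:
                    raise ValueError("spec includes BMI but covariates lack 'bmi'")
                need("BMI", cov["bmi"].astype(float), center=True)
            else:  # a variant dosage column
                if dosages is None or term not in dosages.columns:
                    raise ValueError(f"no dosage column for variant {term!r}")
                dose = dosages[term].astype(float)
                if dose.nunique(dropna=True) <= 1:
                    raise ValueError(f"variant {term!r} is monomorphic in this cohort")
                need(term, dose, center=True)
        if spec.threeway is not None:
            col = {"BMI": "bmi", "glucose": "glucose_2h", "smoking": "smoking"}[
                spec.threeway
            ]
            if cov is None or col not in cov.columns:
                raise ValueError(f"three-way modifier needs covariate column {col!r}")
            mod = cov[col].astype(float)
            if mod.nunique(dropna=True) <= 1:
                raise ValueError(f"modifier {spec.threeway} is constant")
            need(f"mod_{spec.threeway}", mod, center=spec.threeway != "smoking")

        kept_ids = keep.index[keep]
        n_dropped = n_before - len(kept_ids)
        if n_dropped:
            log.info("listwise deletion dropped %d of %d fetuses", n_dropped, n_before)
        if len(kept_ids) < 50:
            log.warning("only %d fetuses remain after listwise deletion", len(kept_ids))
        df = df[df["fetus_id"].isin(set(kept_ids))]

        t = df["ga_days"].to_numpy(dtype=float)
        y = np.log(df[value_col].to_numpy(dtype=float))
        fid = df["fetus_id"].to_numpy()
        ga2 = t**2
        cols = {"const": np.ones_like(t), "ga": t, "ga2": ga2}
        for term in terms:
            vals = per_fetus[term].reindex(df["fetus_id"]).to_numpy(dtype=float)
            cols[f"ga2_x_{term}"] = ga2 * vals
        if spec.threeway is not None:
            mname = f"mod_{spec.threeway}"
            mvals = per_fetus[mname].reindex(df["fetus_id"]).to_numpy(dtype=float)
            gvals = per_fetus["GRS"].reindex(df["fetus_id"]).to_numpy(dtype=float)
            cols[f"ga2_x_{spec.threeway}"] = ga2 * mvals
            cols[f"ga2_x_GRS_x_{spec.threeway}"] = ga2 * gvals * mvals
        X = pd.DataFrame(cols)
        return cls(y, X, fid, t, list(X.columns), spec, centers)

    def fit(self, **fit_kwargs) -> "GrowthCurveResults":
        res = self._lmm.fit(**fit_kwargs)
        return GrowthCurveResults(spec=self.spec, centers=self.centers, lmm=res)


_SCALE_BY_KIND = {
    "intercept": "g (geometric mean at GA 0)",
    "linear": "% per day",
    "quadratic": "%-points per day",
}


@dataclass
class GrowthCurveResults:
    """Growth-curve fit with raw and back-transformed effects."""

    spec: GrowthModelSpec
    centers: dict[str, float]
    lmm: SpatialLMMResults
    params: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.params = self.lmm.params

    # -- pass-throughs -------------------------------------------------
    @property
    def bse(self) -> pd.Series:
        return self.lmm.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.lmm.pvalues

    @property
    def converged(self) -> bool:
        return self.lmm.converged

    @property
    def vc(self):
        return self.lmm.vc

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.lmm.conf_int(alpha)

    # -- interpretable scales -------------------------------------------
    @staticmethod
    def _term_kind(name: str) -> str:
        if name == "const":
            return "intercept"
        if name == "ga":
            return "linear"
        return "quadratic"  # ga2 and every GA^2 interaction

    def transformed_effects(self, alpha: float = 0.05) -> pd.DataFrame:
        """Raw estimates plus their values on the interpretable scale,
        with CIs mapped through the same monotone transformation."""
        ci = self.conf_int(alpha)
        rows = []
        for name in self.params.index:
            kind = self._term_kind(name)
            f = {
                "intercept": transform_intercept,
                "linear": transform_linear,
                "quadratic": transform_quadratic,
            }[kind]
            rows.append(
                {
                    "term": name,
                    "raw": self.params[name],
                    "raw_ci_low": ci.loc[name, "lower"],
                    "raw_ci_high": ci.loc[name, "upper"],
                    "transformed": f(self.params[name]),
                    "ci_low": f(ci.loc[name, "lower"]),
                    "ci_high": f(ci.loc[name, "upper"]),
                    "scale": _SCALE_BY_KIND[kind],
                    "p_value": self.pvalues[name],
                }
            )
        return pd.DataFrame(rows).set_index("term")

    # -- prediction ------------------------------------------------------
    def _linear_predictor(self, ga_days: float, covariate_values: dict) -> float:
        t = float(ga_days)
        x = {"const": 1.0, "ga": t, "ga2": t * t}
        for name in self.params.index:
            if name in x:
                continue
            key = name.removeprefix("ga2_x_")
            val = covariate_values.get(key, 0.0)
            if key in self.centers:
                val = val - self.centers[key] if key in covariate_values else 0.0
            x[name] = t * t * val
        return float(sum(self.params[k] * x[k] for k in self.params.index))

    def predict_weight(self, ga_days: float, **covariate_values) -> float:
        """Population-level predicted size (g or mm) at ``ga_days``.

        Covariates are given on their natural scale (e.g. ``GRS=60``,
        ``BMI=25``, ``Sex=1`` for female); omitted centered covariates
        sit at their cohort means. Random effects are set to zero.
        """
        if not 0.0 <= ga_days <= 310.0:
            log.warning("predicting outside the modeled GA range: %s days", ga_days)
        return math.exp(self._linear_predictor(ga_days, covariate_values))

    def term_difference(
        self, grs_low: float, grs_high: float, ga_days: float = 280.0, **covariates
    ) -> float:
        """Predicted weight gap (g) at ``ga_days`` between the highest-
        and lowest-GRS fetus, other covariates at cohort means."""
        if "ga2_x_GRS" not in self.params.index:
            raise ValueError("model has no GA^2 x GRS term")
        if grs_low > grs_high:
            raise ValueError("grs_low must not exceed grs_high")
        hi = self.predict_weight(ga_days, GRS=grs_high, **covariates)
        lo = self.predict_weight(ga_days, GRS=grs_low, **covariates)
        return hi - lo

    def summary(self) -> str:
        base = self.lmm.summary()
        te = self.transformed_effects()
        lines = [base, "", "Interpretable scale:"]
        for term, row in te.iterrows():
            lines.append(
                f"  {term:<22}{row['transformed']:>12.4g}  "
                f"({row['ci_low']:.4g}; {row['ci_high']:.4g})  [{row['scale']}]"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = self.lmm.to_dict()
        d["spec"] = {
            "outcome": self.spec.outcome,
            "include_birth": self.spec.include_birth,
            "ga2_interactions": list(self.spec.ga2_interactions),
            "threeway": self.spec.threeway,
        }
        d["centers"] = dict(self.centers)
        te = self.transformed_effects()
        d["transformed"] = {
            term: {
                "value": float(row["transformed"]),
                "ci_low": float(row["ci_low"]),
                "ci_high": float(row["ci_high"]),
                "scale": row["scale"],
            }
            for term, row in te.iterrows()
        }
        return d


def anchored_term_difference(
    b0: float,
    b1: float,
    b2: float,
    gamma_grs: float,
    grs_low: float,
    grs_high: float,
    grs_mean: float,
    ga_days: float = 280.0,
) -> float:
    """Weight gap (g) at ``ga_days`` implied by a per-allele curvature
    shift ``gamma_grs`` around an unconditional quadratic anchor.

    Used when a conditional fit's own intercept/GA terms are not
    available: the unconditional curve (b0, b1, b2) is taken as the
    trajectory of a fetus at the cohort-mean GRS and the curvature is
    shifted by gamma_grs per allele away from that mean.
    """
    if grs_low > grs_high:
        raise ValueError("grs_low must not exceed grs_high")
    t2 = ga_days * ga_days
    base = b0 + b1 * ga_days + b2 * t2

    def w(g):
        return math.exp(base + gamma_grs * (g - grs_mean) * t2)

    return w(grs_high) - w(grs_low)


# ----------------------------------------------------------------------
# convenience entry points
# ----------------------------------------------------------------------
def fit_growth(
    spec: GrowthModelSpec,
    weights: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    grs: pd.Series | None = None,
    scans: pd.DataFrame | None = None,
    dosages: pd.DataFrame | None = None,
    **fit_kwargs,
) -> GrowthCurveResults:
    """Build and fit a growth-curve model in one call."""
    model = GrowthCurveModel.from_dataframes(
        weights, covariates=covariates, grs=grs, spec=spec, scans=scans,
        dosages=dosages,
    )
    return model.fit(**fit_kwargs)


def fit_threeway(
    modifier: str,
    weights: pd.DataFrame,
    covariates: pd.DataFrame,
    grs: pd.Series,
    include_birth: bool = True,
    adjusted: bool = True,
    **fit_kwargs,
) -> GrowthCurveResults:
    """Gene-environment test: GA^2 x GRS x modifier added to the
    conditional model (with its constituent GA^2 x modifier term)."""
    inter = ("GRS", "Sex", "BMI") if adjusted else ("GRS",)
    if modifier == "BMI" and "BMI" not in inter:
        inter = inter + ("BMI",)
    spec = GrowthModelSpec(
        outcome="weight",
        include_birth=include_birth,
        ga2_interactions=inter,
        threeway=modifier,
    )
    return fit_growth(spec, weights, covariates=covariates, grs=grs, **fit_kwargs)


def per_variant_scan(
    panel: VariantPanel,
    weights: pd.DataFrame,
    covariates: pd.DataFrame,
    dosages: pd.DataFrame,
    adjusted: bool = True,
    include_birth: bool = True,
    **fit_kwargs,
) -> pd.DataFrame:
    """Independent per-variant growth effects.

    For each panel variant, the GA^2 x GRS term is replaced by
    GA^2 x dosage (sex/BMI-adjusted when ``adjusted``); one row per
    variant with the raw estimate, SE, Wald p and the %-points-per-day
    transform. No multiplicity correction is applied — the loci carry
    strong prior evidence. Monomorphic variants are flagged and skipped.
    """
    rows = []
    extra = ("Sex", "BMI") if adjusted else ()
    for vid in panel.variant_ids:
        if vid not in dosages.columns:
            raise ValueError(f"dosage matrix lacks panel variant {vid!r}")
        if dosages[vid].nunique(dropna=True) <= 1:
            log.warning("variant %s is monomorphic; skipped", vid)
            rows.append(
                {"variant_id": vid, "estimate": np.nan, "se": np.nan,
                 "z": np.nan, "p_value": np.nan, "transformed": np.nan,
                 "status": "monomorphic"}
            )
            continue
        spec = GrowthModelSpec(
            outcome="weight",
            include_birth=include_birth,
            ga2_interactions=(vid,) + extra,
        )
        res = fit_growth(
            spec, weights, covariates=covariates, dosages=dosages, **fit_kwargs
        )
        term = f"ga2_x_{vid}"
        rows.append(
            {
                "variant_id": vid,
                "estimate": res.params[term],
                "se": res.bse[term],
                "z": res.lmm.zvalues[term],
                "p_value": res.pvalues[term],
                "transformed": transform_quadratic(res.params[term]),
                "status": "ok" if res.converged else "not_converged",
            }
        )
    return pd.DataFrame(rows).set_index("variant_id")
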