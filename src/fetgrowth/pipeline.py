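"""Reproducible end-to-end pipeline: simulate -> EFW -> GRS -> growth
fits -> period fits -> publication-shaped report tables.

Every stochastic stage is driven by the single configured seed; a run
writes a manifest recording the configuration, package version and
SHA-256 of every output file, so two runs from the same config are
byte-identical and self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biometry import hadlock_weight, head_circumference
from .grs import compute_grs, grs_tertiles
from .growth import GrowthCurveResults, GrowthModelSpec, fit_growth
from .panel import default_panel
from .periods import PERIODS, fit_period
from .simulate import DEFAULT_TRUTH, CohortData, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "render_tables", "hadlock_from_scans"]

log = logging.getLogger(__name__)

_TRUTH_FIELDS = {f.name for f in dataclasses.fields(DEFAULT_TRUTH)}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a pipeline run."""

    seed: int
    out_dir: str
    truth_overrides: dict = field(default_factory=dict)
    adjusted: bool = True
    include_birth: bool = True
    significant_digits: int = 3

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        unknown = set(self.truth_overrides) - _TRUTH_FIELDS
        if unknown:
            raise ValueError(f"unknown truth overrides: {sorted(unknown)}")
        if self.significant_digits < 1:
            raise ValueError("significant_digits must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def hadlock_from_scans(scans: pd.DataFrame) -> pd.DataFrame:
    """Estimated fetal weight records from a biometry scan table.

    HC is derived from BPD/OFD via the ellipse-perimeter rule; output
    has the weights-table layout with source='ultrasound'.
    """
    hc = np.array(
        [head_circumference(b, o) for b, o in zip(scans["bpd_mm"], scans["ofd_mm"])]
    )
    w = np.array(
        [
            hadlock_weight(a, f, h, bounds=None)
            for a, f, h in zip(scans["ac_mm"], scans["fl_mm"], hc)
        ]
    )
    return pd.DataFrame(
        {
            "fetus_id": scans["fetus_id"],
            "ga_days": scans["ga_days"],
            "weight_g": w,
            "source": "ultrasound",
        }
    )


def _fmt(x: float, sig: int) -> str:
    return "NA" if not np.isfinite(x) else f"{x:.{sig}g}"


def render_tables(
    fits: dict[str, GrowthCurveResults], significant_digits: int = 3
) -> dict[str, str]:
    """Publication-shaped TSVs from a dict of outcome-name -> fit.

    'unconditional' table: intercept/GA/GA^2 raw + transformed columns;
    'conditional' table: every GA^2 interaction term's raw and
    transformed estimate with CI and p. Unconverged fits are flagged in
    a status column rather than dropped.
    """
    sig = significant_digits
    uncond_rows = ["\t".join(
        ["outcome", "status",
         "intercept_raw", "intercept_ci", "intercept_transformed",
         "intercept_transformed_ci",
         "ga_raw", "ga_ci", "ga_pct_per_day", "ga_pct_ci",
         "ga2_raw", "ga2_ci", "ga2_pctpts_per_day", "ga2_pctpts_ci"]
    )]
    cond_rows = ["\t".join(
        ["outcome", "term", "status", "raw", "raw_ci", "transformed",
         "transformed_ci", "p_value"]
    )]
    for name, fit in fits.items():
        te = fit.transformed_effects()
        status = "ok" if fit.converged else "NOT_CONVERGED"
        cells = [name, status]
        for term in ("const", "ga", "ga2"):
            r = te.loc[term]
            cells += [
                _fmt(r["raw"], sig),
                f"({_fmt(r['raw_ci_low'], sig)}; {_fmt(r['raw_ci_high'], sig)})",
                _fmt(r["transformed"], sig),
                f"({_fmt(r['ci_low'], sig)}; {_fmt(r['ci_high'], sig)})",
            ]
        uncond_rows.append("\t".join(cells))
        for term in te.index:
            if not term.startswith("ga2_x_"):
                continue
            r = te.loc[term]
            cond_rows.append("\t".join([
                name, term, status,
                _fmt(r["raw"], sig),
                f"({_fmt(r['raw_ci_low'], sig)}; {_fmt(r['raw_ci_high'], sig)})",
                _fmt(r["transformed"], sig),
                f"({_fmt(r['ci_low'], sig)}; {_fmt(r['ci_high'], sig)})",
                _fmt(r["p_value"], sig),
            ]))
    return {
        "unconditional": "\n".join(uncond_rows) + "\n",
        "conditional": "\n".join(cond_rows) + "\n",
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in dependency order; returns the run directory.

    Stages: simulate the cohort, recompute EFW from biometry via the
    Hadlock stage, score the GRS with tertiles, fit unconditional and
    conditional growth models (weight and each biometry measure for the
    unconditional set), fit the three period regressions, render report
    tables, and write the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        truth = DEFAULT_TRUTH.replace(**config.truth_overrides)
        cohort: CohortData = simulate_cohort(truth, seed=config.seed)
        paths = cohort.to_dir(out)

        stage = "hadlock"
        efw = hadlock_from_scans(cohort.scans)
        paths["efw"] = out / "efw_hadlock.csv"
        efw.to_csv(paths["efw"], index=False, float_format="%.10g")

        stage = "grs"
        scores = compute_grs(cohort.dosages, cohort.panel)
        tert = grs_tertiles(scores["score"])
        scores = scores.assign(tertile=tert.tertile)
        paths["grs"] = out / "grs.csv"
        scores.to_csv(paths["grs"], index_label="fetus_id", float_format="%.10g")

        stage = "fit-growth"
        grs_series = scores["score"]
        fits: dict[str, GrowthCurveResults] = {}
        fits["weight_incl_birth"] = fit_growth(
            GrowthModelSpec(outcome="weight", include_birth=True),
            cohort.weights,
        )
        inter = ("GRS", "Sex", "BMI") if config.adjusted else ("GRS",)
        fits["weight_conditional"] = fit_growth(
            GrowthModelSpec(
                outcome="weight",
                include_birth=config.include_birth,
                ga2_interactions=inter,
            ),
            cohort.weights,
            covariates=cohort.covariates,
            grs=grs_series,
        )
        paths["fits"] = out / "fits.json"
        paths["fits"].write_text(
            json.dumps({k: v.to_dict() for k, v in fits.items()},
                       indent=2, sort_keys=True) + "\n"
        )

        stage = "fit-periods"
        period_lines = ["period\tn\tcoef_g_per_allele\tcoef_g_per_day_per_allele"
                        "\tse_g_per_allele\tp_value"]
        for period in PERIODS:
            pf = fit_period(
                period, cohort.weights, grs_series,
                covariates=cohort.covariates, adjusted=config.adjusted,
            )
            period_lines.append(
                f"{pf.period}\t{pf.n}\t{pf.coef_g_per_allele:.6g}"
                f"\t{pf.coef_g_per_day_per_allele:.6g}"
                f"\t{pf.se_g_per_allele:.6g}\t{pf.p_value:.4g}"
            )
        paths["periods"] = out / "periods.tsv"
        paths["periods"].write_text("\n".join(period_lines) + "\n")

        stage = "report"
        tables = render_tables(fits, config.significant_digits)
        for key, text in tables.items():
            paths[f"table_{key}"] = out / f"table_{key}.tsv"
            paths[f"table_{key}"].write_text(text)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "truth": cohort.truth.as_dict(),
        "outputs": {k: {"path": p.name, "sha256": _sha256(p)}
                    for k, p in sorted(paths.items())},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out
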