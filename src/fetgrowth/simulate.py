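"""Synthetic pregnancy-cohort generator.

Emulates the statistical structure of a Danish ultrasound cohort: each
fetus receives three growth scans near gestational days 140, 175 and
224 (20, 25 and 32 weeks) plus a birth-weight measurement near
279 +/- 10 days. Log fetal weight follows a quadratic trend in
gestational age whose curvature is shifted by the fetus's genetic risk
score (GRS), sex and maternal pre-pregnancy BMI, on top of a per-fetus
random intercept and slope and a Gaussian-correlated residual process:

    log w(t) = b0 + b1*t + (b2 + g_grs*GRS_c + g_sex*female + g_bmi*BMI_c)*t^2
               + u0 + u1*t + e(t)

with (u0, u1) ~ N(0, [[tau00, tau01], [tau01, tau11]]) and
cov(e(s), e(t)) = sigma2 * exp(-((s-t)/rho)^2). GRS_c and BMI_c are
centered at the realized cohort means, matching the interaction-only
model specification downstream.

Biometry (AC/FL/BPD/OFD) is generated from per-measure log-quadratic
trends with multiplicative log-normal noise, which keeps measurements
positive and lets the Hadlock weight stage be exercised end to end.

The defaults are the study conditions: 665 fetuses, published growth
and interaction coefficients, maternal BMI 24.8 +/- 4.9, 10% smoking,
a 155/665 glucose subset, and a 58-variant dosage panel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import VariantPanel, default_panel

__all__ = [
    "SimulationTruth",
    "CohortData",
    "DEFAULT_TRUTH",
    "BIOMETRY_TRUTH",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_biometry",
]

#: Per-measure (intercept, linear, quadratic) log-scale growth trends in
#: mm: abdominal circumference, femur length, biparietal and
#: occipitofrontal diameters.
BIOMETRY_TRUTH: dict[str, tuple[float, float, float]] = {
    "ac_mm": (2.95, 0.0190, -3.10e-5),
    "fl_mm": (0.861, 0.0249, -4.64e-5),
    "bpd_mm": (1.89, 0.0187, -3.28e-5),
    "ofd_mm": (2.04, 0.0198, -3.62e-5),
}


@dataclass(frozen=True)
class SimulationTruth:
    """Generative parameters for the synthetic cohort.

    Fixed-effect defaults are the published unconditional and adjusted
    conditional growth coefficients for weight including birth weight;
    variance components are package choices calibrated so the log-scale
    weight SD (~0.12-0.13) matches the observed coefficients of
    variation (e.g. 42.6/328 g at 20 weeks, 474/3580 g at birth).
    """

    b0: float = 0.774  # log-g intercept at GA 0
    b1: float = 0.0456  # per-day linear log-weight slope
    b2: float = -6.82e-5  # per-day^2 curvature
    gamma_grs: float = 4.46e-8  # GA^2 x GRS, day^-2 per allele
    gamma_sex: float = -4.99e-7  # GA^2 x female sex, day^-2
    gamma_bmi: float = 4.10e-8  # GA^2 x BMI, day^-2 per kg/m^2
    tau00: float = 0.012  # random-intercept variance (log^2)
    tau01: float = 0.0  # intercept-slope covariance
    tau11: float = 2.0e-8  # random-slope variance (day^-2)
    sigma2: float = 0.003  # residual variance (log^2)
    rho: float = 20.0  # Gaussian correlation range, days
    scan_days: tuple[float, ...] = (140.0, 175.0, 224.0)
    scan_jitter_sd: float = 3.0
    birth_ga_mean: float = 279.0
    birth_ga_sd: float = 10.0
    birth_ga_window: tuple[float, float] = (240.0, 300.0)
    n_fetuses: int = 665
    bmi_mean: float = 24.8
    bmi_sd: float = 4.9
    age_mean: float = 30.2
    age_sd: float = 4.7
    smoking_rate: float = 0.10
    glucose_fraction: float = 155.0 / 665.0
    glucose_mean: float = 5.9  # mmol/L, 2-h post-load
    glucose_sd: float = 1.2
    missing_sex_rate: float = 10.0 / 665.0
    birth_extra_sd: float = 0.0  # extra log-scale birth measurement noise
    biometry_noise_sd: float = 0.03  # log-scale multiplicative noise

    def __post_init__(self) -> None:
        if self.tau00 < 0 or self.tau11 < 0:
            raise ValueError("random-effect variances must be non-negative")
        if abs(self.tau01) > np.sqrt(self.tau00 * self.tau11) + 1e-15:
            raise ValueError("tau01 violates positive semidefiniteness")
        if self.sigma2 < 0 or self.rho <= 0:
            raise ValueError("sigma2 must be non-negative and rho positive")
        if self.n_fetuses < 1:
            raise ValueError("need at least one fetus")

    def replace(self, **kwargs) -> "SimulationTruth":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scan_days"] = list(self.scan_days)
        d["birth_ga_window"] = list(self.birth_ga_window)
        return d


DEFAULT_TRUTH = SimulationTruth()


@dataclass
class CohortData:
    """In-memory synthetic cohort: the standard long/wide tables plus
    the generative truth that produced them."""

    weights: pd.DataFrame  # fetus_id, ga_days, weight_g, source
    scans: pd.DataFrame  # fetus_id, ga_days, ac_mm, fl_mm, bpd_mm, ofd_mm
    covariates: pd.DataFrame  # per-fetus maternal + fetal covariates
    dosages: pd.DataFrame  # fetus x variant dosage matrix
    panel: VariantPanel
    truth: SimulationTruth
    seed: int

    def to_dir(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the cohort as plain-text tables; deterministic bytes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "weights": out / "weights.csv",
            "scans": out / "scans.csv",
            "covariates": out / "covariates.csv",
            "dosages": out / "dosages.tsv",
            "truth": out / "truth.json",
        }
        fmt = "%.10g"
        self.weights.to_csv(paths["weights"], index=False, float_format=fmt)
        self.scans.to_csv(paths["scans"], index=False, float_format=fmt)
        self.covariates.to_csv(paths["covariates"], index=False, float_format=fmt)
        self.dosages.to_csv(
            paths["dosages"], sep="\t", index_label="fetus_id", float_format=fmt
        )
        payload = {"seed": self.seed, "truth": self.truth.as_dict()}
        paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return paths


def simulate_genotypes(
    panel: VariantPanel,
    n: int,
    seed: int | np.random.Generator,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Hardy-Weinberg dosages: Binomial(2, EAF) per fetus and variant.

    An optional ``missing_rate`` masks entries to NaN afterwards,
    emulating genotyping dropout.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    dosages = rng.binomial(2, panel.eaf_array, size=(n, len(panel))).astype(float)
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan
    ids = [f"F{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame(dosages, index=pd.Index(ids, name="fetus_id"),
                        columns=list(panel.variant_ids))


def _scan_and_birth_times(truth: SimulationTruth, n: int, rng) -> np.ndarray:
    """(n, k+1) observation times: jittered scans then birth, ordered."""
    k = len(truth.scan_days)
    base = np.asarray(truth.scan_days, dtype=float)
    times = base + rng.normal(0.0, truth.scan_jitter_sd, size=(n, k))
    lo, hi = truth.birth_ga_window
    birth = np.clip(
        rng.normal(truth.birth_ga_mean, truth.birth_ga_sd, size=n), lo, hi
    )
    # enforce strict ordering 20w < 25w < 32w < birth by re-sorting the
    # jittered scans and nudging any scan that crossed the next one
    times = np.sort(times, axis=1)
    times = np.minimum(times, birth[:, None] - 5.0)
    for j in range(1, k):
        times[:, j] = np.maximum(times[:, j], times[:, j - 1] + 1.0)
    return np.column_stack([times, birth])


def _gp_residuals(times: np.ndarray, sigma2: float, rho: float, rng) -> np.ndarray:
    """Stationary Gaussian-kernel residual draws, one row per fetus."""
    if sigma2 == 0.0:
        return np.zeros_like(times)
    d = times[:, :, None] - times[:, None, :]
    cov = sigma2 * np.exp(-((d / rho) ** 2))
    cov += 1e-12 * sigma2 * np.eye(times.shape[1])
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal(times.shape + (1,))
    return (L @ z)[:, :, 0]


def simulate_cohort(
    truth: SimulationTruth = DEFAULT_TRUTH,
    panel: VariantPanel | None = None,
    seed: int = 0,
    with_biometry: bool = True,
) -> CohortData:
    """Generate a complete synthetic cohort under ``truth``.

    Returns weight records (3 ultrasound estimates plus birth weight per
    fetus), maternal/fetal covariates, the dosage matrix, and — unless
    ``with_biometry`` is disabled — raw biometry scans generated from
    the per-measure growth trends.
    """
    rng = np.random.default_rng(seed)
    if panel is None:
        panel = default_panel()
    n = truth.n_fetuses
    fetus_ids = np.array([f"F{i:04d}" for i in range(1, n + 1)])

    # --- covariates -------------------------------------------------
    bmi = np.maximum(rng.normal(truth.bmi_mean, truth.bmi_sd, size=n), 15.0)
    age = np.maximum(rng.normal(truth.age_mean, truth.age_sd, size=n), 18.0)
    smoking = rng.random(n) < truth.smoking_rate
    parity = rng.choice(6, size=n, p=[0.38, 0.42, 0.145, 0.030, 0.020, 0.005])
    glucose = np.where(
        rng.random(n) < truth.glucose_fraction,
        rng.normal(truth.glucose_mean, truth.glucose_sd, size=n),
        np.nan,
    )
    female = rng.random(n) < 0.5
    sex_missing = rng.random(n) < truth.missing_sex_rate

    dosages = simulate_genotypes(panel, n, rng)
    dosages.index = pd.Index(fetus_ids, name="fetus_id")
    grs = dosages.sum(axis=1).to_numpy()
    grs_c = grs - grs.mean()
    bmi_c = bmi - bmi.mean()

    # --- observation times and log-weight trajectories ---------------
    times = _scan_and_birth_times(truth, n, rng)  # (n, 4)
    quad = (
        truth.b2
        + truth.gamma_grs * grs_c
        + truth.gamma_sex * female.astype(float)
        + truth.gamma_bmi * bmi_c
    )
    mean_log_w = truth.b0 + truth.b1 * times + quad[:, None] * times**2

    re_cov = np.array(
        [[truth.tau00, truth.tau01], [truth.tau01, truth.tau11]]
    )
    eig = np.linalg.eigvalsh(re_cov)
    if eig[0] < -1e-12:
        raise ValueError("random-effect covariance is not positive semidefinite")
    if np.any(eig > 0):
        L = np.linalg.cholesky(re_cov + 1e-18 * np.eye(2))
        u = rng.standard_normal((n, 2)) @ L.T
    else:
        u = np.zeros((n, 2))
    log_w = mean_log_w + u[:, [0]] + u[:, [1]] * times
    log_w += _gp_residuals(times, truth.sigma2, truth.rho, rng)
    if truth.birth_extra_sd > 0:
        log_w[:, -1] += rng.normal(0.0, truth.birth_extra_sd, size=n)

    k = len(truth.scan_days)
    source = np.array(["ultrasound"] * k + ["birth"])
    weights = pd.DataFrame(
        {
            "fetus_id": np.repeat(fetus_ids, k + 1),
            "ga_days": times.ravel(),
            "weight_g": np.exp(log_w).ravel(),
            "source": np.tile(source, n),
        }
    )

    covariates = pd.DataFrame(
        {
            "fetus_id": fetus_ids,
            "mother_id": [f"M{i:04d}" for i in range(1, n + 1)],
            "bmi": bmi,
            "age": age,
            "smoking": smoking.astype(int),
            "parity": parity,
            "glucose_2h": glucose,
            "sex": np.where(sex_missing, "", np.where(female, "female", "male")),
            "birth_ga": times[:, -1],
            "birth_weight": np.exp(log_w[:, -1]),
        }
    )

    scans = (
        simulate_biometry(times[:, :k], fetus_ids, truth, rng)
        if with_biometry
        else pd.DataFrame(
            columns=["fetus_id", "ga_days", "ac_mm", "fl_mm", "bpd_mm", "ofd_mm"]
        )
    )

    return CohortData(
        weights=weights,
        scans=scans,
        covariates=covariates,
        dosages=dosages,
        panel=panel,
        truth=truth,
        seed=seed if isinstance(seed, int) else -1,
    )


def simulate_biometry(
    scan_times: np.ndarray,
    fetus_ids: np.ndarray,
    truth: SimulationTruth = DEFAULT_TRUTH,
    rng: np.random.Generator | int = 0,
    trends: dict[str, tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Biometry (mm) at scan times from log-quadratic trends.

    Noise is multiplicative log-normal (SD ``truth.biometry_noise_sd``
    on the log scale), so generated measurements are always positive.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if trends is None:
        trends = BIOMETRY_TRUTH
    t = np.asarray(scan_times, dtype=float)
    n, k = t.shape
    out = {
        "fetus_id": np.repeat(np.asarray(fetus_ids), k),
        "ga_days": t.ravel(),
    }
    for measure, (a0, a1, a2) in trends.items():
        log_m = a0 + a1 * t + a2 * t**2
        if truth.biometry_noise_sd > 0:
            log_m = log_m + rng.normal(0.0, truth.biometry_noise_sd, size=t.shape)
        out[measure] = np.exp(log_m).ravel()
    return pd.DataFrame(out)
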