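"""Unweighted genetic risk score (GRS) from effect-allele dosages.

The score for a fetus is the plain sum of its effect-allele dosages
over the variant panel — every birth-weight-raising allele counts one,
regardless of published effect size. Units are therefore "alleles";
fractional values arise from imputed dosages. Tertile groups are cut at
the empirical 33.3%/66.7% quantiles of the cohort's score distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import VariantPanel

__all__ = ["compute_grs", "grs_tertiles", "TertileResult", "read_dosages"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TertileResult:
    """Tertile cut points and per-fetus tertile labels."""

    cut_low: float
    cut_high: float
    tertile: pd.Series  # int in {1,2,3}, indexed like the input scores


def compute_grs(
    dosages: pd.DataFrame,
    panel: VariantPanel,
    missing_policy: str = "impute_eaf",
) -> pd.DataFrame:
    """Sum effect-allele dosages into a per-fetus risk score.

    Parameters
    ----------
    dosages
        Fetus-by-variant dosage matrix; index = fetus ids, columns =
        variant ids matching the panel; values in [0, 2] or NaN.
    panel
        The variant panel; columns are aligned to it by variant id.
    missing_policy
        "impute_eaf" replaces a missing dosage with its Hardy-Weinberg
        expectation 2*EAF; "drop" sums observed dosages only.

    Returns
    -------
    DataFrame indexed by fetus id with columns ``score`` (alleles) and
    ``n_missing`` (variants imputed or dropped for that fetus).
    """
    if missing_policy not in ("impute_eaf", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    unknown = [c for c in dosages.columns if c not in set(panel.variant_ids)]
    if unknown:
        raise ValueError(f"dosage columns not in panel: {unknown}")
    absent = [v for v in panel.variant_ids if v not in dosages.columns]
    if absent:
        raise ValueError(f"panel variants absent from dosage matrix: {absent}")
    mat = dosages.loc[:, list(panel.variant_ids)].astype(float)
    values = mat.to_numpy()
    finite = np.isfinite(values)
    if np.any((values[finite] < 0) | (values[finite] > 2)):
        bad = np.argwhere(finite & ((values < 0) | (values > 2)))[0]
        raise ValueError(
            f"dosage outside [0, 2] at fetus {mat.index[bad[0]]!r}, "
            f"variant {mat.columns[bad[1]]!r}: {values[tuple(bad)]}"
        )
    n_missing = (~finite).sum(axis=1)
    if missing_policy == "impute_eaf":
        expected = 2.0 * panel.eaf_array
        values = np.where(finite, values, np.broadcast_to(expected, values.shape))
    else:
        values = np.where(finite, values, 0.0)
    return pd.DataFrame(
        {"score": values.sum(axis=1), "n_missing": n_missing}, index=mat.index
    )


def grs_tertiles(scores: pd.Series) -> TertileResult:
    """Empirical tertile cut points and labels for a cohort of scores.

    Cut points are linear-interpolation quantiles at 1/3 and 2/3. Ties at
    a cut point go to the lower tertile. A degenerate distribution (all
    scores equal) returns everyone in tertile 1 with a warning.
    """
    s = pd.Series(scores).astype(float)
    if s.size < 3:
        raise ValueError(f"need at least 3 scores for tertiles, got {s.size}")
    cut_low, cut_high = np.quantile(s.to_numpy(), [1.0 / 3.0, 2.0 / 3.0])
    if cut_low == cut_high:
        log.warning(
            "degenerate GRS distribution: tertile cut points coincide at %s", cut_low
        )
    tert = pd.Series(np.ones(s.size, dtype=int), index=s.index)
    tert[s > cut_low] = 2
    tert[s > cut_high] = 3
    return TertileResult(cut_low=float(cut_low), cut_high=float(cut_high), tertile=tert)


def read_dosages(path: str) -> pd.DataFrame:
    """Read a fetus-by-variant dosage matrix.

    Accepts the tab-separated text layout (first column = fetus id,
    remaining columns = variant ids) or a VCF with a per-genotype ``DS``
    FORMAT field (requires the optional cyvcf2 dependency; variant rows
    become columns keyed by their ID).
    """
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf_dosages(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def _read_vcf_dosages(path: str) -> pd.DataFrame:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF dosages requires cyvcf2") from exc
    vcf = VCF(path)
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for record in vcf:
        vid = record.ID or f"{record.CHROM}:{record.POS}"
        ds = record.format("DS")
        if ds is None:
            raise ValueError(f"variant {vid} has no DS (dosage) FORMAT field")
        columns[vid] = np.asarray(ds, dtype=float).reshape(-1)
    return pd.DataFrame(columns, index=pd.Index(samples, name="fetus_id"))
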