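"""Two-dimensional ultrasound biometry to estimated fetal weight.

Estimated fetal weight (EFW) follows the Hadlock log10-linear regression on
abdominal circumference (AC), femur length (FL) and head circumference (HC).
HC is not always exported by the scanner; when only the two head diameters
are available it is approximated from the biparietal (BPD) and
occipitofrontal (OFD) diameters by the ellipse-perimeter rule
HC = (pi/2) * (BPD + OFD).

Birth size classification (SGA / AGA / LGA) uses percent deviation of the
observed birth weight from an expected weight-for-gestational-age reference,
with the Scandinavian clinical thresholds of -15% (10th percentile) and
+22% (90th percentile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

__all__ = [
    "head_circumference",
    "hadlock_weight",
    "classify_sga_lga",
    "GrowthCategory",
    "SGA_THRESHOLD_PCT",
    "LGA_THRESHOLD_PCT",
    "BiometryBounds",
    "DEFAULT_BOUNDS",
]

#: Percent deviation below which a newborn is small-for-gestational-age.
SGA_THRESHOLD_PCT = -15.0
#: Percent deviation above which a newborn is large-for-gestational-age.
LGA_THRESHOLD_PCT = 22.0


@dataclass(frozen=True)
class BiometryBounds:
    """Physiological upper bounds (mm) for EFW inputs.

    Values outside these bounds almost always indicate unit errors
    (cm vs mm) or transcription problems, so they raise rather than clamp.
    """

    ac_max_mm: float = 450.0
    fl_max_mm: float = 90.0
    hc_max_mm: float = 400.0


DEFAULT_BOUNDS = BiometryBounds()


@dataclass(frozen=True)
class GrowthCategory:
    """Birth-size classification relative to expected weight for GA."""

    label: str  # "SGA" | "AGA" | "LGA"
    deviation_pct: float


def head_circumference(bpd_mm: float, ofd_mm: float) -> float:
    """Head circumference (mm) from the two skull diameters.

    Uses the ellipse-perimeter approximation HC = (pi/2)(BPD + OFD),
    exact for a circle and adequate for the mild ellipticity of the
    fetal skull. Depends on the diameters only through their sum.
    """
    if not (bpd_mm > 0 and ofd_mm > 0):
        raise ValueError(
            f"head diameters must be positive, got BPD={bpd_mm}, OFD={ofd_mm}"
        )
    return (math.pi / 2.0) * (bpd_mm + ofd_mm)


def hadlock_weight(
    ac_mm: float,
    fl_mm: float,
    hc_mm: float,
    *,
    bounds: BiometryBounds | None = DEFAULT_BOUNDS,
) -> float:
    """Hadlock estimated fetal weight in grams from biometry in mm.

    weight = 10 ** (1.326 - 0.00326*AC*FL/100 + 0.0107*HC/10
                    + 0.0438*AC/10 + 0.158*FL/10)

    The /100 and /10 factors convert mm inputs onto the cm scale of the
    original Hadlock coefficients. Pass ``bounds=None`` to disable the
    physiological range check (e.g. for formula-level testing).
    """
    for name, v in (("AC", ac_mm), ("FL", fl_mm), ("HC", hc_mm)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {v}")
    if bounds is not None:
        if ac_mm > bounds.ac_max_mm:
            raise ValueError(f"AC={ac_mm} mm exceeds bound {bounds.ac_max_mm} mm")
        if fl_mm > bounds.fl_max_mm:
            raise ValueError(f"FL={fl_mm} mm exceeds bound {bounds.fl_max_mm} mm")
        if hc_mm > bounds.hc_max_mm:
            raise ValueError(f"HC={hc_mm} mm exceeds bound {bounds.hc_max_mm} mm")
    exponent = (
        1.326
        - 0.00326 * ac_mm * fl_mm / 100.0
        + 0.0107 * hc_mm / 10.0
        + 0.0438 * ac_mm / 10.0
        + 0.158 * fl_mm / 10.0
    )
    return 10.0 ** exponent


def classify_sga_lga(
    birth_weight_g: float,
    birth_ga_days: float,
    reference: Callable[[float], float],
) -> GrowthCategory:
    """Classify a newborn as SGA / AGA / LGA.

    ``reference`` maps gestational age in days to the expected birth
    weight in grams (an injectable national standard or a fitted growth
    curve). The deviation is 100*(observed - expected)/expected, labelled
    SGA below -15%, LGA above +22%, AGA otherwise.
    """
    expected = reference(birth_ga_days)
    if not (isinstance(expected, (int, float)) and math.isfinite(expected)) or expected <= 0:
        raise ValueError(
            f"reference returned non-positive expected weight {expected!r} "
            f"at GA {birth_ga_days} days"
        )
    deviation = 100.0 * (birth_weight_g - expected) / expected
    if deviation < SGA_THRESHOLD_PCT:
        label = "SGA"
    elif deviation > LGA_THRESHOLD_PCT:
        label = "LGA"
    else:
        label = "AGA"
    return GrowthCategory(label=label, deviation_pct=deviation)
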