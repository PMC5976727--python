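"""Variant panel for the birth-weight genetic risk score.

The score sums effect-allele dosages over a fixed panel of biallelic
GWAS loci associated with birth weight; the default panel size is 58
(60 published loci minus two not capturable on the genotyping array).
Per-variant effect-allele frequencies (EAF) are not published for the
study cohort, so the default panel draws them once from uniform(0.05,
0.95) under a fixed panel seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VariantPanel", "default_panel", "DEFAULT_N_VARIANTS", "PANEL_SEED"]

DEFAULT_N_VARIANTS = 58
#: Seed used once to draw the default panel's allele frequencies.
PANEL_SEED = 20180530

_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantPanel:
    """A panel of biallelic variants scored by effect-allele dosage.

    Parameters
    ----------
    variant_ids
        Unique variant identifiers (e.g. rsIDs), one per locus.
    effect_alleles
        Effect (score-raising) allele per variant, one of A/C/G/T.
    eaf
        Effect-allele frequency per variant, strictly inside (0, 1).
    """

    variant_ids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    eaf: tuple[float, ...] = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.variant_ids)
        if len(self.effect_alleles) != n or len(self.eaf) != n:
            raise ValueError("variant_ids, effect_alleles and eaf must align")
        if len(set(self.variant_ids)) != n:
            raise ValueError("variant identifiers must be unique")
        for a in self.effect_alleles:
            if a not in _VALID_ALLELES:
                raise ValueError(f"effect allele must be one of A/C/G/T, got {a!r}")
        freqs = np.asarray(self.eaf, dtype=float)
        if not np.all(np.isfinite(freqs)) or np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
            raise ValueError("effect-allele frequencies must lie strictly in (0, 1)")

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def eaf_array(self) -> np.ndarray:
        return np.asarray(self.eaf, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "effect_allele": self.effect_alleles,
                "eaf": self.eaf,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VariantPanel":
        required = {"variant_id", "effect_allele", "eaf"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        return cls(
            variant_ids=tuple(df["variant_id"].astype(str)),
            effect_alleles=tuple(df["effect_allele"].astype(str)),
            eaf=tuple(df["eaf"].astype(float)),
        )


def default_panel(
    n_variants: int = DEFAULT_N_VARIANTS, seed: int = PANEL_SEED
) -> VariantPanel:
    """The default score panel with EAFs drawn once under a fixed seed.

    Frequencies are uniform(0.05, 0.95); effect alleles are drawn
    uniformly from A/C/G/T (they are labels only — dosages are already
    oriented to the effect allele).
    """
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(0.05, 0.95, size=n_variants)
    alleles = rng.choice(list("ACGT"), size=n_variants)
    ids = tuple(f"rsSYN{i:04d}" for i in range(1, n_variants + 1))
    return VariantPanel(
        variant_ids=ids,
        effect_alleles=tuple(alleles),
        eaf=tuple(eaf),
    )
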