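"""Polysome-gradient distribution analysis.

A sucrose gradient separates free mRNPs (light fractions), monosomes and
polysomes; the per-fraction amount of a transcript, measured by RT-qPCR,
reports its translational status.  An exogenous spike RNA added equally to
every fraction corrects fraction-to-fraction recovery differences; the
corrected quantities are normalized to the sum over fractions, giving a
distribution whose mass in the polysome fractions is the translated
proportion.

Default fraction classes for a 14-fraction gradient: LIGHT = 1-6 (free
mRNPs), MONOSOME = 7-8 (span the 80S peak, counted in neither numerator),
POLYSOME = 9-13, fraction 14 UNASSIGNED.  The heavy-polysome subrange
(>= 4 ribosomes per mRNA) defaults to fractions 11-13 and is configurable,
since the fraction-to-ribosome mapping is gradient-specific.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "FractionClass",
    "PolysomeProfile",
    "TranslationSummary",
    "ShiftReport",
    "default_fraction_classes",
    "spike_correct",
    "fraction_distribution",
    "translated_proportion",
    "compare_conditions",
    "summarize_profile",
]

DEFAULT_N_FRACTIONS = 14
DEFAULT_HEAVY_RANGE = (11, 13)


class FractionClass(str, enum.Enum):
    LIGHT = "LIGHT"
    MONOSOME = "MONOSOME"
    POLYSOME = "POLYSOME"
    UNASSIGNED = "UNASSIGNED"


def default_fraction_classes(n_fractions: int = DEFAULT_N_FRACTIONS) -> dict[int, FractionClass]:
    """LIGHT 1-6, MONOSOME 7-8, POLYSOME 9-13, UNASSIGNED beyond."""
    classes = {}
    for f in range(1, n_fractions + 1):
        if f <= 6:
            classes[f] = FractionClass.LIGHT
        elif f <= 8:
            classes[f] = FractionClass.MONOSOME
        elif f <= 13:
            classes[f] = FractionClass.POLYSOME
        else:
            classes[f] = FractionClass.UNASSIGNED
    return classes


@dataclass
class PolysomeProfile:
    """Per-fraction quantities for one condition: targets x fractions 1..F."""

    condition: str
    quantities: pd.DataFrame  # index = targets, columns = fraction ints 1..F
    spike: pd.Series  # per-fraction spike quantity
    fraction_classes: Optional[Mapping[int, FractionClass]] = None
    n_fractions: int = field(init=False)

    def __post_init__(self) -> None:
        cols = list(self.quantities.columns)
        expected = list(range(1, len(cols) + 1))
        if cols != expected:
            raise ValueError("fractions must be contiguous integers from 1")
        self.n_fractions = len(cols)
        if self.n_fractions < 3:
            raise ValueError("need at least 3 fractions")
        if (self.quantities.to_numpy() < 0).any():
            raise ValueError("quantities must be non-negative")
        self.spike = self.spike.reindex(cols)
        if self.spike.isna().any() or (self.spike <= 0).any():
            raise ValueError("spike must be positive in every fraction")
        if self.fraction_classes is None:
            self.fraction_classes = default_fraction_classes(self.n_fractions)
        else:
            self.fraction_classes = {
                int(f): FractionClass(c) for f, c in self.fraction_classes.items()
            }
            if set(self.fraction_classes) != set(cols):
                raise ValueError("fraction class map must cover all fractions")


@dataclass
class TranslationSummary:
    target: str
    condition: str
    distribution: pd.Series  # over fractions, sums to 1
    translated_proportion: float
    heavy_polysome_proportion: float


@dataclass
class ShiftReport:
    """Condition b relative to condition a; positive = more translated in b."""

    target: str
    condition_a: str
    condition_b: str
    delta_distribution: pd.Series
    delta_translated_proportion: float
    delta_heavy_polysome_proportion: float


def spike_correct(profile: PolysomeProfile) -> pd.DataFrame:
    """Divide each fraction by its relative (mean-centered) spike recovery.

    A fraction recovering twice the average spike has its quantities halved;
    a uniform spike leaves quantities unchanged.  The correction is unit-free
    and preserves within-fraction ratios between targets.
    """
    rel = profile.spike / profile.spike.mean()
    return profile.quantities.div(rel, axis=1)


def fraction_distribution(corrected: pd.DataFrame, target: str) -> pd.Series:
    """Normalize one target's corrected quantities to sum to 1."""
    if target not in corrected.index:
        raise ValueError(f"unknown target {target!r}")
    q = corrected.loc[target]
    if (q < 0).any():
        raise ValueError("negative quantity")
    total = float(q.sum())
    if total <= 0:
        raise ValueError(f"all-zero quantities for target {target!r}")
    return q / total


def translated_proportion(
    distribution: pd.Series,
    fraction_classes: Mapping[int, FractionClass],
    target: str = "",
    condition: str = "",
    heavy_range: tuple[int, int] = DEFAULT_HEAVY_RANGE,
) -> TranslationSummary:
    """Mass in POLYSOME fractions; heavy subrange reported separately.

    MONOSOME and UNASSIGNED fractions count in the denominator (the
    distribution sums to 1) but in neither numerator.
    """
    fracs = list(distribution.index)
    classes = {int(f): FractionClass(c) for f, c in fraction_classes.items()}
    if set(classes) != set(int(f) for f in fracs):
        raise ValueError("fraction class map must cover all fractions")
    poly = [f for f in fracs if classes[int(f)] is FractionClass.POLYSOME]
    heavy = [f for f in fracs if heavy_range[0] <= int(f) <= heavy_range[1]]
    return TranslationSummary(
        target=target,
        condition=condition,
        distribution=distribution,
        translated_proportion=float(distribution.loc[poly].sum()),
        heavy_polysome_proportion=float(distribution.loc[heavy].sum()),
    )


def compare_conditions(summary_a: TranslationSummary, summary_b: TranslationSummary) -> ShiftReport:
    """Per-fraction and summary deltas, b minus a."""
    if summary_a.target != summary_b.target:
        raise ValueError("summaries describe different targets")
    if not summary_a.distribution.index.equals(summary_b.distribution.index):
        raise ValueError("mismatched fraction layouts")
    return ShiftReport(
        target=summary_a.target,
        condition_a=summary_a.condition,
        condition_b=summary_b.condition,
        delta_distribution=summary_b.distribution - summary_a.distribution,
        delta_translated_proportion=(
            summary_b.translated_proportion - summary_a.translated_proportion
        ),
        delta_heavy_polysome_proportion=(
            summary_b.heavy_polysome_proportion - summary_a.heavy_polysome_proportion
        ),
    )


def summarize_profile(
    profile: PolysomeProfile,
    heavy_range: tuple[int, int] = DEFAULT_HEAVY_RANGE,
) -> list[TranslationSummary]:
    """Spike-correct, normalize and summarize every target in a profile."""
    corrected = spike_correct(profile)
    return [
        translated_proportion(
            fraction_distribution(corrected, target),
            profile.fraction_classes,
            target=target,
            condition=profile.condition,
            heavy_range=heavy_range,
        )
        for target in corrected.index
    ]
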