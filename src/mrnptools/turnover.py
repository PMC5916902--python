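"""Densitometry calibration and protein half-life estimation.

Western-blot band intensities are calibrated against a serial dilution of a
reference sample (least-squares line through the origin: zero protein gives
zero signal), converted to relative amounts with an optional per-lane loading
factor, and cycloheximide-chase series — amounts relative to t = 0 — are fit
with a single-exponential decay model: ordinary least squares on log2(amount)
versus time with a free intercept, so t = 0 measurement noise does not anchor
the fit.  The decay constant k = -slope * ln 2 is clipped at zero (apparent
growth warns rather than errors) and the half-life is ln 2 / k, infinite when
k = 0.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DilutionSeries",
    "ChaseSeries",
    "DecayFit",
    "AmountEstimate",
    "fit_dilution_calibration",
    "signal_to_amount",
    "fit_exponential_decay",
]

LN2 = math.log(2.0)


@dataclass
class DilutionSeries:
    """Serial-dilution calibration: signal = slope x amount through origin."""

    points: list  # (relative_amount, signal) pairs
    slope: Optional[float] = None
    r_squared: Optional[float] = None
    calibration_range: Optional[tuple[float, float]] = None


@dataclass
class ChaseSeries:
    """Cycloheximide-chase time course, amounts relative to t = 0."""

    protein: str
    condition: str
    times: Sequence[float]  # minutes, strictly increasing from 0
    amounts: Sequence[float]  # positive

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amounts, dtype=float)
        if t.shape != a.shape:
            raise ValueError("times and amounts must have equal length")
        if t[0] != 0:
            raise ValueError("time course must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(a <= 0):
            raise ValueError("amounts must be positive")
        self.times = t
        self.amounts = a


@dataclass
class DecayFit:
    protein: str
    condition: str
    k: float  # per-minute decay constant, >= 0
    half_life: float  # minutes, inf when k == 0
    intercept: float  # fitted log2 amount at t = 0
    residual_sd: float
    clipped: bool = False  # True when an apparent-growth slope was clipped


@dataclass
class AmountEstimate:
    amount: float
    in_calibration_range: bool


def fit_dilution_calibration(
    points: Sequence[tuple[float, float]],
) -> DilutionSeries:
    """Fit signal = slope x amount by least squares through the origin.

    The reported r^2 is the uncentered coefficient of determination
    (1 - SS_res / sum signal^2), which equals 1 exactly on noiseless
    proportional data.
    """
    pts = [(float(a), float(s)) for a, s in points]
    amounts = np.array([a for a, _ in pts])
    signals = np.array([s for _, s in pts])
    if len(set(amounts)) < 2:
        raise ValueError("need at least 2 distinct dilution amounts")
    if np.any(amounts <= 0):
        raise ValueError("dilution amounts must be positive")
    if np.any(signals < 0):
        raise ValueError("signals must be non-negative")
    if np.all(signals == 0):
        raise ValueError("all signals are zero; cannot calibrate")
    slope = float(np.dot(signals, amounts) / np.dot(amounts, amounts))
    residuals = signals - slope * amounts
    ss_tot = float(np.dot(signals, signals))
    r2 = 1.0 - float(np.dot(residuals, residuals)) / ss_tot
    return DilutionSeries(
        points=pts,
        slope=slope,
        r_squared=r2,
        calibration_range=(float(amounts.min()), float(amounts.max())),
    )


def signal_to_amount(
    signal: float,
    calibration: DilutionSeries,
    loading_factor: float = 1.0,
) -> AmountEstimate:
    """Invert the calibration: amount = (signal / slope) / loading_factor.

    Signals mapping outside the calibrated amount range are converted but
    flagged through ``in_calibration_range``.
    """
    if calibration.slope is None or calibration.slope <= 0:
        raise ValueError("calibration slope must be positive")
    if loading_factor <= 0:
        raise ValueError("loading_factor must be positive")
    amount = (signal / calibration.slope) / loading_factor
    lo, hi = calibration.calibration_range
    raw_amount = signal / calibration.slope
    return AmountEstimate(amount=amount, in_calibration_range=bool(lo <= raw_amount <= hi))


def fit_exponential_decay(series: ChaseSeries) -> DecayFit:
    """Single-exponential fit of a chase series; see module docstring."""
    t = np.asarray(series.times, dtype=float)
    a = np.asarray(series.amounts, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    y = np.log2(a)
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    residuals = y - design @ coef
    dof = len(t) - 2
    residual_sd = float(np.sqrt(np.dot(residuals, residuals) / dof)) if dof > 0 else 0.0
    clipped = False
    k = -slope * LN2
    if k < 0:
        _warnings.warn(
            f"{series.protein}/{series.condition}: apparent growth; "
            "decay constant clipped at 0",
            stacklevel=2,
        )
        k = 0.0
        clipped = True
    half_life = math.inf if k == 0 else LN2 / k
    return DecayFit(
        protein=series.protein,
        condition=series.condition,
        k=k,
        half_life=half_life,
        intercept=intercept,
        residual_sd=residual_sd,
        clipped=clipped,
    )
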