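"""Translation step time from β-galactosidase induction assays.

After IPTG induction of lacZ, no enzyme activity appears until the first
complete β-galactosidase chain (1,024 amino acids) has been elongated.  The
classic linearization plots sqrt(A420 − 1.75·A540) against time after
correcting each channel for reagent background and the time-zero sample; the
transformed signal rises linearly once the first complete protein appears, and
its x-axis intercept is the step time.  The elongation (synthesis) rate is
1024 aa divided by the step time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StepTimeError",
    "InductionSeries",
    "TransformedSeries",
    "StepTimeResult",
    "schleif_transform",
    "estimate_step_time",
    "BETA_GAL_LENGTH",
    "SCATTER_COEFF",
]

BETA_GAL_LENGTH = 1024      # amino acids in β-galactosidase
SCATTER_COEFF = 1.75        # light-scattering correction of A420 by A540
DEFAULT_MIN_FIT_POINTS = 4


class StepTimeError(ValueError):
    """Raised for invalid induction data or non-inducing assays."""


@dataclass
class InductionSeries:
    """Raw A420/A540 readings taken at fixed intervals after induction."""

    times: np.ndarray           # seconds since induction
    a420: np.ndarray
    a540: np.ndarray
    background_a420: float      # ONPG in Z buffer without cells
    background_a540: float
    t0_a420: float              # time-zero sample (pre-induction)
    t0_a540: float
    strain_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a420 = np.asarray(self.a420, dtype=float)
        self.a540 = np.asarray(self.a540, dtype=float)
        if not (self.times.shape == self.a420.shape == self.a540.shape):
            raise StepTimeError("times, a420 and a540 must have equal length")
        if self.times.size and (np.any(np.diff(self.times) <= 0) or self.times[0] < 0):
            raise StepTimeError("times must be nonnegative and strictly increasing")
        for name in ("background_a420", "background_a540", "t0_a420", "t0_a540"):
            if not math.isfinite(getattr(self, name)):
                raise StepTimeError(f"{name} must be finite")
        if not (np.isfinite(self.a420).all() and np.isfinite(self.a540).all()):
            raise StepTimeError("absorbance readings must be finite")


@dataclass
class TransformedSeries:
    """sqrt-transformed, background- and t0-corrected induction signal."""

    times: np.ndarray
    signal: np.ndarray          # sqrt(max(0, corrA420 - 1.75*corrA540))
    clamped: np.ndarray         # True where the sqrt operand was negative
    strain_id: str = ""


@dataclass
class StepTimeResult:
    step_time: float            # seconds
    synthesis_rate: float       # amino acids / second; rate * step_time == 1024
    relative_rate: float        # vs a supplied reference rate (NaN if none given)
    fit_slope: float
    fit_intercept: float
    fit_window: tuple[int, int]  # [start, end] indices into the series
    strain_id: str = ""


def schleif_transform(series: InductionSeries) -> TransformedSeries:
    """Correct and linearize an induction series.

    Each channel is corrected by subtracting the reagent background and then
    the background-corrected time-zero value; the transformed signal is
    sqrt(corrA420 − 1.75·corrA540).  Negative square-root operands occur
    legitimately before induction (noise around zero) and are clamped to 0
    and flagged.
    """
    corr420 = (series.a420 - series.background_a420) - (series.t0_a420 - series.background_a420)
    corr540 = (series.a540 - series.background_a540) - (series.t0_a540 - series.background_a540)
    operand = corr420 - SCATTER_COEFF * corr540
    clamped = operand < 0
    signal = np.sqrt(np.where(clamped, 0.0, operand))
    return TransformedSeries(
        times=series.times.copy(),
        signal=signal,
        clamped=clamped,
        strain_id=series.strain_id,
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    syy = float(((y - ym) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 1.0 if syy == 0.0 else min((sxy * sxy) / (sxx * syy), 1.0)
    return slope, intercept, r2


def estimate_step_time(
    transformed: TransformedSeries,
    min_fit_points: int = DEFAULT_MIN_FIT_POINTS,
    reference_rate: float | None = None,
    protein_length: int = BETA_GAL_LENGTH,
) -> StepTimeResult:
    """Estimate the step time as the x-intercept of the rising induced curve.

    Points are eligible once the transformed signal exceeds 3x the standard
    deviation of the pre-induction (zero-plateau) values.  Among trailing
    suffix windows of at least ``min_fit_points`` eligible points, the one
    with the highest R² is fitted by ordinary least squares; ties go to the
    longer window.  The fitted line's x-intercept (−intercept/slope) is the
    step time, and synthesis_rate = protein_length / step_time.

    Raises
    ------
    StepTimeError
        If fewer than ``min_fit_points`` points rise above the noise
        threshold, or the fitted line does not cross zero from below
        (no induction).
    """
    t = transformed.times
    y = transformed.signal
    if t.size < min_fit_points:
        raise StepTimeError("series shorter than min_fit_points")

    # noise threshold from the pre-induction plateau: the leading stretch of
    # points whose signal never rises, i.e. everything before the last zero
    zero_idx = np.flatnonzero(y <= 0)
    if zero_idx.size:
        baseline = y[: zero_idx[-1] + 1]
        threshold = 3.0 * float(np.std(baseline))
    else:
        threshold = 0.0
    eligible = np.flatnonzero(y > threshold)
    if eligible.size < min_fit_points:
        raise StepTimeError(
            f"only {eligible.size} points above noise threshold, need {min_fit_points}"
        )

    first = int(eligible[0])
    n = t.size
    best: tuple[float, int] | None = None      # (r2, window length)
    best_fit: tuple[float, float, int] | None = None
    for start in range(first, n - min_fit_points + 1):
        slope, intercept, r2 = _ols(t[start:], y[start:])
        key = (r2, n - start)
        if best is None or key > best:
            best = key
            best_fit = (slope, intercept, start)
    assert best_fit is not None
    slope, intercept, start = best_fit
    if slope <= 0 or intercept >= 0:
        raise StepTimeError(
            f"no induction: fitted slope {slope:.4g}, intercept {intercept:.4g} "
            "do not give a positive x-axis crossing"
        )
    step = -intercept / slope
    rate = protein_length / step
    rel = rate / reference_rate if reference_rate else math.nan
    return StepTimeResult(
        step_time=step,
        synthesis_rate=rate,
        relative_rate=rel,
        fit_slope=slope,
        fit_intercept=intercept,
        fit_window=(start, n - 1),
        strain_id=transformed.strain_id,
    )
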