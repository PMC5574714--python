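"""Growth-curve kinetics: doubling time, lag time, maximum OD and relative fitness.

The estimator follows the classical Bioscreen workflow: blank-correct each
sample well against its medium-only control, log-transform, fit ordinary least
squares on a sliding window of exactly ``window_points`` consecutive readings
(50 min at 5-min sampling), and take the window with the steepest slope as the
exponential phase.  From that fit,

    DT  = ln(2) / slope
    lag = (initial log OD - y intercept) / slope

and the maximum OD is simply the largest blank-corrected reading over the run.
Relative fitness of a strain is the mean over its replicates of
(reference mean DT) / (replicate DT), so slower-growing strains score < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthError",
    "PlateReaderSeries",
    "CorrectedLogSeries",
    "GrowthFit",
    "GrowthParameters",
    "RelativeFitness",
    "preprocess_curve",
    "fit_exponential_window",
    "growth_parameters",
    "relative_fitness",
    "analyze_curve",
]

DEFAULT_WINDOW_POINTS = 10
DEFAULT_OD_FLOOR = 1e-4


class GrowthError(ValueError):
    """Raised for invalid or degenerate growth-curve input."""


@dataclass
class PlateReaderSeries:
    """One well's OD600 time series.

    ``times`` are minutes since the start of the run and must be strictly
    increasing; ``role`` is ``"sample"`` or ``"blank"`` (medium-only control).
    """

    well_id: str
    times: np.ndarray
    od600: np.ndarray
    role: str = "sample"
    strain_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape:
            raise GrowthError(
                f"well {self.well_id}: times and od600 lengths differ "
                f"({self.times.size} vs {self.od600.size})"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise GrowthError(f"well {self.well_id}: times not strictly increasing")
        if self.role not in ("sample", "blank"):
            raise GrowthError(f"well {self.well_id}: role must be sample|blank, got {self.role!r}")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class CorrectedLogSeries:
    """Blank-corrected curve: natural-log OD with sub-floor points masked."""

    times: np.ndarray
    corrected_od: np.ndarray
    log_od: np.ndarray          # natural log; NaN where masked
    mask: np.ndarray            # True where the point is usable
    well_id: str = ""
    strain_id: str = ""
    replicate_id: str = ""

    @property
    def n_usable(self) -> int:
        return int(self.mask.sum())


@dataclass
class GrowthFit:
    """OLS fit of the selected exponential-phase window (log scale)."""

    slope: float                # d ln(OD)/dt, per minute
    y_intercept: float          # ln-OD at t = 0
    window_start: float         # minutes
    window_end: float
    r_squared: float            # NaN for a degenerate (flat) series
    initial_od_log: float       # first usable ln-OD of the series
    window_indices: tuple[int, int] = (0, 0)
    degenerate: bool = False


@dataclass
class GrowthParameters:
    doubling_time: float        # minutes; NaN when the curve is non-growing
    lag_time: float             # minutes
    max_od: float
    strain_id: str = ""
    replicate_id: str = ""


@dataclass
class RelativeFitness:
    strain_id: str
    fitness: float
    reference_mean_dt: float
    per_replicate_values: list[float] = field(default_factory=list)


def preprocess_curve(
    sample: PlateReaderSeries,
    blank: PlateReaderSeries,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> CorrectedLogSeries:
    """Blank-correct a sample well and log-transform it.

    Points whose corrected OD is at or below ``od_floor`` are masked (excluded
    from fitting) rather than clamped, so the log transform never manufactures
    spurious low outliers.

    Raises
    ------
    GrowthError
        If the time grids differ or every point falls below the floor.
    """
    if len(sample) != len(blank) or not np.allclose(sample.times, blank.times):
        raise GrowthError(
            f"sample well {sample.well_id} and blank well {blank.well_id} "
            "are on different time grids"
        )
    corrected = sample.od600 - blank.od600
    mask = corrected > od_floor
    if not mask.any():
        raise GrowthError(
            f"well {sample.well_id}: no corrected OD above floor {od_floor} (empty curve)"
        )
    log_od = np.full_like(corrected, np.nan)
    log_od[mask] = np.log(corrected[mask])
    return CorrectedLogSeries(
        times=sample.times.copy(),
        corrected_od=corrected,
        log_od=log_od,
        mask=mask,
        well_id=sample.well_id,
        strain_id=sample.strain_id,
        replicate_id=sample.replicate_id,
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, r_squared).

    r_squared is NaN when y has zero variance (undefined, flat window).
    """
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    syy = float(((y - ym) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    if syy <= 1e-20:     # flat within floating-point noise
        return slope, intercept, math.nan
    r2 = (sxy * sxy) / (sxx * syy)
    return slope, intercept, min(r2, 1.0)


def _smooth_runs(y: np.ndarray, runs: list[np.ndarray], k: int) -> np.ndarray:
    """Centered moving average of width ``k`` within each contiguous run.

    Edges use the available one-sided neighborhood.  A symmetric window
    preserves straight lines exactly, so smoothing never shifts the slope of
    a noiseless exponential phase; it only suppresses read noise when ranking
    candidate windows.
    """
    out = np.full_like(y, np.nan)
    h = k // 2
    for run in runs:
        vals = y[run]
        for i in range(run.size):
            lo, hi = max(0, i - h), min(run.size, i + h + 1)
            out[run[i]] = vals[lo:hi].mean()
    return out


def _slope_se(x: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> float:
    n = x.size
    resid = y - (intercept + slope * x)
    sxx = float(((x - x.mean()) ** 2).sum())
    if n <= 2 or sxx == 0:
        return 0.0
    return math.sqrt(float((resid**2).sum()) / (n - 2) / sxx)


def fit_exponential_window(
    log_series: CorrectedLogSeries,
    window_points: int = DEFAULT_WINDOW_POINTS,
    smooth_points: int = 9,
) -> GrowthFit:
    """Find the steepest log-linear window of exactly ``window_points`` points.

    Every contiguous run of usable points is scanned with an exhaustive
    sliding window.  Candidate windows are ranked on a lightly smoothed copy
    of the log curve (centered moving average over ``smooth_points`` points)
    so plate-reader noise at low OD cannot promote a spuriously steep window.
    Because the steepest *observed* slope among many noisy windows is biased
    upward, the selected window is not the argmax itself but the earliest
    window whose smoothed slope is statistically consistent with the maximum
    (within two standard errors of the argmax window's slope); on a noiseless
    curve the standard error is zero and this reduces to the plain
    maximum-slope rule with ties broken by earlier start.  The selected
    window is then refitted by ordinary least squares on the raw points and
    those raw coefficients are reported.  ``smooth_points=1`` disables
    smoothing.  A completely flat series returns slope 0 with
    ``degenerate=True`` and NaN R².

    The reported ``initial_od_log`` is a plateau estimate: starting from the
    first usable log OD, the implied lag is computed and the median of the
    pre-lag points (on the OD scale) refines it, twice.  For a curve with no
    lag the estimate stays the first point, so lag 0 is recovered exactly.
    """
    if window_points < 2:
        raise GrowthError("window_points must be >= 2")
    if smooth_points < 1 or smooth_points % 2 == 0:
        raise GrowthError("smooth_points must be a positive odd number")
    idx = np.flatnonzero(log_series.mask)
    if idx.size < window_points:
        raise GrowthError(
            f"well {log_series.well_id}: only {idx.size} usable points, "
            f"need {window_points} for a window"
        )
    t = log_series.times
    y = log_series.log_od
    # windows run over consecutive usable points; a gap of masked points
    # breaks contiguity so the fit never straddles an unusable stretch
    runs: list[np.ndarray] = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    ys = _smooth_runs(y, runs, smooth_points) if smooth_points > 1 else y

    windows: list[tuple[np.ndarray, float, float]] = []   # (indices, slope, r2)
    for run in runs:
        for s in range(0, run.size - window_points + 1):
            w = run[s : s + window_points]
            slope, _, r2 = _ols(t[w], ys[w])
            windows.append((w, slope, -math.inf if math.isnan(r2) else r2))
    best_w, best_slope, _ = max(windows, key=lambda v: (v[1], v[2], -int(v[0][0])))
    # tolerance from the raw-scale uncertainty of the argmax window's slope
    rs, ri, _ = _ols(t[best_w], y[best_w])
    tol = 2.0 * _slope_se(t[best_w], y[best_w], rs, ri)
    for w, slope, _ in windows:
        if slope >= best_slope - tol:
            best_w = w
            break
    slope, intercept, r2 = _ols(t[best_w], y[best_w])
    i0, i1 = int(best_w[0]), int(best_w[-1])

    # plateau-refined initial OD (log scale): the pre-lag plateau holds the
    # points where the plateau level sits above the fitted exponential line;
    # that classification uses the (precise) line value, not the noisy
    # reading, so membership is stable.  Fixed-point: level = mean OD of the
    # points the current level classifies as plateau.
    initial_od_log = float(y[idx[0]])
    if slope > 0:
        od = log_series.corrected_od
        pre = idx[idx < i0]
        level = initial_od_log
        for _ in range(8):
            plateau = pre[intercept + slope * t[pre] < level]
            if plateau.size == 0 or od[plateau].mean() <= 0:
                level = float(y[idx[0]])
                break
            new_level = float(np.log(od[plateau].mean()))
            if abs(new_level - level) < 1e-12:
                level = new_level
                break
            level = new_level
        initial_od_log = level

    return GrowthFit(
        slope=slope,
        y_intercept=intercept,
        window_start=float(t[i0]),
        window_end=float(t[i1]),
        r_squared=r2,
        initial_od_log=initial_od_log,
        window_indices=(i0, i1),
        degenerate=math.isnan(r2) or slope == 0.0,
    )


def growth_parameters(fit: GrowthFit, corrected_series: CorrectedLogSeries) -> GrowthParameters:
    """Convert a window fit into doubling time, lag time and max OD.

    DT = ln(2)/slope and lag = (initial log OD − y-intercept)/slope.  A
    non-positive slope leaves DT and lag as NaN (non-growing curve) but max OD
    is still reported from the corrected series.
    """
    if corrected_series.n_usable == 0:
        raise GrowthError("corrected series has no usable points")
    max_od = float(corrected_series.corrected_od.max())
    if fit.slope <= 0:
        return GrowthParameters(
            doubling_time=math.nan,
            lag_time=math.nan,
            max_od=max_od,
            strain_id=corrected_series.strain_id,
            replicate_id=corrected_series.replicate_id,
        )
    dt = math.log(2.0) / fit.slope
    lag = (fit.initial_od_log - fit.y_intercept) / fit.slope
    return GrowthParameters(
        doubling_time=dt,
        lag_time=lag,
        max_od=max_od,
        strain_id=corrected_series.strain_id,
        replicate_id=corrected_series.replicate_id,
    )


def analyze_curve(
    sample: PlateReaderSeries,
    blank: PlateReaderSeries,
    window_points: int = DEFAULT_WINDOW_POINTS,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> GrowthParameters:
    """Convenience wrapper: preprocess, window-fit, and report parameters."""
    series = preprocess_curve(sample, blank, od_floor=od_floor)
    fit = fit_exponential_window(series, window_points=window_points)
    return growth_parameters(fit, series)


def relative_fitness(
    strain_dts: list[GrowthParameters],
    reference_dts: list[GrowthParameters],
) -> RelativeFitness:
    """Fitness of a strain relative to the reference strain's mean doubling time.

    Each replicate doubling time is compared to the reference mean, then the
    per-replicate ratios are averaged; the reference strain against itself
    therefore averages to 1 up to replicate noise.
    """
    if not strain_dts or not reference_dts:
        raise GrowthError("relative_fitness requires nonempty strain and reference lists")
    ref_vals = [p.doubling_time for p in reference_dts if not math.isnan(p.doubling_time)]
    vals = [p.doubling_time for p in strain_dts if not math.isnan(p.doubling_time)]
    if not ref_vals or not vals:
        raise GrowthError("relative_fitness: all doubling times are NaN (non-growing curves)")
    ref_mean = float(np.mean(ref_vals))
    per_rep = [ref_mean / v for v in vals]
    return RelativeFitness(
        strain_id=strain_dts[0].strain_id,
        fitness=float(np.mean(per_rep)),
        reference_mean_dt=ref_mean,
        per_replicate_values=per_rep,
    )
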