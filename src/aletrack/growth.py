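"""Growth-curve processing: smoothing, mu_max, doubling time and generations.

A colony growth curve is a time series of estimated total cell counts.  The
processing chain is:

1. remove isolated measurement spikes with a rolling median filter;
2. reduce remaining local noise with a Gaussian filter on log2 counts;
3. find the maximum specific growth rate ``mu_max`` as the steepest slope of
   an ordinary-least-squares line fitted over every run of 5 consecutive
   points of log2 counts vs time, and convert it to a population doubling
   time ``D = 1 / mu_max`` (hours per doubling);
4. count generations ``G = log2(last / first)`` on the despiked series.

All smoothing and regression operate on log2-transformed counts, which makes
exponential growth linear and mu_max directly a doublings-per-hour slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .config import QCThresholds
from .errors import ParameterError


class QCStatus(str, Enum):
    OK = "ok"
    FLAGGED = "flagged"
    EXCLUDED = "excluded"
    NO_GROWTH = "no_growth"


@dataclass
class GrowthCurve:
    """One colony's population-size time series for one cultivation cycle."""

    times: np.ndarray          # hours, strictly increasing
    cells: np.ndarray          # positive counts, same length
    plate_id: str = ""
    row: int = 0
    col: int = 0
    cycle: int = 1
    population_id: str = ""
    qc_status: QCStatus = QCStatus.OK
    # Bookkeeping from the forward model (indices of injected spikes), empty
    # for real data.
    spike_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cells = np.asarray(self.cells, dtype=float)
        if self.times.shape != self.cells.shape or self.times.ndim != 1:
            raise ParameterError("times and cells must be 1-D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(self.cells <= 0):
            raise ParameterError("cells must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class CycleRecord:
    """Derived growth parameters for one colony in one cycle."""

    mu_max: float              # doublings per hour
    doubling_time_h: float     # 1 / mu_max; NaN if no growth
    generations: float         # population doublings over the cycle
    window_start_index: int    # start of the steepest regression window
    qc_status: QCStatus


def despike_median(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Rolling-median filter removing isolated spikes.

    The window shrinks symmetrically at the boundaries: at index ``i`` of an
    n-point series the effective half-width is ``min((window-1)//2, i, n-1-i)``,
    so the first and last points are returned unchanged.

    Parameters
    ----------
    series : array
        Values to filter (any scale; the filter is order-based).
    window : odd int >= 3
        Nominal window length.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if window % 2 == 0:
        raise ParameterError(f"median window must be odd, got {window}")
    if window < 3:
        raise ParameterError(f"median window must be >= 3, got {window}")
    if window > n:
        raise ParameterError(f"median window {window} exceeds series length {n}")
    half = (window - 1) // 2
    out = np.empty_like(x)
    # interior: vectorized via sliding windows
    if n >= window:
        from numpy.lib.stride_tricks import sliding_window_view
        out[half:n - half] = np.median(sliding_window_view(x, window), axis=1)
    # edges: symmetric shrink
    for i in range(half):
        out[i] = np.median(x[: 2 * i + 1])
        j = n - 1 - i
        out[j] = np.median(x[n - (2 * i + 1):])
    return out


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Discrete Gaussian kernel truncated at +/- 4 sigma, normalized to sum 1."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    radius = max(1, int(math.ceil(4.0 * sigma)))
    offsets = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (offsets / sigma) ** 2)
    return k / k.sum()


def smooth_gaussian(series: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Gaussian smoothing with edge renormalization.

    Near the boundaries the kernel mass falling outside the series is
    dropped and the remaining weights renormalized, so a constant series is
    reproduced exactly everywhere.  In the processing chain this is applied
    to log2-transformed counts.
    """
    x = np.asarray(series, dtype=float)
    k = gaussian_kernel(sigma)
    num = np.convolve(x, k, mode="same")
    den = np.convolve(np.ones_like(x), k, mode="same")
    return num / den


def _window_slopes(times: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """OLS slope of y on times for every run of `window` consecutive points."""
    from numpy.lib.stride_tricks import sliding_window_view
    tw = sliding_window_view(times, window)
    yw = sliding_window_view(y, window)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    tc = tw - tm
    sxx = np.sum(tc * tc, axis=1)
    sxy = np.sum(tc * (yw - ym), axis=1)
    return sxy / sxx


def estimate_mu_max(curve: GrowthCurve, window: int = 5) -> CycleRecord:
    """Locate mu_max by local regression over consecutive time points.

    For every run of ``window`` consecutive points, fit OLS of log2(cells)
    on time; ``mu_max`` is the maximum slope in doublings per hour (ties
    broken by the earliest window) and ``D = 1/mu_max`` hours.  A maximum
    slope <= 0 marks the curve as no-growth with undefined D.

    The curve passed in should already be despiked and smoothed; this
    function only log2-transforms and regresses.
    """
    if window < 2:
        raise ParameterError("regression window must be >= 2")
    n = len(curve)
    if n < window:
        raise ParameterError(f"curve has {n} points, fewer than window {window}")
    y = np.log2(curve.cells)
    slopes = _window_slopes(curve.times, y, window)
    idx = int(np.argmax(slopes))          # argmax returns earliest on ties
    mu = float(slopes[idx])
    g = count_generations(curve)
    if mu <= 0:
        return CycleRecord(mu_max=mu, doubling_time_h=float("nan"),
                           generations=g, window_start_index=idx,
                           qc_status=QCStatus.NO_GROWTH)
    return CycleRecord(mu_max=mu, doubling_time_h=1.0 / mu, generations=g,
                       window_start_index=idx, qc_status=curve.qc_status)


def count_generations(curve: GrowthCurve) -> float:
    """Generations G = log2(last / first population size).

    Computed on the series as given; in the pipeline the despiked (but not
    Gaussian-smoothed) series is used so that a spiked endpoint does not
    inflate G.
    """
    first = curve.cells[0]
    last = curve.cells[-1]
    return float(np.log2(last / first))


def qc_curve(curve: GrowthCurve, thresholds: QCThresholds | None = None,
             median_window: int = 5) -> QCStatus:
    """Deterministic quality control for a raw growth curve.

    Flags, in order of severity:

    * ``no_growth``   -- dynamic range after despiking below the minimum
      number of doublings;
    * ``excluded``    -- too few points for estimation;
    * ``flagged``     -- too many points altered by the median filter
      (spike-riddled curve), or despiked endpoints dropping below start
      beyond tolerance;
    * ``ok``          -- otherwise.
    """
    thr = thresholds or QCThresholds()
    n = len(curve)
    if n < thr.min_points:
        return QCStatus.EXCLUDED
    w = min(median_window, n if n % 2 == 1 else n - 1)
    despiked = despike_median(curve.cells, w)
    y = np.log2(despiked)
    dynamic_range = float(y.max() - y.min())
    if dynamic_range < thr.min_doublings:
        return QCStatus.NO_GROWTH
    altered = np.abs(np.log2(curve.cells) - y) > thr.spike_detect_log2
    if altered.mean() > thr.max_spike_fraction:
        return QCStatus.FLAGGED
    if y[-1] - y[0] < -thr.endpoint_drop_tol_log2:
        return QCStatus.FLAGGED
    return QCStatus.OK


def process_curve(curve: GrowthCurve, median_window: int = 5,
                  gaussian_sigma: float = 1.5, mu_window: int = 5,
                  thresholds: QCThresholds | None = None) -> CycleRecord:
    """Full chain: QC -> despike -> log2 Gaussian smooth -> mu_max + G.

    Generations are computed from the despiked (not Gaussian-smoothed)
    endpoints; mu_max from the fully smoothed series.
    """
    status = qc_curve(curve, thresholds, median_window)
    if status is QCStatus.EXCLUDED:
        return CycleRecord(float("nan"), float("nan"), float("nan"), -1, status)
    despiked = despike_median(curve.cells, median_window)
    g = float(np.log2(despiked[-1] / despiked[0]))
    if status is QCStatus.NO_GROWTH:
        return CycleRecord(float("nan"), float("nan"), g, -1, status)
    y = smooth_gaussian(np.log2(despiked), gaussian_sigma)
    slopes = _window_slopes(curve.times, y, mu_window)
    idx = int(np.argmax(slopes))
    mu = float(slopes[idx])
    if mu <= 0:
        return CycleRecord(mu, float("nan"), g, idx, QCStatus.NO_GROWTH)
    return CycleRecord(mu, 1.0 / mu, g, idx, status)
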