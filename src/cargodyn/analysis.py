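"""Time-average single-trajectory statistics.

For a 2D path r(t) sampled at interval delta, with lag Delta = n*delta:

    TAMSD(Delta) = < [r(t+Delta) - r(t)]^2 >_t        (um^2)
    TAMD(Delta)  = < r(t+Delta) - r(t) >_t            (um, vector)
    TAVAR(Delta) = TAMSD(Delta) - |TAMD(Delta)|^2     (um^2)

where <.>_t slides the window over every start sample.  TAVAR is the
variance of the window displacement: it removes directed motion, so a
run-and-rest path with power-law run times shows its Levy-walk-like
super-diffusion (TAVAR ~ Delta^{3-mu}) where the TAMSD is simply
ballistic.  Anomalous exponents are least-squares log-log slopes over an
explicit lag window, always recorded with the fit.

Also provided: the mean first passage time of the displacement modulus to
a distance L (averaged over all start samples that reach L), and the
pooled window-velocity histogram used to read off cargo speeds without
segmenting trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .dynamics import Trajectory

__all__ = [
    "LagGrid",
    "SummaryCurve",
    "MfptCurve",
    "VelocityHistogram",
    "make_lag_grid",
    "tamsd",
    "tamd",
    "tavar",
    "anomalous_exponent",
    "mfpt",
    "velocity_distribution",
    "dominant_peak",
    "detrend",
]


@dataclass(frozen=True)
class LagGrid:
    """Strictly increasing lag times, each an integer multiple of delta."""

    lags: np.ndarray  # s
    delta: float      # sampling interval, s

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        object.__setattr__(self, "lags", lags)
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        n = np.rint(lags / self.delta)
        if np.any(n < 1) or not np.allclose(lags, n * self.delta, rtol=1e-9, atol=0):
            raise ValueError("each lag must be a positive integer multiple of delta")

    @property
    def indices(self) -> np.ndarray:
        return np.rint(self.lags / self.delta).astype(np.int64)


def make_lag_grid(
    traj: Trajectory,
    lag_min: float,
    lag_max: float,
    points_per_decade: int = 20,
) -> LagGrid:
    """Geometric lag grid snapped to the sampling grid (duplicates dropped)."""
    delta = traj.dt
    if lag_max >= traj.duration:
        raise ValueError("max lag must be below the trajectory duration")
    n_dec = np.log10(lag_max / lag_min)
    n_pts = max(int(np.ceil(n_dec * points_per_decade)) + 1, 2)
    lags = np.geomspace(lag_min, lag_max, n_pts)
    idx = np.unique(np.rint(lags / delta).astype(np.int64))
    idx = idx[idx >= 1]
    return LagGrid(lags=idx * delta, delta=delta)


@dataclass
class SummaryCurve:
    """A statistic evaluated on a lag grid, with an optional fitted exponent."""

    lags: np.ndarray
    values: np.ndarray
    statistic: str
    components: dict = field(default_factory=dict)
    alpha: Optional[float] = None
    fit_window: Optional[tuple] = None
    meta: dict = field(default_factory=dict)


@dataclass
class MfptCurve:
    """Mean first passage time to each distance L, with contributing-start counts."""

    L: np.ndarray       # um
    mfpt: np.ndarray    # s; NaN where no start point reaches L
    counts: np.ndarray  # contributing start points per L


@dataclass
class VelocityHistogram:
    """Unweighted histogram of window speeds pooled over lags and start points."""

    edges: np.ndarray   # um/s
    counts: np.ndarray
    lag_range: tuple    # (delta_min, delta_max) s

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _displacements(traj: Trajectory, n: int) -> tuple[np.ndarray, np.ndarray]:
    dx = traj.x[n:] - traj.x[:-n]
    dy = traj.y[n:] - traj.y[:-n]
    return dx, dy


def _check_grid(traj: Trajectory, grid: LagGrid) -> np.ndarray:
    idx = grid.indices
    if idx[-1] >= len(traj) - 1:
        raise ValueError("largest lag must be smaller than the trajectory duration")
    return idx


def tamsd(traj: Trajectory, grid: LagGrid, detrend_per_lag: bool = False) -> SummaryCurve:
    """Time-averaged mean squared 2D displacement on the lag grid.

    With ``detrend_per_lag=True`` the mean window displacement at each lag
    is removed before squaring, which reproduces TAVAR exactly.
    """
    idx = _check_grid(traj, grid)
    vals = np.empty(idx.size)
    for j, n in enumerate(idx):
        dx, dy = _displacements(traj, n)
        if detrend_per_lag:
            dx = dx - dx.mean()
            dy = dy - dy.mean()
        vals[j] = np.mean(dx * dx + dy * dy)
    return SummaryCurve(lags=idx * grid.delta, values=vals, statistic="tamsd")


def tamd(traj: Trajectory, grid: LagGrid) -> SummaryCurve:
    """Time-averaged mean displacement; modulus as values, components kept."""
    idx = _check_grid(traj, grid)
    mx = np.empty(idx.size)
    my = np.empty(idx.size)
    for j, n in enumerate(idx):
        dx, dy = _displacements(traj, n)
        mx[j] = dx.mean()
        my[j] = dy.mean()
    return SummaryCurve(
        lags=idx * grid.delta,
        values=np.hypot(mx, my),
        statistic="tamd",
        components={"x": mx, "y": my},
    )


def tavar(traj: Trajectory, grid: LagGrid) -> SummaryCurve:
    """Time-averaged variance TAMSD - |TAMD|^2 (drift-corrected TAMSD)."""
    msd = tamsd(traj, grid)
    md = tamd(traj, grid)
    vals = msd.values - md.values**2
    return SummaryCurve(lags=msd.lags, values=np.maximum(vals, 0.0), statistic="tavar")


def anomalous_exponent(curve: SummaryCurve, window: tuple) -> float:
    """Least-squares log-log slope of ``curve`` over lags in [window[0], window[1]].

    Records alpha and the window on the curve.  Requires >= 5 positive
    values inside the window.
    """
    lo, hi = window
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    if mask.sum() < 5:
        raise ValueError("need at least 5 lags inside the fit window")
    v = curve.values[mask]
    if np.any(v <= 0):
        raise ValueError("nonpositive values inside the fit window")
    slope = np.polyfit(np.log(curve.lags[mask]), np.log(v), 1)[0]
    curve.alpha = float(slope)
    curve.fit_window = (float(lo), float(hi))
    return curve.alpha


def detrend(traj: Trajectory) -> Trajectory:
    """Subtract the mean increment so the path starts and ends at the same point."""
    n = len(traj) - 1
    mx = (traj.x[-1] - traj.x[0]) / n
    my = (traj.y[-1] - traj.y[0]) / n
    i = np.arange(n + 1)
    return Trajectory(
        times=traj.times.copy(),
        x=traj.x - i * mx,
        y=traj.y - i * my,
        attached=traj.attached,
        motor_x=traj.motor_x,
        meta={**traj.meta, "detrended": True},
    )


@njit(cache=True)
def _mfpt_core(x, y, L, stride):  # pragma: no cover
    n = x.size
    nL = L.size
    total = np.zeros(nL)
    count = np.zeros(nL, dtype=np.int64)
    L2 = L * L
    for s in range(0, n - 1, stride):
        k = 0  # next threshold to cross
        for j in range(s + 1, n):
            dx = x[j] - x[s]
            dy = y[j] - y[s]
            r2 = dx * dx + dy * dy
            while k < nL and r2 >= L2[k]:
                total[k] += j - s
                count[k] += 1
                k += 1
            if k == nL:
                break
    return total, count


def mfpt(traj: Trajectory, L_grid: Sequence[float], start_stride: int = 1) -> MfptCurve:
    """Mean first passage time of |r(t'+Delta) - r(t')| to each distance L.

    The first crossing is the first sampled lag with displacement modulus
    >= L.  Start points slide over every ``start_stride``-th sample; starts
    that never reach L are excluded and the contributing count reported
    (NaN where no start reaches L).
    """
    L = np.asarray(L_grid, dtype=float)
    if np.any(L <= 0) or np.any(np.diff(L) < 0):
        raise ValueError("L grid must be positive and nondecreasing")
    total, count = _mfpt_core(traj.x, traj.y, L, start_stride)
    out = np.full(L.size, np.nan)
    ok = count > 0
    out[ok] = total[ok] / count[ok] * traj.dt
    return MfptCurve(L=L, mfpt=out, counts=count)


def velocity_distribution(
    traj: Trajectory,
    delta_min: float,
    max_fraction: float = 0.1,
    bin_width: float = 0.02,
    v_max: Optional[float] = None,
    points_per_decade: int = 20,
) -> VelocityHistogram:
    """Pooled distribution of window speeds |r(t'+Delta) - r(t')| / Delta.

    Speeds are pooled over all start points and over a geometric lag grid
    from delta_min up to max_fraction of the duration (default 1/10), with
    an unweighted histogram of fixed-width bins.
    """
    if delta_min < traj.dt:
        raise ValueError("delta_min must be at least the sampling interval")
    delta_max = max_fraction * traj.duration
    if delta_max < 10 * delta_min:
        raise ValueError("trajectory too short for the requested lag range")
    grid = make_lag_grid(traj, delta_min, delta_max, points_per_decade)
    if v_max is None:
        # generous default: cover the fastest window at the smallest lag
        dx, dy = _displacements(traj, grid.indices[0])
        v_max = float(np.sqrt(np.max(dx * dx + dy * dy)) / grid.lags[0]) + bin_width
    edges = np.arange(0.0, v_max + bin_width, bin_width)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    for n, lag in zip(grid.indices, grid.lags):
        dx, dy = _displacements(traj, n)
        speeds = np.hypot(dx, dy) / lag
        counts += np.histogram(speeds, bins=edges)[0]
    return VelocityHistogram(edges=edges, counts=counts, lag_range=(delta_min, delta_max))


def dominant_peak(
    hist: VelocityHistogram, min_speed: float = 0.0, smooth_bins: int = 5
) -> float:
    """Speed (um/s) of the strongest *local* maximum above min_speed.

    Pooling speeds over lags produces a monotonically falling noise
    background (a superposition of Rayleigh-like bumps at every lag
    scale); the cargo's run velocity sits on top of it as a local peak.
    Counts are moving-average smoothed over ``smooth_bins`` bins and the
    highest interior local maximum with center >= min_speed is returned;
    the global maximum is the fallback when no interior peak exists.
    """
    c = hist.counts.astype(float)
    smooth = np.convolve(c, np.ones(smooth_bins) / smooth_bins, mode="same")
    centers = hist.centers
    best = None
    for i in range(1, smooth.size - 1):
        if centers[i] < min_speed:
            continue
        if smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1]:
            if best is None or smooth[i] > best[0]:
                best = (smooth[i], centers[i])
    if best is not None:
        return float(best[1])
    mask = centers >= min_speed
    if not np.any(mask):
        raise ValueError("no bins above min_speed")
    return float(centers[mask][np.argmax(smooth[mask])])
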