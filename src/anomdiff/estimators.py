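"""MSD statistics, ergodicity diagnostics and the baseline exponent estimator.

Definitions (unit time step, L samples, N tracers; squared displacements
summed over dimensions):

* EA-MSD(t)  = (1/N) sum_i [x_i(t) - x_i(0)]^2         (ensemble average)
* TA-MSD(m)  = 1/(L-m) sum_i [x(t_i + m) - x(t_i)]^2   (time average, lag m)
* TEA-MSD(m) = ensemble mean of per-trajectory TA-MSDs
* EB         = <zeta^2> - 1,  zeta = TA-MSD / TEA-MSD  (-> 0 for ergodic)
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .models import DegenerateTrajectoryError, InvalidParameterError, RegularTrajectory

__all__ = [
    "MsdCurve",
    "MsdKind",
    "ea_msd",
    "ta_msd",
    "tea_msd",
    "eb_parameter",
    "fit_alpha_tamsd",
    "fit_window",
    "rmse_random",
    "loglog_slope",
]


class MsdKind(Enum):
    ENSEMBLE = "ensemble"
    TIME_AVG = "time_avg"
    TIME_ENSEMBLE = "time_ensemble"


@dataclass
class MsdCurve:
    lags: np.ndarray
    values: np.ndarray
    kind: MsdKind

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise InvalidParameterError("lags must be strictly increasing")
        if np.any(self.values < 0):
            raise InvalidParameterError("MSD values must be non-negative")


def _positions(traj) -> np.ndarray:
    if isinstance(traj, RegularTrajectory):
        return traj.positions
    return np.atleast_2d(np.asarray(traj, dtype=float))


def ea_msd(trajectories, times=None) -> MsdCurve:
    """Ensemble-averaged MSD over tracers of common length.

    ``times`` selects the evaluation times (default: 1..L-1); squared
    displacements from the initial position are summed over dimensions.
    """
    arrs = [_positions(t) for t in trajectories]
    if not arrs:
        raise InvalidParameterError("need at least one trajectory")
    length = arrs[0].shape[1]
    if any(a.shape[1] != length for a in arrs):
        raise InvalidParameterError("trajectories must share a common length")
    if times is None:
        times = np.arange(1, length)
    times = np.asarray(times, dtype=int)
    sq = np.zeros(times.size)
    for a in arrs:
        disp = a[:, times] - a[:, [0]]
        sq += np.sum(disp**2, axis=0)
    return MsdCurve(times, sq / len(arrs), MsdKind.ENSEMBLE)


def ta_msd(traj, max_lag: int | None = None) -> MsdCurve:
    """Time-averaged MSD of a single trajectory for lags 1..max_lag."""
    pos = _positions(traj)
    length = pos.shape[1]
    if max_lag is None:
        max_lag = length - 1
    if not (1 <= max_lag <= length - 1):
        raise InvalidParameterError("max_lag must lie in [1, L-1]")
    values = np.empty(max_lag)
    for m in range(1, max_lag + 1):
        disp = pos[:, m:] - pos[:, :-m]
        values[m - 1] = np.mean(np.sum(disp**2, axis=0))
    return MsdCurve(np.arange(1, max_lag + 1), values, MsdKind.TIME_AVG)


def _ta_msd_at_lag(arrs: list[np.ndarray], lag: int) -> np.ndarray:
    """Per-trajectory TA-MSD at one lag (vectorized over the ensemble)."""
    out = np.empty(len(arrs))
    for i, a in enumerate(arrs):
        disp = a[:, lag:] - a[:, :-lag]
        out[i] = np.mean(np.sum(disp**2, axis=0))
    return out


def tea_msd(trajectories, lag: int) -> float:
    """Time- and ensemble-averaged MSD: mean over tracers of TA-MSD(lag)."""
    arrs = [_positions(t) for t in trajectories]
    if not arrs:
        raise InvalidParameterError("need at least one trajectory")
    return float(np.mean(_ta_msd_at_lag(arrs, lag)))


def eb_parameter(trajectories, lag: int = 1) -> float:
    """Ergodicity-breaking parameter EB = <zeta^2> - 1 at the given lag.

    zeta is the ratio of each trajectory's TA-MSD to the ensemble TEA-MSD;
    EB -> 0 for ergodic diffusion, EB > 0 under weak ergodicity breaking.
    Meaningful in the small lag/L limit.
    """
    arrs = [_positions(t) for t in trajectories]
    if len(arrs) < 2:
        raise InvalidParameterError("EB needs at least two trajectories")
    ta = _ta_msd_at_lag(arrs, lag)
    tea = float(np.mean(ta))
    if tea == 0.0:
        raise DegenerateTrajectoryError("TEA-MSD is zero; zeta undefined")
    zeta = ta / tea
    return float(np.mean(zeta**2) - 1.0)


def fit_window(length: int) -> int:
    """Number of TA-MSD points fitted: max(10, 10% of L), capped at L-1.

    The 10% rule uses round-half-even; the cap keeps the window inside the
    available lags for very short trajectories.
    """
    return min(length - 1, max(10, round(0.1 * length)))


def fit_alpha_tamsd(traj) -> float:
    """Baseline anomalous-exponent estimate: log-log linear fit of the TA-MSD.

    Ordinary least squares of ln TA-MSD against ln lag over lags 1..k with
    k = max(10, 10% of L) (capped at L-1); zero TA-MSD points are excluded;
    the slope is clipped to the physical range [0, 2].
    """
    pos = _positions(traj)
    length = pos.shape[1]
    if length < 4:
        raise InvalidParameterError("need at least 4 samples to fit")
    k = fit_window(length)
    curve = ta_msd(pos, max_lag=k)
    mask = curve.values > 0
    if mask.sum() < 2:
        raise DegenerateTrajectoryError("TA-MSD vanishes; exponent undefined")
    slope = np.polyfit(np.log(curve.lags[mask]), np.log(curve.values[mask]), 1)[0]
    return float(np.clip(slope, 0.0, 2.0))


def rmse_random(t_gt: float, length: float) -> float:
    """Expected RMSE of a uniform random changepoint predictor on [0, L].

    Closed form sqrt((t_GT^3 + (L - t_GT)^3) / (3 L)).
    """
    if not (0 <= t_gt <= length):
        raise InvalidParameterError("t_gt must lie in [0, L]")
    return float(np.sqrt((t_gt**3 + (length - t_gt) ** 3) / (3.0 * length)))


def loglog_slope(curve: MsdCurve, min_lag: float = 1, max_lag: float | None = None) -> float:
    """OLS slope of log MSD vs log lag over the selected lag window."""
    lags = np.asarray(curve.lags, dtype=float)
    mask = (lags >= min_lag) & (curve.values > 0)
    if max_lag is not None:
        mask &= lags <= max_lag
    if mask.sum() < 2:
        raise InvalidParameterError("not enough points for a slope")
    return float(np.polyfit(np.log(lags[mask]), np.log(curve.values[mask]), 1)[0])
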