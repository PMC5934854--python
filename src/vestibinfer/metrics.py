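"""Perception metrics computed from a posterior trace.

These operationalize how well an agent perceived its own head motion:

* perceived gain — the ratio of estimated to true movement magnitude,
  measured two ways: at the velocity peak (``peak_gain``) and as the
  ratio of time-integrated displacements (``displacement_gain``, the
  headline metric, robust to jitter at the peak). A gain below 1 is the
  perceptual analogue of a vestibulo-ocular reflex with reduced gain.
* response lag — how far the estimate trails the true velocity, found
  by maximizing the cross-correlation over non-negative lags with
  parabolic interpolation for sub-step resolution. The causal filter
  cannot systematically lead the stimulus, so negative lags are not
  searched.
* mean uncertainty — average posterior sd over the movement window.
* zero-motion score — the peak-normalized maximum of |posterior mean|:
  near 0 when the agent perceives no motion at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import PosteriorTrace
from .model_core import VelocitySeries

__all__ = [
    "MetricsReport",
    "perceived_gain",
    "response_lag",
    "mean_uncertainty",
    "zero_motion_score",
    "compute_metrics",
]


@dataclass(frozen=True)
class MetricsReport:
    peak_gain: float
    displacement_gain: float
    lag: float
    mean_uncertainty: float
    zero_motion_score: float
    direction_correct: bool


def _check_shared_grid(trace: PosteriorTrace, truth: VelocitySeries) -> None:
    if trace.grid.n_steps != truth.grid.n_steps or not np.allclose(
        trace.grid.times, truth.grid.times
    ):
        raise ValueError("trace and truth must share one time grid")


def perceived_gain(
    trace: PosteriorTrace, truth: VelocitySeries
) -> tuple[float, float]:
    """(peak_gain, displacement_gain) of the estimate relative to truth.

    ``peak_gain`` is the signed posterior mean at the time of the true
    speed peak, divided by the signed true peak. ``displacement_gain``
    is the ratio of the time integrals (total perceived / total actual
    displacement). Both are scale-equivariant in the trace.
    """
    _check_shared_grid(trace, truth)
    if not np.any(truth.values):
        raise ValueError(
            "truth is identically zero; use zero_motion_score instead"
        )
    peak_idx = int(np.argmax(np.abs(truth.values)))
    peak_gain = float(trace.mean[peak_idx] / truth.values[peak_idx])
    displacement_gain = float(np.sum(trace.mean) / np.sum(truth.values))
    return peak_gain, displacement_gain


def response_lag(
    trace: PosteriorTrace, truth: VelocitySeries, max_lag: float = 0.3
) -> float:
    """Lag (seconds, >= 0) of the estimate behind the true velocity.

    Maximizes ``sum_k mean[k] * truth[k - L]`` over integer lags
    ``L in [0, max_lag]``, then refines the argmax by fitting a parabola
    through the three surrounding correlation values. A flat trace has
    no defined lag; it returns 0.0 with a warning.
    """
    _check_shared_grid(trace, truth)
    dt = trace.grid.dt
    if max_lag < dt:
        raise ValueError("max_lag must be at least one time step")
    if np.ptp(truth.values) == 0:
        raise ValueError("truth must be non-constant")
    if np.ptp(trace.mean) == 0:
        warnings.warn("flat posterior trace: lag is undefined, returning 0")
        return 0.0
    n = trace.grid.n_steps
    max_steps = min(int(round(max_lag / dt)), n - 2)
    corr = np.array(
        [np.dot(trace.mean[lag:], truth.values[: n - lag]) for lag in range(max_steps + 1)]
    )
    best = int(np.argmax(corr))
    lag = best * dt
    if 0 < best < max_steps:  # parabolic sub-step refinement
        c_lo, c_mid, c_hi = corr[best - 1], corr[best], corr[best + 1]
        denom = c_lo - 2 * c_mid + c_hi
        if denom < 0:
            lag += 0.5 * dt * (c_lo - c_hi) / denom
    return float(min(max(lag, 0.0), max_lag))


def mean_uncertainty(
    trace: PosteriorTrace, window: tuple[float, float]
) -> float:
    """Arithmetic mean of the posterior sd over ``window`` seconds."""
    start, end = window
    t = trace.grid.times
    if start > end or start < t[0] - 1e-12 or end > t[-1] + 1e-12:
        raise ValueError("window must lie within the time grid")
    mask = (t >= start - 1e-12) & (t <= end + 1e-12)
    if not np.any(mask):
        raise ValueError("window contains no grid points")
    return float(np.mean(trace.sd[mask]))


def zero_motion_score(trace: PosteriorTrace, truth: VelocitySeries) -> float:
    """max_k |posterior mean| / |true peak|: 0 = no motion perceived."""
    _check_shared_grid(trace, truth)
    peak = np.max(np.abs(truth.values))
    if peak == 0:
        raise ValueError("truth peak is zero; the score is undefined")
    return float(np.max(np.abs(trace.mean)) / peak)


def compute_metrics(
    trace: PosteriorTrace,
    truth: VelocitySeries,
    window: tuple[float, float] | None = None,
    max_lag: float = 0.3,
) -> MetricsReport:
    """Assemble the full report; ``window`` defaults to the movement span."""
    if window is None:
        nz = np.nonzero(truth.values)[0]
        if len(nz):
            window = (trace.grid.times[nz[0]], trace.grid.times[nz[-1]])
        else:
            window = (trace.grid.times[0], trace.grid.times[-1])
    peak_gain, displacement_gain = perceived_gain(trace, truth)
    return MetricsReport(
        peak_gain=peak_gain,
        displacement_gain=displacement_gain,
        lag=response_lag(trace, truth, max_lag=max_lag),
        mean_uncertainty=mean_uncertainty(trace, window),
        zero_motion_score=zero_motion_score(trace, truth),
        direction_correct=bool(displacement_gain > 0),
    )
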