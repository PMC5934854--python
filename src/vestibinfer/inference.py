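"""Sequential Bayesian inference of head velocity.

Three inference routes over the same internal model:

* :func:`particle_filter` — a bootstrap (prior-proposal) particle filter
  with systematic resampling, the sequential Monte Carlo algorithm the
  simulations are built on;
* :func:`exact_filter` — the closed-form Kalman recursion. Because the
  internal model is conditionally linear-Gaussian given the knowledge
  signal and the switch, the exact posterior is available and serves as
  the correctness oracle for the particle filter;
* :func:`run_imagery` — the prediction chain alone, with no sensory
  update: the model run in off-line simulation mode, as during imagined
  self-motion.

All filters emit a :class:`PosteriorTrace` (per-step posterior mean, sd,
and — for the particle filter — effective sample size and resampling
flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .internal_model import InternalModel, observation_loglik, predict_step
from .model_core import KnowledgeSignal, TimeGrid, VelocitySeries

__all__ = [
    "ParticleEnsemble",
    "PosteriorTrace",
    "particle_filter",
    "exact_filter",
    "run_imagery",
    "systematic_resample",
]

_WEIGHT_TOL = 1e-12


@dataclass
class ParticleEnsemble:
    """Weighted particle approximation of the velocity posterior."""

    velocities: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.velocities.shape != self.weights.shape:
            raise ValueError("velocities and weights must have the same shape")
        if len(self.velocities) < 2:
            raise ValueError("need at least 2 particles")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        if abs(self.weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError("weights must sum to 1")

    @property
    def n(self) -> int:
        return len(self.velocities)

    def ess(self) -> float:
        """Effective sample size, 1 / sum(w_i^2)."""
        return float(1.0 / np.sum(self.weights**2))


@dataclass
class PosteriorTrace:
    """Per-step posterior summary of the filtered head velocity.

    ``ess`` and ``resampled`` are absent (None) for the exact filter and
    the imagery mode, which have no particle ensemble.
    """

    grid: TimeGrid
    mean: np.ndarray
    sd: np.ndarray
    ess: np.ndarray | None = None
    resampled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        n = self.grid.n_steps
        if len(self.mean) != n or len(self.sd) != n:
            raise ValueError("trace length does not match grid")
        if np.any(self.sd < 0):
            raise ValueError("posterior sd must be >= 0")

    def to_dataframe(self):
        import pandas as pd

        n = self.grid.n_steps
        return pd.DataFrame(
            {
                "time_s": self.grid.times,
                "post_mean": self.mean,
                "post_sd": self.sd,
                "ess": self.ess if self.ess is not None else np.full(n, np.nan),
                "resampled": (
                    self.resampled if self.resampled is not None else np.zeros(n, bool)
                ),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def systematic_resample(
    ensemble: ParticleEnsemble, uniform: float
) -> ParticleEnsemble:
    """Systematic (single-sweep stratified) resampling.

    One uniform draw ``u`` in [0, 1) places N equally spaced pointers
    ``(u + i) / N`` on the cumulative weight profile; each pointer selects
    one offspring. Offspring counts therefore differ from ``N * w_i`` by
    less than 1 for every particle, and the output weights are uniform.
    """
    if not 0.0 <= uniform < 1.0:
        raise ValueError("uniform must be in [0, 1)")
    n = ensemble.n
    positions = (uniform + np.arange(n)) / n
    cumulative = np.cumsum(ensemble.weights)
    cumulative[-1] = 1.0  # guard against rounding at the top
    indices = np.searchsorted(cumulative, positions, side="right")
    return ParticleEnsemble(
        velocities=ensemble.velocities[indices],
        weights=np.full(n, 1.0 / n),
    )


def _check_grids(observations: VelocitySeries, knowledge: KnowledgeSignal) -> TimeGrid:
    if observations.grid.n_steps != knowledge.grid.n_steps or not np.allclose(
        observations.grid.times, knowledge.grid.times
    ):
        raise ValueError("observations and knowledge must share one time grid")
    return observations.grid


def particle_filter(
    observations: VelocitySeries,
    knowledge: KnowledgeSignal,
    switch_active: bool,
    model: InternalModel,
    n_particles: int = 5000,
    seed: int | np.random.SeedSequence = 0,
    resample_threshold: float = 0.5,
) -> PosteriorTrace:
    """Bootstrap particle filter over the internal model.

    Particles start from the initial belief ``N(initial_mean,
    initial_sd^2)`` and are weighted by the likelihood of the first
    observation. At each later step every particle is propagated through
    the dynamic prior (prediction mean from :func:`predict_step` plus a
    Gaussian innovation of sd sigma_q) and reweighted by the observation
    likelihood. Weights are kept in log space and normalized by
    log-sum-exp; when the effective sample size falls below
    ``resample_threshold * n_particles`` the ensemble is systematically
    resampled. Posterior mean and sd are the weighted moments recorded
    before any resampling. Fully reproducible given ``seed``.
    """
    if n_particles < 100:
        raise ValueError("n_particles must be >= 100")
    grid = _check_grids(observations, knowledge)
    rng = np.random.default_rng(seed)
    n = grid.n_steps

    particles = rng.normal(model.initial_mean, model.initial_sd, size=n_particles)
    log_w = observation_loglik(observations.values[0], particles, model)

    mean = np.empty(n)
    sd = np.empty(n)
    ess = np.empty(n)
    resampled = np.zeros(n, dtype=bool)

    for k in range(n):
        if k > 0:
            pred_mean, pred_sd = predict_step(
                particles, knowledge.values[k], switch_active, model
            )
            particles = pred_mean + rng.normal(0.0, pred_sd, size=n_particles)
            log_w = log_w + observation_loglik(
                observations.values[k], particles, model
            )
        norm = logsumexp(log_w)
        if not np.isfinite(norm):
            raise RuntimeError("particle weights degenerated to zero")
        log_w = log_w - norm
        w = np.exp(log_w)
        mean[k] = np.sum(w * particles)
        sd[k] = np.sqrt(max(np.sum(w * (particles - mean[k]) ** 2), 0.0))
        ess[k] = 1.0 / np.sum(w**2)
        if ess[k] < resample_threshold * n_particles:
            ensemble = systematic_resample(
                ParticleEnsemble(particles, w), rng.uniform()
            )
            particles = ensemble.velocities
            log_w = np.zeros(n_particles)
            resampled[k] = True

    return PosteriorTrace(grid=grid, mean=mean, sd=sd, ess=ess, resampled=resampled)


def exact_filter(
    observations: VelocitySeries,
    knowledge: KnowledgeSignal,
    switch_active: bool,
    model: InternalModel,
) -> PosteriorTrace:
    """Exact Kalman recursion for the conditionally linear-Gaussian model.

    Prediction: mean from :func:`predict_step`; variance
    ``(a * (1 - b * S))^2 * prev_var + sigma_q^2`` where ``S`` is the
    knowledge switch. Update: scalar Kalman gain ``P / (P + sigma_v^2)``.
    The noiseless limit sigma_v = 0 is allowed: the posterior collapses
    onto each observation.
    """
    grid = _check_grids(observations, knowledge)
    n = grid.n_steps
    a, b = model.decay, model.knowledge_weight
    shrink = (a * (1.0 - b)) if switch_active else a
    q2 = model.process_noise_sd**2
    r2 = model.assumed_sensor_noise_sd**2

    mean = np.empty(n)
    var = np.empty(n)
    m, p = model.initial_mean, model.initial_sd**2
    for k in range(n):
        if k > 0:
            m, _ = predict_step(m, knowledge.values[k], switch_active, model)
            p = shrink**2 * p + q2
        denom = p + r2
        if denom == 0.0:  # noiseless sensor and collapsed prior
            gain = 1.0
        else:
            gain = p / denom
        m = m + gain * (observations.values[k] - m)
        p = (1.0 - gain) * p
        mean[k] = m
        var[k] = p
    return PosteriorTrace(grid=grid, mean=mean, sd=np.sqrt(var))


def run_imagery(knowledge: KnowledgeSignal, model: InternalModel) -> PosteriorTrace:
    """Run the generative model off-line: predictions with no updates.

    Models imagined self-motion: the prediction chain is driven by the
    knowledge signal (imagery always engages the knowledge route) and the
    uncertainty follows the prediction-variance recursion, growing toward
    its stationary value since no observation ever corrects it.
    """
    grid = knowledge.grid
    n = grid.n_steps
    a, b = model.decay, model.knowledge_weight
    shrink = a * (1.0 - b)
    q2 = model.process_noise_sd**2

    mean = np.empty(n)
    var = np.empty(n)
    m, p = model.initial_mean, model.initial_sd**2
    mean[0], var[0] = m, p
    for k in range(1, n):
        m, _ = predict_step(m, knowledge.values[k], True, model)
        p = shrink**2 * p + q2
        mean[k], var[k] = m, p
    return PosteriorTrace(grid=grid, mean=mean, sd=np.sqrt(var))
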