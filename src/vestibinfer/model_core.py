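"""World side of the simulation: true head motion, sensors, and knowledge.

This module defines everything that exists outside the inferring agent's
head: the discrete time grid, the true yaw angular-velocity trajectory, the
process that turns true velocity into semicircular-canal afferent
observations (intact or deafferented), and the "knowledge" signal — an
efference-copy-like expectation of head velocity available to the agent
during self-initiated movement.

Sign convention: positive angular velocity is a leftward yaw turn
(counter-clockwise when viewed from above). All velocities are in deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LEFTWARD_POSITIVE",
    "TimeGrid",
    "TrajectoryProfile",
    "VelocitySeries",
    "WorldModel",
    "KnowledgeParams",
    "KnowledgeSignal",
    "make_time_grid",
    "generate_trajectory",
    "generate_observations",
    "generate_knowledge",
]

#: Documented sign convention: +velocity = leftward (CCW from above) yaw.
LEFTWARD_POSITIVE = True

_TRAJECTORY_SHAPES = ("raised_cosine_bell", "trapezoid", "zero")
_SENSOR_MODES = ("healthy", "bvp")


@dataclass(frozen=True)
class TimeGrid:
    """Uniform discrete time grid starting at t = 0.

    Attributes
    ----------
    dt : float
        Step size in seconds; must be positive.
    n_steps : int
        Number of grid points (>= 2).
    times : numpy.ndarray
        ``times[k] = k * dt``, shape ``(n_steps,)``.
    """

    dt: float
    n_steps: int
    times: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")
        if len(self.times) != self.n_steps:
            raise ValueError("times length does not match n_steps")

    @property
    def total_time(self) -> float:
        return float(self.times[-1])


def make_time_grid(dt: float, total_time: float) -> TimeGrid:
    """Build a uniform grid covering ``[0, total_time]`` with step ``dt``.

    The number of points is ``round(total_time / dt) + 1``, so the grid
    always contains t = 0 and (up to rounding) t = total_time.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if total_time <= 0:
        raise ValueError(f"total_time must be positive, got {total_time}")
    if total_time < 2 * dt:
        raise ValueError("total_time must be at least 2*dt")
    n_steps = int(round(total_time / dt)) + 1
    times = np.arange(n_steps, dtype=float) * dt
    return TimeGrid(dt=float(dt), n_steps=n_steps, times=times)


@dataclass(frozen=True)
class TrajectoryProfile:
    """Parameters of the true head-velocity profile.

    ``amplitude`` is the signed peak angular velocity in deg/s (positive =
    leftward). The movement occupies ``[onset, onset + movement_duration]``
    seconds and the velocity is exactly zero outside that window.
    """

    amplitude: float = 60.0
    movement_duration: float = 1.0
    onset: float = 0.5
    shape: str = "raised_cosine_bell"

    def __post_init__(self) -> None:
        if self.movement_duration <= 0:
            raise ValueError("movement_duration must be positive")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.shape not in _TRAJECTORY_SHAPES:
            raise ValueError(
                f"unknown shape {self.shape!r}; expected one of {_TRAJECTORY_SHAPES}"
            )


@dataclass
class VelocitySeries:
    """An angular-velocity time series (deg/s) on a :class:`TimeGrid`."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_steps:
            raise ValueError("values length does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def displacement(self) -> float:
        """Time integral of velocity (total angular displacement, deg)."""
        return float(np.sum(self.values) * self.grid.dt)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.grid.times, "value_deg_per_s": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def generate_trajectory(profile: TrajectoryProfile, grid: TimeGrid) -> VelocitySeries:
    """Deterministic true head-velocity trajectory on ``grid``.

    The default ``raised_cosine_bell`` shape is
    ``A * sin^2(pi * (t - onset) / T)`` inside the movement window: a
    smooth bell that starts and ends at zero velocity, peaks (at the
    signed amplitude ``A``) mid-movement, and integrates to ``A * T / 2``
    degrees of displacement.

    The ``trapezoid`` shape ramps linearly over the first and last
    quarter of the window and holds the peak in between.
    """
    end = profile.onset + profile.movement_duration
    if end > grid.total_time + 1e-12:
        raise ValueError(
            "movement window [onset, onset + duration] exceeds the time grid"
        )
    t = grid.times
    values = np.zeros_like(t)
    if profile.shape == "zero" or profile.amplitude == 0:
        return VelocitySeries(grid=grid, values=values)

    in_window = (t >= profile.onset) & (t <= end)
    tau = (t[in_window] - profile.onset) / profile.movement_duration  # in [0, 1]
    if profile.shape == "raised_cosine_bell":
        values[in_window] = profile.amplitude * np.sin(np.pi * tau) ** 2
    elif profile.shape == "trapezoid":
        ramp = np.minimum.reduce([4 * tau, np.ones_like(tau), 4 * (1 - tau)])
        values[in_window] = profile.amplitude * ramp
    return VelocitySeries(grid=grid, values=values)


@dataclass(frozen=True)
class WorldModel:
    """How semicircular-canal observations are actually generated.

    In ``healthy`` mode the afferents measure the true velocity with
    additive Gaussian noise of sd ``sensor_noise_sd``. In ``bvp`` mode
    (bilateral vestibulopathy, i.e. deafferented end organs) the signal
    carries no information about head motion: it is pure zero-mean
    Gaussian neuronal noise of sd ``bvp_noise_sd``, drawn independently
    of the true trajectory.
    """

    sensor_mode: str = "healthy"
    sensor_noise_sd: float = 10.0
    bvp_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.sensor_mode not in _SENSOR_MODES:
            raise ValueError(
                f"unknown sensor_mode {self.sensor_mode!r}; expected one of {_SENSOR_MODES}"
            )
        if self.sensor_noise_sd < 0 or self.bvp_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def generate_observations(
    truth: VelocitySeries, world: WorldModel, seed: int | np.random.SeedSequence
) -> VelocitySeries:
    """Simulate one run of sensor observations for ``truth``.

    Reproducible: the same (truth, world, seed) gives a bit-identical
    series. In ``bvp`` mode the output is statistically independent of
    the truth by construction.
    """
    rng = np.random.default_rng(seed)
    n = truth.grid.n_steps
    if world.sensor_mode == "healthy":
        values = truth.values + rng.normal(0.0, world.sensor_noise_sd, size=n)
    else:
        values = rng.normal(0.0, world.bvp_noise_sd, size=n)
    return VelocitySeries(grid=truth.grid, values=values)


@dataclass(frozen=True)
class KnowledgeParams:
    """Parameters of the knowledge (expected-velocity) signal.

    The knowledge signal stands in for every non-vestibular source of
    information about the ongoing movement — efference copies of motor
    commands foremost, but also vision, proprioception, or memory. It is
    expressed directly on the velocity level: a scaled (``knowledge_gain``),
    optionally delayed (``knowledge_delay`` seconds) copy of the true
    velocity with additive Gaussian noise (``knowledge_noise_sd`` deg/s).
    """

    knowledge_gain: float = 1.0
    knowledge_noise_sd: float = 1.0
    knowledge_delay: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.knowledge_gain <= 1.5:
            raise ValueError("knowledge_gain must be in [0, 1.5]")
        if self.knowledge_noise_sd < 0:
            raise ValueError("knowledge_noise_sd must be >= 0")
        if self.knowledge_delay < 0:
            raise ValueError("knowledge_delay must be >= 0")


@dataclass
class KnowledgeSignal:
    """Expected head velocity per step (deg/s); all zeros when passive."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_steps:
            raise ValueError("values length does not match grid")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.grid.times, "value_deg_per_s": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def generate_knowledge(
    truth: VelocitySeries,
    params: KnowledgeParams,
    switch_active: bool,
    seed: int | np.random.SeedSequence,
) -> KnowledgeSignal:
    """Generate the knowledge signal for one run.

    Passive movement (``switch_active=False``) means the agent has no
    advance information: the signal is identically zero. Active movement
    yields ``u(t) = gain * truth(t - delay) + e(t)`` with i.i.d. Gaussian
    noise ``e``; the truth is taken as zero before t = 0.
    """
    grid = truth.grid
    if not switch_active:
        return KnowledgeSignal(grid=grid, values=np.zeros(grid.n_steps))
    shifted_t = grid.times - params.knowledge_delay
    base = np.interp(shifted_t, grid.times, truth.values, left=0.0, right=0.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, params.knowledge_noise_sd, size=grid.n_steps)
    return KnowledgeSignal(grid=grid, values=params.knowledge_gain * base + noise)
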