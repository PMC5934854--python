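"""Configuration-driven experiment runner.

Composes the world model, internal model, filter, and metrics into named
experimental conditions and two standard simulation suites:

* the four-condition comparison of a healthy agent and a patient with
  bilateral vestibulopathy (BVP), each under passive and active
  (self-initiated) movement;
* the three-condition rehabilitation comparison for an active BVP
  patient: untreated, conventional rehabilitation (sensor-noise
  inflation), and conventional plus cognitive training (prior
  sharpening + stronger knowledge reliance).

Each suite checks a set of named qualitative properties (tracking,
lag reduction, zero-motion perception, amplitude attenuation, ordered
improvement under therapy) and reports them in a JSON summary. Parameter
sweeps over the two intervention mechanisms are also provided.

Seeding: every (condition, replicate) gets its own seed derived by a
stable SHA-256 hash of ``(master_seed, condition_label, replicate)``, so
replicate r of one condition is paired with replicate r of another
(identical world noise where the worlds coincide) and results are
reproducible across platforms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import PosteriorTrace, exact_filter, particle_filter
from .internal_model import (
    ConditionDefaults,
    ConditionSpec,
    InternalModel,
    apply_conventional_rehab,
    apply_cognitive_training,
)
from .metrics import MetricsReport, compute_metrics
from .model_core import (
    KnowledgeParams,
    TrajectoryProfile,
    WorldModel,
    generate_knowledge,
    generate_observations,
    generate_trajectory,
    make_time_grid,
)

__all__ = [
    "SCHEMA_VERSION",
    "STANDARD_CONDITIONS",
    "RunConfig",
    "SweepSpec",
    "ConfigError",
    "load_config",
    "resolve_condition",
    "derive_seed",
    "run_condition",
    "run_replicates",
    "perception_suite",
    "rehabilitation_suite",
    "run_sweep",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

STANDARD_CONDITIONS = (
    "healthy_passive",
    "healthy_active",
    "bvp_passive",
    "bvp_active",
    "bvp_active_conventional",
    "bvp_active_conventional_plus_cognitive",
)

_SWEEP_PARAMETERS = ("sensor_inflation", "prior_sharpening", "knowledge_weight")


class ConfigError(ValueError):
    """Raised for unresolvable labels or invalid configuration blocks."""


@dataclass(frozen=True)
class InferenceConfig:
    method: str = "particle"  # "particle" or "exact"
    n_particles: int = 5000
    resample_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in ("particle", "exact"):
            raise ConfigError("inference.method must be 'particle' or 'exact'")


@dataclass(frozen=True)
class RunConfig:
    """Full experiment configuration (YAML/JSON-mappable)."""

    dt: float = 0.01
    total_time: float = 2.0
    trajectory: TrajectoryProfile = field(default_factory=TrajectoryProfile)
    defaults: ConditionDefaults = field(default_factory=ConditionDefaults)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    conditions: tuple[str, ...] = STANDARD_CONDITIONS
    n_seeds: int = 20
    master_seed: int = 0
    output_dir: str | None = None
    max_lag: float = 0.3

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ConfigError("n_seeds must be >= 1")
        for label in self.conditions:
            resolve_condition(label)


def _build(cls, block: dict, where: str):
    try:
        return cls(**block)
    except TypeError as exc:
        raise ConfigError(f"bad {where} block: {exc}") from None
    except ValueError as exc:
        raise ConfigError(f"bad {where} block: {exc}") from None


def config_from_dict(raw: dict) -> RunConfig:
    """Build a :class:`RunConfig` from nested plain dictionaries."""
    raw = dict(raw)
    kwargs: dict = {}
    for key in ("dt", "total_time", "n_seeds", "master_seed", "output_dir", "max_lag"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if "trajectory" in raw:
        kwargs["trajectory"] = _build(TrajectoryProfile, raw.pop("trajectory"), "trajectory")
    defaults_kwargs: dict = {}
    if "world" in raw:
        defaults_kwargs["world"] = _build(WorldModel, raw.pop("world"), "world")
    if "internal_model" in raw:
        defaults_kwargs["internal"] = _build(
            InternalModel, raw.pop("internal_model"), "internal_model"
        )
    if "knowledge" in raw:
        defaults_kwargs["knowledge"] = _build(
            KnowledgeParams, raw.pop("knowledge"), "knowledge"
        )
    for key in (
        "conventional_inflation",
        "cognitive_prior_sharpening",
        "cognitive_knowledge_weight",
    ):
        if key in raw:
            defaults_kwargs[key] = raw.pop(key)
    if defaults_kwargs:
        kwargs["defaults"] = _build(ConditionDefaults, defaults_kwargs, "defaults")
    if "inference" in raw:
        kwargs["inference"] = _build(InferenceConfig, raw.pop("inference"), "inference")
    if "conditions" in raw:
        kwargs["conditions"] = tuple(raw.pop("conditions"))
    if raw:
        raise ConfigError(f"unknown config keys: {sorted(raw)}")
    try:
        return RunConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from None


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — YAML superset) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(raw)


def resolve_condition(label: str) -> ConditionSpec:
    """Parse a condition label like ``bvp_active_conventional``."""
    parts = label.split("_")
    if len(parts) < 2:
        raise ConfigError(f"unresolvable condition label: {label!r}")
    patient, movement, rest = parts[0], parts[1], "_".join(parts[2:])
    intervention = rest if rest else "none"
    try:
        return ConditionSpec(
            patient=patient, movement=movement, intervention=intervention, label=label
        )
    except ValueError as exc:
        raise ConfigError(f"unresolvable condition label {label!r}: {exc}") from None


def derive_seed(master_seed: int, label: str, replicate: int) -> int:
    """Stable per-(condition, replicate) seed below 2^31.

    SHA-256 of the textual triple, truncated to 31 bits; identical on
    every platform and Python version.
    """
    digest = hashlib.sha256(f"{master_seed}|{label}|{replicate}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def run_condition(
    spec: ConditionSpec,
    config: RunConfig,
    seed: int,
    internal_override: InternalModel | None = None,
) -> tuple[PosteriorTrace, MetricsReport]:
    """Simulate one replicate of one condition end to end.

    Generates the deterministic trajectory, draws sensor observations
    and knowledge signal from independent sub-streams of ``seed``, runs
    the configured filter, and computes the metrics report.
    Deterministic given ``(spec, config, seed)``.
    """
    from .internal_model import make_condition

    grid = make_time_grid(config.dt, config.total_time)
    truth = generate_trajectory(config.trajectory, grid)
    world, internal, switch_active, knowledge_params = make_condition(
        spec, config.defaults
    )
    if internal_override is not None:
        internal = internal_override
    seed_obs, seed_knowledge, seed_filter = np.random.SeedSequence(seed).spawn(3)
    observations = generate_observations(truth, world, seed_obs)
    knowledge = generate_knowledge(truth, knowledge_params, switch_active, seed_knowledge)
    if config.inference.method == "exact":
        trace = exact_filter(observations, knowledge, switch_active, internal)
    else:
        trace = particle_filter(
            observations,
            knowledge,
            switch_active,
            internal,
            n_particles=config.inference.n_particles,
            seed=seed_filter,
            resample_threshold=config.inference.resample_threshold,
        )
    report = compute_metrics(trace, truth, max_lag=config.max_lag)
    return trace, report


def _metrics_row(label: str, seed: int, report: MetricsReport) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "condition_label": label,
        "seed": seed,
        "peak_gain": report.peak_gain,
        "displacement_gain": report.displacement_gain,
        "lag_s": report.lag,
        "mean_uncertainty": report.mean_uncertainty,
        "zero_motion_score": report.zero_motion_score,
        "direction_correct": report.direction_correct,
    }


def run_replicates(
    label: str, config: RunConfig
) -> tuple[pd.DataFrame, PosteriorTrace]:
    """Run ``config.n_seeds`` paired replicates of one condition.

    Returns the tidy metrics table and a trace whose mean/sd are the
    across-replicate averages (for plotting and CSV export).
    """
    spec = resolve_condition(label)
    rows = []
    mean_stack, sd_stack = [], []
    last_trace = None
    for replicate in range(config.n_seeds):
        seed = derive_seed(config.master_seed, label, replicate)
        trace, report = run_condition(spec, config, seed)
        rows.append(_metrics_row(label, seed, report))
        mean_stack.append(trace.mean)
        sd_stack.append(trace.sd)
        last_trace = trace
    logger.info("condition %s: %d replicates done", label, config.n_seeds)
    mean_trace = PosteriorTrace(
        grid=last_trace.grid,
        mean=np.mean(mean_stack, axis=0),
        sd=np.mean(sd_stack, axis=0),
    )
    return pd.DataFrame(rows), mean_trace


def _write_outputs(
    out_dir: str | Path | None,
    suite: str,
    metrics: pd.DataFrame,
    traces: dict[str, PosteriorTrace],
    summary: dict,
) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(out / f"{suite}_metrics.csv", index=False)
    for label, trace in traces.items():
        trace.to_csv(out / f"{suite}_trace_{label}.csv")
    with open(out / f"{suite}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("suite %s: outputs written to %s", suite, out)


def _condition_means(metrics: pd.DataFrame) -> dict:
    numeric = [
        "peak_gain",
        "displacement_gain",
        "lag_s",
        "mean_uncertainty",
        "zero_motion_score",
    ]
    grouped = metrics.groupby("condition_label")
    means = grouped[numeric].mean()
    means["zero_motion_score_median"] = grouped["zero_motion_score"].median()
    means["n_direction_correct"] = grouped["direction_correct"].sum()
    return {label: row.to_dict() for label, row in means.iterrows()}


def perception_suite(config: RunConfig) -> dict:
    """Healthy vs. BVP under passive vs. active movement.

    Checks four qualitative properties of self-motion perception:
    healthy tracking, lag reduction by self-initiation, absent motion
    percept in passive BVP, and attenuated-but-directed percept in
    active BVP.
    """
    labels = ["healthy_passive", "healthy_active", "bvp_passive", "bvp_active"]
    metrics, traces = _run_suite_conditions(labels, config)
    means = _condition_means(metrics)
    n = config.n_seeds
    properties = {
        "healthy_passive_tracks": bool(
            0.8 <= means["healthy_passive"]["displacement_gain"] <= 1.1
        ),
        "active_reduces_lag": bool(
            means["healthy_active"]["lag_s"] < means["healthy_passive"]["lag_s"]
        ),
        "bvp_passive_stays_at_zero": bool(
            means["bvp_passive"]["zero_motion_score_median"] < 0.1
        ),
        "bvp_active_attenuated_correct_direction": bool(
            0.0 < means["bvp_active"]["displacement_gain"] < 1.0
            and means["bvp_active"]["n_direction_correct"] >= int(np.ceil(0.9 * n))
        ),
    }
    summary = _summary("perception", properties, means)
    _write_outputs(config.output_dir, "perception", metrics, traces, summary)
    return summary


def rehabilitation_suite(config: RunConfig) -> dict:
    """Rehabilitation comparison for the active BVP patient.

    Checks that perceived displacement gain is strictly ordered
    untreated < conventional < conventional+cognitive on matched seeds,
    and that cognitive training lowers posterior uncertainty relative to
    conventional rehabilitation alone.
    """
    labels = [
        "bvp_active",
        "bvp_active_conventional",
        "bvp_active_conventional_plus_cognitive",
    ]
    metrics, traces = _run_suite_conditions(labels, config)
    means = _condition_means(metrics)
    gains = [means[label]["displacement_gain"] for label in labels]
    properties = {
        "gain_strictly_ordered_by_intervention": bool(
            gains[0] < gains[1] < gains[2]
        ),
        "cognitive_training_lowers_uncertainty": bool(
            means[labels[2]]["mean_uncertainty"] < means[labels[1]]["mean_uncertainty"]
        ),
    }
    summary = _summary("rehabilitation", properties, means)
    _write_outputs(config.output_dir, "rehabilitation", metrics, traces, summary)
    return summary


def _run_suite_conditions(labels, config):
    frames, traces = [], {}
    for label in labels:
        df, mean_trace = run_replicates(label, config)
        frames.append(df)
        traces[label] = mean_trace
    return pd.concat(frames, ignore_index=True), traces


def _summary(suite: str, properties: dict, means: dict) -> dict:
    return {
        "suite": suite,
        "schema_version": SCHEMA_VERSION,
        "properties": properties,
        "passed": all(properties.values()),
        "condition_means": means,
    }


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter dose-response sweep over an intervention mechanism."""

    parameter: str
    values: tuple[float, ...]
    base_condition: ConditionSpec

    def __post_init__(self) -> None:
        if self.parameter not in _SWEEP_PARAMETERS:
            raise ConfigError(f"parameter must be one of {_SWEEP_PARAMETERS}")
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", values)
        if len(values) < 3:
            raise ConfigError("a sweep needs at least 3 values")
        if not all(lo < hi for lo, hi in zip(values, values[1:])):
            raise ConfigError("sweep values must be strictly increasing")


def _sweep_internal(base: InternalModel, parameter: str, value: float) -> InternalModel:
    if parameter == "sensor_inflation":
        return apply_conventional_rehab(base, value)
    if parameter == "prior_sharpening":
        return apply_cognitive_training(base, value, base.knowledge_weight)
    return dataclasses.replace(base, knowledge_weight=value)


def run_sweep(sweep: SweepSpec, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Run the sweep; one metrics row per (value, replicate).

    Seeds are matched across values (same replicate, same world noise),
    so the dose-response curve of the seed-mean displacement gain is a
    paired comparison. The summary reports the Spearman rank sign of the
    seed-mean gain against the swept values.
    """
    from scipy.stats import spearmanr

    from .internal_model import make_condition

    label = sweep.base_condition.label
    _, base_internal, _, _ = make_condition(sweep.base_condition, config.defaults)
    rows = []
    for value in sweep.values:
        internal = _sweep_internal(base_internal, sweep.parameter, value)
        for replicate in range(config.n_seeds):
            seed = derive_seed(config.master_seed, label, replicate)
            _, report = run_condition(
                sweep.base_condition, config, seed, internal_override=internal
            )
            row = _metrics_row(label, seed, report)
            row["parameter"] = sweep.parameter
            row["value"] = value
            rows.append(row)
    df = pd.DataFrame(rows)
    seed_means = df.groupby("value")["displacement_gain"].mean()
    rho = spearmanr(seed_means.index.to_numpy(), seed_means.to_numpy()).statistic
    summary = {
        "parameter": sweep.parameter,
        "base_condition": label,
        "values": list(sweep.values),
        "seed_mean_gain": seed_means.to_dict(),
        "spearman_sign": int(np.sign(rho)),
        "gain_non_decreasing": bool(np.all(np.diff(seed_means.to_numpy()) >= 0)),
    }
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"sweep_{sweep.parameter}.csv", index=False)
        with open(out / f"sweep_{sweep.parameter}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return df, summary


def sweep_from_dict(raw: dict) -> SweepSpec:
    try:
        base = resolve_condition(raw["base_condition"])
        return SweepSpec(
            parameter=raw["parameter"], values=tuple(raw["values"]), base_condition=base
        )
    except KeyError as exc:
        raise ConfigError(f"sweep config missing key: {exc}") from None
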