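"""The agent's internal generative model and the rehabilitation knobs.

The internal model is what the brain *believes* about head dynamics and
about its sensors — not what is actually true. It has two halves:

* a process model: head velocity is a damped random walk
  (``x_k = a * x_{k-1} + w_k``, ``w_k ~ N(0, sigma_q^2)``) whose one-step
  predictive distribution is the *dynamic prior*. When the movement is
  self-initiated, the prediction mean is additionally pulled toward the
  knowledge signal by a convex combination with weight ``b``;
* a sensor model: observations are the current velocity plus Gaussian
  noise of assumed sd ``sigma_v``.

Interventions act purely on this belief object, never on the world:
conventional rehabilitation widens the assumed sensor-noise distribution
(so abnormal sensory data are down-weighted), while cognitive training
sharpens the dynamic prior and raises the reliance on predicted movement.

An untreated patient with bilateral vestibulopathy keeps the *healthy*
internal model: the agent does not know its sensors are broken. This
mis-specification is what lets pure sensor noise pull the posterior
toward zero during movement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .model_core import KnowledgeParams, WorldModel

__all__ = [
    "InternalModel",
    "ConditionSpec",
    "ConditionDefaults",
    "predict_step",
    "observation_loglik",
    "apply_conventional_rehab",
    "apply_cognitive_training",
    "make_condition",
]

_PATIENTS = ("healthy", "bvp")
_MOVEMENTS = ("passive", "active")
_INTERVENTIONS = ("none", "conventional", "conventional_plus_cognitive")


@dataclass(frozen=True)
class InternalModel:
    """Assumed process + sensor model used for inference.

    Parameters
    ----------
    decay : float
        Per-step velocity persistence ``a`` in [0, 1]; at the default
        0.01-s step, 0.995 corresponds to a ~2-s damping time constant.
    process_noise_sd : float
        sigma_q, deg/s per step — the width of the dynamic prior's
        innovation; the quantity cognitive training shrinks.
    knowledge_weight : float
        ``b`` in [0, 1]: how strongly the prediction mean is pulled
        toward the knowledge signal when the movement is self-initiated.
    assumed_sensor_noise_sd : float
        sigma_v, deg/s — the sensor-noise width the filter assumes; the
        quantity conventional rehabilitation inflates.
    initial_mean, initial_sd : float
        Gaussian belief about velocity before the first observation.
    """

    decay: float = 0.995
    process_noise_sd: float = 6.0
    knowledge_weight: float = 0.8
    assumed_sensor_noise_sd: float = 10.0
    initial_mean: float = 0.0
    initial_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("decay must be in [0, 1]")
        if not 0.0 <= self.knowledge_weight <= 1.0:
            raise ValueError("knowledge_weight must be in [0, 1]")
        for name in ("process_noise_sd", "assumed_sensor_noise_sd", "initial_sd"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def predict_step(
    prev_velocity, knowledge_value, switch_active: bool, model: InternalModel
):
    """One-step-ahead prediction (the dynamic prior's mean and sd).

    The base prediction is the damped previous velocity,
    ``a * prev``. With the knowledge switch on, the mean becomes the
    convex combination ``(1 - b) * a * prev + b * u``; with it off the
    knowledge signal is ignored. The returned sd is the innovation width
    sigma_q. Deterministic and linear in ``(prev_velocity,
    knowledge_value)``; accepts scalars or arrays (e.g. a particle
    ensemble).
    """
    base = model.decay * np.asarray(prev_velocity, dtype=float)
    if switch_active:
        b = model.knowledge_weight
        mean = (1.0 - b) * base + b * np.asarray(knowledge_value, dtype=float)
    else:
        mean = base
    if np.ndim(prev_velocity) == 0:
        mean = float(mean)
    return mean, model.process_noise_sd


def observation_loglik(observation, velocity, model: InternalModel):
    """Gaussian log-likelihood of an observation under the sensor model.

    ``log N(observation | velocity, sigma_v^2)``, vectorized over
    ``velocity``. The noiseless limit sigma_v = 0 has no density; use the
    exact filter for that case.
    """
    sd = model.assumed_sensor_noise_sd
    if sd <= 0:
        raise ValueError(
            "assumed_sensor_noise_sd must be > 0 for a likelihood; "
            "use the exact filter for the noiseless limit"
        )
    from scipy.stats import norm

    out = norm.logpdf(np.asarray(observation, dtype=float),
                      loc=np.asarray(velocity, dtype=float), scale=sd)
    if np.ndim(velocity) == 0 and np.ndim(observation) == 0:
        return float(out)
    return out


def apply_conventional_rehab(model: InternalModel, inflation: float) -> InternalModel:
    """Widen the assumed sensor-noise distribution by ``inflation`` (>= 1).

    Models conventional vestibular rehabilitation: the patient learns to
    down-weight the uninformative vestibular data. Only the belief about
    sensor noise changes; as inflation grows the posterior approaches the
    pure prediction chain.
    """
    if inflation < 1:
        raise ValueError(f"inflation must be >= 1, got {inflation}")
    return replace(
        model, assumed_sensor_noise_sd=model.assumed_sensor_noise_sd * inflation
    )


def apply_cognitive_training(
    model: InternalModel, prior_sharpening: float, knowledge_weight_new: float
) -> InternalModel:
    """Sharpen the dynamic prior and raise reliance on predicted movement.

    Models cognitive (e.g. mental-imagery) training: predictions of head
    motion become more confident (sigma_q divided by ``prior_sharpening``)
    and are trusted more (``knowledge_weight`` raised to
    ``knowledge_weight_new``; lowering it is not a training outcome and
    is rejected).
    """
    if prior_sharpening < 1:
        raise ValueError(f"prior_sharpening must be >= 1, got {prior_sharpening}")
    if knowledge_weight_new < model.knowledge_weight:
        raise ValueError("cognitive training cannot lower knowledge_weight")
    return replace(
        model,
        process_noise_sd=model.process_noise_sd / prior_sharpening,
        knowledge_weight=knowledge_weight_new,
    )


@dataclass(frozen=True)
class ConditionSpec:
    """A named experimental condition: who moves, how, and with what therapy."""

    patient: str
    movement: str
    intervention: str = "none"
    label: str = ""

    def __post_init__(self) -> None:
        if self.patient not in _PATIENTS:
            raise ValueError(f"patient must be one of {_PATIENTS}")
        if self.movement not in _MOVEMENTS:
            raise ValueError(f"movement must be one of {_MOVEMENTS}")
        if self.intervention not in _INTERVENTIONS:
            raise ValueError(f"intervention must be one of {_INTERVENTIONS}")
        if self.intervention != "none" and self.patient != "bvp":
            raise ValueError("interventions model rehabilitation of BVP patients")
        if not self.label:
            object.__setattr__(self, "label", default_label(self))


def default_label(spec: ConditionSpec) -> str:
    label = f"{spec.patient}_{spec.movement}"
    if spec.intervention != "none":
        label += f"_{spec.intervention}"
    return label


@dataclass(frozen=True)
class ConditionDefaults:
    """Shared baseline configuration from which conditions are derived."""

    world: WorldModel = WorldModel()
    internal: InternalModel = InternalModel()
    knowledge: KnowledgeParams = KnowledgeParams()
    conventional_inflation: float = 10.0
    cognitive_prior_sharpening: float = 3.0
    cognitive_knowledge_weight: float = 0.95


def make_condition(
    spec: ConditionSpec, defaults: ConditionDefaults | None = None
) -> tuple[WorldModel, InternalModel, bool, KnowledgeParams]:
    """Resolve a condition into (world, internal model, switch, knowledge).

    The world's sensor mode follows the patient; the knowledge switch
    follows the movement type. Interventions transform only the internal
    model — beliefs, not physiology — and an untreated BVP patient keeps
    the healthy internal model (the agent is unaware its sensors carry
    no signal).
    """
    if defaults is None:
        defaults = ConditionDefaults()
    world = replace(defaults.world, sensor_mode=spec.patient)
    internal = defaults.internal
    if spec.intervention in ("conventional", "conventional_plus_cognitive"):
        internal = apply_conventional_rehab(internal, defaults.conventional_inflation)
    if spec.intervention == "conventional_plus_cognitive":
        internal = apply_cognitive_training(
            internal,
            defaults.cognitive_prior_sharpening,
            defaults.cognitive_knowledge_weight,
        )
    switch_active = spec.movement == "active"
    return world, internal, switch_active, defaults.knowledge
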