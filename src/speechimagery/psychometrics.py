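"""Continuum encoding, the latency-difference decision rule, and model
psychometric curves.

A seven-step /ba/-/da/ continuum is encoded as complementary drives to the
/ba/ and /da/ sensory nodes during a 100-ms consonant window, followed by a
shared-vowel window (0.5 to both) for 200 ms.  The decision rule converts
the peak latencies of the two competing phonological nodes into a choice
probability via a logistic in the latency difference, with decision noise N
(per-ms slope) and an additive choice bias B_c.

Convention: curves are computed as p(choice = /da/), so the baseline curve
rises with continuum level; imagery shifts are reported as displacement
toward the imagined syllable's percept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .network import (
    GainProfile,
    NetworkParams,
    NetworkTopology,
    StimulusProtocol,
    StimulusSegment,
    simulate,
)
from .repetition import TaskGains

__all__ = [
    "LEVELS",
    "FITTED_DECISION",
    "DecisionParams",
    "ScalingParams",
    "PsychometricCurve",
    "continuum_drives",
    "encode_continuum",
    "choice_probability",
    "model_psychometric",
    "scale_gains",
    "imagery_curves",
]

LEVELS = tuple(range(1, 8))
CONSONANT_MS = 100.0
VOWEL_MS = 200.0
VOWEL_DRIVE = 0.5
TRIAL_DURATION_MS = 500.0

#: decision parameters fitted to the baseline categorization data
FITTED_DECISION = None  # set below once DecisionParams is defined


@dataclass(frozen=True)
class DecisionParams:
    """Decision noise ``N`` (logistic slope per ms of latency difference)
    and additive choice bias ``B_c`` toward the modelled choice."""

    noise: float = 0.0193
    bias: float = 0.0469

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("decision noise must be non-negative")
        if abs(self.bias) >= 0.5:
            raise ValueError("|choice bias| must be below 0.5")


FITTED_DECISION = DecisionParams(noise=0.0193, bias=0.0469)


@dataclass(frozen=True)
class ScalingParams:
    """Per-task scaling of a fitted gain profile.

    ``gain_scale`` (Sg) pulls each modulated node gain toward 1:
    ``g -> g - Sg * (g - 1)``; 0 is the identity, 1 full neutralization.
    ``attention_scale`` (SG_A) multiplies the attentional gain.
    """

    gain_scale: float
    attention_scale: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gain_scale <= 1.0:
            raise ValueError("gain_scale must lie in [0, 1]")
        if self.attention_scale <= 0:
            raise ValueError("attention_scale must be strictly positive")


@dataclass(frozen=True)
class PsychometricCurve:
    """Per-level proportion of /da/ choices with condition labels."""

    p_choice_da: tuple[float, ...]
    condition: str = "model"
    imagery_token: str = "none"

    def __post_init__(self) -> None:
        if len(self.p_choice_da) != len(LEVELS):
            raise ValueError("expected one proportion per continuum level")
        if any(not 0.0 <= p <= 1.0 for p in self.p_choice_da):
            raise ValueError("proportions must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p_choice_da)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition,
            "imagery_token": self.imagery_token,
            "level": list(LEVELS),
            "p_choice_da": list(self.p_choice_da),
        })


def continuum_drives(level: int) -> tuple[float, float]:
    """Consonant-window drives (ba, da) for one continuum level.

    Linear interpolation between the anchors (1, 0) at level 1, (0.5, 0.5)
    at level 4 and (0, 1) at level 7, i.e. the /ba/ drive is
    ``1 - (level - 1) / 6``.
    """
    if level not in LEVELS:
        raise ValueError(f"continuum level must be in 1..7, got {level}")
    da = (level - 1) / 6.0
    return 1.0 - da, da


def encode_continuum(level: int,
                     duration_ms: float = TRIAL_DURATION_MS) -> StimulusProtocol:
    """Stimulus protocol for one continuum trial.

    [0, 100) ms: level-dependent complementary drives to /ba/ and /da/;
    [100, 300) ms: the shared vowel, 0.5 to both; silence afterwards.
    """
    ba, da = continuum_drives(level)
    segments = []
    if ba > 0:
        segments.append(StimulusSegment("ba", ba, 0.0, CONSONANT_MS))
    if da > 0:
        segments.append(StimulusSegment("da", da, 0.0, CONSONANT_MS))
    vowel_end = CONSONANT_MS + VOWEL_MS
    segments.append(StimulusSegment("ba", VOWEL_DRIVE, CONSONANT_MS, vowel_end))
    segments.append(StimulusSegment("da", VOWEL_DRIVE, CONSONANT_MS, vowel_end))
    if vowel_end > duration_ms:
        raise ValueError("trial duration shorter than the stimulus")
    return StimulusProtocol(segments=tuple(segments))


def choice_probability(t_alternative: float, t_choice: float,
                       decision: DecisionParams) -> float:
    """Logistic of ``N * (t_alt - t_choice)`` plus bias, clamped to [0, 1].

    An earlier peak of the choice node (relative to the alternative) makes
    the choice more likely; the additive bias can push the raw value outside
    [0, 1], hence the clamp.
    """
    if not (np.isfinite(t_alternative) and np.isfinite(t_choice)):
        raise ValueError("latencies must be finite")
    z = decision.noise * (t_alternative - t_choice)
    p = float(special.expit(z)) + decision.bias
    return float(min(1.0, max(0.0, p)))


def model_psychometric(gains: GainProfile | None,
                       decision: DecisionParams,
                       params: NetworkParams | None = None,
                       topology: NetworkTopology | None = None,
                       condition: str = "model",
                       imagery_token: str = "none") -> PsychometricCurve:
    """Model psychometric curve p(/da/) over the seven continuum levels.

    For each level the network is simulated under the given gain profile;
    the peak latencies of the phonological /ba/ and /da/ nodes feed the
    decision rule.  A node that never fires is assigned the simulation
    duration as its latency (slowest possible).  Deterministic.
    """
    params = (params or NetworkParams()).with_duration(TRIAL_DURATION_MS)
    topology = topology or NetworkTopology.from_params(params)
    gains = gains or GainProfile.neutral()
    ps = []
    for level in LEVELS:
        protocol = encode_continuum(level, params.sim_duration)
        result = simulate(protocol, gains, params, topology)
        t_ba = result.node_peak_latency("ba")
        t_da = result.node_peak_latency("da")
        ps.append(choice_probability(t_ba, t_da, decision))
    return PsychometricCurve(p_choice_da=tuple(ps), condition=condition,
                             imagery_token=imagery_token)


def scale_gains(gains: GainProfile, scaling: ScalingParams) -> GainProfile:
    """Apply the per-task scaling to a gain profile.

    Every node gain moves toward neutral, ``g - Sg * (g - 1)`` (gains already
    at 1 are unchanged), and the attentional gain is multiplied by SG_A.
    """
    sg = scaling.gain_scale
    node_gains = tuple(g - sg * (g - 1.0) for g in gains.node_gains)
    return GainProfile(node_gains=node_gains,
                       attentional_gain=gains.attentional_gain *
                       scaling.attention_scale)


def imagery_curves(ai_gains: TaskGains, hi_gains: TaskGains,
                   decision: DecisionParams, imagined: str = "ba",
                   params: NetworkParams | None = None,
                   topology: NetworkTopology | None = None,
                   ai_scaling: ScalingParams | None = None,
                   hi_scaling: ScalingParams | None = None,
                   ) -> dict[str, PsychometricCurve]:
    """Baseline, AI and HI model curves for one imagined token.

    ``g_repeated`` follows the imagined token's node; optional per-task
    scaling (used for imagery /da/) is applied to the profiles before
    simulation.
    """
    topology = topology or NetworkTopology()
    curves = {"BL": model_psychometric(None, decision, params, topology,
                                       condition="BL")}
    for name, task_gains, scaling in (("AI", ai_gains, ai_scaling),
                                      ("HI", hi_gains, hi_scaling)):
        profile = task_gains.profile(imagined, topology)
        if scaling is not None:
            profile = scale_gains(profile, scaling)
        curves[name] = model_psychometric(profile, decision, params, topology,
                                          condition=name,
                                          imagery_token=imagined)
    return curves
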