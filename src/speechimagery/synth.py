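"""Synthetic data generators mirroring the study's design.

Every analysis stage can be exercised without any recorded data: trial-level
behavioral datasets are drawn from condition-specific psychometric curves
with between-participant variability, empirical-style MEG repetition
effects are produced by forward simulation plus measurement noise, and
baseline psychometric curves by binomial sampling of the model's choice
probabilities.

Defaults mirror the experiment: 19 participants, three blocks of 252 trials
(36 per continuum level, split 18/18 between imagined tokens in the imagery
blocks).  Two generation paths exist for the behavioral curves — direct
logistic curves (used when testing aggregation/statistics, so those tests
are not circular through the network model) and model-generated
probabilities (used when testing decision-rule recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import COLUMNS, BehavioralDataset
from .network import GainProfile, NetworkParams, NetworkTopology
from .psychometrics import (
    LEVELS,
    DecisionParams,
    PsychometricCurve,
    model_psychometric,
)
from .repetition import RepetitionEffects, TaskGains, simulate_repetition_effects

__all__ = [
    "LogisticCurve",
    "SynthConfig",
    "synth_behavior",
    "synth_meg_effects",
    "synth_bl_curve",
]


@dataclass(frozen=True)
class LogisticCurve:
    """Direct psychometric-curve parametrization: p(/da/) by level.

    ``midpoint`` is the category boundary in level units (4 = mid-continuum),
    ``slope`` the logistic steepness per level, ``lapse`` a symmetric lapse
    rate compressing the asymptotes, ``bias`` an additive shift.
    """

    midpoint: float = 4.0
    slope: float = 1.2
    lapse: float = 0.05
    bias: float = 0.0

    def probabilities(self) -> np.ndarray:
        x = np.asarray(LEVELS, dtype=float)
        core = 1.0 / (1.0 + np.exp(-self.slope * (x - self.midpoint)))
        p = self.lapse + (1.0 - 2.0 * self.lapse) * core + self.bias
        return np.clip(p, 0.0, 1.0)


#: condition-specific generating curves: the imagery of a token shifts the
#: boundary toward that token's percept, more after articulation imagery
#: than hearing imagery (and less for imagined /da/ than /ba/)
DEFAULT_CURVES: dict[tuple[str, str], LogisticCurve] = {
    ("BL", "none"): LogisticCurve(midpoint=4.0),
    ("AI", "ba"): LogisticCurve(midpoint=4.55),
    ("HI", "ba"): LogisticCurve(midpoint=4.25),
    ("AI", "da"): LogisticCurve(midpoint=3.85),
    ("HI", "da"): LogisticCurve(midpoint=3.90),
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; identical seeds give identical datasets."""

    n_participants: int = 19
    trials_per_level_per_token: int = 18
    bl_trials_per_level: int = 36
    curves: dict[tuple[str, str], LogisticCurve] = field(
        default_factory=lambda: dict(DEFAULT_CURVES))
    midpoint_sd: float = 0.4
    bias_sd: float = 0.03
    rt_location: float = 6.35   # log-ms; exp(6.35) ~ 572 ms
    rt_boundary_gain: float = 0.25
    rt_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if min(self.trials_per_level_per_token, self.bl_trials_per_level) < 1:
            raise ValueError("trial counts must be positive")
        if min(self.midpoint_sd, self.bias_sd, self.rt_sigma) < 0:
            raise ValueError("spreads must be non-negative")


def _draw_rts(rng: np.random.Generator, levels: np.ndarray,
              config: SynthConfig) -> np.ndarray:
    """Log-normal RTs whose location grows near the category boundary."""
    proximity = 1.0 - np.abs(levels - 4.0) / 3.0
    mu = config.rt_location + config.rt_boundary_gain * proximity
    return np.exp(mu + config.rt_sigma * rng.standard_normal(levels.size))


def synth_behavior(config: SynthConfig | None = None,
                   seed: int | None = None) -> BehavioralDataset:
    """Generate a trial-level dataset from the configured curves.

    Per participant, curve parameters are jittered (midpoint and bias), the
    per-level /da/ probabilities are computed per (condition, token), and
    choices are drawn as independent Bernoulli trials with log-normal RTs.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = []
    for pid in range(1, config.n_participants + 1):
        mid_jit = rng.normal(0.0, config.midpoint_sd)
        bias_jit = rng.normal(0.0, config.bias_sd)
        for (condition, token), curve in config.curves.items():
            jittered = LogisticCurve(midpoint=curve.midpoint + mid_jit,
                                     slope=curve.slope, lapse=curve.lapse,
                                     bias=curve.bias + bias_jit)
            probs = jittered.probabilities()
            n_trials = (config.bl_trials_per_level if condition == "BL"
                        else config.trials_per_level_per_token)
            for level in LEVELS:
                p = probs[level - 1]
                draws = rng.random(n_trials) < p
                lv = np.full(n_trials, level, dtype=float)
                rts = _draw_rts(rng, lv, config)
                for trial, (is_da, rt) in enumerate(zip(draws, rts), 1):
                    records.append((pid, condition, token, level, trial,
                                    "da" if is_da else "ba", float(rt)))
    frame = pd.DataFrame(records, columns=COLUMNS)
    return BehavioralDataset(frame)


def synth_meg_effects(true_ai_gains: TaskGains, true_hi_gains: TaskGains,
                      noise_sd: float = 0.0, seed: int = 0,
                      params: NetworkParams | None = None,
                      topology: NetworkTopology | None = None,
                      ) -> RepetitionEffects:
    """Empirical-style repetition effects: forward simulation plus noise.

    ``noise_sd`` is the standard deviation of seeded Gaussian noise added to
    each of the four fractional changes (0 returns the exact forward
    simulation).  Stands in for repetition-effect magnitudes measured with
    MEG, which are inputs to the gain fit rather than outputs of this model.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    clean = simulate_repetition_effects(true_ai_gains, true_hi_gains,
                                        params, topology)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    noisy = clean.as_array() + rng.normal(0.0, noise_sd, 4)
    return RepetitionEffects.from_array(noisy, clean.baseline_mean)


def synth_bl_curve(decision: DecisionParams, binomial_n: int | None = 684,
                   seed: int = 0,
                   params: NetworkParams | None = None,
                   topology: NetworkTopology | None = None,
                   ) -> PsychometricCurve:
    """Baseline psychometric curve: model probabilities, binomial sampling.

    ``binomial_n`` trials per level (default 19 participants x 36 trials);
    ``None`` returns the exact model probabilities (infinite-data limit).
    """
    model = model_psychometric(None, decision, params, topology,
                               condition="BL")
    if binomial_n is None:
        return model
    if binomial_n < 1:
        raise ValueError("binomial_n must be positive (or None)")
    rng = np.random.default_rng(seed)
    sampled = rng.binomial(binomial_n, model.as_array()) / binomial_n
    return PsychometricCurve(p_choice_da=tuple(float(p) for p in sampled),
                             condition="BL")
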