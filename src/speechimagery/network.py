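"""Two-layer rate-coded network with synaptic depression and gain modulation.

The model is a pair of six-node layers — a sensory (acoustic) layer feeding a
phonological layer — in which each node is a rate-coded point neuron.  A
node's output is the product of its firing probability ``p = max(v - theta, 0)``
and a postsynaptic firing amplitude ``a`` that is depleted by the node's own
output and slowly recovers toward 1 (synaptic depression).  Membrane
potentials integrate three conductance channels (excitation toward 1, leak
and lateral inhibition toward 0) with one forward-Euler integration rate per
layer.  Top-down influences enter as multiplicative gains on the bottom-up
input of phonological nodes (per-node ``g_i`` plus a global attentional gain
``G_A``).

Units: time is in milliseconds; potentials, amplitudes, outputs and drives
are dimensionless in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SYLLABLES",
    "GROUPS",
    "NetworkParams",
    "NetworkTopology",
    "GainProfile",
    "StimulusSegment",
    "StimulusProtocol",
    "SimResult",
    "SimulationUnstableError",
    "node_output",
    "step_network",
    "simulate",
    "peak_latency",
    "peak_window_mean",
]

SYLLABLES = ("ba", "da", "ga", "pi", "ti", "ki")
GROUPS = (("ba", "da", "ga"), ("pi", "ti", "ki"))

#: tolerance for declaring the Euler integration unstable
_V_TOL = 1e-9


class SimulationUnstableError(RuntimeError):
    """A membrane potential left [0, 1]; the step size is too large."""


@dataclass(frozen=True)
class NetworkParams:
    """Fixed dynamical constants plus integration settings.

    The defaults are the model's fixed parameter set: leak ``L`` = 0.30,
    lateral inhibition ``I`` = 0.15, firing threshold ``theta`` = 0.15,
    depletion rate ``D`` = 0.324, recovery rate ``R`` = 0.022, and per-step
    integration rates 0.031 (sensory) and 0.01 (phonological).  Reversal
    potentials fix the channel targets: excitation pulls ``v`` toward 1,
    leak and inhibition toward 0.
    """

    leak_strength: float = 0.30
    inhibition_strength: float = 0.15
    firing_threshold: float = 0.15
    depletion_rate: float = 0.324
    recovery_rate: float = 0.022
    tau_sensory: float = 0.031
    tau_phonological: float = 0.01
    weight_same: float = 1.0
    weight_cross: float = 0.22
    excitatory_reversal: float = 1.0
    inhibitory_reversal: float = 0.0
    leak_reversal: float = 0.0
    step_size: float = 1.0
    sim_duration: float = 800.0

    def __post_init__(self) -> None:
        positive = (
            "leak_strength inhibition_strength depletion_rate recovery_rate "
            "tau_sensory tau_phonological step_size sim_duration"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.firing_threshold < 1:
            raise ValueError("firing_threshold must lie in (0, 1)")
        for name in ("weight_same", "weight_cross"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.excitatory_reversal != 1.0 or self.inhibitory_reversal != 0.0 \
                or self.leak_reversal != 0.0:
            raise ValueError(
                "reversal potentials are fixed at E_e=1, E_i=E_l=0"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.sim_duration / self.step_size))

    def with_duration(self, sim_duration: float) -> "NetworkParams":
        return replace(self, sim_duration=sim_duration)


@dataclass(frozen=True)
class NetworkTopology:
    """Node labels, phonemic groups and the bottom-up weight matrix.

    Connections exist only within a group: weight ``weight_same`` between the
    two layers' nodes of the same syllable and ``weight_cross`` between
    different syllables of the same group, so the matrix is block-diagonal
    over groups.
    """

    nodes: tuple[str, ...] = SYLLABLES
    groups: tuple[tuple[str, ...], ...] = GROUPS
    weight_same: float = 1.0
    weight_cross: float = 0.22

    def __post_init__(self) -> None:
        flat = tuple(n for g in self.groups for n in g)
        if sorted(flat) != sorted(self.nodes):
            raise ValueError("groups must partition the node labels")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, label: str) -> int:
        return self.nodes.index(label)

    def group_of(self, label: str) -> tuple[str, ...]:
        for group in self.groups:
            if label in group:
                return group
        raise KeyError(label)

    def group_indices(self, which: int) -> list[int]:
        return [self.index(n) for n in self.groups[which]]

    @property
    def weight_matrix(self) -> np.ndarray:
        w = np.zeros((self.n_nodes, self.n_nodes))
        for group in self.groups:
            for a in group:
                for b in group:
                    w[self.index(a), self.index(b)] = (
                        self.weight_same if a == b else self.weight_cross
                    )
        return w

    @classmethod
    def from_params(cls, params: NetworkParams) -> "NetworkTopology":
        return cls(weight_same=params.weight_same,
                   weight_cross=params.weight_cross)


@dataclass(frozen=True)
class GainProfile:
    """Multiplicative bottom-up gains at the phonological layer.

    ``node_gains[i]`` multiplies the bottom-up input of phonological node i;
    ``attentional_gain`` multiplies the bottom-up input of every phonological
    node.  The neutral profile (all ones) leaves the network unmodulated.
    """

    node_gains: tuple[float, ...] = (1.0,) * 6
    attentional_gain: float = 1.0

    def __post_init__(self) -> None:
        if len(self.node_gains) != 6:
            raise ValueError("expected one gain per phonological node")
        if any(g <= 0 for g in self.node_gains) or self.attentional_gain <= 0:
            raise ValueError("gains must be strictly positive")

    @classmethod
    def neutral(cls) -> "GainProfile":
        return cls()

    @property
    def is_neutral(self) -> bool:
        return self.attentional_gain == 1.0 and all(
            g == 1.0 for g in self.node_gains
        )

    def effective(self) -> np.ndarray:
        """Per-node gain including the attentional factor."""
        return np.asarray(self.node_gains) * self.attentional_gain

    def as_array(self) -> np.ndarray:
        return np.asarray(self.node_gains, dtype=float)


@dataclass(frozen=True)
class StimulusSegment:
    """Constant drive ``value`` to one sensory node over [onset, offset) ms."""

    node: str
    value: float
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("drive values must lie in [0, 1]")
        if self.offset <= self.onset or self.onset < 0:
            raise ValueError("segment must satisfy 0 <= onset < offset")


@dataclass(frozen=True)
class StimulusProtocol:
    """Step-wise external drive to the sensory layer."""

    segments: tuple[StimulusSegment, ...]

    @classmethod
    def constant(cls, node: str, value: float = 1.0, onset: float = 0.0,
                 offset: float = 500.0) -> "StimulusProtocol":
        return cls(segments=(StimulusSegment(node, value, onset, offset),))

    @classmethod
    def silence(cls) -> "StimulusProtocol":
        return cls(segments=())

    @property
    def end(self) -> float:
        return max((s.offset for s in self.segments), default=0.0)

    def drive_matrix(self, params: NetworkParams,
                     topology: NetworkTopology) -> np.ndarray:
        """(n_steps, n_nodes) drive sampled at integration steps."""
        if self.end > params.sim_duration:
            raise ValueError(
                f"protocol extends to {self.end} ms but sim_duration is "
                f"{params.sim_duration} ms"
            )
        n = params.n_steps
        drive = np.zeros((n, topology.n_nodes))
        t = np.arange(n) * params.step_size
        for seg in self.segments:
            mask = (t >= seg.onset) & (t < seg.offset)
            drive[mask, topology.index(seg.node)] += seg.value
        if drive.max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("summed drives exceed 1 on some node")
        return drive


@dataclass
class SimResult:
    """Full time series for both layers plus summed-waveform summaries.

    ``peak_latency_ms`` / ``peak_window_mean`` are ``None`` when the summed
    phonological waveform is identically zero (never-active network); callers
    that need a latency convention for silent nodes use the simulation
    duration instead.
    """

    time_ms: np.ndarray
    sensory: np.ndarray
    phonological: np.ndarray
    params: NetworkParams
    topology: NetworkTopology
    peak_latency_ms: float | None = None
    peak_window_mean: float | None = None

    @property
    def summed_phonological(self) -> np.ndarray:
        return self.phonological.sum(axis=1)

    def node_series(self, layer: str, label: str) -> np.ndarray:
        arr = {"sensory": self.sensory, "phonological": self.phonological}[layer]
        return arr[:, self.topology.index(label)]

    def node_peak_latency(self, label: str,
                          layer: str = "phonological") -> float:
        """Peak latency of one node, with the silent-node convention.

        A node whose output never rises above zero is assigned the full
        simulation duration (the slowest possible latency).
        """
        series = self.node_series(layer, label)
        lat = peak_latency(series, self.params.step_size)
        return self.params.sim_duration if lat is None else lat

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_ms": self.time_ms}
        for layer, arr in (("sensory", self.sensory),
                           ("phonological", self.phonological)):
            for j, label in enumerate(self.topology.nodes):
                cols[f"{layer}.{label}"] = arr[:, j]
        cols["summed_phonological"] = self.summed_phonological
        return pd.DataFrame(cols)


def node_output(v: float | np.ndarray, a: float | np.ndarray,
                theta: float) -> float | np.ndarray:
    """Rate-coded output ``o = max(v - theta, 0) * a``.

    The firing probability is rectified at zero: a sub-threshold potential
    emits nothing rather than a negative rate (negative outputs would inflate
    the depression amplitude without bound).
    """
    return np.maximum(v - theta, 0.0) * a


def step_network(state: dict[str, np.ndarray], drive: np.ndarray,
                 gains: GainProfile, params: NetworkParams,
                 topology: NetworkTopology,
                 weight_matrix: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """One forward-Euler update of all node states.

    ``state`` maps ``v_s, a_s, v_p, a_p`` to length-6 arrays.  The sensory
    layer uses the external drive as its bottom-up term with rate
    ``tau_sensory``; the phonological layer integrates
    ``g_i * G_A * sum_j w_ij o_j(sensory)`` with rate ``tau_phonological``.
    Lateral inhibition sums the outputs of the other same-layer nodes.
    Amplitude recovery/depletion is integrated at the same per-layer rate as
    the membrane potential.

    Returns a new state dict; raises :class:`SimulationUnstableError` if a
    potential leaves [0, 1] beyond tolerance.
    """
    w = topology.weight_matrix if weight_matrix is None else weight_matrix
    theta = params.firing_threshold
    L, I = params.leak_strength, params.inhibition_strength
    R, D = params.recovery_rate, params.depletion_rate
    ts = params.tau_sensory * params.step_size
    tp = params.tau_phonological * params.step_size
    g = gains.effective()

    v_s, a_s = state["v_s"], state["a_s"]
    v_p, a_p = state["v_p"], state["a_p"]
    o_s = node_output(v_s, a_s, theta)
    o_p = node_output(v_p, a_p, theta)

    inh_s = I * (o_s.sum() - o_s)
    inh_p = I * (o_p.sum() - o_p)
    new_v_s = v_s + ts * ((1.0 - v_s) * drive - v_s * (L + inh_s))
    new_v_p = v_p + tp * (g * (1.0 - v_p) * (w @ o_s) - v_p * (L + inh_p))
    new_a_s = a_s + ts * (R * (1.0 - a_s) - D * o_s)
    new_a_p = a_p + tp * (R * (1.0 - a_p) - D * o_p)

    for v in (new_v_s, new_v_p):
        if v.min() < -_V_TOL or v.max() > 1.0 + _V_TOL:
            raise SimulationUnstableError(
                "membrane potential left [0, 1]; reduce step_size"
            )
    return {"v_s": new_v_s, "a_s": new_a_s, "v_p": new_v_p, "a_p": new_a_p}


def rest_state(n_nodes: int = 6) -> dict[str, np.ndarray]:
    """All potentials at 0, all amplitudes at 1."""
    return {
        "v_s": np.zeros(n_nodes), "a_s": np.ones(n_nodes),
        "v_p": np.zeros(n_nodes), "a_p": np.ones(n_nodes),
    }


def _sensory_outputs(drive: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Sensory-layer output time series (gain-independent, cacheable).

    The sensory layer receives no feedback from the phonological layer, so
    its trajectory depends only on the drive; fitting routines reuse it
    across gain profiles.
    """
    theta = params.firing_threshold
    L, I = params.leak_strength, params.inhibition_strength
    R, D = params.recovery_rate, params.depletion_rate
    ts = params.tau_sensory * params.step_size
    n, m = drive.shape
    v = np.zeros(m)
    a = np.ones(m)
    out = np.empty((n, m))
    for t in range(n):
        o = np.maximum(v - theta, 0.0) * a
        out[t] = o
        inh = I * (o.sum() - o)
        v = v + ts * ((1.0 - v) * drive[t] - v * (L + inh))
        a = a + ts * (R * (1.0 - a) - D * o)
        if v.min() < -_V_TOL or v.max() > 1.0 + _V_TOL:
            raise SimulationUnstableError(
                "sensory potential left [0, 1]; reduce step_size"
            )
    return out


def _phonological_outputs_batch(sensory_out: np.ndarray, gains: np.ndarray,
                                params: NetworkParams,
                                weight_matrix: np.ndarray) -> np.ndarray:
    """Phonological sweeps for ``k`` effective gain vectors at once.

    ``gains`` has shape (k, m); returns (k, n_steps, m).  Batching amortizes
    the per-step Python overhead across conditions that share a stimulus,
    which the fitting routines exploit heavily.
    """
    theta = params.firing_threshold
    L, I = params.leak_strength, params.inhibition_strength
    R, D = params.recovery_rate, params.depletion_rate
    tp = params.tau_phonological * params.step_size
    g = np.atleast_2d(np.asarray(gains, dtype=float))
    bottom_up = sensory_out @ weight_matrix.T
    n, m = sensory_out.shape
    k = g.shape[0]
    v = np.zeros((k, m))
    a = np.ones((k, m))
    out = np.empty((k, n, m))
    for t in range(n):
        o = np.maximum(v - theta, 0.0) * a
        out[:, t] = o
        inh = I * (o.sum(axis=1, keepdims=True) - o)
        v = v + tp * (g * (1.0 - v) * bottom_up[t] - v * (L + inh))
        a = a + tp * (R * (1.0 - a) - D * o)
        if v.min() < -_V_TOL or v.max() > 1.0 + _V_TOL:
            raise SimulationUnstableError(
                "phonological potential left [0, 1]; reduce step_size"
            )
    return out


def _phonological_outputs(sensory_out: np.ndarray, gains: GainProfile,
                          params: NetworkParams,
                          weight_matrix: np.ndarray) -> np.ndarray:
    return _phonological_outputs_batch(sensory_out, gains.effective()[None, :],
                                       params, weight_matrix)[0]


def simulate(protocol: StimulusProtocol, gains: GainProfile | None = None,
             params: NetworkParams | None = None,
             topology: NetworkTopology | None = None,
             require_peak: bool = False) -> SimResult:
    """Run the full network for ``params.sim_duration`` ms.

    Deterministic given its inputs.  Peak summaries of the summed
    phonological waveform are populated when the waveform is non-zero; with
    ``require_peak=True`` a silent waveform raises ``ValueError`` instead of
    flagging the summaries as ``None``.
    """
    params = params or NetworkParams()
    topology = topology or NetworkTopology.from_params(params)
    gains = gains or GainProfile.neutral()
    drive = protocol.drive_matrix(params, topology)
    sens = _sensory_outputs(drive, params)
    phon = _phonological_outputs(sens, gains, params, topology.weight_matrix)
    time_ms = np.arange(params.n_steps) * params.step_size
    result = SimResult(time_ms=time_ms, sensory=sens, phonological=phon,
                       params=params, topology=topology)
    summed = result.summed_phonological
    lat = peak_latency(summed, params.step_size)
    if lat is None:
        if require_peak:
            raise ValueError("summed waveform is identically zero; "
                             "peak summary undefined")
        return result
    result.peak_latency_ms = lat
    result.peak_window_mean = peak_window_mean(summed, params.step_size)
    return result


def peak_latency(waveform: Sequence[float] | np.ndarray,
                 step_size: float = 1.0) -> float | None:
    """Time (ms) of the waveform's global maximum; earliest index on ties.

    Returns ``None`` (flagged-undefined) when the maximum is 0, i.e. the
    node never fired; callers choose their own convention for that case.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size == 0:
        raise ValueError("empty waveform")
    if w.max() <= 0.0:
        return None
    return float(np.argmax(w)) * step_size


def peak_window_mean(waveform: Sequence[float] | np.ndarray,
                     step_size: float = 1.0,
                     width_ms: float = 25.0) -> float | None:
    """Mean over a ``width_ms`` window centered on the peak latency.

    The window covers samples within ``width_ms / 2`` of the peak and is
    truncated at the series boundaries.  Returns ``None`` for an all-zero
    waveform (undefined peak).
    """
    if width_ms <= 0:
        raise ValueError("width_ms must be positive")
    w = np.asarray(waveform, dtype=float)
    lat = peak_latency(w, step_size)
    if lat is None:
        return None
    t = np.arange(w.size) * step_size
    mask = np.abs(t - lat) <= width_ms / 2.0
    return float(w[mask].mean())
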