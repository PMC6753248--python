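"""Unit and property tests for the rate-coded network core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from speechimagery.network import (
    GROUPS,
    SYLLABLES,
    GainProfile,
    NetworkParams,
    NetworkTopology,
    SimulationUnstableError,
    StimulusProtocol,
    StimulusSegment,
    node_output,
    peak_latency,
    peak_window_mean,
    rest_state,
    simulate,
    step_network,
)


@pytest.mark.parametrize("v,a,theta,expected", [
    (0.15, 1.0, 0.15, 0.0),       # boundary: v equals threshold
    (0.10, 0.9, 0.15, 0.0),       # sub-threshold is rectified to zero
    (0.65, 0.8, 0.15, 0.40),      # (0.65 - 0.15) * 0.8
])
def test_node_output_values(v, a, theta, expected):
    assert node_output(v, a, theta) == pytest.approx(expected)


def test_node_output_never_negative():
    v = np.linspace(0, 1, 21)
    out = node_output(v, np.full_like(v, 0.7), 0.15)
    assert (out >= 0).all()


class TestWeightMatrix:
    def test_block_diagonal_over_groups(self, topology):
        w = topology.weight_matrix
        for i, a in enumerate(SYLLABLES):
            for j, b in enumerate(SYLLABLES):
                same_group = topology.group_of(a) == topology.group_of(b)
                if a == b:
                    assert w[i, j] == 1.0
                elif same_group:
                    assert w[i, j] == 0.22
                else:
                    assert w[i, j] == 0.0

    def test_groups_must_partition_nodes(self):
        with pytest.raises(ValueError):
            NetworkTopology(groups=(("ba", "da"), ("pi", "ti", "ki")))


class TestParamsValidation:
    def test_defaults_valid(self):
        NetworkParams()

    @pytest.mark.parametrize("kwargs", [
        {"leak_strength": 0.0},
        {"firing_threshold": 1.5},
        {"weight_cross": -0.1},
        {"excitatory_reversal": 0.9},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkParams(**kwargs)


class TestStepNetwork:
    def test_rest_with_zero_drive_is_fixed_point(self, params, topology):
        state = rest_state()
        new = step_network(state, np.zeros(6), GainProfile.neutral(),
                           params, topology)
        for key in state:
            np.testing.assert_array_equal(new[key], state[key])

    def test_single_step_unit_drive(self, params, topology):
        """From rest, one step with unit drive moves only the driven node's
        sensory potential, by tau_s * 1 * (1 - 0)."""
        drive = np.zeros(6)
        drive[topology.index("ba")] = 1.0
        new = step_network(rest_state(), drive, GainProfile.neutral(),
                           params, topology)
        expected = np.zeros(6)
        expected[topology.index("ba")] = params.tau_sensory
        np.testing.assert_allclose(new["v_s"], expected)
        np.testing.assert_array_equal(new["v_p"], np.zeros(6))
        np.testing.assert_array_equal(new["a_s"], np.ones(6))

    def test_scalar_oracle_agreement(self, params, topology):
        """One Euler step matches an independent scalar expansion of the
        update equations on an arbitrary valid state."""
        rng = np.random.default_rng(5)
        state = {
            "v_s": rng.uniform(0, 0.9, 6), "a_s": rng.uniform(0.3, 1.0, 6),
            "v_p": rng.uniform(0, 0.9, 6), "a_p": rng.uniform(0.3, 1.0, 6),
        }
        drive = rng.uniform(0, 1, 6)
        gains = GainProfile(node_gains=tuple(rng.uniform(0.8, 1.2, 6)),
                            attentional_gain=1.1)
        new = step_network({k: v.copy() for k, v in state.items()},
                           drive, gains, params, topology)

        th = params.firing_threshold
        w = topology.weight_matrix
        o_s = [max(state["v_s"][i] - th, 0.0) * state["a_s"][i]
               for i in range(6)]
        o_p = [max(state["v_p"][i] - th, 0.0) * state["a_p"][i]
               for i in range(6)]
        for i in range(6):
            inh_s = params.inhibition_strength * sum(
                o_s[k] for k in range(6) if k != i)
            v_s = state["v_s"][i] + params.tau_sensory * (
                (1 - state["v_s"][i]) * drive[i]
                - state["v_s"][i] * (params.leak_strength + inh_s))
            assert new["v_s"][i] == pytest.approx(v_s, abs=1e-14)

            bottom_up = sum(w[i, j] * o_s[j] for j in range(6))
            inh_p = params.inhibition_strength * sum(
                o_p[k] for k in range(6) if k != i)
            g_eff = gains.node_gains[i] * gains.attentional_gain
            v_p = state["v_p"][i] + params.tau_phonological * (
                g_eff * (1 - state["v_p"][i]) * bottom_up
                - state["v_p"][i] * (params.leak_strength + inh_p))
            assert new["v_p"][i] == pytest.approx(v_p, abs=1e-14)

            a_p = state["a_p"][i] + params.tau_phonological * (
                params.recovery_rate * (1 - state["a_p"][i])
                - params.depletion_rate * o_p[i])
            assert new["a_p"][i] == pytest.approx(a_p, abs=1e-14)

    def test_instability_signalled(self, topology):
        params = NetworkParams(step_size=80.0, sim_duration=800.0)
        protocol = StimulusProtocol.constant("ba")
        with pytest.raises(SimulationUnstableError):
            simulate(protocol, None, params, topology)


class TestSimulate:
    def test_zero_drive_silent_and_flagged(self, params, topology):
        result = simulate(StimulusProtocol.silence(), None, params, topology)
        assert result.summed_phonological.max() == 0.0
        assert result.peak_latency_ms is None
        assert result.peak_window_mean is None
        with pytest.raises(ValueError):
            simulate(StimulusProtocol.silence(), None, params, topology,
                     require_peak=True)

    def test_rest_stability_all_nodes(self, params, topology):
        result = simulate(StimulusProtocol.silence(), None, params, topology)
        assert np.all(result.sensory == 0.0)
        assert np.all(result.phonological == 0.0)

    def test_summed_waveform_is_nodewise_sum(self, params, topology):
        result = simulate(StimulusProtocol.constant("ba"), None, params,
                          topology)
        np.testing.assert_allclose(result.summed_phonological,
                                   result.phonological.sum(axis=1))

    def test_group_relabelling_symmetry(self, params, topology):
        """Driving /ba/ vs /ki/ gives identical dynamics up to swapping the
        two groups (machine precision)."""
        res_ba = simulate(StimulusProtocol.constant("ba"), None, params,
                          topology)
        res_ki = simulate(StimulusProtocol.constant("ki"), None, params,
                          topology)
        # relabelling (ba,da,ga)<->(ki,ti,pi): ba maps to position of ki
        # within its group reversed; build the permutation explicitly
        perm = [topology.index(n) for n in ("ki", "ti", "pi",
                                            "ga", "da", "ba")]
        np.testing.assert_allclose(res_ba.phonological,
                                   res_ki.phonological[:, perm],
                                   rtol=1e-12, atol=1e-15)

    def test_within_group_exchangeability(self, params, topology):
        """/ba/ and /da/ have identical weights, so equal drives to both
        produce equal node outputs."""
        protocol = StimulusProtocol(segments=(
            StimulusSegment("ba", 0.5, 0.0, 300.0),
            StimulusSegment("da", 0.5, 0.0, 300.0),
        ))
        result = simulate(protocol, None, params, topology)
        np.testing.assert_allclose(result.node_series("phonological", "ba"),
                                   result.node_series("phonological", "da"),
                                   rtol=1e-12, atol=1e-15)

    def test_attentional_gain_monotonicity(self, params, topology):
        """Raising G_A never decreases the driven group's windowed output."""
        protocol = StimulusProtocol.constant("ba")
        base = simulate(protocol, GainProfile(attentional_gain=1.0),
                        params, topology, require_peak=True)
        boosted = simulate(protocol, GainProfile(attentional_gain=2.0),
                           params, topology, require_peak=True)
        assert boosted.peak_window_mean >= base.peak_window_mean

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(SYLLABLES),
                              st.floats(0.1, 1.0),
                              st.integers(0, 300),
                              st.integers(301, 700)),
                    min_size=1, max_size=3, unique_by=lambda s: s[0]))
    def test_boundedness_over_random_protocols(self, segments):
        """v stays in [0, 1] and a in (0, 1] for arbitrary valid drives."""
        params = NetworkParams()
        topology = NetworkTopology()
        protocol = StimulusProtocol(segments=tuple(
            StimulusSegment(n, v, float(on), float(off))
            for n, v, on, off in segments))
        drive = protocol.drive_matrix(params, topology)
        state = rest_state()
        lo_v, hi_v, lo_a = 0.0, 0.0, 1.0
        gains = GainProfile.neutral()
        for t in range(params.n_steps):
            state = step_network(state, drive[t], gains, params, topology)
            lo_v = min(lo_v, state["v_s"].min(), state["v_p"].min())
            hi_v = max(hi_v, state["v_s"].max(), state["v_p"].max())
            lo_a = min(lo_a, state["a_s"].min(), state["a_p"].min())
        assert lo_v >= -1e-12 and hi_v <= 1.0 + 1e-12
        assert 0.0 < lo_a <= 1.0


class TestPeakMeasures:
    def test_monotone_series_peaks_at_end(self):
        assert peak_latency(np.linspace(0, 1, 11)) == 10.0

    def test_unique_maximum(self):
        w = np.zeros(400)
        w[200] = 1.0
        assert peak_latency(w) == 200.0

    def test_plateau_takes_earliest(self):
        w = np.array([0.0, 1.0, 1.0, 1.0, 0.5])
        assert peak_latency(w) == 1.0

    def test_zero_waveform_flagged(self):
        assert peak_latency(np.zeros(10)) is None
        assert peak_window_mean(np.zeros(10)) is None

    def test_empty_waveform_raises(self):
        with pytest.raises(ValueError):
            peak_latency(np.array([]))

    def test_constant_waveform_mean(self):
        w = np.full(100, 0.37)
        assert peak_window_mean(w) == pytest.approx(0.37)

    def test_triangular_window_arithmetic(self):
        # peak at t=50 with slope 0.01/ms either side; the 25-ms window
        # holds t = 38..62, mean = 0.5 - 0.01 * mean(|t-50|)
        t = np.arange(101, dtype=float)
        w = 0.5 - 0.01 * np.abs(t - 50)
        offsets = np.abs(np.arange(38, 63) - 50)
        expected = 0.5 - 0.01 * offsets.mean()
        assert peak_window_mean(w) == pytest.approx(expected)

    def test_window_wider_than_series(self):
        w = np.array([0.1, 0.5, 0.3])
        assert peak_window_mean(w, width_ms=100.0) == pytest.approx(w.mean())

    def test_step_size_scales_latency(self):
        w = np.zeros(50)
        w[20] = 1.0
        assert peak_latency(w, step_size=2.0) == 40.0
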