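"""Single-cell integration contract: kernels, spiking, LTP, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hippogamma.cell_model import (
    CellClass,
    CellClassName,
    CellState,
    SynapseKind,
    SynapseSpec,
    deliver_spike,
    ltp_update,
    psp_kernel_peak_time,
    step_cell,
)

REST = -70.0


def make_class(**over):
    params = dict(
        name=CellClassName.granule,
        resting_potential=REST,
        threshold=-54.0,
        refractory=10.0,
        leak_rate=0.25,
        compartment_coupling=0.6,
    )
    params.update(over)
    return CellClass(**params)


def make_state(weights=None):
    w = np.zeros(16)
    if weights:
        for sid, val in weights.items():
            w[sid - 1] = val
    return CellState(np.full(16, REST), w)


def syn(sid=1, kind=SynapseKind.AMPA, weight=1.0, wmax=50.0, plastic=False,
        rise=2.0, decay=10.0):
    return SynapseSpec(sid, kind, weight, wmax, plastic, rise, decay)


def run_cell(cls, synapses, events, n_steps, state=None):
    """Drive one cell; ``events`` maps step -> set of synapse ids."""
    state = state or make_state(
        {s.synapse_id: s.weight for s in synapses}
    )
    spikes, trace = [], []
    for k in range(n_steps):
        state, fired = step_cell(state, cls, synapses, events.get(k, ()), float(k))
        if fired:
            spikes.append(k)
        trace.append(state.compartment_potentials[0])
    return state, spikes, np.asarray(trace)


class TestStepCell:
    def test_rest_is_fixed_point(self):
        cls = make_class()
        state = make_state({1: 1.0})
        new, fired = step_cell(state, cls, [syn()], set(), 0.0)
        assert not fired
        np.testing.assert_allclose(new.compartment_potentials, REST)

    def test_strong_epsp_fires_exactly_once(self):
        # weight chosen so the somatic PSP peak just clears threshold - rest
        spec = syn(weight=30.0)
        cls = make_class()
        horizon = int(spec.psp_rise + 5 * spec.psp_decay)
        _, spikes, _ = run_cell(cls, [spec], {0: {1}}, horizon + 5)
        assert len(spikes) == 1
        assert spikes[0] <= horizon

    def test_subthreshold_peak_matches_direct_summation(self):
        # oracle: scalar recursion of the same discrete system, written out
        # independently of the vectorised integrator
        spec = syn(weight=3.0)
        cls = make_class(compartment_coupling=0.5)
        _, spikes, trace = run_cell(cls, [spec], {0: {1}}, 60)
        assert not spikes
        # brute force: 16-compartment explicit loop
        from hippogamma.cell_model import COMPARTMENT_PARENT, _kernel_norm

        v = np.full(16, REST)
        a = b = 0.0
        norm = float(_kernel_norm(np.array(spec.psp_rise), np.array(spec.psp_decay)))
        adj = np.zeros((16, 16))
        for child, parent in enumerate(COMPARTMENT_PARENT, start=1):
            adj[child, parent] = adj[parent, child] = 1.0
        avg = adj / adj.sum(axis=1, keepdims=True)
        expected = []
        for k in range(60):
            if k == 0:  # delivery precedes the per-step kernel decay
                a += spec.weight
                b += spec.weight
            a *= np.exp(-1.0 / spec.psp_decay)
            b *= np.exp(-1.0 / spec.psp_rise)
            drive = norm * (a - b)
            v = REST + (v - REST) * np.exp(-cls.leak_rate)
            v = v + cls.compartment_coupling * (avg @ v - v)
            v[1] += drive  # synapse 1 contacts compartment 1
            expected.append(v[0])
        np.testing.assert_allclose(trace, expected, atol=1e-9)

    def test_unknown_synapse_id_rejected(self):
        cls = make_class()
        with pytest.raises(KeyError):
            step_cell(make_state(), cls, [syn()], {17}, 0.0)

    def test_non_finite_state_rejected(self):
        cls = make_class()
        bad = make_state()
        bad.compartment_potentials[3] = np.nan
        with pytest.raises(FloatingPointError):
            step_cell(bad, cls, [syn()], set(), 0.0)

    def test_refractoriness(self):
        # continuous strong drive: inter-spike intervals >= refractory
        spec = syn(weight=30.0)
        cls = make_class(refractory=7.0)
        events = {k: {1} for k in range(0, 200, 5)}
        _, spikes, _ = run_cell(cls, [spec], events, 200)
        assert len(spikes) >= 3
        assert np.diff(spikes).min() >= cls.refractory

    def test_determinism(self):
        spec = syn(weight=25.0)
        cls = make_class()
        events = {k: {1} for k in range(0, 150, 17)}
        out1 = run_cell(cls, [spec], events, 150)
        out2 = run_cell(cls, [spec], events, 150)
        assert out1[1] == out2[1]
        np.testing.assert_array_equal(out1[2], out2[2])

    @given(scale=st.floats(min_value=1.0, max_value=3.0))
    @settings(max_examples=10, deadline=None)
    def test_monotone_drive(self, scale):
        """Scaling excitatory weights up never lowers the spike count."""
        cls = make_class()
        events = {k: {1, 2} for k in range(0, 300, 11)}
        base = [syn(1, weight=8.0), syn(2, weight=8.0)]
        boosted = [syn(1, weight=8.0 * scale), syn(2, weight=8.0 * scale)]
        _, s0, _ = run_cell(cls, base, events, 300)
        _, s1, _ = run_cell(cls, boosted, events, 300)
        assert len(s1) >= len(s0)

    def test_inhibition_lowers_potential(self):
        cls = make_class()
        gaba = syn(14, kind=SynapseKind.GABA, weight=5.0)
        _, spikes, trace = run_cell(cls, [gaba], {0: {14}}, 40)
        assert not spikes
        assert trace.min() < REST


class TestLTP:
    def test_no_presynaptic_spike_no_change(self):
        spec = syn(weight=1.0, wmax=2.0, plastic=True)
        state = make_state({1: 1.0})
        new = ltp_update(state, spec, pre_spike=False, t=0.0)
        assert new.synapse_weights[0] == 1.0

    def test_nmda_block_at_rest(self):
        spec = syn(weight=1.0, wmax=2.0, plastic=True)
        state = make_state({1: 1.0})
        new = ltp_update(state, spec, pre_spike=True, t=0.0)
        assert new.synapse_weights[0] == 1.0

    @pytest.mark.parametrize("n", [1, 4, 20])
    def test_coincidence_counting(self, n):
        # expected value from the arithmetic recursion, computed in the test
        w0, dw_frac, wmax = 0.5, 0.05, 1.0
        spec = SynapseSpec(1, SynapseKind.AMPA, w0, wmax, True, 2.0, 10.0)
        state = make_state({1: w0})
        state.compartment_potentials[spec.compartment] = REST + 15.0
        for _ in range(n):
            state = ltp_update(state, spec, True, 0.0, increment_frac=dw_frac)
        assert state.synapse_weights[0] == pytest.approx(
            min(w0 + dw_frac * wmax * n, wmax)
        )

    def test_non_plastic_rejected(self):
        spec = syn(plastic=False)
        with pytest.raises(ValueError):
            ltp_update(make_state(), spec, True, 0.0)

    def test_weights_bounded_under_heavy_drive(self):
        """Engine-level weight boundedness: saturates at weight_max."""
        spec = syn(weight=10.0, wmax=20.0, plastic=True)
        cls = make_class()
        events = {k: {1} for k in range(0, 400, 3)}
        state, _, _ = run_cell(cls, [spec], events, 400)
        assert state.synapse_weights[0] <= spec.weight_max + 1e-12
        assert state.synapse_weights[0] > spec.weight  # LTP happened


class TestDeliverSpike:
    def test_zero_weight_zero_amplitude(self):
        assert deliver_spike(syn(weight=0.0), 1.0).amplitude == 0.0

    def test_linear_in_weight_and_signed(self):
        assert deliver_spike(syn(weight=2.5), 0.0).amplitude == 2.5
        gaba = syn(14, kind=SynapseKind.GABA, weight=2.5)
        assert deliver_spike(gaba, 0.0).amplitude == -2.5

    def test_superposition_of_two_events(self):
        """Two deliveries on one synapse superpose additively (subthreshold)."""
        spec = syn(weight=2.0)
        cls = make_class()
        _, _, tr_both = run_cell(cls, [spec], {0: {1}, 5: {1}}, 50)
        _, _, tr_a = run_cell(cls, [spec], {0: {1}}, 50)
        _, _, tr_b = run_cell(cls, [spec], {5: {1}}, 50)
        np.testing.assert_allclose(
            tr_both - REST, (tr_a - REST) + (tr_b - REST), atol=1e-9
        )


def test_kernel_peak_time_monotone():
    assert psp_kernel_peak_time(2.0, 10.0) < psp_kernel_peak_time(5.0, 50.0)


def test_invalid_class_parameters_rejected():
    with pytest.raises(ValueError):
        make_class(threshold=-80.0)
    with pytest.raises(ValueError):
        make_class(leak_rate=0.0)
    with pytest.raises(ValueError):
        SynapseSpec(1, SynapseKind.GABA, 1.0, 2.0, True, 2.0, 20.0)  # plastic GABA
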