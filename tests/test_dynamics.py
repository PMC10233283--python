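"""Single-cell and whole-network dynamics contracts.

The deep check is equivalence of the fused vectorized engine with an
independent per-cell scalar reference on a three-area micro-network.
"""

import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp

from fastmapnet import (
    CellState,
    GlobalInhibitionParams,
    NeuronParams,
    step_excitatory,
    step_global_inhibition,
    step_inhibitory,
    total_input,
)
from oracles import ScalarNetworkReference


@pytest.fixture()
def params() -> NeuronParams:
    return NeuronParams()


class TestExcitatoryCell:
    def test_resting_state_is_fixed_point(self, params):
        cell = CellState()
        for _ in range(20):
            cell = step_excitatory(cell, 0.0, params)
        assert cell.V == 0.0 and cell.O == 0.0 and cell.omega_A == 0.0

    def test_no_adaptation_limit_fires_every_step(self, params):
        p = dataclasses.replace(params, alpha=0.0)
        cell = CellState()
        fired = []
        for _ in range(30):
            cell = step_excitatory(cell, 100.0, p)  # V -> k1*100 = 1.0 >> thresh
            fired.append(cell.O)
        # once V crosses threshold the cell fires on every subsequent step
        first = fired.index(1.0)
        assert all(o == 1.0 for o in fired[first:])

    def test_trace_matches_scalar_recurrence_and_isis_lengthen(self, params):
        """50 steps of constant input: exact trace vs an independently coded
        recurrence; adaptation stretches the inter-spike intervals."""
        inp = 60.0
        cell = CellState()
        trace = []
        for _ in range(50):
            cell = step_excitatory(cell, inp, params)
            trace.append((cell.V, cell.O, cell.omega_A, cell.omega_E))
        # independent recurrence
        V = oA = oE = 0.0
        spikes = []
        for t in range(50):
            V = V + (1.0 / params.tau_exc) * (-V + params.k1 * inp)
            O = 1.0 if V - params.alpha * oA >= params.thresh else 0.0
            oA = oA + (1.0 / params.tau_adapt) * (-oA + O)
            oE = oE + (1.0 / params.tau_favg) * (-oE + O)
            assert trace[t] == (V, O, oA, oE)
            if O:
                spikes.append(t)
        isis = np.diff(spikes)
        assert len(spikes) >= 3
        assert isis[-1] > isis[0]  # adaptation lengthens intervals

    def test_nan_input_raises(self, params):
        with pytest.raises(FloatingPointError):
            step_excitatory(CellState(), float("nan"), params)


class TestInhibitoryCell:
    def test_zero_input_stays_zero(self, params):
        cell = CellState()
        for _ in range(10):
            cell = step_inhibitory(cell, 0.0, params)
        assert cell.V == 0.0 and cell.O == 0.0

    def test_fixed_point_is_k1_scaled(self, params):
        c = 40.0
        cell = CellState()
        for _ in range(400):
            cell = step_inhibitory(cell, c, params)
        assert cell.V == pytest.approx(params.k1 * c, rel=1e-9)
        assert cell.O == pytest.approx(params.k1 * c, rel=1e-9)

    def test_step_response_matches_scalar_recurrence(self, params):
        cell = CellState()
        V = 0.0
        for _ in range(20):
            cell = step_inhibitory(cell, 25.0, params)
            V = V + (1.0 / params.tau_inh) * (-V + params.k1 * 25.0)
            assert cell.V == V
            assert cell.O == max(V, 0.0)


class TestGlobalInhibition:
    def test_decays_geometrically_without_activity(self):
        gp = GlobalInhibitionParams()
        g = 3.0
        for _ in range(5):
            g_prev = g
            g = step_global_inhibition(g, 0.0, gp)
            assert g == pytest.approx(g_prev * (1 - 1 / gp.tau_glob))

    def test_fixed_point_proportional_to_kG_and_activity(self):
        gp = GlobalInhibitionParams()
        g = 0.0
        for _ in range(800):
            g = step_global_inhibition(g, 50.0, gp)
        assert g == pytest.approx(gp.kG * gp.input_scale * 50.0, rel=1e-9)

    def test_monotone_in_kG(self):
        gp = GlobalInhibitionParams()
        acts = [30.0, 10.0, 40.0, 5.0, 20.0]
        g_hi = g_lo = 0.0
        for s in acts:
            g_hi = step_global_inhibition(g_hi, s, gp, kG=0.70)
            g_lo = step_global_inhibition(g_lo, s, gp, kG=0.50)
            assert g_lo < g_hi


class TestTotalInput:
    def test_zero_weights_no_stimulus_gives_zero_field(self, params):
        O = np.zeros((2, 25))
        w = sp.csr_matrix((25, 25))
        X = total_input([(0, 1, w)], O, None, None, None, params)
        assert not X.any()

    def test_single_synapse_contributes_exactly_its_weight(self, params):
        O = np.zeros((2, 25))
        O[0, 3] = 1.0
        w = sp.csr_matrix(([0.37], ([3], [11])), shape=(25, 25))
        X = total_input([(0, 1, w)], O, None, None, None, params)
        assert X[1, 11] == 0.37
        assert X.sum() == 0.37

    def test_three_cell_circuit_matches_hand_computation(self, params):
        # cells 0,1,2 in one area; 0->2 (w=.5), 1->2 (w=.25), 2->0 (w=1.5)
        w = sp.csr_matrix(
            ([0.5, 0.25, 1.5], ([0, 1, 2], [2, 2, 0])), shape=(25, 25)
        )
        O = np.zeros((1, 25))
        O[0, [0, 1, 2]] = 1.0
        ext = np.zeros((1, 25))
        ext[0, 1] = 2.0
        O_i = np.zeros((1, 25))
        O_i[0, 2] = 0.01
        g = np.array([0.2])
        X = total_input([(0, 0, w)], O, ext, O_i, g, params)
        ks = params.local_inhibition_strength
        assert X[0, 0] == pytest.approx(1.5 - 0.2)
        assert X[0, 1] == pytest.approx(2.0 - 0.2)
        assert X[0, 2] == pytest.approx(0.5 + 0.25 - ks * 0.01 - 0.2)

    def test_shape_mismatch_raises(self, params):
        with pytest.raises(ValueError):
            total_input(
                [(0, 1, sp.csr_matrix((9, 9)))], np.zeros((2, 25)),
                None, None, None, params,
            )


class TestNetworkDynamics:
    def test_quiescence_without_noise_or_stimulus(self, micro_net):
        for _ in range(50):
            micro_net.step(noise_on=False, learning=False)
        assert not micro_net.V_e.any()
        assert not micro_net.O_e.any()
        assert not micro_net.glob_inhib.any()

    def test_outputs_binary_and_nonnegative(self, micro_net):
        ext = np.zeros((3, 25))
        ext[0, :7] = 300.0
        for _ in range(100):
            micro_net.step(external=ext, noise_on=True, learning=False)
            assert set(np.unique(micro_net.O_e)) <= {0.0, 1.0}
            assert (micro_net.O_i >= 0.0).all()

    def test_activity_bounded_under_constant_stimulus(self, micro_net):
        """Global + local inhibition keep mean firing well below saturation."""
        ext = np.zeros((3, 25))
        ext[0, :10] = 500.0
        rates = []
        for _ in range(300):
            micro_net.step(external=ext, noise_on=True, learning=False)
            rates.append(micro_net.O_e.mean())
        assert np.mean(rates[100:]) < 0.5

    def test_vectorized_engine_bit_identical_to_scalar_reference(self, micro_net):
        """>=100 steps on the 3-area micro-network, noise off, stimulus on."""
        ref = ScalarNetworkReference(micro_net)
        ext = np.zeros((3, 25))
        ext[0, [1, 7, 13, 19]] = 200.0
        for t in range(120):
            micro_net.step(external=ext, noise_on=False, learning=False)
            ref.step(external=ext)
        assert np.array_equal(micro_net.V_e, np.array(ref.V_e))
        assert np.array_equal(micro_net.O_e, np.array(ref.O_e))
        assert np.array_equal(micro_net.omega_A, np.array(ref.oA))
        assert np.array_equal(micro_net.omega_E, np.array(ref.oE))
        assert np.array_equal(micro_net.V_i, np.array(ref.V_i))
        assert np.array_equal(micro_net.glob_inhib, np.array(ref.g))
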