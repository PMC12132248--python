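"""Unit and property tests for the circuit model right-hand side."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recflip import (
    CircuitParameters,
    CircuitTopology,
    PromoterActivities,
    SystemState,
    closed_form_fixed_point,
    hill_activation,
    ode_rhs,
    promoter_activities,
    resource_share,
)
from recflip.model import rhs_array

TOPOS = list(CircuitTopology)


class TestHillActivation:
    def test_zero_dose_is_leak(self, params):
        assert hill_activation(0.0, params) == params.leak

    def test_half_saturation_at_K_L(self, params):
        assert hill_activation(params.K_L, params) == pytest.approx(0.5, abs=1e-12)

    def test_saturation_limit(self, params):
        assert hill_activation(1e6 * params.K_L, params) == pytest.approx(1.0, abs=1e-6)

    def test_negative_dose_rejected(self, params):
        with pytest.raises(ValueError):
            hill_activation(-1e-4, params)

    @given(st.floats(0, 1e-2), st.floats(0, 1e-2))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_nondecreasing_and_bounded(self, d1, d2):
        params = CircuitParameters(leak=0.05)
        lo, hi = sorted((d1, d2))
        h_lo, h_hi = hill_activation(lo, params), hill_activation(hi, params)
        assert h_lo <= h_hi
        assert params.leak <= h_lo and h_hi < 1.0


class TestPromoterActivities:
    def test_no_flipped_promoters_no_feedforward(self, params):
        state = SystemState(P_LR=1.0)
        acts = promoter_activities(state, 5e-3, params, CircuitTopology.RE_NF_FF)
        assert acts.u_G == 1.0

    def test_feedforward_arithmetic_fully_flipped(self):
        # hill = 1 exactly is approached at saturating dose; use a huge dose
        p = CircuitParameters(beta_FF=0.8)
        acts = promoter_activities(SystemState(P_LR=0.0), 1e9 * p.K_L, p, CircuitTopology.RE_NF_FF)
        assert acts.u_G == pytest.approx(1.8, rel=1e-9)

    def test_feedforward_absent_without_ff_topology(self):
        p = CircuitParameters(beta_FF=0.8)
        acts = promoter_activities(SystemState(P_LR=0.0), 1e9 * p.K_L, p, CircuitTopology.RE_NF)
        assert acts.u_G == 1.0

    def test_rfp_tracks_orientation_fraction(self, params):
        half = promoter_activities(SystemState(P_LR=0.5), params.K_L, params, CircuitTopology.RE_NF)
        assert half.u_R == pytest.approx(0.25)  # hill(K_L)=0.5 times P_LR=0.5

    def test_integrase_off_without_recombinase_genes(self, params):
        acts = promoter_activities(SystemState(), 0.0, params, CircuitTopology.NO_CONTROLLER)
        assert acts.u_I == 0.0


class TestResourceShare:
    def test_no_competition_limit(self):
        p = CircuitParameters(w_G=0, w_R=0, w_I=0)
        assert resource_share(PromoterActivities(1, 1, 1), p) == 1.0

    def test_single_unit_load_halves_share(self):
        p = CircuitParameters(w_G=1, w_R=0, w_I=0)
        assert resource_share(PromoterActivities(1, 0, 0), p) == 0.5

    @given(st.floats(0.01, 10), st.floats(0.01, 10))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_strictly_decreasing_in_load(self, u_R, w_R):
        p = CircuitParameters(w_R=w_R)
        lo = resource_share(PromoterActivities(1, u_R, 0), p)
        hi = resource_share(PromoterActivities(1, 2 * u_R, 0), p)
        assert 0 < hi < lo <= 1


def _rand_state(rng) -> np.ndarray:
    y = rng.uniform(0, 100, 6)
    y[5] = rng.uniform(0, 1)
    return y


class TestOdeRhs:
    def test_origin_open_loop_only_constitutive_gfp(self):
        p = CircuitParameters(leak=0.0)
        d = ode_rhs(SystemState(P_LR=1.0), 0.0, p, CircuitTopology.OPEN_LOOP_MUT)
        assert d.R == 0 and d.C == 0 and d.P_LR == 0
        # excisionase synthesis needs RFP-module activity, absent at zero dose
        assert d.X == 0
        phi = 1.0 / (1.0 + p.w_G + p.w_I)
        assert d.G == pytest.approx(p.copy_gain * p.k_G * phi)
        assert d.G > 0

    def test_zero_feedback_relaxes_toward_lr(self, params):
        p = params.with_value("V_off", 0.0)
        d = ode_rhs(SystemState(I=1.0, P_LR=0.3), 1e-3, p, CircuitTopology.RE_NF)
        assert d.P_LR > 0

    def test_closed_form_fixed_point_annihilates_rhs(self, decoupled_params):
        for topo in TOPOS:
            for dose in (0.0, 6.25e-4, 5e-3):
                fp = closed_form_fixed_point(decoupled_params, topo, dose)
                d = ode_rhs(fp, dose, decoupled_params, topo).to_array()
                assert np.max(np.abs(d)) < 1e-9, (topo, dose)

    def test_nonfinite_state_rejected(self, params):
        with pytest.raises(ValueError):
            ode_rhs(SystemState(G=np.nan), 0.0, params, CircuitTopology.RE_NF)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, deadline=None, max_examples=40)
    def test_topology_reductions_bitwise_on_rhs(self, seed):
        """The variant lattice collapses exactly under the stated parameter pins."""
        rng = np.random.default_rng(seed)
        y = _rand_state(rng)
        dose = rng.uniform(0, 5e-3)
        p = CircuitParameters(beta_FF=rng.uniform(0, 2))

        # feedforward off == plain negative feedback
        lhs = rhs_array(y, dose, p.with_value("beta_FF", 0.0), CircuitTopology.RE_NF_FF)
        rhs = rhs_array(y, dose, p, CircuitTopology.RE_NF)
        np.testing.assert_array_equal(lhs, rhs)

        # flip rates zeroed == flip-disabled mutant (orientation pinned)
        p0 = dataclasses.replace(p, V_on=0.0, V_off=0.0)
        lhs = rhs_array(y, dose, p0, CircuitTopology.RE_NF)
        rhs = rhs_array(y, dose, p0, CircuitTopology.OPEN_LOOP_MUT)
        np.testing.assert_array_equal(lhs, rhs)

        # recombinase synthesis and weight zeroed == no-controller reference
        p00 = dataclasses.replace(p0, k_X=0.0, k_I=0.0, w_I=0.0)
        lhs = rhs_array(y, dose, p00, CircuitTopology.OPEN_LOOP_MUT)
        rhs = rhs_array(y, dose, p00, CircuitTopology.NO_CONTROLLER)
        np.testing.assert_array_equal(lhs, rhs)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, deadline=None, max_examples=40)
    def test_vector_field_points_into_invariant_box(self, seed):
        """Each derivative is >= 0 on its species' zero boundary; the
        orientation fraction cannot exit [0, 1]."""
        rng = np.random.default_rng(seed)
        dose = rng.uniform(0, 5e-3)
        p = CircuitParameters()
        for topo in TOPOS:
            for i in range(5):
                y = _rand_state(rng)
                y[i] = 0.0
                d = rhs_array(y, dose, p, topo)
                assert d[i] >= 0, (topo, i)
            y = _rand_state(rng)
            y[5] = 0.0
            assert rhs_array(y, dose, p, topo)[5] >= 0
            y[5] = 1.0
            y[2] = y[3] = y[4] = 0.0  # no integrase: nothing pushes past LR
            assert rhs_array(y, dose, p, topo)[5] <= 0


class TestParametersAndState:
    def test_round_trip_dict(self, params):
        assert CircuitParameters.from_dict(params.to_dict()) == params

    def test_unknown_field_rejected(self, params):
        with pytest.raises(ValueError):
            params.with_value("not_a_field", 1.0)
        with pytest.raises(ValueError):
            CircuitParameters.from_dict({"bogus": 1.0})

    @pytest.mark.parametrize(
        "bad",
        [
            {"d_G": 0.0},
            {"n_H": 0.5},
            {"leak": 1.0},
            {"copy_gain": 0.0},
            {"k_G": -1.0},
            {"K_L": float("nan")},
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            CircuitParameters(**bad)

    def test_state_invariants_enforced(self):
        with pytest.raises(ValueError):
            SystemState(G=-1.0).validate()
        with pytest.raises(ValueError):
            SystemState(P_LR=1.5).validate()

    def test_digest_distinguishes_parameterizations(self, params):
        assert params.digest != params.with_value("V_off", 0.1).digest
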