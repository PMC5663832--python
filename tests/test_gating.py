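"""Rate expressions, scheme topology and master-equation integration."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from iklgate import (
    N_STATES,
    OPEN_MASK,
    STATE_LABELS,
    RateParameters,
    SchemeVariant,
    SimulationSettings,
    build_generator,
    build_scheme,
    horizontal_rates,
    open_probability,
    propagate,
    steady_state,
)
from iklgate.gating import exact_propagator, propagator_matrix

IDX = {s: i for i, s in enumerate(STATE_LABELS)}


class TestHorizontalRates:
    def test_printed_values_at_zero_mv(self, params):
        alpha, beta = horizontal_rates(0.0, params)
        assert alpha == pytest.approx(0.99)
        assert beta == pytest.approx(1.57e-6)

    def test_one_efold_per_k_alpha(self, params):
        alpha, _ = horizontal_rates(12.67, params)
        assert alpha == pytest.approx(0.99 * np.e, rel=1e-12)

    def test_against_direct_evaluation(self, params):
        # frozen from independent scalar evaluation of the rate expressions
        alpha, beta = horizontal_rates(-64.0, params)
        assert alpha == pytest.approx(0.006336982154500224, rel=1e-12)
        assert beta == pytest.approx(0.0002452744795716696, rel=1e-12)

    def test_monotonicity(self, params):
        vs = np.linspace(-150, 60, 40)
        alphas, betas = zip(*(horizontal_rates(v, params) for v in vs))
        assert np.all(np.diff(alphas) > 0)
        assert np.all(np.diff(betas) < 0)

    def test_overflow_guard(self, params):
        with pytest.raises(ValueError):
            horizontal_rates(501.0, params)


class TestSchemeTopology:
    @pytest.mark.parametrize("variant", list(SchemeVariant))
    def test_ten_states_and_paired_edges(self, variant):
        scheme = build_scheme(RateParameters(variant=variant))
        assert len(scheme.states) == N_STATES
        index = scheme.edge_index()
        assert all((j, i) in index for i, j in index)

    def test_final_opening_rate_is_voltage_independent(self, final_rung_scheme):
        for v in (-134.0, -104.0, -64.0, -44.0):
            q = build_generator(final_rung_scheme, v)
            assert q[IDX["C4"], IDX["O4"]] == pytest.approx(4.25)
            assert q[IDX["O4"], IDX["C4"]] == pytest.approx(0.38)

    def test_vertical_rates_identical_across_voltages(self, scheme):
        qa = build_generator(scheme, -104.0)
        qb = build_generator(scheme, -44.0)
        for i in range(5):
            assert qa[i, i + 5] == pytest.approx(qb[i, i + 5])
            assert qa[i + 5, i] == pytest.approx(qb[i + 5, i])

    def test_statistical_factor_on_first_closed_transition(self):
        scheme = build_scheme(RateParameters(variant=SchemeVariant.FINAL_RUNG))
        alpha, _ = horizontal_rates(-64.0, scheme.params)
        q = build_generator(scheme, -64.0)
        assert q[IDX["C0"], IDX["C1"]] == pytest.approx(4 * alpha, rel=1e-12)

    def test_multiplicity_flag_off(self):
        scheme = build_scheme(
            RateParameters(variant=SchemeVariant.FINAL_RUNG,
                           closed_chain_multiplicity=False))
        alpha, _ = horizontal_rates(-64.0, scheme.params)
        q = build_generator(scheme, -64.0)
        assert q[IDX["C0"], IDX["C1"]] == pytest.approx(alpha, rel=1e-12)

    def test_microscopic_reversibility_of_allosteric_ladder(self, scheme):
        # every 4-cycle C_i, C_{i+1}, O_{i+1}, O_i within the allosteric
        # ladder (rungs 0..3): clockwise and counter-clockwise rate products
        # agree; the final rung is deliberately outside the ladder
        q = build_generator(scheme, -74.0)
        for i in range(3):
            cw = (q[i, i + 1] * q[i + 1, i + 6] * q[i + 6, i + 5]
                  * q[i + 5, i])
            ccw = (q[i, i + 5] * q[i + 5, i + 6] * q[i + 6, i + 1]
                   * q[i + 1, i])
            assert cw == pytest.approx(ccw, rel=1e-12)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            RateParameters(variant="ring")

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            RateParameters(alpha0=0.0)


class TestGenerator:
    @given(v=st.floats(min_value=-150, max_value=60))
    @hyp_settings(max_examples=40, deadline=None, derandomize=True)
    def test_rows_sum_to_zero_and_offdiag_nonnegative(self, v):
        scheme = build_scheme(RateParameters())
        q = build_generator(scheme, v)
        assert np.max(np.abs(q.sum(axis=1))) < 1e-12 * max(1.0, np.abs(q).max())
        off = q[~np.eye(N_STATES, dtype=bool)]
        assert np.all(off >= 0)


class TestPropagation:
    def test_probability_conservation_with_renormalization(self, scheme):
        p0 = steady_state(scheme, -134.0)
        traj = propagate(p0, scheme, -64.0, 500.0)
        assert np.max(np.abs(traj.sum(axis=1) - 1.0)) < 1e-9

    def test_bounded_drift_without_renormalization(self, scheme):
        p0 = steady_state(scheme, -134.0)
        traj = propagate(
            p0, scheme, -64.0, 1000.0,
            SimulationSettings(renormalize_each_step=False))
        assert np.max(np.abs(traj.sum(axis=1) - 1.0)) < 1e-4

    def test_matches_matrix_exponential(self, scheme):
        p0 = steady_state(scheme, -134.0)
        exact = p0 @ exact_propagator(scheme, -64.0, 1000.0)
        errs = []
        for dt in (0.1, 0.05, 0.025):
            traj = propagate(p0, scheme, -64.0, 1000.0, SimulationSettings(dt=dt))
            errs.append(np.abs(traj[-1] - exact).max())
        assert errs[0] < 1e-3
        assert errs[0] > errs[1] > errs[2]  # halving dt improves the error

    def test_short_window_matches_matrix_exponential_per_state(self, scheme):
        p0 = steady_state(scheme, -134.0)
        traj = propagate(p0, scheme, -64.0, 10.0)
        exact = p0 @ exact_propagator(scheme, -64.0, 10.0)
        assert np.abs(traj[-1] - exact).max() < 1e-3

    def test_step_size_independence(self, scheme):
        p0 = steady_state(scheme, -134.0)
        end_a = propagate(p0, scheme, -64.0, 1000.0, SimulationSettings(dt=0.1))[-1]
        end_b = propagate(p0, scheme, -64.0, 1000.0, SimulationSettings(dt=0.05))[-1]
        assert np.abs(end_a - end_b).max() < 1e-3

    def test_still_rising_after_one_second_at_minus_84(self, scheme):
        # weak depolarization: channels have not equilibrated within 1 s
        p0 = steady_state(scheme, -104.0)
        traj = propagate(p0, scheme, -84.0, 1000.0)
        po = traj[:, OPEN_MASK].sum(axis=1)
        assert po[-1] > po[-1001]  # open fraction still increasing at 1 s

    def test_substepping_keeps_strong_depolarization_stable(self, scheme):
        p0 = steady_state(scheme, -64.0)
        traj = propagate(p0, scheme, 16.0, 50.0)
        assert np.all(traj >= -1e-12)
        assert np.max(np.abs(traj.sum(axis=1) - 1.0)) < 1e-9

    def test_unnormalized_initial_rejected(self, scheme):
        with pytest.raises(ValueError):
            propagate(np.full(N_STATES, 0.2), scheme, -64.0, 1.0)


class TestSteadyState:
    def test_fixed_point_of_propagation(self, scheme):
        ss = steady_state(scheme, -64.0)
        traj = propagate(ss, scheme, -64.0, 100.0)
        assert np.abs(traj[-1] - ss).max() < 1e-8

    def test_equals_long_time_limit(self, scheme):
        p0 = steady_state(scheme, -134.0)
        traj = propagate(p0, scheme, -64.0, 10_000.0)
        assert np.abs(traj[-1] - steady_state(scheme, -64.0)).max() < 1e-6

    def test_final_rung_equilibrium_ratio(self, final_rung_scheme):
        # at -64 mV occupancy concentrates on C4/O4 with O4:C4 = a:b
        ss = steady_state(final_rung_scheme, -64.0)
        assert ss[IDX["C4"]] + ss[IDX["O4"]] > 0.95
        assert ss[IDX["O4"]] / ss[IDX["C4"]] == pytest.approx(4.25 / 0.38, rel=1e-6)

    def test_ninety_percent_open_at_minus_64(self, scheme):
        ss = steady_state(scheme, -64.0)
        assert ss[IDX["O4"]] == pytest.approx(0.90, abs=0.03)
        closed_rest = ss[:5].sum()
        assert ss[IDX["C4"]] > 0.8 * closed_rest

    def test_open_fraction_monotone_in_voltage(self, scheme):
        vs = np.arange(-120.0, -39.0, 5.0)
        po = [open_probability(steady_state(scheme, v)) for v in vs]
        assert np.all(np.diff(po) >= -1e-12)


class TestOpenProbability:
    def test_pure_states(self, scheme):
        p = np.zeros(N_STATES)
        p[IDX["C0"]] = 1.0
        assert open_probability(p, scheme) == 0.0
        p = np.zeros(N_STATES)
        p[IDX["O4"]] = 1.0
        assert open_probability(p, scheme) == 1.0

    def test_matches_null_space_oracle(self, scheme):
        ss = steady_state(scheme, -64.0)
        assert open_probability(ss, scheme) == pytest.approx(ss[5:].sum())


def test_propagator_matrix_substeps_match_plain_euler():
    # composing n equal Euler sub-steps equals the matrix power exactly
    scheme = build_scheme(RateParameters())
    q = build_generator(scheme, 16.0)
    m = propagator_matrix(q, 0.1, stability=0.5)
    rate = -q.diagonal().min()
    n_sub = int(np.ceil(0.1 * rate / 0.5))
    expected = np.linalg.matrix_power(np.eye(N_STATES) + (0.1 / n_sub) * q, n_sub)
    assert np.allclose(m, expected, atol=0, rtol=1e-15)
    assert n_sub > 1
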