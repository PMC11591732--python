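"""Markov gating schemes: generators, stationary laws, count sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from crucell.gating import (LCCParams, RyRParams, lcc_rate_matrix,
                            ryr_open_rate, ryr_rate_matrix, sample_transitions,
                            stationary_distribution, LCC_OPEN, RYR_OPEN)
from crucell._engine import simulate_cluster_path


class TestRyRMatrix:
    def test_zero_calcium_blocks_opening(self):
        q = ryr_rate_matrix(0.0, RyRParams())
        assert q[0, 1] == 0.0
        assert q[1, 0] > 0 and q[1, 2] > 0 and q[2, 0] > 0

    def test_rows_sum_to_zero_and_offdiag_nonneg(self):
        q = ryr_rate_matrix(25.0, RyRParams())
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        off = q[~np.eye(3, dtype=bool)]
        assert (off >= 0).all()

    def test_sensitivity_scale_multiplies_opening_exactly(self):
        """Raising kryr+ from 14 to 21 scales the C->O rate by exactly 1.5."""
        base = RyRParams(k_plus_scale=14.0)
        hyper = RyRParams(k_plus_scale=21.0)
        for ca in (0.1, 1.0, 15.0, 300.0):
            assert ryr_open_rate(ca, hyper) == pytest.approx(
                1.5 * ryr_open_rate(ca, base), rel=1e-12)

    def test_opening_rate_monotone_in_calcium(self):
        p = RyRParams()
        rates = [ryr_open_rate(ca, p) for ca in np.linspace(0, 500, 200)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            ryr_rate_matrix(-1.0, RyRParams())


class TestLCCMatrix:
    def test_structure_and_row_sums(self):
        q = lcc_rate_matrix(0.0, 5.0, LCCParams())
        assert q.shape == (6, 6)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_deep_hyperpolarization_closes_channel(self):
        """Stationary open probability at -90 mV is below 1e-3."""
        q = lcc_rate_matrix(-90.0, 0.1, LCCParams())
        pi = stationary_distribution(q)
        assert pi[LCC_OPEN] < 1e-3

    def test_zero_gamma_confines_to_normal_mode(self):
        q = lcc_rate_matrix(0.0, 0.0, LCCParams())
        # no entry into the Ca mode from a normal-mode start
        assert np.all(q[:3, 3:] == 0.0)

    def test_ca_mode_entry_linear_in_calcium(self):
        p = LCCParams()
        q1 = lcc_rate_matrix(-20.0, 10.0, p)
        q2 = lcc_rate_matrix(-20.0, 20.0, p)
        for i in range(3):
            assert q2[i, i + 3] == pytest.approx(2.0 * q1[i, i + 3])

    def test_activation_rates_monotone_in_voltage(self):
        p = LCCParams()
        alphas = [p.activation_rates(v)[0] for v in np.linspace(-90, 60, 100)]
        assert all(b >= a for a, b in zip(alphas, alphas[1:]))


class TestStationaryDistribution:
    def test_two_state_symmetric(self):
        q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        assert np.allclose(stationary_distribution(q), [0.5, 0.5])

    def test_cyclic_three_state_matches_flux_balance(self):
        # unidirectional cycle with rates (1, 2, 4): pi_i proportional to the
        # mean dwell time 1/rate_i -> (4/7, 2/7, 1/7)
        q = np.array([[-1.0, 1.0, 0.0],
                      [0.0, -2.0, 2.0],
                      [4.0, 0.0, -4.0]])
        assert np.allclose(stationary_distribution(q), [4 / 7, 2 / 7, 1 / 7])

    def test_reducible_chain_rejected(self):
        q = np.zeros((2, 2))
        with pytest.raises(ValueError):
            stationary_distribution(q)

    def test_long_path_occupancy_matches_stationary(self):
        """Kernel-path time-average equals the stationary law within 3 SE."""
        params = RyRParams()
        ca = 40.0
        q = ryr_rate_matrix(ca, params)
        pi = stationary_distribution(q)
        dt, n_steps = 0.05, 400_000
        occ = simulate_cluster_path(q, np.array([49.0, 0.0, 0.0]), dt,
                                    n_steps, seed=7)
        # effective number of independent samples ~ T / correlation time
        t_total = dt * n_steps
        tau = 1.0 / min(-q[i, i] for i in range(3) if q[i, i] < 0)
        n_eff = 49 * t_total / (2.0 * tau)
        for k in range(3):
            se = np.sqrt(max(pi[k] * (1 - pi[k]), 1e-12) / n_eff)
            assert abs(occ[k] - pi[k]) < 3 * se + 1e-4


class TestSampleTransitions:
    def test_zero_generator_is_identity(self, rng):
        counts = np.array([10, 5, 34])
        out = sample_transitions(counts, np.zeros((3, 3)), 0.1, rng)
        assert (out == counts).all()

    def test_step_contract_enforced(self, rng):
        q = ryr_rate_matrix(500.0, RyRParams())
        dt_bad = 0.3 / max(-np.diag(q))
        with pytest.raises(ValueError, match="substep"):
            sample_transitions(np.array([49, 0, 0]), q, dt_bad * 2, rng)

    @given(seed=st.integers(0, 2**31 - 1), ca=st.floats(0.0, 400.0),
           dt=st.floats(0.001, 0.05))
    @settings(max_examples=50, deadline=None)
    def test_channel_number_conserved(self, seed, ca, dt):
        rng = np.random.default_rng(seed)
        q = ryr_rate_matrix(ca, RyRParams())
        counts = np.array([30, 10, 9])
        if dt * max(-np.diag(q)) > 0.2:
            return
        out = sample_transitions(counts, q, dt, rng)
        assert out.sum() == counts.sum()
        assert (out >= 0).all()

    def test_single_step_mean_matches_master_equation(self, rng):
        """Mean occupancy after one step agrees with expm(Q dt) within 3 SE."""
        params = RyRParams()
        q = ryr_rate_matrix(30.0, params)
        dt = 0.1
        counts0 = np.array([40, 6, 3])
        p0 = counts0 / counts0.sum()
        expected = counts0.sum() * (p0 @ expm(q * dt))
        n_rep = 10_000
        acc = np.zeros(3)
        for _ in range(n_rep):
            acc += sample_transitions(counts0, q, dt, rng)
        mean = acc / n_rep
        for k in range(3):
            se = np.sqrt(counts0.sum() * 0.25 / n_rep) + 1e-9
            assert abs(mean[k] - expected[k]) < 3 * se + 0.05
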