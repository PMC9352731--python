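"""Unit and property tests for the connection-strength chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinedrift.chain import (
    ChainSpec,
    SpecValidationError,
    asymptotic_variance,
    build_transition_matrix,
    evolve_distribution,
    first_passage_times,
    fundamental_matrix,
    simulate_connections,
    spectral_summary,
    state_lifetimes,
    verify_equilibrium,
)

# ---------------------------------------------------------------------------
# hypothesis strategy: arbitrary valid chain specs
# ---------------------------------------------------------------------------

@st.composite
def chain_specs(draw):
    S = draw(st.integers(min_value=2, max_value=8))
    raw = draw(
        st.lists(st.floats(min_value=0.05, max_value=1.0), min_size=S, max_size=S)
    )
    x = np.asarray(raw) / np.sum(raw)
    y_raw = np.asarray(
        draw(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=S - 1, max_size=S - 1))
    )
    # scale y so every row's off-diagonal mass stays below 0.9
    up = np.concatenate([x[1:] * y_raw, [0.0]])
    down = np.concatenate([[0.0], x[:-1] * y_raw])
    worst = np.max(up + down)
    y = y_raw * min(1.0, 0.9 / worst)
    return ChainSpec(x=x, y=y)


# ---------------------------------------------------------------------------
# construction and stationarity
# ---------------------------------------------------------------------------

class TestBuildTransitionMatrix:
    def test_three_state_example(self, spec3):
        P = build_transition_matrix(spec3)
        expected = np.array(
            [[0.94, 0.06, 0.0], [0.10, 0.88, 0.02], [0.0, 0.03, 0.97]]
        )
        np.testing.assert_allclose(P, expected, atol=1e-15)

    def test_two_state_example(self, spec2):
        P = build_transition_matrix(spec2)
        np.testing.assert_allclose(P, [[0.9, 0.1], [0.1, 0.9]], atol=1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(chain_specs())
    def test_invariants_for_arbitrary_specs(self, spec):
        P = build_transition_matrix(spec)
        x = spec.x_arr
        # tridiagonal, stochastic, entries in [0,1]
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((P >= 0) & (P <= 1))
        assert np.allclose(P, np.triu(np.tril(P, 1), -1))
        # detailed balance as an exact product identity
        i = np.arange(spec.S - 1)
        np.testing.assert_allclose(
            x[i] * P[i, i + 1], x[i + 1] * P[i + 1, i], atol=1e-14
        )
        # stationarity
        assert verify_equilibrium(spec, P) <= 1e-12

    def test_rejects_invalid_specs(self):
        with pytest.raises(SpecValidationError):
            ChainSpec(x=(0.5, 0.6), y=(0.1,))  # x does not sum to 1
        with pytest.raises(SpecValidationError):
            ChainSpec(x=(0.5, 0.3, 0.2), y=(0.2,))  # wrong y length
        with pytest.raises(SpecValidationError, match="row"):
            # middle row off-diagonal mass 0.45*1.4 + 0.45*1.4 > 1
            ChainSpec(x=(0.45, 0.10, 0.45), y=(1.4, 1.4))

    def test_spec_roundtrip_json_yaml(self, tmp_path, spec3):
        for name in ("s.json", "s.yaml"):
            p = tmp_path / name
            spec3.save(p)
            back = ChainSpec.load(p)
            assert back == spec3


class TestVerifyEquilibrium:
    def test_constructed_matrices_are_stationary(self, spec3, spec2):
        for spec in (spec3, spec2):
            assert verify_equilibrium(spec, build_transition_matrix(spec)) <= 1e-12

    def test_perturbed_matrix_has_large_residual(self, spec3):
        P = build_transition_matrix(spec3).copy()
        P[0, 1] += 0.01
        P[0, 0] -= 0.01
        assert verify_equilibrium(spec3, P) > 1e-3

    def test_dimension_mismatch(self, spec3):
        with pytest.raises(ValueError):
            verify_equilibrium(spec3, np.eye(4))


# ---------------------------------------------------------------------------
# lifetimes
# ---------------------------------------------------------------------------

class TestStateLifetimes:
    def test_worked_lifetimes(self, spec3, spec2):
        np.testing.assert_allclose(
            state_lifetimes(build_transition_matrix(spec3)),
            [1 / 0.06, 1 / 0.12, 1 / 0.03],
        )
        np.testing.assert_allclose(
            state_lifetimes(build_transition_matrix(spec2)), [10.0, 10.0]
        )

    def test_top_state_ten_thousand_days(self):
        # x_{S-1}=0.02, y_{S-1}=0.005: reversion probability 1/10,000/day
        spec = ChainSpec(x=(0.60, 0.24, 0.10, 0.02, 0.04), y=(0.2, 0.1, 0.02, 0.005))
        life = state_lifetimes(build_transition_matrix(spec))
        assert life[-1] == pytest.approx(10_000, rel=1e-12)

    def test_absorbing_state_reports_infinity(self):
        P = np.array([[1.0, 0.0], [0.5, 0.5]])
        life = state_lifetimes(P)
        assert np.isinf(life[0]) and life[1] == 2.0

    def test_monotone_plasticity_gives_increasing_high_state_lifetimes(self, grid):
        # decreasing y: expected lifetime grows with state index above state 1
        for spec in grid:
            life = state_lifetimes(build_transition_matrix(spec))
            assert np.all(np.diff(life[1:]) > 0), spec

    def test_dwell_times_match_simulation(self, spec3, rng):
        # Monte-Carlo dwell oracle: step walkers until they leave the state
        P = build_transition_matrix(spec3)
        n = 10_000
        for state in range(3):
            stay_p = P[state, state]
            alive = np.ones(n, dtype=bool)
            dwell = np.ones(n)
            while alive.any():
                stay = rng.random(alive.sum()) < stay_p
                dwell[alive] += stay
                alive[alive] = stay
            se = dwell.std(ddof=1) / np.sqrt(n)
            assert abs(dwell.mean() - 1 / (1 - stay_p)) < 3 * se


# ---------------------------------------------------------------------------
# fundamental matrix, passage times, variances
# ---------------------------------------------------------------------------

class TestFundamentalMatrix:
    def test_two_state_closed_form(self, spec2):
        Z = fundamental_matrix(spec2, build_transition_matrix(spec2))
        np.testing.assert_allclose(Z, [[3.0, -2.0], [-2.0, 3.0]], atol=1e-10)

    def test_fully_mixing_chain_gives_identity(self):
        spec = ChainSpec(x=(0.5, 0.5), y=(1.0,))
        P = build_transition_matrix(spec)
        np.testing.assert_allclose(P, [[0.5, 0.5], [0.5, 0.5]])
        Z = fundamental_matrix(spec, P)
        np.testing.assert_allclose(Z, np.eye(2), atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(chain_specs())
    def test_rows_sum_to_one(self, spec):
        Z = fundamental_matrix(spec, build_transition_matrix(spec))
        np.testing.assert_allclose(Z.sum(axis=1), 1.0, atol=1e-9)


class TestFirstPassageTimes:
    def test_two_state_geometric_waiting_time(self, spec2):
        Z = fundamental_matrix(spec2, build_transition_matrix(spec2))
        t = first_passage_times(Z, spec2.x_arr)
        assert t[0, 1] == pytest.approx(10.0)  # 1 / P[1,2]
        assert np.all(np.diag(t) == 0.0)

    def test_off_diagonal_positive(self, spec3):
        Z = fundamental_matrix(spec3, build_transition_matrix(spec3))
        t = first_passage_times(Z, spec3.x_arr)
        off = t[~np.eye(3, dtype=bool)]
        assert np.all(off > 0)

    def test_matches_monte_carlo_hitting_times(self, rng):
        # consolidation time t_{2,S} on a moderately fast 4-state chain
        spec = ChainSpec(x=(0.4, 0.3, 0.2, 0.1), y=(0.3, 0.2, 0.15))
        P = build_transition_matrix(spec)
        Z = fundamental_matrix(spec, P)
        t_analytic = first_passage_times(Z, spec.x_arr)[1, 3]
        n = 20_000
        state = np.ones(n, dtype=np.int64)  # 0-based: start in state 2
        hit_time = np.zeros(n)
        cum = np.cumsum(P, axis=1)
        t = 0
        active = state != 3
        while active.any():
            t += 1
            u = rng.random(active.sum())
            state[active] = (u[:, None] >= cum[state[active]]).sum(axis=1)
            newly = active & (state == 3)
            hit_time[newly] = t
            active = state != 3
        se = hit_time.std(ddof=1) / np.sqrt(n)
        assert abs(hit_time.mean() - t_analytic) < 3 * se


class TestAsymptoticVariance:
    def test_two_state_closed_form(self, spec2):
        Z = fundamental_matrix(spec2, build_transition_matrix(spec2))
        sigma2 = asymptotic_variance(Z, spec2.x_arr)
        assert sigma2[0] == pytest.approx(2.25)

    def test_fully_mixing_reduces_to_bernoulli_variance(self):
        spec = ChainSpec(x=(0.5, 0.5), y=(1.0,))
        Z = fundamental_matrix(spec, build_transition_matrix(spec))
        x = spec.x_arr
        np.testing.assert_allclose(asymptotic_variance(Z, x), x - x**2, atol=1e-12)

    def test_matches_empirical_occupancy_variance(self, spec3):
        # variance of time-average occupancy over long runs: Var ~ sigma2 / T
        P = build_transition_matrix(spec3)
        Z = fundamental_matrix(spec3, P)
        sigma2 = asymptotic_variance(Z, spec3.x_arr)
        rng = np.random.default_rng(11)
        T, n_runs = 20_000, 2_000
        cum = np.cumsum(P, axis=1)
        counts = np.zeros((n_runs, 3))
        state = rng.choice(3, size=n_runs, p=spec3.x_arr)
        idx = np.arange(n_runs)
        for _ in range(T):
            counts[idx, state] += 1
            u = rng.random(n_runs)
            state = (u[:, None] >= cum[state]).sum(axis=1)
        emp = counts.var(axis=0, ddof=1) / T  # Var(N_j(T)) ~ sigma2_j * T
        np.testing.assert_allclose(emp, sigma2, rtol=0.10)


# ---------------------------------------------------------------------------
# evolution and spectrum
# ---------------------------------------------------------------------------

class TestEvolveDistribution:
    def test_zero_steps_is_identity(self, spec3):
        P = build_transition_matrix(spec3)
        v = np.array([1.0, 0.0, 0.0])
        np.testing.assert_array_equal(evolve_distribution(v, P, 0), v)

    def test_single_step(self, spec3):
        P = build_transition_matrix(spec3)
        out = evolve_distribution(np.array([1.0, 0.0, 0.0]), P, 1)
        np.testing.assert_allclose(out, [0.94, 0.06, 0.0], atol=1e-15)

    def test_ergodic_limit(self, spec3):
        P = build_transition_matrix(spec3)
        out = evolve_distribution(np.array([1.0, 0.0, 0.0]), P, 10**6)
        np.testing.assert_allclose(out, spec3.x_arr, atol=1e-8)

    def test_negative_steps_rejected(self, spec3):
        with pytest.raises(ValueError):
            evolve_distribution(spec3.x_arr, build_transition_matrix(spec3), -1)


class TestSpectralSummary:
    def test_two_state_closed_form(self, spec2):
        P = build_transition_matrix(spec2)
        ss = spectral_summary(P, spec2.x_arr)
        np.testing.assert_allclose(ss.eigenvalues, [1.0, 0.8], atol=1e-12)
        assert ss.lambda2 == pytest.approx(0.8)
        assert ss.tail_rate == pytest.approx(-np.log(0.8))

    def test_rank_one_chain_mixes_in_one_step(self):
        spec = ChainSpec(x=(0.5, 0.5), y=(1.0,))
        ss = spectral_summary(build_transition_matrix(spec), spec.x_arr)
        assert ss.lambda2 == pytest.approx(0.0, abs=1e-12)

    def test_convergence_ratio_approaches_inverse_lambda2(self, spec3):
        P = build_transition_matrix(spec3)
        ss = spectral_summary(P, spec3.x_arr)
        v = np.array([1.0, 0.0, 0.0])
        x = spec3.x_arr
        t = 0
        vt = v
        while np.linalg.norm(vt - x) > 1e-6:
            vt = vt @ P
            t += 1
        ratio = np.linalg.norm(vt - x) / np.linalg.norm(vt @ P - x)
        assert ratio == pytest.approx(1 / ss.lambda2, rel=0.01)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(chain_specs())
    def test_spectrum_real_sorted_leading_one(self, spec):
        ss = spectral_summary(build_transition_matrix(spec), spec.x_arr)
        assert ss.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(ss.eigenvalues) <= 1e-12)
        assert np.all(ss.eigenvalues > -1.0 - 1e-12)
        assert ss.lambda2 < 1.0


# ---------------------------------------------------------------------------
# Monte-Carlo simulator
# ---------------------------------------------------------------------------

class TestSimulateConnections:
    def test_counts_conserved_and_reproducible(self, spec3):
        occ1 = simulate_connections(spec3, n=500, t_max=50, seed=42)
        occ2 = simulate_connections(spec3, n=500, t_max=50, seed=42)
        np.testing.assert_array_equal(occ1, occ2)
        assert np.all(occ1.sum(axis=1) == 500)

    def test_stationary_start_stays_near_equilibrium(self, spec3):
        n = 100_000
        occ = simulate_connections(spec3, n=n, t_max=100, seed=1)
        frac = occ / n
        se = np.sqrt(spec3.x_arr * (1 - spec3.x_arr) / n)
        assert np.all(np.abs(frac - spec3.x_arr) < 4 * se + 1e-12)

    def test_matches_distribution_evolution(self, spec3):
        n = 100_000
        v0 = np.array([1.0, 0.0, 0.0])
        occ = simulate_connections(spec3, n=n, t_max=20, v0=v0, seed=3)
        P = build_transition_matrix(spec3)
        for t in (5, 10, 20):
            expected = evolve_distribution(v0, P, t)
            se = np.sqrt(expected * (1 - expected) / n)
            assert np.all(np.abs(occ[t] / n - expected) < 4 * se + 1e-12)
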