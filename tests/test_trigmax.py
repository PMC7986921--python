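"""Trigonometric fixed-point maximization: updates, convergence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trigsar as ts
from conftest import random_psd
from trigsar import trigmax
from trigsar.qmodel import QMatrixSet, ValidationError
from trigsar.trigmax import TrigMaxConfig, TrigMaxState


def random_amps(nc, seed):
    return np.random.default_rng(seed).random(nc) + 0.05


class TestPhaseForm:
    def test_two_channel_closed_form(self, two_channel_q):
        for phi2 in (-np.pi / 2, 0.0, 1.3):
            val = ts.sar_phase_form(two_channel_q, [1, 1], [0, phi2])
            assert val == pytest.approx(2 + np.cos(phi2 + np.pi / 2), rel=1e-12)

    def test_diagonal_matrix_phase_independent(self):
        q = np.diag([2.0, 3.0, 1.0])
        a = np.array([1.0, 0.5, 2.0])
        v0 = ts.sar_phase_form(q, a, np.zeros(3))
        v1 = ts.sar_phase_form(q, a, [1.0, -2.0, 0.4])
        assert v0 == v1 == pytest.approx(float(a**2 @ np.diag(q)), rel=1e-14)

    @given(seed=st.integers(0, 200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_quadratic_form(self, seed):
        q = random_psd(4, 3, seed)
        rng = np.random.default_rng(seed)
        a = rng.random(4)
        phi = rng.uniform(-np.pi, np.pi, 4)
        s = a * np.exp(1j * phi)
        quad = float(np.real(s.conj() @ q @ s))
        assert ts.sar_phase_form(q, a, phi) == pytest.approx(quad, rel=1e-12, abs=1e-14)


class TestGradient:
    def test_two_channel_value(self, two_channel_q):
        g = ts.sar_gradient(two_channel_q, [1, 1], [0, 0])
        assert g[1] == pytest.approx(-1.0, rel=1e-12)
        assert g[0] == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_central_finite_differences(self, seed):
        q = random_psd(5, 3, seed)
        a = random_amps(5, seed)
        rng = np.random.default_rng(seed + 50)
        phi = rng.uniform(-np.pi, np.pi, 5)
        g = ts.sar_gradient(q, a, phi)
        h = 1e-6
        for l in range(5):
            e = np.zeros(5)
            e[l] = h
            fd = (ts.sar_phase_form(q, a, phi + e) - ts.sar_phase_form(q, a, phi - e)) / (
                2 * h
            )
            assert g[l] == pytest.approx(fd, abs=1e-6)

    def test_zero_at_returned_solution(self):
        q = random_psd(6, 3, 11)
        a = random_amps(6, 11)
        cfg = TrigMaxConfig(epsilon=1e-14, epsilon_rel=1e-15, grad_tol=1e-8)
        res = ts.maximize_phases(q, a, cfg)
        g = ts.sar_gradient(q, a, res.phases)
        assert np.max(np.abs(g)) <= 1e-8

    def test_hessian_matches_finite_difference_of_gradient(self):
        q = random_psd(4, 3, 5)
        a = random_amps(4, 5)
        phi = np.array([0.1, -0.7, 2.0, 0.0])
        h = ts.sar_hessian(q, a, phi)
        step = 1e-6
        for m in range(4):
            e = np.zeros(4)
            e[m] = step
            fd = (ts.sar_gradient(q, a, phi + e) - ts.sar_gradient(q, a, phi - e)) / (
                2 * step
            )
            assert np.allclose(h[:, m], fd, atol=1e-6)
        # global-phase null direction
        assert np.allclose(h @ np.ones(4), 0.0, atol=1e-12)


class TestCoordinateUpdate:
    def test_two_channel_single_step_attains_max(self, two_channel_q):
        state = TrigMaxState.from_matrix(two_channel_q, [1.0, 1.0])
        phi = np.array([0.0, 0.0])
        new = trigmax.coordinate_update(state, phi, 0)
        assert new == pytest.approx(np.pi / 2, rel=1e-12)
        assert ts.sar_phase_form(two_channel_q, [1, 1], [new, 0.0]) == pytest.approx(3.0)

    def test_zero_amplitude_channel_keeps_phase(self, two_channel_q):
        state = TrigMaxState.from_matrix(two_channel_q, [1.0, 0.0])
        phi = np.array([0.3, 0.7])
        assert trigmax.coordinate_update(state, phi, 1) == pytest.approx(0.7)
        assert 1 in state.degenerate_channels

    @pytest.mark.parametrize("seed", range(4))
    def test_update_beats_dense_1d_scan(self, seed):
        q = random_psd(4, 3, seed + 300)
        a = random_amps(4, seed + 300)
        rng = np.random.default_rng(seed)
        phi = rng.uniform(-np.pi, np.pi, 4)
        state = TrigMaxState.from_matrix(q, a)
        grid = np.linspace(-np.pi, np.pi, 720, endpoint=False)
        for l in range(4):
            new = trigmax.coordinate_update(state, phi, l)
            trial = phi.copy()
            trial[l] = new
            best_update = ts.sar_phase_form(q, a, trial)
            scans = []
            for g in grid:
                trial[l] = g
                scans.append(ts.sar_phase_form(q, a, trial))
            assert best_update >= max(scans) - 1e-12

    def test_coefficient_form_equals_complex_sweep(self):
        q = random_psd(5, 3, 77)
        a = random_amps(5, 77)
        rng = np.random.default_rng(77)
        phi = rng.uniform(-np.pi, np.pi, 5)
        state = TrigMaxState.from_matrix(q, a)
        coord = np.array(
            [trigmax.coordinate_update(state, phi, l) for l in range(5)]
        )
        swept = trigmax._sweep(q[None], a, phi[None], "jacobi")[0]
        assert np.allclose(np.exp(1j * coord), np.exp(1j * swept), atol=1e-12)


class TestMaximizePhases:
    def test_rank_one_constructive_interference(self, rank1_q):
        res = ts.maximize_phases(rank1_q, [1.0, 2.0])
        a = np.array([1.0, 2.0])
        assert res.max_sar == pytest.approx(9.0, rel=1e-9)
        assert res.max_sar == pytest.approx(
            float(a @ np.abs(rank1_q) @ a), rel=1e-12
        )

    def test_two_channel_phase_difference(self, two_channel_q):
        res = ts.maximize_phases(two_channel_q, [1.0, 1.0])
        assert res.max_sar == pytest.approx(3.0, rel=1e-9)
        diff = np.angle(np.exp(1j * (res.phases[1] - res.phases[0])))
        assert diff == pytest.approx(-np.pi / 2, abs=1e-6)

    @pytest.mark.parametrize("nc", [3, 4])
    def test_agrees_with_grid_oracle(self, nc):
        cfg = TrigMaxConfig(epsilon=1e-12, epsilon_rel=1e-13)
        for seed in range(20):
            q = random_psd(nc, 3, seed + nc * 1000)
            a = random_amps(nc, seed)
            tm = ts.maximize_phases(q, a, cfg).max_sar
            oracle = ts.brute_force_max(q, a, grid_points=180)
            assert tm == pytest.approx(oracle, rel=1e-3)

    def test_never_below_initial_sar(self):
        for seed in range(10):
            q = random_psd(5, 3, seed)
            a = random_amps(5, seed)
            rng = np.random.default_rng(seed)
            phi0 = rng.uniform(-np.pi, np.pi, 5)
            cfg = TrigMaxConfig(initial_phases=phi0)
            res = ts.maximize_phases(q, a, cfg)
            assert res.max_sar >= ts.sar_phase_form(q, a, phi0) - 1e-12

    def test_invariant_to_global_shift_of_initial_guess(self):
        q = random_psd(5, 3, 42)
        a = random_amps(5, 42)
        base = ts.maximize_phases(q, a).max_sar
        shifted = ts.maximize_phases(
            q, a, TrigMaxConfig(initial_phases=np.full(5, 1.234))
        ).max_sar
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_gauss_seidel_monotone_ascent(self):
        for seed in range(5):
            q = random_psd(6, 3, seed + 7)
            a = random_amps(6, seed + 7)
            cfg = TrigMaxConfig(sweep_scheme="gauss_seidel", epsilon=1e-13)
            res = ts.maximize_phases(q, a, cfg)
            diffs = np.diff(res.sar_history)
            assert np.all(diffs >= -1e-12 * max(res.max_sar, 1.0))

    def test_jacobi_and_gauss_seidel_reach_same_value(self):
        for seed in range(8):
            q = random_psd(5, 3, seed + 900)
            a = random_amps(5, seed + 900)
            vj = ts.maximize_phases(q, a, TrigMaxConfig(epsilon=1e-13)).max_sar
            vg = ts.maximize_phases(
                q, a, TrigMaxConfig(epsilon=1e-13, sweep_scheme="gauss_seidel")
            ).max_sar
            assert vj == pytest.approx(vg, rel=1e-8)

    def test_no_underestimation_over_random_phases(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            q = random_psd(6, 3, seed + 60)
            a = random_amps(6, seed + 60)
            best = ts.maximize_phases(q, a, TrigMaxConfig(epsilon=1e-12)).max_sar
            for _ in range(200):
                phi = rng.uniform(-np.pi, np.pi, 6)
                assert ts.sar_phase_form(q, a, phi) <= best * (1 + 1e-9)

    def test_total_power_eigenvalue_bound(self):
        for seed in range(6):
            q = random_psd(5, 3, seed + 400)
            a = random_amps(5, seed + 400)
            res = ts.maximize_phases(q, a, TrigMaxConfig(epsilon=1e-12))
            w, v = np.linalg.eigh(q)
            bound = w[-1] * float(np.sum(a**2))
            assert res.max_sar <= bound * (1 + 1e-9)
        # equality when |s| proportional to |v_max| and phases from v_max
        vmax = v[:, -1]
        amps = np.abs(vmax)
        res = ts.maximize_phases(q, amps, TrigMaxConfig(epsilon=1e-14))
        assert res.max_sar == pytest.approx(w[-1] * np.sum(amps**2), rel=1e-9)

    def test_saddle_escape_from_real_symmetric_minimum(self):
        # phi=0 is a stationary minimum of SAR = 2 - cos(phi2 - phi1)
        q = np.array([[1.0, -0.5], [-0.5, 1.0]])
        res = ts.maximize_phases(q, [1.0, 1.0])
        assert res.max_sar == pytest.approx(3.0, rel=1e-9)
        assert res.n_escapes >= 1

    def test_zero_amplitudes_rejected(self, two_channel_q):
        with pytest.raises(ValidationError):
            ts.maximize_phases(two_channel_q, [0.0, 0.0])


class TestWorstCasePsar:
    def test_diagonal_set_is_phase_independent(self):
        entries = np.stack([np.diag([1.0, 2.0, 0.5]), np.diag([0.3, 0.1, 3.0])])
        qset = QMatrixSet(entries=entries, averaged=True)
        a = np.array([1.0, 0.5, 1.5])
        res = ts.worst_case_psar(qset, a)
        expected = max(float(a**2 @ np.diag(e.real)) for e in entries)
        assert res.peak_sar == pytest.approx(expected, rel=1e-12)

    def test_singleton_equals_single_matrix_path(self):
        q = random_psd(5, 3, 123)
        a = random_amps(5, 123)
        single = ts.maximize_phases(q, a, TrigMaxConfig(epsilon=1e-12)).max_sar
        setres = ts.worst_case_psar(
            QMatrixSet(entries=q[None], averaged=True), a, TrigMaxConfig(epsilon=1e-12)
        )
        assert setres.peak_sar == pytest.approx(single, rel=1e-10)

    def test_order_independence(self):
        entries = np.stack([random_psd(4, 3, s) for s in range(12)])
        a = random_amps(4, 5)
        fwd = ts.worst_case_psar(QMatrixSet(entries=entries, averaged=True), a)
        perm = np.random.default_rng(0).permutation(12)
        bwd = ts.worst_case_psar(QMatrixSet(entries=entries[perm], averaged=True), a)
        assert fwd.peak_sar == pytest.approx(bwd.peak_sar, rel=1e-10)
        assert np.allclose(np.sort(fwd.max_sar), np.sort(bwd.max_sar), rtol=1e-10)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            QMatrixSet(entries=np.zeros((0, 2, 2)))


class TestTimeIntegrated:
    def test_constant_trajectory_equals_static(self):
        entries = np.stack([random_psd(4, 3, s) for s in range(6)])
        qset = QMatrixSet(entries=entries, averaged=True)
        a = random_amps(4, 9)
        static = ts.worst_case_psar(qset, a)
        traj = ts.time_integrated_worst_case(qset, [a] * 5, [0.1] * 5)
        assert traj.peak_sar == pytest.approx(static.peak_sar, rel=1e-10)
        assert np.allclose(traj.per_matrix, static.max_sar, rtol=1e-10)

    def test_two_decoupled_steps_average(self, two_channel_q):
        qset = QMatrixSet(entries=two_channel_q[None], averaged=True)
        step1 = np.array([1.0, 0.0])
        step2 = np.array([0.0, 1.0])
        res = ts.time_integrated_worst_case(qset, [step1, step2], [1.0, 3.0])
        s1 = ts.worst_case_psar(qset, step1).peak_sar
        s2 = ts.worst_case_psar(qset, step2).peak_sar
        assert res.peak_sar == pytest.approx((1.0 * s1 + 3.0 * s2) / 4.0, rel=1e-12)

    def test_random_trajectory_matches_explicit_loop(self):
        entries = np.stack([random_psd(5, 3, s + 30) for s in range(4)])
        qset = QMatrixSet(entries=entries, averaged=True)
        rng = np.random.default_rng(77)
        amps = rng.random((10, 5)) + 0.05
        durs = rng.random(10) + 0.1
        res = ts.time_integrated_worst_case(qset, amps, durs)
        acc = np.zeros(4)
        for a_t, d_t in zip(amps, durs):
            acc += d_t * ts.worst_case_psar(qset, a_t).max_sar
        assert np.allclose(res.per_matrix, acc / durs.sum(), rtol=1e-12)

    def test_empty_trajectory_rejected(self, two_channel_q):
        qset = QMatrixSet(entries=two_channel_q[None], averaged=True)
        with pytest.raises(ValidationError):
            ts.time_integrated_worst_case(qset, np.zeros((0, 2)), [])
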