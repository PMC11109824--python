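"""Smectic stack theory: equipartition, correlations, structure factor,
and elasticity fitting."""

import numpy as np
import pytest

from ampscat import caille, synth
from ampscat.caille import (StackModel, fit_elasticity, height_correlation,
                            mode_spectrum, predict_pattern, structure_factor,
                            symmetrize_and_subtract)


class TestModeSpectrum:
    def test_matches_eigendecomposition_of_coupling_matrix(self, stack):
        """Equipartition amplitudes equal k_BT over the eigenvalues of the
        discrete elastic coupling matrix (circulant layer Laplacian)."""
        N = stack.N_layers
        q_r = 0.05
        lap = 2 * np.eye(N) - np.roll(np.eye(N), 1, 0) - np.roll(np.eye(N), -1, 0)
        M = stack.K_C * q_r**4 * np.eye(N) + stack.B * lap
        expected = np.sort(1.0 / np.linalg.eigvalsh(M))
        got = np.sort([mode_spectrum(stack, q_r, k, area=1.0)
                       for k in range(N)])
        assert got == pytest.approx(expected, rel=1e-10)

    def test_mode_zero_is_helfrich_single_membrane(self, stack):
        q_r = 0.07
        assert mode_spectrum(stack, q_r, 0, area=1.0) == pytest.approx(
            1.0 / (stack.K_C * q_r**4), rel=1e-12)

    def test_infinite_compression_kills_coupled_modes(self, stack):
        stiff = StackModel(K_C=stack.K_C, B=1e12, N_layers=stack.N_layers,
                           L_r=stack.L_r, D=stack.D)
        assert mode_spectrum(stiff, 0.07, 3, area=1.0) < 1e-11

    def test_doubling_kc_halves_bending_dominated_amplitude(self, stack):
        q_r = 0.2  # bending term dominates at large q_r
        a1 = mode_spectrum(stack, q_r, 0, area=1.0)
        doubled = StackModel(K_C=2 * stack.K_C, B=stack.B,
                             N_layers=stack.N_layers, L_r=stack.L_r, D=stack.D)
        assert mode_spectrum(doubled, q_r, 0, area=1.0) == pytest.approx(
            a1 / 2, rel=1e-12)

    def test_goldstone_mode_rejected(self, stack):
        with pytest.raises(ValueError):
            mode_spectrum(stack, 0.0, 0)


class TestHeightCorrelation:
    def test_self_correlation_at_origin_vanishes(self, stack):
        assert height_correlation(stack, 0, 0.0)[0] == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_lateral_distance(self, stack):
        r = np.linspace(0.0, 400.0, 30)
        d = height_correlation(stack, 0, r)
        assert np.all(np.diff(d) >= -1e-9)

    def test_monte_carlo_gaussian_mode_oracle(self):
        """delta_k(r) agrees with direct Monte-Carlo sampling of the
        discretised Gaussian mode ensemble within 3 standard errors."""
        m = StackModel(K_C=20.0, B=2e-7, N_layers=8, L_r=2000.0, D=58.0)
        N = m.N_layers
        q, w = caille._q_grid(m, 256)
        modes = np.arange(N)
        den = m.K_C * q[None, :]**4 + 2.0 * m.B * (
            1.0 - np.cos(2 * np.pi * modes[:, None] / N))
        V = (w * q / (2 * np.pi) / den / N).ravel()       # (N*nq,)
        qj = np.tile(q, N)
        mj = np.repeat(modes, q.size)
        rng = np.random.default_rng(42)
        R = 3000
        k, r_test = 1, 120.0
        theta = rng.uniform(0, 2 * np.pi, size=(R, V.size))
        phi = rng.uniform(0, 2 * np.pi, size=(R, V.size))
        amp = np.sqrt(2.0 * V)
        # u_n(x) = sum_modes amp * cos(q e.x + 2 pi m n / N + phi)
        arg_x1 = qj * np.cos(theta) * r_test + phi        # position (r,0), n=0
        arg_x2 = phi + 2 * np.pi * mj * k / N             # position (0,0), n=k
        du = (amp * np.cos(arg_x1)).sum(axis=1) - (amp * np.cos(arg_x2)).sum(axis=1)
        sq = du**2
        mc, se = sq.mean(), sq.std(ddof=1) / np.sqrt(R)
        analytic = height_correlation(m, k, r_test, n_q=256)[0]
        assert abs(mc - analytic) < 3 * se

    def test_offset_out_of_range_rejected(self, stack):
        with pytest.raises(ValueError):
            height_correlation(stack, stack.N_layers, 10.0)


class TestStructureFactor:
    def test_rigid_stack_bragg_limit(self, stack):
        """A frozen stack at q_r -> 0 gives the ideal N^2 Laue maximum."""
        N = stack.N_layers
        r, wr = caille._r_grid(stack, 400)
        S = structure_factor(stack, [2 * np.pi / stack.D], [1e-8],
                             delta=np.zeros((N, r.size)), r_nodes=(r, wr))
        assert S[0, 0] == pytest.approx(N**2, rel=1e-3)

    def test_lateral_mirror_symmetry(self, stack):
        S_pos = structure_factor(stack, [0.11], [0.05, 0.12])
        S_neg = structure_factor(stack, [0.11], [-0.05, -0.12])
        assert S_pos == pytest.approx(S_neg, rel=1e-12)

    def test_single_membrane_against_lattice_fft_oracle(self):
        """For N=1 the Gaussian-damping kernel exp(-q_z^2 delta/2) used by
        the analytic path reproduces the ensemble average of |FFT|^2 of
        sampled height fields on a periodic lattice."""
        rng = np.random.default_rng(11)
        L, a = 12, 12.0                    # lattice points, spacing (A)
        K_C = 20.0
        area = (L * a) ** 2
        ii = np.fft.fftfreq(L, d=1.0 / L)
        qx, qy = np.meshgrid(2 * np.pi / (L * a) * ii, 2 * np.pi / (L * a) * ii)
        q2 = qx**2 + qy**2
        sel = q2 > 0
        qvx, qvy = qx[sel], qy[sel]
        V = 1.0 / (area * K_C * q2[sel] ** 2)
        xs = a * np.arange(L)
        X, Y = np.meshgrid(xs, xs)
        pos = np.column_stack([X.ravel(), Y.ravel()])    # (P, 2)
        B = np.exp(1j * (np.outer(qvx, pos[:, 0]) + np.outer(qvy, pos[:, 1])))
        R = 600
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(R, V.size)))
        u = np.real((phases * np.sqrt(2 * V)) @ B)       # (R, P)
        q_z = 0.15
        test_q = [(0.0, 0.0), (2 * np.pi / (L * a), 0.0)]
        # analytic lattice path: S = sum_d e^{iq.d} exp(-q_z^2 delta(d)/2)
        C = (V @ np.real(B))                              # covariance vs offset
        delta = 2.0 * (C[0] - C)
        for (qa, qb) in test_q:
            phase_d = np.exp(1j * (qa * pos[:, 0] + qb * pos[:, 1]))
            S_exact = np.real(np.sum(phase_d * np.exp(-0.5 * q_z**2 * delta)))
            amp = np.exp(1j * q_z * u) @ phase_d.conj()
            vals = np.abs(amp) ** 2 / pos.shape[0]
            mc, se = vals.mean(), vals.std(ddof=1) / np.sqrt(R)
            assert abs(mc - S_exact) < 3 * se + 1e-9


class TestPredictAndFit:
    def test_flat_formfactor_rigid_stack_pure_interference(self, stack):
        q_z = np.linspace(0.06, 0.3, 12)
        q_r = np.linspace(0.01, 0.2, 8)
        rigid = predict_pattern(stack, lambda q: np.ones_like(q), q_z, q_r,
                                delta=np.zeros((stack.N_layers, 400)),
                                r_nodes=caille._r_grid(stack, 400))
        S = structure_factor(stack, q_z, q_r,
                             delta=np.zeros((stack.N_layers, 400)),
                             r_nodes=caille._r_grid(stack, 400))
        assert rigid.intensity == pytest.approx(S / q_z[:, None], rel=1e-12)

    def test_intensity_linear_in_scale(self, stack):
        q_z = np.linspace(0.06, 0.3, 10)
        q_r = np.linspace(0.01, 0.2, 6)
        p1 = predict_pattern(stack, synth.default_formfactor, q_z, q_r, scale=1.0)
        p2 = predict_pattern(stack, synth.default_formfactor, q_z, q_r, scale=2.0)
        assert p2.intensity == pytest.approx(2.0 * p1.intensity, rel=1e-12)

    def test_noiseless_round_trip_recovers_moduli(self, stack, elasticity_init,
                                                  fit_window):
        pattern, _ = synth.gen_xds(stack, noise=0.0)
        fit = fit_elasticity(pattern, synth.default_formfactor,
                             elasticity_init, fit_window)
        assert fit.K_C_hat == pytest.approx(stack.K_C, rel=1e-2)
        assert fit.B_hat == pytest.approx(stack.B, rel=1e-2)
        assert fit.status == "ok"

    def test_noisy_recovery_within_spread(self, stack, elasticity_init,
                                          fit_window):
        for seed in (0, 1, 2):
            pattern, _ = synth.gen_xds(stack, noise=0.05, seed=seed)
            fit = fit_elasticity(pattern, synth.default_formfactor,
                                 elasticity_init, fit_window)
            assert abs(fit.K_C_hat - stack.K_C) / stack.K_C < 0.15

    def test_frozen_pattern_runs_stiffness_to_bound(self, stack,
                                                    elasticity_init,
                                                    fit_window):
        """A fluctuation-free (frozen-stack) pattern carries no softness
        information: the fit runs the elastic moduli towards infinite
        stiffness and flags the bound hit."""
        q_z = np.linspace(0.06, 0.34, 52)
        q_r = np.linspace(0.012, 0.25, 64)
        r_nodes = caille._r_grid(stack, 800)
        S = structure_factor(stack, q_z, q_r,
                             delta=np.zeros((stack.N_layers, r_nodes[0].size)),
                             r_nodes=r_nodes)
        I = S * (synth.default_formfactor(q_z) ** 2 / q_z)[:, None]
        pattern = caille.DiffusePattern(q_r=q_r, q_z=q_z, intensity=I)
        fit = fit_elasticity(pattern, synth.default_formfactor,
                             elasticity_init, fit_window)
        assert fit.status == "parameter at bound"
        assert max(fit.K_C_hat / elasticity_init.K_C,
                   fit.B_hat / elasticity_init.B) > 1e3

    def test_softening_ordering_detected(self, elasticity_init, fit_window):
        hats = {}
        for K in (20.0, 14.0):
            pattern, _ = synth.gen_xds(synth.default_stack(K_C=K),
                                       noise=0.05, seed=4)
            hats[K] = fit_elasticity(pattern, synth.default_formfactor,
                                     elasticity_init, fit_window).K_C_hat
        assert hats[14.0] < hats[20.0]


class TestSymmetrize:
    def _grids(self):
        q_r = np.linspace(-0.2, 0.2, 21)
        q_z = np.linspace(0.05, 0.3, 11)
        return q_r, q_z

    def test_symmetric_input_fixed_point(self):
        q_r, q_z = self._grids()
        img = np.cos(np.outer(q_z, np.ones_like(q_r))) * np.cos(5 * q_r) ** 2
        out = symmetrize_and_subtract(img, np.zeros_like(img), q_r, q_z)
        assert out.intensity == pytest.approx(img, abs=1e-12)

    def test_self_subtraction_gives_zero(self):
        q_r, q_z = self._grids()
        img = np.random.default_rng(0).random((q_z.size, q_r.size))
        out = symmetrize_and_subtract(img, img, q_r, q_z)
        assert out.intensity == pytest.approx(0.0, abs=1e-12)

    def test_asymmetric_input_mirror_average(self):
        q_r, q_z = self._grids()
        img = np.outer(np.ones(q_z.size), q_r)  # odd in q_r
        out = symmetrize_and_subtract(img, np.zeros_like(img), q_r, q_z)
        assert out.intensity == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        q_r, q_z = self._grids()
        with pytest.raises(ValueError):
            symmetrize_and_subtract(np.zeros((3, 3)), np.zeros((4, 4)), q_r, q_z)
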