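"""FISTA reconstruction: operators, prox, sensitivity estimation, descent."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csmra import (
    MaskParams,
    ReconConfig,
    estimate_sensitivities,
    fista_recon,
    generate_mask,
    make_coil_sensitivities,
    masked_ssim,
    make_vessel_mask,
    mip,
    normalize_p99,
    objective,
    retrospective_undersample,
    simulate_kspace,
    soft_threshold,
)
from csmra.fourier import cifftn
from csmra.phantom import KSpaceData
from csmra.recon import SenseOperator, WaveletTransform


class TestSoftThreshold:
    def test_shrinks_above_threshold(self):
        assert soft_threshold(np.array([0.5]), 0.2)[0] == pytest.approx(0.3)

    def test_zeroes_below_threshold(self):
        assert soft_threshold(np.array([0.1]), 0.2)[0] == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(theta=st.floats(0, 2 * np.pi))
    def test_phase_preserved(self, theta):
        c = 0.3 * np.exp(1j * theta)
        out = soft_threshold(np.array([c]), 0.1)[0]
        assert abs(out) == pytest.approx(0.2, abs=1e-12)
        assert np.angle(out) == pytest.approx(np.angle(c), abs=1e-9)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)


class TestObjective:
    def test_zero_everywhere(self, sens32):
        x = np.zeros((32, 32, 32), complex)
        b = np.zeros(sens32.maps.shape, complex)
        mask = np.ones((32, 32), bool)
        assert objective(x, b, mask, sens32, lam=0.007) == 0.0

    def test_zero_image_gives_half_data_energy(self, kspace32, sens32):
        x = np.zeros((32, 32, 32), complex)
        mask = np.ones((32, 32), bool)
        val = objective(x, kspace32, mask, sens32, lam=0.0)
        assert val == pytest.approx(0.5 * np.sum(np.abs(kspace32.data) ** 2))

    def test_exact_solution_reaches_zero(self, phantom32):
        unit = make_coil_sensitivities((32, 32, 32), 1, uniform=True)
        ks = simulate_kspace(phantom32, unit, 0.0, 0)
        mask = np.ones((32, 32), bool)
        x = SenseOperator(mask, unit).adjoint(ks.data)
        assert objective(x, ks, mask, unit, lam=0.0) < 1e-10

    def test_shape_mismatch_rejected(self, kspace32, sens32):
        with pytest.raises(ValueError):
            objective(
                np.zeros((16, 16, 16), complex),
                kspace32,
                np.ones((32, 32), bool),
                sens32,
                lam=0.0,
            )


class TestSenseOperator:
    def test_adjoint_dot_product(self, kspace32, sens32):
        """<A x, y> equals <x, A^H y> to 1e-8 relative."""
        mask = generate_mask((32, 32), MaskParams(R=4, pp=2, calib=8, seed=0))
        op = SenseOperator(mask, estimate_sensitivities(kspace32, 8))
        rng = np.random.default_rng(0)
        x = rng.standard_normal((32, 32, 32)) + 1j * rng.standard_normal((32, 32, 32))
        y = rng.standard_normal(kspace32.data.shape) + 1j * rng.standard_normal(
            kspace32.data.shape
        )
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-8

    def test_lipschitz_bounded_by_one(self, kspace32):
        mask = generate_mask((32, 32), MaskParams(R=4, pp=2, calib=8, seed=0))
        op = SenseOperator(mask, estimate_sensitivities(kspace32, 8))
        assert op.lipschitz() <= 1.0 + 1e-12


class TestEstimateSensitivities:
    def test_unit_coil_estimates_unit_magnitude(self, phantom32):
        unit = make_coil_sensitivities((32, 32, 32), 1, uniform=True)
        ks = simulate_kspace(phantom32, unit, 0.0, 0)
        est = estimate_sensitivities(ks, 12)
        np.testing.assert_allclose(np.abs(est.maps), 1.0, atol=1e-6)

    def test_accuracy_against_ground_truth(self, phantom64, sens64):
        """Estimated maps track RSS-normalized truth inside the support."""
        ks = simulate_kspace(phantom64, sens64, 0.0, 0)
        truth = sens64.normalized()
        support = phantom64.image > 0.3
        err24 = np.mean(
            np.abs(
                np.abs(estimate_sensitivities(ks, 24).maps) - np.abs(truth.maps)
            )[:, support]
        )
        err12 = np.mean(
            np.abs(
                np.abs(estimate_sensitivities(ks, 12).maps) - np.abs(truth.maps)
            )[:, support]
        )
        assert err24 < 0.05
        assert err12 >= err24

    def test_rss_of_estimate_is_unit_on_support(self, kspace32):
        est = estimate_sensitivities(kspace32, 12)
        rss = est.rss()
        assert np.median(np.abs(rss - 1.0)) < 1e-9

    def test_all_zero_calibration_rejected(self):
        ks = KSpaceData(np.zeros((2, 16, 16, 16), complex))
        with pytest.raises(ValueError, match="zero"):
            estimate_sensitivities(ks, 8)

    def test_calib_exceeding_grid_rejected(self, kspace32):
        with pytest.raises(ValueError, match="exceeds"):
            estimate_sensitivities(kspace32, 64)


class TestRetrospectiveUndersample:
    def test_full_mask_is_identity(self, kspace32):
        out = retrospective_undersample(kspace32, np.ones((32, 32), bool))
        np.testing.assert_array_equal(out.data, kspace32.data)

    def test_calibration_only_mask(self, kspace32):
        from csmra.sampling import calibration_block

        blk = calibration_block((32, 32), 8)
        out = retrospective_undersample(kspace32, blk)
        assert np.all(out.data[:, :, ~blk] == 0)
        np.testing.assert_array_equal(out.data[:, :, blk], kspace32.data[:, :, blk])

    def test_energy_ratio_matches_sampled_fraction(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((2, 8, 32, 32)) + 1j * rng.standard_normal(
            (2, 8, 32, 32)
        )
        ks = KSpaceData(data)
        mask = generate_mask((32, 32), MaskParams(R=3, pp=0, calib=0, seed=2))
        out = retrospective_undersample(ks, mask)
        ratio = np.sum(np.abs(out.data) ** 2) / np.sum(np.abs(ks.data) ** 2)
        assert ratio == pytest.approx(mask.mask.mean(), rel=0.05)

    def test_shape_mismatch_rejected(self, kspace32):
        with pytest.raises(ValueError, match="match"):
            retrospective_undersample(kspace32, np.ones((16, 16), bool))


class TestFistaRecon:
    def test_unregularized_fully_sampled_matches_inverse_fft(self, phantom32):
        """With lam=0 and full sampling FISTA converges to the FFT inverse."""
        unit = make_coil_sensitivities((32, 32, 32), 1, uniform=True)
        ks = simulate_kspace(phantom32, unit, 0.0, 0)
        rec = fista_recon(
            ks, np.ones((32, 32), bool), unit, ReconConfig(lam=0.0, n_iter=20)
        )
        oracle = cifftn(ks.data[0])
        rel = np.linalg.norm(rec.image - oracle) / np.linalg.norm(oracle)
        assert rel < 1e-6

    def test_zero_data_gives_zero_image(self, sens32):
        ks = KSpaceData(np.zeros(sens32.maps.shape, complex))
        rec = fista_recon(ks, np.ones((32, 32), bool), sens32)
        assert np.all(rec.image == 0)
        assert rec.objective_trace == [0.0] * 20

    def test_objective_descends(self, kspace32):
        mask = generate_mask((32, 32), MaskParams(R=6, pp=2, calib=12, seed=1))
        und = retrospective_undersample(kspace32, mask)
        rec = fista_recon(und, mask, estimate_sensitivities(und, 12))
        tr = rec.objective_trace
        assert len(tr) == 20
        assert tr[-1] <= 0.99 * tr[0]
        assert all(tr[i + 1] <= tr[i] + 1e-9 for i in range(3, len(tr) - 1))

    def test_beats_zero_filled_adjoint(self, kspace32, phantom32):
        """CS reconstruction outscores the zero-filled adjoint at R=6."""
        mask = generate_mask((32, 32), MaskParams(R=6, pp=2, calib=12, seed=2))
        und = retrospective_undersample(kspace32, mask)
        sens = estimate_sensitivities(und, 12)
        rec = fista_recon(und, mask, sens)
        zf = np.abs(SenseOperator(mask, sens).adjoint(und.data))
        ref = normalize_p99(mip(phantom32.image))
        vmask = make_vessel_mask(ref)
        s_rec = masked_ssim(ref, normalize_p99(mip(rec.magnitude)), vmask)
        s_zf = masked_ssim(ref, normalize_p99(mip(zf)), vmask)
        assert s_rec > s_zf

    def test_regularization_has_interior_optimum(self, kspace32, phantom32):
        """SSIM over lam in {0.0007, 0.007, 0.07} peaks at the middle value."""
        mask = generate_mask((32, 32), MaskParams(R=6, pp=2, calib=12, seed=11))
        und = retrospective_undersample(kspace32, mask)
        sens = estimate_sensitivities(und, 12)
        ref = normalize_p99(mip(phantom32.image))
        vmask = make_vessel_mask(ref)
        scores = []
        for lam in (0.0007, 0.007, 0.07):
            rec = fista_recon(und, mask, sens, ReconConfig(lam=lam))
            scores.append(masked_ssim(ref, normalize_p99(mip(rec.magnitude)), vmask))
        assert scores[1] > scores[0] and scores[1] > scores[2]

    def test_prox_matches_per_coefficient_minimization(self):
        """One prox step solves the coefficientwise lasso problem exactly."""
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(3)
        v = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        wt = WaveletTransform((8, 8, 8))
        t = 0.3
        coeffs = wt.forward(v)
        prox_coeffs = soft_threshold(coeffs, t)
        for c, p in zip(coeffs.ravel()[::7], prox_coeffs.ravel()[::7]):
            phase = c / abs(c) if abs(c) > 0 else 1.0
            res = minimize_scalar(
                lambda s: 0.5 * abs(s * phase - c) ** 2 + t * abs(s),
                bounds=(-2 * abs(c) - t, 2 * abs(c) + t),
                method="bounded",
                options={"xatol": 1e-10},
            )
            assert p == pytest.approx(res.x * phase, abs=1e-6)

    def test_nonorthogonal_wavelet_rejected(self):
        with pytest.raises(ValueError, match="orthogonal"):
            ReconConfig(wavelet_name="bior2.2")

    def test_invalid_iterations_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(n_iter=0)
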