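"""Tensor estimation: noiseless exactness, independent-fit cross-check,
scalar formulas, denoising, SNR measurement and the noise-bias Monte-Carlo."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from myodti.montecarlo import DWIVolume, PGSEProtocol, rician_noise
from myodti.tensor import (
    design_matrix, evals_for_fa, fit_tensor_volume, lpca_denoise, measure_snr,
    protocol_signals, snr_accuracy_simulation, tensor_from_evals,
    tensor_scalars,
)


def random_spd_tensor(rng):
    """Random SPD tensor with muscle-scale diffusivities (mm^2/s)."""
    ev = rng.uniform(0.3e-3, 2.0e-3, 3)
    R = Rotation.random(random_state=rng.integers(2**31 - 1)).as_matrix()
    return R @ np.diag(ev) @ R.T


def nlls_reference_fit(signals, bvals, bvecs):
    """Independent nonlinear LS route on S = S0 exp(-b g D g)."""
    X = design_matrix(bvals, bvecs)

    def resid(beta):
        return np.exp(X @ beta) - signals

    beta0 = np.zeros(7)
    beta0[1:4] = 1e-3
    sol = least_squares(resid, beta0, method="lm", xtol=1e-14, ftol=1e-14)
    b = sol.x
    return np.array([[b[1], b[4], b[5]], [b[4], b[2], b[6]], [b[5], b[6], b[3]]])


class TestFit:
    def test_noiseless_round_trip_exact(self, protocol):
        D = np.diag([1.2e-3, 1.2e-3, 1.6e-3])
        sig = protocol_signals(D, protocol)
        tf = fit_tensor_volume(sig[None], protocol.bvals(), protocol.bvecs())
        truth = np.array([1.6e-3, 1.2e-3, 1.2e-3])
        assert np.all(np.abs(tf.evals[0] - truth) / truth < 1e-8)

    def test_isotropic_fa_zero(self, protocol):
        sig = protocol_signals(np.eye(3) * 1.1e-3, protocol)
        tf = fit_tensor_volume(sig[None], protocol.bvals(), protocol.bvecs())
        assert tf.fa[0] < 1e-8

    def test_cross_check_against_independent_nlls(self, protocol):
        rng = np.random.default_rng(42)
        bvals, bvecs = protocol.bvals(), protocol.bvecs()
        worst = 0.0
        for _ in range(20):
            D = random_spd_tensor(rng)
            sig = protocol_signals(D, protocol)
            tf = fit_tensor_volume(sig[None], bvals, bvecs)
            D_ref = nlls_reference_fit(sig, bvals, bvecs)
            worst = max(worst, np.abs(tf.tensor[0] - D_ref).max() / np.abs(D).max())
        assert worst < 1e-6

    def test_rotation_equivariance(self, protocol):
        rng = np.random.default_rng(3)
        D = random_spd_tensor(rng)
        R = Rotation.random(random_state=7).as_matrix()
        sig1 = protocol_signals(D, protocol)
        tf1 = fit_tensor_volume(sig1[None], protocol.bvals(), protocol.bvecs())
        # rotate both the tensor and the gradient table
        proto_r = PGSEProtocol(directions=protocol.directions @ R.T)
        sig2 = protocol_signals(R @ D @ R.T, proto_r)
        tf2 = fit_tensor_volume(sig2[None], proto_r.bvals(), proto_r.bvecs())
        for m in ("fa", "md", "rd"):
            assert getattr(tf1, m)[0] == pytest.approx(getattr(tf2, m)[0],
                                                       abs=1e-10)

    def test_non_positive_signal_masked(self, protocol):
        sig = protocol_signals(np.eye(3) * 1e-3, protocol)
        bad = sig.copy()
        bad[10] = 0.0
        tf = fit_tensor_volume(np.vstack([sig, bad]), protocol.bvals(),
                               protocol.bvecs())
        assert tf.fit_mask.tolist() == [True, False]
        assert tf.meta["masked_reason"]["non_positive_signal"] == 1

    def test_negative_eigenvalues_clamped_and_flagged(self, protocol):
        # DWI signals above b0 imply negative apparent diffusivities
        sig = np.concatenate([np.ones(5), np.full(30, 1.3)])
        tf = fit_tensor_volume(sig[None], protocol.bvals(), protocol.bvecs())
        assert bool(tf.clamped_mask[0])
        assert np.all(tf.evals[0] > 0)

    def test_too_few_directions_rejected(self):
        bvals = np.array([0.0, 500, 500, 500, 500, 500])
        bvecs = np.vstack([np.zeros(3), np.eye(3), np.eye(3)[:2]])
        with pytest.raises(ValueError):
            fit_tensor_volume(np.ones((1, 6)), bvals, bvecs)


class TestScalars:
    @pytest.mark.parametrize("evals, fa, md, rd", [
        ((1e-3, 1e-3, 1e-3), 0.0, 1e-3, 1e-3),
        ((2e-3, 0.0, 0.0), 1.0, 2e-3 / 3, 0.0),
        ((1.6e-3, 1.2e-3, 1.2e-3), 0.17150, 1.3333e-3, 1.2e-3),
    ])
    def test_closed_form_examples(self, evals, fa, md, rd):
        sc = tensor_scalars(np.array(evals))
        assert float(sc["fa"]) == pytest.approx(fa, abs=1e-4)
        assert float(sc["md"]) == pytest.approx(md, rel=1e-4)
        assert float(sc["rd"]) == pytest.approx(rd, abs=1e-9)

    def test_zero_tensor_flagged(self):
        sc = tensor_scalars(np.zeros(3))
        assert float(sc["fa"]) == 0.0
        assert bool(sc["zero_flag"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-5, 3e-3), min_size=3, max_size=3))
    def test_fa_bounded_and_ordering_free(self, evals):
        ev = np.sort(np.array(evals))[::-1]
        sc = tensor_scalars(ev)
        assert 0.0 <= float(sc["fa"]) <= 1.0
        assert float(sc["md"]) == pytest.approx(np.mean(ev))

    def test_prolate_evals_for_target_fa(self):
        ev = evals_for_fa(1.6e-3, 0.25)
        assert float(tensor_scalars(np.array(ev))["fa"]) == pytest.approx(0.25)


class TestDenoise:
    def _volume(self, protocol, sigma, seed=0):
        clean = protocol_signals(tensor_from_evals(evals_for_fa(1.6e-3, 0.25)),
                                 protocol)
        yy, xx = np.mgrid[0:10, 0:10]
        mod = 1.0 + 0.1 * np.sin(xx / 3.0)
        vol = clean[None, None, None, :] * mod[None, :, :, None]
        noisy = rician_noise(vol, sigma, np.random.default_rng(seed))
        return vol, DWIVolume(signals=noisy, bvals=protocol.bvals(),
                              bvecs=protocol.bvecs(), voxel_size_mm=0.5)

    def test_noiseless_passthrough(self, protocol):
        vol, dwi = self._volume(protocol, sigma=0.0)
        den = lpca_denoise(dwi)
        assert np.allclose(den.signals, vol, rtol=1e-6)

    def test_noise_removal_matches_sigma(self, protocol):
        sigma = 1 / 46.0
        _, dwi = self._volume(protocol, sigma)
        den = lpca_denoise(dwi)
        resid = np.sqrt(np.mean((den.signals - dwi.signals) ** 2))
        assert resid == pytest.approx(sigma, rel=0.15)

    def test_denoising_lowers_fa_error(self, protocol):
        """Paired comparison at the measured b=500 SNR of the fine arm."""
        vol, dwi = self._volume(protocol, 1 / 46.0)
        fa_true = float(tensor_scalars(np.array(evals_for_fa(1.6e-3, 0.25)))["fa"])
        m = dwi.signals.shape[-1]
        tf_raw = fit_tensor_volume(dwi.signals.reshape(-1, m),
                                   dwi.bvals, dwi.bvecs)
        den = lpca_denoise(dwi)
        tf_den = fit_tensor_volume(np.maximum(den.signals, 1e-6).reshape(-1, m),
                                   dwi.bvals, dwi.bvecs)
        rmse_raw = np.sqrt(np.mean((tf_raw.fa - fa_true) ** 2))
        rmse_den = np.sqrt(np.mean((tf_den.fa - fa_true) ** 2))
        assert rmse_den < rmse_raw

    def test_patch_larger_than_volume_fails(self, protocol):
        _, dwi = self._volume(protocol, 0.01)
        with pytest.raises(ValueError):
            lpca_denoise(dwi, patch_radius=12)


class TestMeasureSNR:
    def test_definition(self):
        img = np.zeros((10, 10))
        tissue = np.zeros((10, 10), bool)
        noise = np.zeros((10, 10), bool)
        img[:5] = 10.0
        tissue[:5] = True
        rng = np.random.default_rng(0)
        img[5:] = rng.normal(0, 2.0, (5, 10))
        noise[5:] = True
        snr = measure_snr(img, tissue, noise)
        assert snr == pytest.approx(10.0 / img[noise].std(ddof=1))

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        img = np.concatenate([np.full(50, 8.0), rng.normal(0, 1.5, 50)])
        tissue = np.arange(100) < 50
        snr1 = measure_snr(img, tissue, ~tissue)
        snr2 = measure_snr(3.7 * img, tissue, ~tissue)
        assert snr2 == pytest.approx(snr1, rel=1e-12)

    def test_generator_round_trip_at_measured_snr(self):
        """b0 at the fine-arm SNR of 92 measures back within 10%."""
        snr = 92.0
        rng = np.random.default_rng(5)
        tissue_vals = rician_noise(np.ones(4000), 1 / snr, rng)
        bg_vals = rician_noise(np.zeros(4000), 1 / snr, rng)
        img = np.concatenate([tissue_vals, bg_vals])
        tissue = np.arange(8000) < 4000
        measured = measure_snr(img, tissue, ~tissue,
                               rician_background_correction=True)
        assert measured == pytest.approx(snr, rel=0.10)

    def test_region_preconditions(self):
        img = np.ones((4, 4))
        with pytest.raises(ValueError):
            measure_snr(img, np.zeros((4, 4), bool), np.ones((4, 4), bool))
        with pytest.raises(ValueError):
            measure_snr(img, np.ones((4, 4), bool), np.ones((4, 4), bool))
        tissue = np.zeros((4, 4), bool)
        tissue[0] = True
        with pytest.raises(ValueError):  # zero noise SD on a constant image
            measure_snr(img, tissue, ~tissue)


class TestSNRAccuracy:
    def test_infinite_snr_is_exact(self, protocol):
        res = snr_accuracy_simulation(evals_for_fa(1.6e-3, 0.25), protocol,
                                      snr_b0=np.inf, n_reps=100, seed=0)
        assert res["max_abs_bias_pct"] < 1e-8

    def test_fa_bias_positive_near_isotropy(self, protocol):
        """Eigenvalue repulsion inflates FA under noise for low-FA truth."""
        res = snr_accuracy_simulation(evals_for_fa(1.6e-3, 0.10), protocol,
                                      snr_b0=30.0, n_reps=1000, seed=2)
        assert res["metrics"]["fa"]["bias_pct"] > 0

    def test_invalid_snr_rejected(self, protocol):
        with pytest.raises(ValueError):
            snr_accuracy_simulation(evals_for_fa(1.6e-3, 0.25), protocol,
                                    snr_b0=0.0, n_reps=100, seed=0)
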