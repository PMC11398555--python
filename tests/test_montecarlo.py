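"""Monte-Carlo diffusion physics: free-diffusion closed forms, restriction,
permeability calibration, PGSE encoding and DWI synthesis."""

import numpy as np
import pytest

from myodti import FiberLabelMap
from myodti.montecarlo import (
    DWIVolume, PGSEProtocol, SubstrateGeometry, b_value_from_gradient,
    pgse_signal, required_gradient, rician_noise, simulate_walkers,
    synthesize_dwi, uniform_directions, save_dwi, load_dwi,
)
from myodti.tensor import fit_tensor_volume
from tests.conftest import make_disc_map


class TestProtocol:
    def test_delta_ordering_enforced(self):
        with pytest.raises(ValueError):
            PGSEProtocol(delta_ms=16.0, Delta_ms=15.0)

    def test_unit_directions_enforced(self):
        with pytest.raises(ValueError):
            PGSEProtocol(directions=np.array([[1.0, 1.0, 0.0]]))

    def test_direction_set_is_unit_norm(self):
        d = uniform_directions(30)
        assert d.shape == (30, 3)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)

    def test_bvals_bvecs_layout(self, protocol):
        assert len(protocol.bvals()) == 35
        assert protocol.bvals()[:5].sum() == 0
        assert np.all(protocol.bvals()[5:] == 500.0)


class TestRequiredGradient:
    def test_zero_b(self):
        assert required_gradient(PGSEProtocol(b_s_per_mm2=0.0)) == 0.0

    def test_round_trip(self, protocol):
        g = required_gradient(protocol)
        assert b_value_from_gradient(g, 3.1, 15.0) == pytest.approx(500.0, rel=1e-10)

    def test_doubling_delta_halves_gradient(self):
        # keep the (Delta - delta/3) factor fixed while doubling delta
        p1 = PGSEProtocol(delta_ms=3.0, Delta_ms=11.0)   # Delta - delta/3 = 10
        p2 = PGSEProtocol(delta_ms=6.0, Delta_ms=12.0)   # same factor
        assert required_gradient(p2) == pytest.approx(required_gradient(p1) / 2)


@pytest.fixture(scope="module")
def free_trajectories():
    sub = SubstrateGeometry(label_map=None, D_intra=2.0, D_extra=2.0, kappa=0.0)
    return simulate_walkers(sub, 4000, 0.1, 18.1, seed=7)


class TestWalkers:
    def test_free_diffusion_msd(self, free_trajectories):
        traj = free_trajectories
        t = traj.duration_ms
        disp = traj.positions[:, -1] - traj.positions[:, 0]
        msd = (disp**2).mean(axis=0)
        se = np.sqrt(2.0) * 2 * 2.0 * t / np.sqrt(traj.n_walkers)
        assert np.all(np.abs(msd - 2 * 2.0 * t) < 3 * se)

    def test_walker_count_conserved(self, free_trajectories):
        assert free_trajectories.positions.shape[0] == 4000
        assert np.isfinite(free_trajectories.positions).all()

    def test_deterministic(self):
        sub = SubstrateGeometry(label_map=None, D_intra=1.0)
        a = simulate_walkers(sub, 50, 0.1, 5.0, seed=3)
        b = simulate_walkers(sub, 50, 0.1, 5.0, seed=3)
        assert np.array_equal(a.positions, b.positions)

    def test_impermeable_disc_no_crossings_and_saturation(self):
        disc = make_disc_map(diameter_um=30, pixel_size_um=0.25, margin_um=5)
        sub = SubstrateGeometry(label_map=disc, D_intra=2.0, D_extra=2.0,
                                kappa=0.0)
        w, h = disc.extent_um()
        a = 15.0
        traj = simulate_walkers(sub, 4000, 0.05, 300.0, seed=5,
                                start_region_um=(w / 2 - a, h / 2 - a,
                                                 w / 2 + a, h / 2 + a))
        # keep only walkers that started inside the disc
        r0 = np.hypot(traj.positions[:, 0, 0] - w / 2,
                      traj.positions[:, 0, 1] - h / 2)
        pos = traj.positions[r0 < a * 0.98]
        assert traj.crossings == 0
        # long-time displacement variance of two independent uniform points
        # on a disc of radius a: a^2/2 per axis
        disp = pos[:, -1] - pos[:, 0]
        var = (disp**2).mean(axis=0)
        assert np.all(np.abs(var - a * a / 2) < 0.08 * a * a / 2)

    def test_step_size_precondition(self):
        disc = make_disc_map()
        disc.meta["params"] = {"mean_diameter_um": 40.0, "gap_width_um": 1.0}
        sub = SubstrateGeometry(label_map=disc, D_intra=2.0)
        with pytest.raises(ValueError, match="dt"):
            simulate_walkers(sub, 10, 1.0, 5.0, seed=0)

    def test_permeability_flux_calibration(self):
        """Equilibrium unidirectional flux across a flat membrane is
        kappa * concentration (validates the crossing-probability map)."""
        L, px = 40.0, 0.5
        n = int(L / px)
        labels = np.zeros((n, n), np.int32)
        labels[:, n // 2:] = 1
        lm = FiberLabelMap(labels=labels, pixel_size_um=px)
        kappa, D, dt = 0.05, 2.0, 0.05
        sub = SubstrateGeometry(label_map=lm, D_intra=D, D_extra=D, kappa=kappa)
        traj = simulate_walkers(sub, 12000, dt, 80.0, seed=4)
        T = traj.duration_ms
        c = 12000 / (L * L)
        # two membrane lines (center + periodic seam), two directions each
        expected = 4 * kappa * c * L * T
        assert traj.crossings == pytest.approx(expected, rel=0.05)


class TestPGSESignal:
    def test_b0_signal_is_one(self, free_trajectories):
        p0 = PGSEProtocol(b_s_per_mm2=0.0)
        assert pgse_signal(free_trajectories, p0, np.array([1.0, 0, 0])) == 1.0

    def test_free_diffusion_attenuation(self, free_trajectories, protocol):
        # b D = 500 s/mm^2 * 2.0e-3 mm^2/s = 1.0
        expected = np.exp(-1.0)
        se = np.sqrt((1 - expected**2) / (2 * free_trajectories.n_walkers))
        for u in ([1.0, 0, 0], [0, 1.0, 0]):
            s = pgse_signal(free_trajectories, protocol, np.array(u))
            assert abs(s - expected) < 3 * se

    def test_axial_direction_unrestricted(self, protocol):
        """Along the fiber axis the signal is the free-diffusion value for
        D_intra regardless of the transverse restriction."""
        disc = make_disc_map(diameter_um=30, pixel_size_um=0.5)
        sub = SubstrateGeometry(label_map=disc, D_intra=1.5, D_extra=1.5,
                                kappa=0.0)
        traj = simulate_walkers(sub, 200, 0.1, 18.1, seed=2)
        s = pgse_signal(traj, protocol, np.array([0.0, 0.0, 1.0]))
        assert s == pytest.approx(np.exp(-0.5 * 1.5), rel=1e-12)

    def test_non_unit_direction_rejected(self, free_trajectories, protocol):
        with pytest.raises(ValueError):
            pgse_signal(free_trajectories, protocol, np.array([1.0, 1.0, 0.0]))

    def test_short_trajectories_rejected(self, protocol):
        sub = SubstrateGeometry(label_map=None, D_intra=1.0)
        traj = simulate_walkers(sub, 10, 0.1, 5.0, seed=0)
        with pytest.raises(ValueError):
            pgse_signal(traj, protocol, np.array([1.0, 0, 0]))


@pytest.fixture(scope="module")
def packed_discs():
    from myodti import PackingParams, generate_fiber_packing

    return generate_fiber_packing(PackingParams(
        region_width_um=120, region_height_um=120, mean_diameter_um=20,
        diameter_cv=0.2, gap_width_um=2.0, pixel_size_um=0.5, seed=9))


class TestRestrictionContrast:

    def _fit_scalars(self, section, D, Delta_ms, seed):
        proto = PGSEProtocol(Delta_ms=Delta_ms,
                             directions=uniform_directions(30))
        dwi = synthesize_dwi([section], {"D_intra": D, "D_extra": D,
                                         "kappa": 0.0},
                             proto, voxel_size_mm=0.12, snr_b0=np.inf,
                             seed=seed, n_walkers_per_voxel=3000, dt_ms=0.1)
        tf = fit_tensor_volume(dwi.signals, dwi.bvals, dwi.bvecs)
        return tf

    def test_isotropic_medium_fa_near_zero(self):
        sub_free = SubstrateGeometry(label_map=None, D_intra=1.5)
        traj = simulate_walkers(sub_free, 3000, 0.1, 18.1, seed=1,
                                start_region_um=(0, 0, 100, 100))
        proto = PGSEProtocol(directions=uniform_directions(30))
        from myodti.montecarlo import _signals_all_directions

        sig = _signals_all_directions(traj, proto)
        tf = fit_tensor_volume(sig[None], proto.bvals(), proto.bvecs())
        assert tf.fa[0] < 0.08  # MC noise floor only

    def test_aligned_fibers_fa_positive_and_grows_with_Delta(self, packed_discs):
        tf_short = self._fit_scalars(packed_discs, 1.5, 10.0, seed=2)
        tf_long = self._fit_scalars(packed_discs, 1.5, 25.0, seed=3)
        assert tf_short.fa[0] > 0.15
        assert tf_long.fa[0] > tf_short.fa[0]

    def test_radial_diffusivity_non_increasing_in_Delta(self, packed_discs):
        tf_short = self._fit_scalars(packed_discs, 1.5, 10.0, seed=2)
        tf_long = self._fit_scalars(packed_discs, 1.5, 25.0, seed=3)
        assert tf_long.rd[0] <= tf_short.rd[0]


class TestSynthesizeDWI:
    def test_noise_free_b0_exactly_one(self, packing_600um, protocol):
        dwi = synthesize_dwi([packing_600um], {"D_intra": 0.5, "D_extra": 0.5},
                             protocol, voxel_size_mm=0.3, snr_b0=np.inf,
                             seed=1, n_walkers_per_voxel=16)
        assert np.all(dwi.signals[..., :5] == 1.0)
        assert dwi.signals.shape == (1, 2, 2, 35)

    def test_rayleigh_background_mean(self):
        sigma = 0.05
        rng = np.random.default_rng(0)
        mags = rician_noise(np.zeros(20000), sigma, rng)
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt(2 - np.pi / 2) / np.sqrt(20000)
        assert abs(mags.mean() - expected) < 3 * se

    def test_intervoxel_noise_level_matches_snr(self, protocol):
        """Uniform substrate: b0 scatter across voxels ~ 1/SNR."""
        lm = FiberLabelMap(labels=np.ones((600, 600), np.int32),
                           pixel_size_um=1.0)
        snr = 100.0
        dwi = synthesize_dwi([lm], {"D_intra": 0.5, "D_extra": 0.5},
                             protocol, voxel_size_mm=0.1, snr_b0=snr,
                             seed=3, n_walkers_per_voxel=8)
        b0 = dwi.signals[..., :5].ravel()
        sd = b0.std(ddof=1)
        se = (1 / snr) / np.sqrt(2 * len(b0))
        assert abs(sd - 1 / snr) < 3 * se

    def test_voxel_larger_than_substrate_fails(self, packing_600um, protocol):
        with pytest.raises(ValueError):
            synthesize_dwi([packing_600um], {}, protocol, voxel_size_mm=1.0,
                           snr_b0=np.inf, seed=0)

    def test_deterministic_given_seed(self, packing_600um, protocol):
        kw = dict(substrate_params={"D_intra": 0.5, "D_extra": 0.5},
                  protocol=protocol, voxel_size_mm=0.3, snr_b0=50.0, seed=11,
                  n_walkers_per_voxel=8)
        a = synthesize_dwi([packing_600um], **kw)
        b = synthesize_dwi([packing_600um], **kw)
        assert np.array_equal(a.signals, b.signals)

    def test_nifti_fsl_roundtrip(self, tmp_path, packing_600um, protocol):
        dwi = synthesize_dwi([packing_600um], {"D_intra": 0.5, "D_extra": 0.5},
                             protocol, voxel_size_mm=0.3, snr_b0=80.0,
                             seed=2, n_walkers_per_voxel=8)
        save_dwi(dwi, tmp_path / "vol")
        loaded = load_dwi(tmp_path / "vol")
        assert np.allclose(loaded.signals, dwi.signals, rtol=1e-6)
        assert np.allclose(loaded.bvals, dwi.bvals)
        assert np.allclose(loaded.bvecs, dwi.bvecs, atol=1e-6)
        assert loaded.voxel_size_mm == pytest.approx(0.3)
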