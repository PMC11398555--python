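"""Monte-Carlo restricted diffusion and PGSE signal synthesis.

Water diffusion in muscle is simulated as a 2D random walk in the
transverse plane of a periodic fiber packing, composed with analytic free
diffusion along the fiber axis (fibers are translationally invariant along
their length, so the axial component is exactly Gaussian).  Membranes are
the boundaries between raster labels; a walker attempting to cross one is
transmitted with probability p = kappa * sqrt(pi * dt / D) (the standard
mapping for Gaussian steps, derived by equating the one-sided Monte-Carlo
attempt flux with the membrane flux kappa * c) and is otherwise rejected
in place, which preserves the uniform equilibrium distribution.

Internal units: length um, time ms, diffusivity um^2/ms
(1e-3 mm^2/s = 1 um^2/ms), b-value carried as s/mm^2 at the interface
(1 s/mm^2 = 1e-3 ms/um^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .substrate import FiberLabelMap

GAMMA_H = 267.513e6  # gyromagnetic ratio of 1H, rad s^-1 T^-1


# --------------------------------------------------------------------------
# protocol

@dataclass
class PGSEProtocol:
    """Two-lobe pulsed-gradient spin-echo diffusion encoding.

    delta_ms is the gradient lobe duration, Delta_ms the lobe separation
    (the diffusion time), b the diffusion weighting in s/mm^2.
    """

    delta_ms: float = 3.1
    Delta_ms: float = 15.0
    b_s_per_mm2: float = 500.0
    directions: np.ndarray | None = None
    n_b0: int = 5
    TE_ms: float = 25.0
    TR_ms: float = 1200.0
    gamma: float = GAMMA_H

    def __post_init__(self) -> None:
        if self.directions is None:
            self.directions = uniform_directions(30)
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if not (self.delta_ms < self.Delta_ms):
            raise ValueError("gradient duration delta must be shorter than separation Delta")
        if self.b_s_per_mm2 < 0:
            raise ValueError("b must be non-negative")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("all gradient directions must be unit vectors")

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    @property
    def b_um2_per_ms(self) -> float:
        return self.b_s_per_mm2 * 1e-3

    def bvals(self) -> np.ndarray:
        """Per-image b values (b0 images first), s/mm^2."""
        return np.concatenate(
            [np.zeros(self.n_b0), np.full(self.n_directions, self.b_s_per_mm2)]
        )

    def bvecs(self) -> np.ndarray:
        """Per-image unit directions (zero vectors for the b0 images)."""
        return np.vstack([np.zeros((self.n_b0, 3)), self.directions])


def uniform_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the hemisphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = i / n  # hemisphere: z in (0, 1)
    r = np.sqrt(1 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def required_gradient(protocol: PGSEProtocol) -> float:
    """Gradient amplitude g (T/um) satisfying b = gamma^2 g^2 delta^2 (Delta - delta/3)."""
    if protocol.b_s_per_mm2 == 0:
        return 0.0
    b_si = protocol.b_s_per_mm2 * 1e6  # s/m^2
    delta = protocol.delta_ms * 1e-3
    Delta = protocol.Delta_ms * 1e-3
    g_si = np.sqrt(b_si / (protocol.gamma**2 * delta**2 * (Delta - delta / 3.0)))
    return float(g_si * 1e-6)  # T/m -> T/um


def b_value_from_gradient(g_T_per_um: float, delta_ms: float, Delta_ms: float,
                          gamma: float = GAMMA_H) -> float:
    """Inverse of :func:`required_gradient`; returns b in s/mm^2."""
    g_si = g_T_per_um * 1e6
    delta = delta_ms * 1e-3
    Delta = Delta_ms * 1e-3
    return float(gamma**2 * g_si**2 * delta**2 * (Delta - delta / 3.0) * 1e-6)


# --------------------------------------------------------------------------
# substrate and walkers

@dataclass
class SubstrateGeometry:
    """Periodic 2D fiber packing extruded along the fiber axis.

    ``label_map is None`` means a uniform unbounded medium with
    diffusivity ``D_intra``.  ``kappa`` is the sarcolemmal permeability;
    any boundary between two different labels (fiber-fiber or
    fiber-background) counts as one membrane.
    """

    label_map: FiberLabelMap | None = None
    D_intra: float = 1.6  # um^2/ms
    D_extra: float = 1.6
    kappa: float = 0.05  # um/ms
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if self.D_intra <= 0 or self.D_extra <= 0:
            raise ValueError("diffusivities must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        self.axis_direction /= np.linalg.norm(self.axis_direction)


@dataclass
class Trajectories:
    """Transverse walker positions (n_walkers, n_steps + 1, 2), um, unwrapped."""

    positions: np.ndarray
    dt_ms: float
    crossings: int
    substrate: SubstrateGeometry

    @property
    def n_walkers(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_ms(self) -> float:
        return (self.positions.shape[1] - 1) * self.dt_ms


@njit(cache=True)
def _walk_kernel(labels, px, D_in, D_ex, kappa, dt, n_steps, x0, seed):  # pragma: no cover
    np.random.seed(seed)
    nw = x0.shape[0]
    ny, nx = labels.shape
    Lx = nx * px
    Ly = ny * px
    pos = np.empty((nw, n_steps + 1, 2))
    sig_in = np.sqrt(2.0 * D_in * dt)
    sig_ex = np.sqrt(2.0 * D_ex * dt)
    p_in = min(1.0, kappa * np.sqrt(np.pi * dt / D_in))
    p_ex = min(1.0, kappa * np.sqrt(np.pi * dt / D_ex))
    crossings = 0
    for w in range(nw):
        x = x0[w, 0]
        y = x0[w, 1]
        pos[w, 0, 0] = x
        pos[w, 0, 1] = y
        xw = x - Lx * np.floor(x / Lx)
        yw = y - Ly * np.floor(y / Ly)
        lab = labels[min(int(yw / px), ny - 1), min(int(xw / px), nx - 1)]
        for k in range(n_steps):
            if lab > 0:
                sig = sig_in
                p_cross = p_in
            else:
                sig = sig_ex
                p_cross = p_ex
            nxp = x + sig * np.random.normal()
            nyp = y + sig * np.random.normal()
            xw = nxp - Lx * np.floor(nxp / Lx)
            yw = nyp - Ly * np.floor(nyp / Ly)
            new_lab = labels[min(int(yw / px), ny - 1), min(int(xw / px), nx - 1)]
            if new_lab == lab:
                x = nxp
                y = nyp
            else:
                if np.random.random() < p_cross:
                    x = nxp
                    y = nyp
                    lab = new_lab
                    crossings += 1
                # else: rejected attempt, walker stays in place this step
            pos[w, k + 1, 0] = x
            pos[w, k + 1, 1] = y
    return pos, crossings


@njit(cache=True)
def _walk_kernel_free(D, dt, n_steps, x0, seed):  # pragma: no cover
    np.random.seed(seed)
    nw = x0.shape[0]
    pos = np.empty((nw, n_steps + 1, 2))
    sig = np.sqrt(2.0 * D * dt)
    for w in range(nw):
        x = x0[w, 0]
        y = x0[w, 1]
        pos[w, 0, 0] = x
        pos[w, 0, 1] = y
        for k in range(n_steps):
            x += sig * np.random.normal()
            y += sig * np.random.normal()
            pos[w, k + 1, 0] = x
            pos[w, k + 1, 1] = y
    return pos


def _check_step_size(substrate: SubstrateGeometry, dt_ms: float) -> None:
    step = np.sqrt(4.0 * max(substrate.D_intra, substrate.D_extra) * dt_ms)
    limits = []
    if substrate.label_map is not None:
        lm = substrate.label_map
        params = lm.meta.get("params", {}) if isinstance(lm.meta, dict) else {}
        mean_d = params.get("mean_diameter_um")
        if mean_d:
            limits.append(("mean_diameter/10", mean_d / 10.0))
        gap = params.get("gap_width_um")
        if gap:
            limits.append(("gap_width", gap))
    for name, lim in limits:
        if step > lim:
            dmax = lim**2 / (4.0 * max(substrate.D_intra, substrate.D_extra))
            raise ValueError(
                f"step length sqrt(4 D dt) = {step:.3g} um exceeds {name} = {lim:.3g} um; "
                f"use dt <= {dmax:.4g} ms"
            )


def simulate_walkers(
    substrate: SubstrateGeometry,
    n_walkers: int,
    dt_ms: float,
    duration_ms: float,
    seed: int,
    start_region_um: tuple[float, float, float, float] | None = None,
) -> Trajectories:
    """Random-walk trajectories on the substrate.

    Walkers start uniformly in ``start_region_um = (x0, y0, x1, y1)``
    (default: the full raster, or the unit box for a free medium), take
    Gaussian steps with the local diffusivity, attempt membrane crossings
    with the kappa-derived transmission probability, and wrap periodically.
    Deterministic for a given seed.
    """
    _check_step_size(substrate, dt_ms)
    n_steps = int(np.ceil(duration_ms / dt_ms - 1e-9))
    rng = np.random.default_rng(seed)
    if substrate.label_map is None:
        if start_region_um is None:
            start_region_um = (0.0, 0.0, 1.0, 1.0)
        x0 = np.column_stack([
            rng.uniform(start_region_um[0], start_region_um[2], n_walkers),
            rng.uniform(start_region_um[1], start_region_um[3], n_walkers),
        ])
        pos = _walk_kernel_free(substrate.D_intra, dt_ms, n_steps, x0,
                                int(rng.integers(2**31 - 1)))
        return Trajectories(pos, dt_ms, 0, substrate)

    lm = substrate.label_map
    w_um, h_um = lm.extent_um()
    if start_region_um is None:
        start_region_um = (0.0, 0.0, w_um, h_um)
    x0 = np.column_stack([
        rng.uniform(start_region_um[0], start_region_um[2], n_walkers),
        rng.uniform(start_region_um[1], start_region_um[3], n_walkers),
    ])
    pos, crossings = _walk_kernel(
        lm.labels, lm.pixel_size_um, substrate.D_intra, substrate.D_extra,
        substrate.kappa, dt_ms, n_steps, x0, int(rng.integers(2**31 - 1)),
    )
    return Trajectories(pos, dt_ms, int(crossings), substrate)


# --------------------------------------------------------------------------
# PGSE signal

def _waveform_signs(protocol: PGSEProtocol, dt_ms: float, n_steps: int) -> np.ndarray:
    """Per-step gradient signs of the two-lobe waveform (+1, 0, -1)."""
    t_mid = (np.arange(n_steps) + 0.5) * dt_ms
    s = np.zeros(n_steps)
    s[t_mid < protocol.delta_ms] = 1.0
    lobe2 = (t_mid >= protocol.Delta_ms) & (t_mid < protocol.Delta_ms + protocol.delta_ms)
    s[lobe2] = -1.0
    n_pos = (s > 0).sum()
    n_neg = (s < 0).sum()
    if n_neg == 0 or n_pos == 0:
        raise ValueError("trajectory sampling does not cover both gradient lobes")
    s[lobe2] *= n_pos / n_neg  # enforce zeroth-moment balance on the grid
    return s


def _phase_scale(b_um2_per_ms: float, signs: np.ndarray, dt_ms: float) -> float:
    """Phase prefactor c such that the discrete phase variance equals 2 b D.

    For left-endpoint phase accumulation, Var(phi) = c^2 * 2 D dt * sum_j A_j^2
    with A_j the tail sums of the waveform signs; solving for c makes the
    discretized waveform carry exactly the requested b.
    """
    tail = np.cumsum(signs[::-1])[::-1]
    A = np.concatenate([tail[1:], [0.0]])  # A_j = sum_{k > j} s_k
    denom = dt_ms * float((A * A).sum())
    if denom <= 0:
        return 0.0
    return float(np.sqrt(b_um2_per_ms / denom))


def pgse_signal(traj: Trajectories, protocol: PGSEProtocol,
                direction: np.ndarray) -> float:
    """Normalized PGSE magnitude signal for one gradient direction.

    Transverse phase is accumulated over the recorded walk; the axial
    component (free diffusion along the fiber axis at D_intra) contributes
    the exact Gaussian factor exp(-b cos^2(theta) D_axial).  b = 0 returns
    exactly 1.
    """
    u = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise ValueError("direction must be unit-norm")
    if protocol.b_s_per_mm2 == 0:
        return 1.0
    if traj.duration_ms < protocol.Delta_ms + protocol.delta_ms - 1e-9:
        raise ValueError("trajectories do not cover the full waveform [0, Delta + delta]")
    n_steps = traj.positions.shape[1] - 1
    signs = _waveform_signs(protocol, traj.dt_ms, n_steps)
    c = _phase_scale(protocol.b_um2_per_ms, signs, traj.dt_ms)
    axis = traj.substrate.axis_direction
    u_ax = float(u @ axis)
    qx = traj.positions[:, :n_steps, 0] @ signs * c
    qy = traj.positions[:, :n_steps, 1] @ signs * c
    phase = u[0] * qx + u[1] * qy
    transverse = np.abs(np.exp(1j * phase).mean())
    axial = np.exp(-protocol.b_um2_per_ms * u_ax**2 * traj.substrate.D_intra)
    return float(transverse * axial)


def _signals_all_directions(traj: Trajectories, protocol: PGSEProtocol) -> np.ndarray:
    """Noiseless signals for every image in the protocol (b0s first)."""
    n_steps = traj.positions.shape[1] - 1
    signs = _waveform_signs(protocol, traj.dt_ms, n_steps)
    c = _phase_scale(protocol.b_um2_per_ms, signs, traj.dt_ms)
    qx = traj.positions[:, :n_steps, 0] @ signs * c
    qy = traj.positions[:, :n_steps, 1] @ signs * c
    dirs = protocol.directions
    phase = np.outer(qx, dirs[:, 0]) + np.outer(qy, dirs[:, 1])
    transverse = np.abs(np.exp(1j * phase).mean(axis=0))
    u_ax = dirs @ traj.substrate.axis_direction
    axial = np.exp(-protocol.b_um2_per_ms * u_ax**2 * traj.substrate.D_intra)
    return np.concatenate([np.ones(protocol.n_b0), transverse * axial])


# --------------------------------------------------------------------------
# DWI synthesis

@dataclass
class DWIVolume:
    """Stack of diffusion-weighted images on a voxel grid.

    ``signals`` has shape (nz, ny, nx, n_images) with the b0 images first;
    ``noise_sigma`` is the Gaussian channel noise level relative to the
    noiseless b0 signal (Rician magnitude noise).
    """

    signals: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size_mm: float
    noise_sigma: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim == 3:
            self.signals = self.signals[None]
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")
        if len(self.bvals) != self.signals.shape[-1] or len(self.bvecs) != len(self.bvals):
            raise ValueError("bvals/bvecs length must match the image count")


def rician_noise(signals: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (S + n1, n2) with two independent Gaussian channels."""
    if sigma == 0:
        return signals.copy()
    n1 = rng.normal(0.0, sigma, signals.shape)
    n2 = rng.normal(0.0, sigma, signals.shape)
    return np.sqrt((signals + n1) ** 2 + n2**2)


def synthesize_dwi(
    sections: list[FiberLabelMap] | FiberLabelMap,
    substrate_params: dict | None = None,
    protocol: PGSEProtocol | None = None,
    voxel_size_mm: float = 0.5,
    snr_b0: float = np.inf,
    seed: int = 0,
    n_walkers_per_voxel: int = 256,
    dt_ms: float = 0.1,
) -> DWIVolume:
    """Synthesize a diffusion-weighted volume from fiber packings.

    Each section becomes one slice; each voxel's signal comes from walkers
    seeded uniformly in that voxel's sub-region of the packing.  Rician
    noise is applied at the requested b0 SNR (sigma = 1/snr relative to
    the unit b0 signal); the b0 image is replicated ``protocol.n_b0``
    times with independent noise.  Per-voxel and noise random streams are
    split off one master seed, so results are reproducible and independent
    of evaluation order.
    """
    if protocol is None:
        protocol = PGSEProtocol()
    if isinstance(sections, FiberLabelMap):
        sections = [sections]
    sp = substrate_params or {}
    voxel_um = voxel_size_mm * 1000.0

    w_um, h_um = sections[0].extent_um()
    nvx = int(w_um / voxel_um + 1e-9)
    nvy = int(h_um / voxel_um + 1e-9)
    if nvx < 1 or nvy < 1:
        raise ValueError(
            f"voxel size {voxel_size_mm} mm exceeds the substrate extent "
            f"{w_um / 1000:.3g} x {h_um / 1000:.3g} mm"
        )
    n_img = protocol.n_b0 + protocol.n_directions
    duration = protocol.Delta_ms + protocol.delta_ms

    ss = np.random.SeedSequence(seed)
    walk_seeds, noise_seed = ss.spawn(2)
    vox_seeds = walk_seeds.spawn(len(sections) * nvy * nvx)

    signals = np.empty((len(sections), nvy, nvx, n_img))
    k = 0
    for iz, section in enumerate(sections):
        substrate = SubstrateGeometry(label_map=section, **sp)
        for iy in range(nvy):
            for ix in range(nvx):
                region = (ix * voxel_um, iy * voxel_um,
                          (ix + 1) * voxel_um, (iy + 1) * voxel_um)
                traj = simulate_walkers(
                    substrate, n_walkers_per_voxel, dt_ms, duration,
                    seed=int(vox_seeds[k].generate_state(1)[0] % (2**31 - 1)),
                    start_region_um=region,
                )
                signals[iz, iy, ix] = _signals_all_directions(traj, protocol)
                k += 1

    sigma = 0.0 if np.isinf(snr_b0) else 1.0 / snr_b0
    if sigma > 0:
        rng = np.random.default_rng(noise_seed)
        signals = rician_noise(signals, sigma, rng)

    return DWIVolume(
        signals=signals,
        bvals=protocol.bvals(),
        bvecs=protocol.bvecs(),
        voxel_size_mm=voxel_size_mm,
        noise_sigma=sigma,
        meta={"snr_b0": None if np.isinf(snr_b0) else snr_b0,
              "n_walkers_per_voxel": n_walkers_per_voxel, "dt_ms": dt_ms,
              "seed": seed},
    )


# --------------------------------------------------------------------------
# NIfTI + FSL-style I/O

def save_dwi(dwi: DWIVolume, stem) -> None:
    """Write NIfTI (.nii.gz) plus FSL-style ``bvals``/``bvecs`` text files
    (3 x N, column per volume)."""
    import nibabel as nib
    from pathlib import Path

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    # NIfTI axis order (x, y, z, img)
    data = np.transpose(dwi.signals, (2, 1, 0, 3))
    affine = np.diag([dwi.voxel_size_mm, dwi.voxel_size_mm, dwi.voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(stem) + ".nii.gz")
    np.savetxt(stem.parent / (stem.name + ".bval"), dwi.bvals[None], fmt="%.1f")
    np.savetxt(stem.parent / (stem.name + ".bvec"), dwi.bvecs.T, fmt="%.6f")


def load_dwi(stem) -> DWIVolume:
    import nibabel as nib
    from pathlib import Path

    stem = Path(stem)
    img = nib.load(str(stem) + ".nii.gz")
    data = np.asarray(img.dataobj, dtype=float)
    signals = np.transpose(data, (2, 1, 0, 3))
    bvals = np.loadtxt(stem.parent / (stem.name + ".bval")).ravel()
    bvecs = np.loadtxt(stem.parent / (stem.name + ".bvec")).reshape(3, -1).T
    voxel = float(img.header.get_zooms()[0])
    return DWIVolume(signals=signals, bvals=bvals, bvecs=bvecs, voxel_size_mm=voxel)
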