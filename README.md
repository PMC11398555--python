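# myodti

Can scalar diffusion-tensor MRI (DTI) metrics read out skeletal-muscle
microstructure?  For rotator cuff muscle imaged with a spin-echo
pulsed-gradient protocol (b = 500 s/mm², δ/Δ = 3.1/15 ms), the answer turns
on the diffusion length ℓ_D ≈ √(D·Δ): water in cooled, fixed muscle moves
only ~2–3 μm during the encoding, an order of magnitude less than the
30–70 μm myofiber diameter, so the sarcolemma is barely felt and pixel-wise
correlations between DTI metrics (FA, MD, RD) and histological morphometry
(fiber diameter, cross-sectional area, surface-to-volume ratio) come out
negligible.

`myodti` makes that whole argument computable without any wet-lab data.  It
provides, as one tested pipeline:

- **`myodti.substrate`** — synthetic transverse muscle cross-sections:
  space-filling Laguerre (power-diagram) fiber packings with lognormal size
  distributions, endomysial gaps, shrinkage artifacts and spatial size
  gradients, rasterized at slide-scanner resolution.
- **`myodti.morphometry`** — per-fiber diameter/area/perimeter/S/V from
  label rasters (Crofton perimeters, S/V = P/A under the extruded-cylinder
  model), per-pixel metric maps, and gap-compensating masked-mean
  down-sampling with histogram-consistency checks.
- **`myodti.montecarlo`** — Monte-Carlo random walks with permeable
  membranes (transmission probability calibrated against the flat-membrane
  flux κ·Δc), finite-δ PGSE phase accumulation, and Rician-noise DWI
  synthesis at 0.25/0.5 mm voxels.
- **`myodti.tensor`** — signal-weighted linear least-squares tensor fits,
  FA/MD/RD maps, Marchenko–Pastur local-PCA denoising, SNR measurement,
  and the Monte-Carlo mapping b0 SNR → metric accuracy.
- **`myodti.relaxometry`** — mono-exponential T1 (variable TR) and T2
  (CPMG) fits, TE/TR selection helpers, and the diffusion-length
  calculator.
- **`myodti.registration`** — muscle-boundary extraction, thin-plate-spline
  boundary registration, grid resampling, and pooled pixel-wise Pearson
  correlation with the conventional interpretation bands
  (0–0.29 negligible … 0.9–1.0 very high).
- **`myodti.pipeline`** — the end-to-end experiment: study-design
  bookkeeping (rats × shoulders × muscles × sections), QC exclusions,
  and the paired 0.25/0.5 mm synthetic acquisition.

## Worked example

```python
import numpy as np
from myodti import (PackingParams, generate_fiber_packing, fiber_stats,
                    paint_morphometry_maps, downsample_masked_mean,
                    PGSEProtocol, synthesize_dwi, fit_dwi)

params = PackingParams(region_width_um=1000, region_height_um=1000,
                       mean_diameter_um=30, diameter_cv=0.3,
                       gap_width_um=3.0, pixel_size_um=2.5, seed=7)
section = generate_fiber_packing(params)
stats = fiber_stats(section)
print(f"{section.n_fibers} fibers, mean diameter "
      f"{stats.equiv_diameter_um.mean():.1f} um, mean S/V "
      f"{stats.sv_ratio_per_um.mean():.4f} /um")

dwi = synthesize_dwi([section], {"D_intra": 0.417, "D_extra": 0.417,
                                 "kappa": 0.05},
                     PGSEProtocol(), voxel_size_mm=0.5, snr_b0=156.0,
                     seed=7, n_walkers_per_voxel=256)
tf = fit_dwi(dwi)
print(f"voxel grid {tf.fa.shape[1:]}: FA {tf.fa.mean():.3f}, "
      f"MD {tf.md.mean()*1e3:.3f} um^2/ms, RD {tf.rd.mean()*1e3:.3f} um^2/ms")
```

prints

```
1101 fibers, mean diameter 27.9 um, mean S/V 0.1777 /um
voxel grid (2, 2): FA 0.124, MD 0.379 um^2/ms, RD 0.358 um^2/ms
```

The packing recovers the requested ~30 μm size statistics (the slight
deficit at this coarse 2.5 μm raster comes from gap quantization, see
`docs/methods.md`); the fitted MD of ~0.38 μm²/ms sits a little below the
intrinsic 0.417 μm²/ms because the sarcolemma weakly restricts the
transverse walk, and the FA of ~0.12 at this walker count is mostly
Monte-Carlo and Rician noise — exactly the weak-sensitivity regime the
package is built to quantify.

The same stages are scriptable from the shell via the `myodti` CLI
(`simulate-histo`, `morpho`, `simulate-dwi`, `fit-dti`, `relax`,
`diffusion-length`, `correlate`, `run-experiment`); try
`myodti --help`.

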