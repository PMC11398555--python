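"""Synthetic muscle cross-section generator.

Produces label rasters of transverse myofiber packings with controllable
size statistics, endomysial gaps, shrinkage artifacts and spatial size
gradients.  The packing is a Laguerre (power) diagram seeded by dart
throwing and refined by a few Lloyd/weight iterations so that cell areas
track per-fiber lognormal targets; each cell is then eroded to open the
endomysial gap and to emulate preparation shrinkage.

Conventions shared by the whole package: rasters are row-major with the
origin at the top-left corner and pixel centers at ``(i + 0.5, j + 0.5) *
pixel_size``; label 0 is background (gap / tendon), fiber IDs start at 1
and are contiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class PackingParams:
    """Parameters of a synthetic fiber packing.

    ``mean_diameter_um`` / ``diameter_cv`` describe the *fiber* (post-gap,
    pre-shrinkage) equivalent-circle diameter distribution, which is
    lognormal (equivalently lognormal on area: the square of a lognormal
    variate is lognormal).  ``gradient_slope`` is the fractional change in
    mean diameter per mm along the raster x axis.  Healthy myofibers are
    roughly 30-70 um across; post-injury atrophy shifts the distribution
    toward smaller sizes, hence the 30 um default.
    """

    region_width_um: float = 300.0
    region_height_um: float = 300.0
    mean_diameter_um: float = 30.0
    diameter_cv: float = 0.3
    gap_width_um: float = 3.0
    shrink_fraction: float = 0.0
    gradient_slope: float = 0.0
    pixel_size_um: float = 0.22
    seed: int = 0

    def validate(self) -> None:
        if self.mean_diameter_um <= 0:
            raise ValueError("mean_diameter_um must be positive")
        if not (0 <= self.diameter_cv < 1):
            raise ValueError("diameter_cv must lie in [0, 1)")
        if not (0 <= self.shrink_fraction < 0.5):
            raise ValueError("shrink_fraction must lie in [0, 0.5)")
        if self.gap_width_um < 0:
            raise ValueError("gap_width_um must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if min(self.region_width_um, self.region_height_um) < 4 * self.mean_diameter_um:
            raise ValueError(
                "region dimensions must be at least 4x the mean fiber diameter; "
                f"got {self.region_width_um} x {self.region_height_um} um for "
                f"mean diameter {self.mean_diameter_um} um"
            )


@dataclass
class FiberLabelMap:
    """Integer raster assigning each pixel to a fiber ID or background.

    ``labels`` is 2D int32; 0 marks background (gap/tendon), IDs >= 1 mark
    fibers.  ``edge_fiber_ids`` lists fibers whose generating cell touched
    the raster border (clipped, hence biased, geometry).
    """

    labels: np.ndarray
    pixel_size_um: float
    provenance: str = "synthetic"
    position_mm: float = 0.0
    edge_fiber_ids: tuple[int, ...] = ()
    dropped_fiber_ids: tuple[int, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D raster")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_fibers(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the raster in um."""
        h, w = self.labels.shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)


def _draw_seed_points(params: PackingParams, rng: np.random.Generator):
    """Dart-throw fiber centers with per-fiber lognormal cell diameters.

    The *cell* diameter is the fiber diameter plus the gap width, so that
    after gap erosion the measured fiber diameters recover the requested
    distribution.  Returns (xy positions um, cell radii um, fiber target
    radii um).
    """
    width, height = params.region_width_um, params.region_height_um
    area = width * height
    m, cv = params.mean_diameter_um, params.diameter_cv
    if cv > 0:
        sigma2 = np.log1p(cv * cv)
        mu = np.log(m) - sigma2 / 2.0
    else:
        sigma2, mu = 0.0, np.log(m)
    sigma = np.sqrt(sigma2)

    # uniform hash grid for neighbor rejection
    cell = 2.0 * (m + params.gap_width_um)
    grid: dict[tuple[int, int], list[int]] = {}
    xs: list[float] = []
    ys: list[float] = []
    cell_r: list[float] = []
    fib_r: list[float] = []
    total = 0.0
    spacing = 0.82  # accepted center distance as a fraction of radius sum
    while total < area:
        # draw the diameter ONCE, then retry positions until it fits:
        # redrawing on rejection would size-bias the packing toward small
        # fibers (small discs fit leftover gaps more easily)
        z = rng.standard_normal() if cv > 0 else 0.0
        fails = 0
        while True:
            x = rng.uniform(0.0, width)
            y = rng.uniform(0.0, height)
            local_mean = m * (1.0 + params.gradient_slope * (x - width / 2.0) / 1000.0)
            local_mean = max(local_mean, 0.2 * m)
            d = float(np.exp(mu + np.log(local_mean / m) + sigma * z))
            rc = (d + params.gap_width_um) / 2.0
            gi, gj = int(x / cell), int(y / cell)
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for k in grid.get((gi + di, gj + dj), ()):
                        dx, dy = x - xs[k], y - ys[k]
                        lim = spacing * (rc + cell_r[k])
                        if dx * dx + dy * dy < lim * lim:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                break
            fails += 1
            if fails > 300:
                spacing *= 0.95  # relax to guarantee termination
                fails = 0
        k = len(xs)
        xs.append(x)
        ys.append(y)
        cell_r.append(rc)
        fib_r.append(d / 2.0)
        grid.setdefault((gi, gj), []).append(k)
        total += np.pi * rc * rc
    if not xs:
        raise RuntimeError("packing produced no fibers")
    return (
        np.column_stack([np.asarray(xs), np.asarray(ys)]),
        np.asarray(cell_r),
        np.asarray(fib_r),
    )


def _power_assign(points: np.ndarray, weights: np.ndarray, px_xy: np.ndarray) -> np.ndarray:
    """Assign pixels to power-diagram cells via the 3D lifting trick.

    argmin_i |p-s_i|^2 - w_i equals the 3D nearest neighbor of (p, 0)
    among points (s_i, sqrt(max(w) - w_i)).
    """
    lift = np.sqrt(weights.max() - weights)
    pts3 = np.column_stack([points, lift])
    q = np.column_stack([px_xy, np.zeros(len(px_xy))])
    tree = cKDTree(pts3)
    _, idx = tree.query(q, workers=-1)
    return idx


def generate_fiber_packing(params: PackingParams) -> FiberLabelMap:
    """Generate a space-filling polygonal fiber packing as a label raster.

    Deterministic for a given ``params`` (including ``seed``).  Raises
    ``ValueError`` for infeasible parameters (e.g. mean diameter larger
    than the region).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size_um
    nx = max(1, int(round(params.region_width_um / px)))
    ny = max(1, int(round(params.region_height_um / px)))

    points, cell_r, fib_r = _draw_seed_points(params, rng)
    n = len(points)
    target_area = np.pi * cell_r**2
    # rescale targets so they tile the region exactly
    target_area *= (nx * px) * (ny * px) / target_area.sum()
    weights = cell_r**2

    # iterate on a decimated grid (area bookkeeping only needs ~10 px per
    # fiber diameter); the final assignment runs at full resolution
    dec = max(1, int(round(params.mean_diameter_um / (8.0 * px))))
    px_c = px * dec
    nxc, nyc = max(1, nx // dec), max(1, ny // dec)
    jj, ii = np.meshgrid(np.arange(nxc), np.arange(nyc))
    px_xy_c = np.column_stack([(jj.ravel() + 0.5) * px_c, (ii.ravel() + 0.5) * px_c])

    # iterate until cell areas are close to their lognormal targets
    # (capacity-constrained power diagram, additive weight updates)
    min_iter, max_iter, n_lloyd = 9, 30, 2
    for it in range(max_iter):
        idx = _power_assign(points, weights, px_xy_c)
        areas = np.bincount(idx, minlength=n) * px_c * px_c
        if it < n_lloyd:
            cx = np.bincount(idx, weights=px_xy_c[:, 0], minlength=n)
            cy = np.bincount(idx, weights=px_xy_c[:, 1], minlength=n)
            nz = areas > 0
            points[nz, 0] = cx[nz] / (areas[nz] / (px_c * px_c))
            points[nz, 1] = cy[nz] / (areas[nz] / (px_c * px_c))
        rel_err = np.abs(areas - target_area) / target_area
        if it >= min_iter - 1 and rel_err.max() < 0.08:
            break
        weights = weights + 0.8 * (target_area - areas) / np.pi
        empty = areas == 0
        weights[empty] += target_area[empty] / np.pi

    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    px_xy = np.column_stack([(jj.ravel() + 0.5) * px, (ii.ravel() + 0.5) * px])
    labels_flat = _power_assign(points, weights, px_xy)
    labels = labels_flat.reshape(ny, nx).astype(np.int32) + 1

    # erode each cell: half the endomysial gap plus shrinkage proportional
    # to the fiber's own radius
    margin = np.zeros(n + 1)
    margin[1:] = params.gap_width_um / 2.0 + params.shrink_fraction * fib_r
    if margin.max() > 0:
        # per-fiber EDT to the nearest different-label pixel; the true cell
        # edge runs half a pixel beyond same-label pixel centers, so the
        # distance of a pixel center to the edge is (EDT - 0.5) * px
        eroded = np.zeros_like(labels)
        pad = int(np.ceil(margin.max() / px)) + 2
        for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
            if sl is None:
                continue
            r = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, ny))
            c = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, nx))
            mask = labels[r, c] == lab
            dist = (ndimage.distance_transform_edt(mask) - 0.5) * px
            keep = mask & (dist >= margin[lab])
            # erosion of a thin raster cell can pinch off fragments; keep
            # only the largest piece so fibers stay single components
            comp, ncomp = ndimage.label(keep)
            if ncomp > 1:
                sizes = np.bincount(comp.ravel())[1:]
                keep = comp == (np.argmax(sizes) + 1)
            eroded[r, c][keep] = lab
        labels = eroded

    # flag border-touching cells, then relabel contiguously
    border_ids = np.unique(
        np.concatenate(
            [labels_flat.reshape(ny, nx)[0], labels_flat.reshape(ny, nx)[-1],
             labels_flat.reshape(ny, nx)[:, 0], labels_flat.reshape(ny, nx)[:, -1]]
        )
    ) + 1
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    labels = remap[labels]
    edge_ids = tuple(int(remap[i]) for i in border_ids if remap[i] > 0)

    return FiberLabelMap(
        labels=labels,
        pixel_size_um=px,
        provenance="synthetic",
        edge_fiber_ids=edge_ids,
        meta={"params": asdict(params), "n_cells": int(n)},
    )


def generate_section_series(
    params: PackingParams, n_sections: int, section_spacing_mm: float
) -> list[FiberLabelMap]:
    """Generate a series of sections along the muscle, tagged with position.

    Sections share the muscle identity through the master seed; the mean
    fiber diameter of section ``s`` is scaled by
    ``1 + gradient_slope * position_mm``, emulating proximo-distal size
    trends (e.g. toward the myotendinous junction).  A single section is
    identical to ``generate_fiber_packing`` with the same parameters.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    out = []
    for s in range(n_sections):
        z_mm = s * section_spacing_mm
        scale = 1.0 + params.gradient_slope * z_mm
        if scale <= 0:
            raise ValueError("gradient over the section series drives diameter negative")
        if s == 0:
            p = params
        else:
            p = PackingParams(
                **{
                    **asdict(params),
                    "mean_diameter_um": params.mean_diameter_um * scale,
                    "seed": int((params.seed + 7919 * s) % (2**31 - 1)),
                }
            )
        m = generate_fiber_packing(p)
        m.position_mm = z_mm
        out.append(m)
    return out


def rasterize_at(label_map: FiberLabelMap, pixel_size_um: float) -> FiberLabelMap:
    """Resample a label map to a coarser grid by nearest-neighbor lookup.

    Upsampling (target finer than source) is refused.  Fibers that vanish
    (fall below one pixel) are listed in ``dropped_fiber_ids`` of the
    result; surviving IDs are preserved for correspondence with the source.
    """
    src = label_map.pixel_size_um
    if pixel_size_um < src - 1e-12:
        raise ValueError("rasterize_at only coarsens; target pixel must be >= source pixel")
    if abs(pixel_size_um - src) < 1e-12:
        return FiberLabelMap(
            labels=label_map.labels.copy(),
            pixel_size_um=src,
            provenance=label_map.provenance,
            position_mm=label_map.position_mm,
            edge_fiber_ids=label_map.edge_fiber_ids,
            meta=dict(label_map.meta),
        )
    ratio = pixel_size_um / src
    ny, nx = label_map.labels.shape
    ny2 = max(1, int(ny / ratio))
    nx2 = max(1, int(nx / ratio))
    ri = np.minimum((np.arange(ny2) + 0.5) * ratio, ny - 1).astype(int)
    rj = np.minimum((np.arange(nx2) + 0.5) * ratio, nx - 1).astype(int)
    labels = label_map.labels[np.ix_(ri, rj)]
    before = set(np.unique(label_map.labels)) - {0}
    after = set(np.unique(labels)) - {0}
    dropped = tuple(sorted(int(i) for i in before - after))
    return FiberLabelMap(
        labels=labels.astype(np.int32),
        pixel_size_um=pixel_size_um,
        provenance=label_map.provenance,
        position_mm=label_map.position_mm,
        edge_fiber_ids=label_map.edge_fiber_ids,
        dropped_fiber_ids=dropped,
        meta=dict(label_map.meta),
    )


def save_label_map(label_map: FiberLabelMap, path: str | Path) -> None:
    """Write a label raster as 16/32-bit TIFF plus a JSON sidecar."""
    import tifffile

    path = Path(path)
    labels = label_map.labels
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))
    sidecar = {
        "pixel_size_um": label_map.pixel_size_um,
        "provenance": label_map.provenance,
        "position_mm": label_map.position_mm,
        "edge_fiber_ids": list(label_map.edge_fiber_ids),
        "meta": label_map.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_label_map(path: str | Path) -> FiberLabelMap:
    """Read a label raster written by :func:`save_label_map` (or any
    single-channel TIFF with a compatible sidecar)."""
    import tifffile

    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
    else:
        sc = {"pixel_size_um": 1.0, "provenance": "imported"}
    return FiberLabelMap(
        labels=labels,
        pixel_size_um=float(sc.get("pixel_size_um", 1.0)),
        provenance=sc.get("provenance", "imported"),
        position_mm=float(sc.get("position_mm", 0.0)),
        edge_fiber_ids=tuple(sc.get("edge_fiber_ids", ())),
        meta=sc.get("meta", {}),
    )
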