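"""Histology-to-MRI boundary registration and pixel-wise correlation.

The study design registers muscle *boundaries* (no reliable shared
intensity information exists between a stained section and a diffusion
image), so registration here is landmark-based: both contours are
resampled by normalized arc length, matched by circular-shift search after
centroid/scale pre-alignment, and a thin-plate-spline warp is fitted on
the matched landmarks.  Correlation is pooled pixel-wise Pearson r over
the nine (FA, MD, RD) x (diameter, area, S/V) pairs, with the conventional
interpretation bands (negligible < 0.3 <= low < 0.5 <= moderate < 0.7 <=
high < 0.9 <= very high, applied to |r|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.ndimage import map_coordinates
from scipy.stats import pearsonr
from skimage import measure

from .morphometry import METRICS, MorphoMaps, downsample_masked_mean

DTI_METRICS = ("FA", "MD", "RD")
HISTO_METRICS = ("diameter", "area", "sv")


@dataclass
class BoundaryContour:
    """Closed boundary polyline in physical coordinates (mm)."""

    points: np.ndarray
    source: str = "histology"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]  # implicit closure
        if len(pts) < 8:
            raise ValueError("contour needs at least 8 points")
        self.points = pts

    def perimeter(self) -> float:
        p = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())

    def area(self) -> float:
        """Enclosed area by the shoelace formula (absolute value), mm^2."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def resample(self, n: int) -> np.ndarray:
        """n points equally spaced in arc length along the closed contour."""
        p = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        t = np.linspace(0.0, s[-1], n, endpoint=False)
        out = np.empty((n, 2))
        out[:, 0] = np.interp(t, s, p[:, 0])
        out[:, 1] = np.interp(t, s, p[:, 1])
        return out


def extract_boundary(mask: np.ndarray, pixel_size_mm: float,
                     source: str = "histology",
                     smooth_window: int = 7) -> BoundaryContour:
    """Sub-pixel marching-squares contour of the dominant component.

    Fails on an empty mask, and on masks whose second-largest connected
    component is at least half the size of the largest (ambiguous
    dominant muscle), reporting the component sizes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab = measure.label(mask)
    sizes = np.bincount(lab.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    if len(sizes) > 1 and sizes[order[1]] >= 0.5 * sizes[order[0]]:
        raise ValueError(
            f"no dominant component: sizes {sorted(sizes, reverse=True)[:5]}"
        )
    comp = lab == order[0] + 1
    contours = measure.find_contours(comp.astype(float), 0.5)
    contour = max(contours, key=len)
    # (row, col) index space -> (x, y) physical, pixel centers at (i+0.5)px
    xy = np.column_stack([(contour[:, 1] + 0.5) * pixel_size_mm,
                          (contour[:, 0] + 0.5) * pixel_size_mm])
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    # circular moving average removes the staircase of the pixel-level
    # contour (which inflates perimeters by ~5%)
    if len(xy) > 3 * smooth_window > 0:
        k = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        ext = np.vstack([xy[-pad:], xy, xy[:pad]])
        xy = np.column_stack([
            np.convolve(ext[:, 0], k, mode="valid"),
            np.convolve(ext[:, 1], k, mode="valid"),
        ])[: len(xy)]
    return BoundaryContour(points=xy, source=source)


@dataclass
class BoundaryTransform:
    """Forward (moving -> fixed) TPS warp fitted on matched landmarks."""

    landmarks_moving: np.ndarray
    landmarks_fixed: np.ndarray
    rms_residual_mm: float
    _fwd: RBFInterpolator = field(repr=False, default=None)
    _inv: RBFInterpolator = field(repr=False, default=None)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self._fwd(np.atleast_2d(points))

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        return self._inv(np.atleast_2d(points))


def identity_transform() -> BoundaryTransform:
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.5, 0.5]])
    return BoundaryTransform(
        landmarks_moving=pts, landmarks_fixed=pts, rms_residual_mm=0.0,
        _fwd=RBFInterpolator(pts, pts, kernel="thin_plate_spline"),
        _inv=RBFInterpolator(pts, pts, kernel="thin_plate_spline"),
    )


def register_boundaries(moving: BoundaryContour, fixed: BoundaryContour,
                        n_landmarks: int = 64) -> BoundaryTransform:
    """Match contours by normalized arc length and fit a TPS warp.

    Pre-aligns by centroid and RMS-radius scale, searches all circular
    shifts (both orientations) for the correspondence minimizing summed
    squared distance after an optimal rotation, then interpolates the
    matched landmark pairs with a thin-plate spline (exact at landmarks).
    """
    if moving.area() <= 0 or fixed.area() <= 0:
        raise ValueError("degenerate (zero-area) contour")
    A = moving.resample(n_landmarks)
    B = fixed.resample(n_landmarks)

    cA, cB = A.mean(axis=0), B.mean(axis=0)
    a = A - cA
    b = B - cB
    sA = np.sqrt((a**2).sum(axis=1).mean())
    sB = np.sqrt((b**2).sum(axis=1).mean())
    a /= sA
    b /= sB

    best = (np.inf, 0, 1)
    for direction in (1, -1):
        ad = a[::direction]
        for shift in range(n_landmarks):
            ar = np.roll(ad, shift, axis=0)
            # optimal rotation via 2D Procrustes (complex cross-correlation)
            z = (ar[:, 0] + 1j * ar[:, 1]).conj() * (b[:, 0] + 1j * b[:, 1])
            rot = z.sum()
            rot /= abs(rot) if abs(rot) > 0 else 1.0
            arr = ar @ np.array([[rot.real, rot.imag], [-rot.imag, rot.real]])
            # small rotation penalty breaks the tie on (near-)circular
            # contours, whose boundary match is rotationally ambiguous
            cost = ((arr - b) ** 2).sum() + 1e-3 * n_landmarks * (1 - rot.real)
            if cost < best[0]:
                best = (cost, shift, direction)
    _, shift, direction = best
    matched_moving = np.roll(A[::direction], shift, axis=0)

    fwd = RBFInterpolator(matched_moving, B, kernel="thin_plate_spline")
    inv = RBFInterpolator(B, matched_moving, kernel="thin_plate_spline")
    resid = fwd(matched_moving) - B
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return BoundaryTransform(
        landmarks_moving=matched_moving, landmarks_fixed=B,
        rms_residual_mm=rms, _fwd=fwd, _inv=inv,
    )


def warp_morpho_maps(maps: MorphoMaps, transform: BoundaryTransform | None,
                     out_shape: tuple[int, int] | None = None) -> MorphoMaps:
    """Resample maps onto the fixed-space grid at the native resolution.

    For each fixed-grid pixel center the inverse warp locates the source
    position; values are mask-weighted bilinear samples (invalid pixels
    never bleed in).
    """
    if transform is None:
        return maps
    ny, nx = out_shape or maps.shape
    px_mm = maps.pixel_size_um / 1000.0
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    targets = np.column_stack([(jj.ravel() + 0.5) * px_mm, (ii.ravel() + 0.5) * px_mm])
    src = transform.apply_inverse(targets)
    # physical -> fractional index
    cols = src[:, 0] / px_mm - 0.5
    rows = src[:, 1] / px_mm - 0.5
    coords = np.vstack([rows, cols])

    w = np.where(maps.valid_mask, maps.weight, 0.0)
    wi = map_coordinates(w, coords, order=1, mode="constant", cval=0.0)
    out = {}
    for m in METRICS:
        v = np.where(maps.valid_mask, maps[m], 0.0) * w
        vi = map_coordinates(v, coords, order=1, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore"):
            out[m] = np.where(wi > 1e-9, vi / np.where(wi > 1e-9, wi, 1.0), np.nan)
        out[m] = out[m].reshape(ny, nx)
    wi = wi.reshape(ny, nx)
    return MorphoMaps(
        diameter=out["diameter"], area=out["area"], sv=out["sv"],
        valid_mask=wi > 1e-9, pixel_size_um=maps.pixel_size_um,
        weight=wi, meta=dict(maps.meta),
    )


def resample_to_grid(maps: MorphoMaps, transform: BoundaryTransform | None,
                     target_pixel_mm: float = 0.5) -> MorphoMaps:
    """Warp into fixed space, then masked block mean down to the target grid.

    The source-to-target pixel ratio must be an integer (e.g. the 2x2
    kernel taking 0.25 mm data to the 0.5 mm grid); masks are propagated
    conservatively (a target pixel is valid iff >= 1 contributor was).
    """
    warped = warp_morpho_maps(maps, transform)
    src_mm = maps.pixel_size_um / 1000.0
    ratio = target_pixel_mm / src_mm
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-6:
        raise ValueError(
            f"target grid {target_pixel_mm} mm is not an integer multiple of the "
            f"source pixel {src_mm} mm; request explicit interpolation instead"
        )
    return downsample_masked_mean(warped, factor) if factor > 1 else warped


# --------------------------------------------------------------------------
# correlation

def interpret_r(r: float) -> str:
    """Correlation-strength category of |r| on the conventional scale."""
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise ValueError(f"|r| = {a} exceeds 1")
    if a < 0.3:
        return "negligible"
    if a < 0.5:
        return "low"
    if a < 0.7:
        return "moderate"
    if a < 0.9:
        return "high"
    return "very high"


@dataclass
class CorrelationReport:
    """Pooled pixel-wise Pearson correlations for the nine metric pairs.

    ``pairs`` maps "FA_vs_diameter"-style keys to dicts with n_pixels,
    pearson_r (None when undefined by zero variance) and the
    interpretation category.  ``scatter`` optionally carries the pooled
    per-pixel values for plotting/export.
    """

    pairs: dict
    n_pixels: int
    resolution_mm: float
    scatter: dict | None = None

    def max_abs_r(self) -> float:
        rs = [abs(p["pearson_r"]) for p in self.pairs.values()
              if p["pearson_r"] is not None]
        if not rs:
            raise ValueError("no defined correlations in report")
        return max(rs)

    def to_dict(self) -> dict:
        return {"pairs": self.pairs, "n_pixels": self.n_pixels,
                "resolution_mm": self.resolution_mm}


def correlate_pooled(data: dict[str, np.ndarray], resolution_mm: float,
                     keep_scatter: bool = True) -> CorrelationReport:
    """Pearson r for each DTI x histology pair over pooled valid pixels.

    ``data`` maps metric names (FA, MD, RD, diameter, area, sv) to 1D
    arrays of equal length.  Pairs with zero variance in either variable
    are reported as undefined (r = None), never as 0.
    """
    n = {len(v) for v in data.values()}
    if len(n) != 1:
        raise ValueError("pooled metric vectors must have equal length")
    n = n.pop()
    if n < 10:
        raise ValueError(f"need >= 10 pooled pixels, got {n}")
    pairs = {}
    for dm in DTI_METRICS:
        for hm in HISTO_METRICS:
            x = np.asarray(data[hm], dtype=float)
            y = np.asarray(data[dm], dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                pairs[f"{dm}_vs_{hm}"] = {
                    "n_pixels": n, "pearson_r": None,
                    "interpretation": "undefined (zero variance)",
                }
                continue
            r = float(pearsonr(x, y).statistic)
            pairs[f"{dm}_vs_{hm}"] = {
                "n_pixels": n, "pearson_r": r, "interpretation": interpret_r(r),
            }
    return CorrelationReport(
        pairs=pairs, n_pixels=n, resolution_mm=resolution_mm,
        scatter={k: np.asarray(v, dtype=float) for k, v in data.items()}
        if keep_scatter else None,
    )


def pixelwise_correlation(morpho: MorphoMaps, scalars: dict[str, np.ndarray],
                          mask: np.ndarray | None = None,
                          resolution_mm: float | None = None) -> CorrelationReport:
    """Correlate co-registered morphometry and DTI scalar maps pixel-wise.

    ``scalars`` maps FA/MD/RD to rasters on the same grid as ``morpho``;
    ``mask`` further restricts the pooled pixels (e.g. excluding voxels
    flagged by the tensor fit).
    """
    for dm in DTI_METRICS:
        if scalars[dm].shape != morpho.shape:
            raise ValueError("morphometry and DTI maps must share one grid")
    valid = morpho.valid_mask.copy()
    for dm in DTI_METRICS:
        valid &= np.isfinite(scalars[dm])
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    data = {hm: morpho[hm][valid] for hm in HISTO_METRICS}
    data.update({dm: scalars[dm][valid] for dm in DTI_METRICS})
    if resolution_mm is None:
        resolution_mm = morpho.pixel_size_um / 1000.0
    return correlate_pooled(data, resolution_mm)
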