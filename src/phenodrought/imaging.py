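"""Image-based trait extraction from multi-view RGB and NIR rasters.

A plant is segmented from each RGB side view with an excess-green index
(2G - R - B) thresholded by Otsu's method; the mask's pixel count divided
by the squared pixel density gives a per-view projected area, and the
projected shoot area (PSA) is aggregated over the three side views
(SV0/SV120/SV240). NIR cameras sit in a different frame and at a different
resolution than the RGB cameras, so paired control points are fitted with a
least-squares affine map (NIR pixel coords -> RGB pixel coords); the mean
NIR gray value of the plant is then read by inverse-lookup of NIR pixel
centers against the RGB mask — gray values are never resampled.

Raster convention: row-major arrays, origin top-left; a point is (x, y) =
(column, row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "PlantMask",
    "AffineMap",
    "excess_green",
    "segment_plant",
    "projected_area",
    "psa_from_views",
    "psa_per_tiller",
    "growth_rate",
    "register_nir",
    "mean_nir_intensity",
]


@dataclass
class PlantMask:
    """Binary plant mask for one view, with the view's pixel density."""

    view: str
    mask: np.ndarray  # bool, same shape as the source image
    px_per_cm: float

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class AffineMap:
    """x_rgb = A @ x_nir + b, fitted from paired control points."""

    linear: np.ndarray  # 2x2
    offset: np.ndarray  # 2
    residual_rms: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.offset

    @classmethod
    def identity(cls) -> "AffineMap":
        return cls(linear=np.eye(2), offset=np.zeros(2))


def excess_green(rgb: np.ndarray) -> np.ndarray:
    """ExG = 2G - R - B as float; positive where vegetation dominates."""
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 raster, got shape {rgb.shape}")
    r, g, b = (rgb[..., i].astype(float) for i in range(3))
    return 2.0 * g - r - b


def segment_plant(
    rgb: np.ndarray,
    px_per_cm: float,
    view: str = "",
    min_size: int = 25,
) -> PlantMask:
    """Segment the plant via Otsu thresholding of the excess-green index.

    Components smaller than ``min_size`` pixels are dropped as speckle.
    A view without green contrast (constant index, or Otsu split with no
    genuinely green pixels) yields an empty mask rather than an error.
    """
    exg = excess_green(rgb)
    if np.ptp(exg) == 0:
        mask = np.zeros(exg.shape, dtype=bool)
    else:
        thr = threshold_otsu(exg)
        # Otsu always splits; demand actual green dominance so that a
        # plant-free gray-level gradient does not segment as plant.
        mask = (exg > thr) & (exg > 0)
    if min_size > 1 and mask.any():
        # 8-connected components; thin strokes touch diagonally
        labels, _ = ndimage.label(mask, structure=np.ones((3, 3), int))
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_size
        keep[0] = False
        mask = keep[labels]
    return PlantMask(view=view, mask=mask, px_per_cm=px_per_cm)


def projected_area(mask: PlantMask) -> float:
    """Projected area of one view in cm2: pixel count / (px/cm)^2."""
    if mask.px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    return mask.pixel_count / mask.px_per_cm**2


def psa_from_views(masks: dict[str, PlantMask], aggregate: str = "mean") -> float:
    """PSA in cm2 from the three side views SV0/SV120/SV240.

    The mean of the per-view areas (default) is rotation-stable on the
    single-view scale; ``aggregate='sum'`` accumulates them instead.
    """
    expected = {"SV0", "SV120", "SV240"}
    if set(masks) != expected:
        raise ValueError(f"need exactly views {sorted(expected)}, got {sorted(masks)}")
    scales = {m.px_per_cm for m in masks.values()}
    if len(scales) != 1:
        raise ValueError("side views must share px_per_cm")
    areas = [projected_area(masks[v]) for v in ("SV0", "SV120", "SV240")]
    if aggregate == "mean":
        return float(np.mean(areas))
    if aggregate == "sum":
        return float(np.sum(areas))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def psa_per_tiller(psa_cm2: float, tillers: int) -> float:
    """PSA normalized by tiller count, a leaf-architecture descriptor."""
    if tillers < 1:
        raise ValueError(f"tiller count must be >= 1, got {tillers}")
    return psa_cm2 / tillers


def growth_rate(ppa_t2_cm2: float, ppa_t1_cm2: float, dt_days: float) -> float:
    """Top-view projected-area change per day; negative under leaf rolling."""
    if dt_days <= 0:
        raise ValueError(f"time interval must be positive, got {dt_days}")
    return (ppa_t2_cm2 - ppa_t1_cm2) / dt_days


def register_nir(nir_points: np.ndarray, rgb_points: np.ndarray) -> AffineMap:
    """Least-squares affine from paired control points (NIR -> RGB).

    Needs at least three non-collinear pairs; degenerate geometry raises.
    """
    nir_points = np.asarray(nir_points, dtype=float)
    rgb_points = np.asarray(rgb_points, dtype=float)
    if nir_points.shape != rgb_points.shape or nir_points.ndim != 2 or nir_points.shape[1] != 2:
        raise ValueError("control points must be two equally-shaped (n, 2) arrays")
    n = nir_points.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 control point pairs, got {n}")
    design = np.column_stack([nir_points, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("control points are collinear; affine map is degenerate")
    coeffs, *_ = np.linalg.lstsq(design, rgb_points, rcond=None)
    linear = coeffs[:2].T
    offset = coeffs[2]
    if abs(np.linalg.det(linear)) < 1e-12:
        raise ValueError("fitted linear part is singular")
    residuals = design @ coeffs - rgb_points
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return AffineMap(linear=linear, offset=offset, residual_rms=rms)


def mean_nir_intensity(nir: np.ndarray, mask: PlantMask, nir_to_rgb: AffineMap) -> float:
    """Mean gray value (0-255) of NIR pixels that map inside the RGB mask.

    Each NIR pixel center is pushed through the affine map and looked up
    in the mask at the nearest RGB pixel; NIR gray values are used as-is
    (no interpolation). Raises when no NIR pixel lands on the plant.
    """
    if nir.ndim != 2:
        raise ValueError(f"expected a single-channel NIR raster, got shape {nir.shape}")
    h, w = nir.shape
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    mapped = np.rint(
        np.stack([xs.ravel(), ys.ravel()], axis=1) @ nir_to_rgb.linear.T + nir_to_rgb.offset
    ).astype(int)
    mh, mw = mask.mask.shape
    inside = (
        (mapped[:, 0] >= 0) & (mapped[:, 0] < mw) & (mapped[:, 1] >= 0) & (mapped[:, 1] < mh)
    )
    hit = np.zeros(h * w, dtype=bool)
    hit[inside] = mask.mask[mapped[inside, 1], mapped[inside, 0]]
    if not hit.any():
        raise ValueError("no plant found: mapped mask is empty in the NIR frame")
    return float(nir.ravel()[hit].mean())
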