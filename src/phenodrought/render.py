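"""Procedural rendering of multi-view plant images.

A stand-in for glasshouse imaging: each genotype/stage is drawn as a fan of
tapering tiller strokes (sampled quadratic arcs expanded to polygons) on a
contrasting background, in three RGB side views plus a top view, and in
three lower-resolution NIR side views whose frame is related to the RGB
frame by a known affine map. The renderer guarantees that the drawn
silhouette area matches the requested projected area: a global stroke-width
multiplier is bisected until the rasterized mask hits the pixel target
within 1 %, so image-trait extraction can be validated by round-trip.

Leaf rolling (0..1) narrows individual strokes and splits them into more,
thinner tillers — the architectural signature of drought — while the area
target stays the one requested by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .imaging import AffineMap

__all__ = ["RenderConfig", "ImageSet", "render_views"]


@dataclass(frozen=True)
class RenderConfig:
    """Canvas geometry and colors of the procedural imager."""

    rgb_size: tuple[int, int] = (640, 640)  # (width, height)
    nir_size: tuple[int, int] = (320, 320)
    px_per_cm: float = 5.0
    #: NIR -> RGB affine: RGB cameras image the same scene at twice the
    #: resolution with a small mounting offset.
    nir_scale: float = 2.0
    nir_offset: tuple[float, float] = (4.0, -6.0)
    n_control_points: int = 130
    plant_rgb: tuple[int, int, int] = (30, 150, 40)
    background_rgb: tuple[int, int, int] = (190, 190, 195)
    nir_background: int = 90
    base_tillers: int = 10
    #: drawn area may not exceed this fraction of the canvas
    max_fill: float = 0.35

    def nir_to_rgb(self) -> AffineMap:
        return AffineMap(
            linear=np.eye(2) * self.nir_scale, offset=np.asarray(self.nir_offset, float)
        )


@dataclass
class ImageSet:
    """Rendered rasters for one plant observation plus registration truth."""

    rgb: dict[str, np.ndarray]  # SV0/SV120/SV240/top, HxWx3 uint8
    nir: dict[str, np.ndarray]  # SV0/SV120/SV240, HxW uint8
    px_per_cm: float
    control_points_nir: np.ndarray  # (n, 2) in NIR frame
    control_points_rgb: np.ndarray  # (n, 2) in RGB frame
    true_affine: AffineMap
    true_masks: dict[str, np.ndarray] = field(default_factory=dict)  # ground truth, RGB frame


def _tiller_polygons(
    rng: np.random.Generator,
    size: tuple[int, int],
    n_tillers: int,
    lengths: np.ndarray,
    angles: np.ndarray,
    curves: np.ndarray,
    base_widths: np.ndarray,
    width_mult: float,
) -> list[np.ndarray]:
    """Strokes as closed polygons: sampled arcs thickened perpendicular."""
    w, h = size
    base = np.array([w / 2.0, h * 0.92])
    polys = []
    ts = np.linspace(0.0, 1.0, 12)
    for i in range(n_tillers):
        direction = np.array([np.sin(angles[i]), -np.cos(angles[i])])
        normal = np.array([-direction[1], direction[0]])
        # quadratic arc: straight stem bending by `curves[i]` at the tip
        pts = (
            base
            + np.outer(ts * lengths[i], direction)
            + np.outer((ts**2) * curves[i] * lengths[i], normal)
        )
        half = 0.5 * base_widths[i] * width_mult * (1.0 - 0.7 * ts)  # taper to tip
        left = pts + normal[None, :] * half[:, None]
        right = pts - normal[None, :] * half[:, None]
        polys.append(np.vstack([left, right[::-1]]))
    return polys


def _rasterize(polys: list[np.ndarray], size: tuple[int, int]) -> np.ndarray:
    img = Image.new("1", size, 0)
    draw = ImageDraw.Draw(img)
    for poly in polys:
        draw.polygon([tuple(p) for p in poly], fill=1)
    return np.asarray(img, dtype=bool)


def _render_mask(
    rng_geom: np.random.Generator,
    size: tuple[int, int],
    target_px: int,
    n_tillers: int,
    rolling: float,
) -> np.ndarray:
    """Bisect a width multiplier so the silhouette hits target_px within 1%."""
    w, h = size
    # size the architecture to the area target: stroke widths stay near
    # 3 px so thin tillers neither vanish nor fragment when rasterized
    n_eff = int(np.clip(round(np.sqrt(target_px / 45.0)), 3, 16))
    n_eff = max(3, int(round(n_eff * (1.0 + rolling))))
    mean_len = float(np.clip(target_px / (3.0 * n_eff), 20.0, 0.55 * h))
    lengths = rng_geom.uniform(0.7, 1.3, n_eff) * mean_len
    angles = rng_geom.uniform(-0.9, 0.9, n_eff)
    curves = rng_geom.uniform(-0.25, 0.25, n_eff)
    base_widths = rng_geom.uniform(0.8, 1.2, n_eff) * 3.0 * (1.0 - 0.6 * rolling)

    def area(mult: float) -> int:
        return int(
            _rasterize(
                _tiller_polygons(rng_geom, size, n_eff, lengths, angles, curves, base_widths, mult),
                size,
            ).sum()
        )

    # NB: _tiller_polygons must not consume rng state; geometry is fixed above.
    lo, hi = 0.05, 4.0
    while area(hi) < target_px and hi < 200.0:
        hi *= 2.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        a = area(mid)
        if abs(a - target_px) <= max(1, 0.01 * target_px):
            lo = hi = mid
            break
        if a < target_px:
            lo = mid
        else:
            hi = mid
    final = 0.5 * (lo + hi)
    return _rasterize(
        _tiller_polygons(rng_geom, size, n_eff, lengths, angles, curves, base_widths, final),
        size,
    )


def _top_view_mask(
    rng_geom: np.random.Generator, size: tuple[int, int], target_px: int, rolling: float
) -> np.ndarray:
    """Top view: a rosette of radial strokes around the canvas center."""
    w, h = size
    n = int(np.clip(round(np.sqrt(target_px / 40.0)), 4, 18))
    n = max(4, int(round(n * (1.0 + rolling))))
    mean_len = float(np.clip(target_px / (3.0 * n), 20.0, 0.45 * min(w, h)))
    lengths = rng_geom.uniform(0.7, 1.3, n) * mean_len
    angles = rng_geom.uniform(0, 2 * np.pi, n)
    widths = rng_geom.uniform(0.8, 1.2, n) * 3.0 * (1.0 - 0.6 * rolling)
    center = np.array([w / 2.0, h / 2.0])
    ts = np.linspace(0, 1, 10)

    def polys(mult: float) -> list[np.ndarray]:
        out = []
        for i in range(n):
            d = np.array([np.cos(angles[i]), np.sin(angles[i])])
            nrm = np.array([-d[1], d[0]])
            pts = center + np.outer(ts * lengths[i], d)
            half = 0.5 * widths[i] * mult * (1.0 - 0.6 * ts)
            out.append(np.vstack([pts + nrm * half[:, None], (pts - nrm * half[:, None])[::-1]]))
        return out

    lo, hi = 0.05, 4.0
    while int(_rasterize(polys(hi), size).sum()) < target_px and hi < 200.0:
        hi *= 2.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        a = int(_rasterize(polys(mid), size).sum())
        if abs(a - target_px) <= max(1, 0.01 * target_px):
            lo = hi = mid
            break
        (lo, hi) = (mid, hi) if a < target_px else (lo, mid)
    return _rasterize(polys(0.5 * (lo + hi)), size)


def render_views(
    psa_target_cm2: float,
    rolling: float = 0.0,
    nir_level: int = 170,
    config: RenderConfig | None = None,
    seed: int = 0,
    ppa_target_cm2: float | None = None,
) -> ImageSet:
    """Render RGB side/top views and NIR side views for one observation.

    psa_target_cm2 is the per-side-view silhouette area the rendered plant
    exposes (the quantity image extraction should recover); nir_level is
    the gray value painted inside the plant in the NIR frame (drier plant =
    brighter). Raises when the target exceeds the canvas capacity.
    """
    config = config or RenderConfig()
    if psa_target_cm2 < 0:
        raise ValueError("psa_target must be >= 0")
    if not 0.0 <= rolling <= 1.0:
        raise ValueError("rolling must be in [0, 1]")
    target_px = int(round(psa_target_cm2 * config.px_per_cm**2))
    w, h = config.rgb_size
    if target_px > config.max_fill * w * h:
        raise ValueError(
            f"psa_target {psa_target_cm2} cm2 needs {target_px} px, above canvas capacity"
        )
    ppa_px = int(round((ppa_target_cm2 if ppa_target_cm2 is not None else 0.7 * psa_target_cm2)
                       * config.px_per_cm**2))

    rng = np.random.default_rng(seed)
    affine = config.nir_to_rgb()

    rgb_views: dict[str, np.ndarray] = {}
    nir_views: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    bg = np.asarray(config.background_rgb, np.uint8)
    fg = np.asarray(config.plant_rgb, np.uint8)
    for view in ("SV0", "SV120", "SV240"):
        geom = np.random.default_rng(rng.integers(2**31))
        mask = (
            _render_mask(geom, config.rgb_size, target_px, config.base_tillers, rolling)
            if target_px > 0
            else np.zeros((h, w), bool)
        )
        rgb = np.empty((h, w, 3), np.uint8)
        rgb[:] = bg
        rgb[mask] = fg
        rgb_views[view] = rgb
        masks[view] = mask

        # NIR raster: inverse-map each NIR pixel center into the RGB frame
        # and paint nir_level where it lands on the plant.
        nw, nh = config.nir_size
        xs, ys = np.meshgrid(np.arange(nw, dtype=float), np.arange(nh, dtype=float))
        mapped = np.rint(
            np.stack([xs.ravel(), ys.ravel()], 1) @ affine.linear.T + affine.offset
        ).astype(int)
        inside = (
            (mapped[:, 0] >= 0) & (mapped[:, 0] < w) & (mapped[:, 1] >= 0) & (mapped[:, 1] < h)
        )
        plant = np.zeros(nh * nw, bool)
        plant[inside] = mask[mapped[inside, 1], mapped[inside, 0]]
        nir = np.full(nh * nw, config.nir_background, np.uint8)
        nir[plant] = np.uint8(np.clip(nir_level, 0, 255))
        nir_views[view] = nir.reshape(nh, nw)

    geom = np.random.default_rng(rng.integers(2**31))
    top_mask = (
        _top_view_mask(geom, config.rgb_size, ppa_px, rolling) if ppa_px > 0 else np.zeros((h, w), bool)
    )
    top = np.empty((h, w, 3), np.uint8)
    top[:] = bg
    top[top_mask] = fg
    rgb_views["top"] = top
    masks["top"] = top_mask

    nw, nh = config.nir_size
    cp_nir = rng.uniform([0, 0], [nw - 1, nh - 1], size=(config.n_control_points, 2))
    cp_rgb = cp_nir @ affine.linear.T + affine.offset
    return ImageSet(
        rgb=rgb_views,
        nir=nir_views,
        px_per_cm=config.px_per_cm,
        control_points_nir=cp_nir,
        control_points_rgb=cp_rgb,
        true_affine=affine,
        true_masks=masks,
    )
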