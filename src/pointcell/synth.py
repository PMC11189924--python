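"""Synthetic overlapping cervical-cell scenes with dense ground truth.

Emulates the construction of the ISBI-2014-style synthetic cytology set:
each scene composites 2–10 isolated-cell templates onto a bright
background with minor brightness variation, so that cells form clumps
whose mean overlap rate spans 0–0.5. Cytoplasm outlines are smoothly
perturbed ellipses with a darker nucleus inside; overlapping regions are
rendered by multiplicative translucent blending, so clump interiors are
darker — the appearance extended-depth-of-field micrographs show.

Ground truth is a set of per-cell binary masks that MAY overlap (a label
image cannot represent it). Rasterization uses the pixel-centre
convention: a pixel belongs to a cell iff its centre lies inside the
cell's outline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import rescale

log = logging.getLogger(__name__)

__all__ = [
    "CellTemplate",
    "SynthConfig",
    "InstanceMaskSet",
    "sample_cell",
    "compose_image",
    "measure_overlap_rate",
    "augment",
    "generate_scene",
    "generate_dataset",
]


@dataclass
class CellTemplate:
    """An isolated cell: perturbed-ellipse cytoplasm with a nucleus inside.

    The cytoplasm outline is the polar curve
    ``r(theta) = r_ellipse(theta) * (1 + sum_k a_k cos(k theta + phi_k))``
    in the cell frame (axes ``ax``, ``ay``, rotated by ``angle``); the
    nucleus is a scaled copy of the unperturbed ellipse, offset slightly,
    guaranteeing nucleus ⊂ cytoplasm for ``nucleus_scale`` + offset < 1.
    """

    ax: float
    ay: float
    angle: float
    perturb_amp: np.ndarray  # Fourier amplitudes a_k, k >= 2
    perturb_phase: np.ndarray
    nucleus_scale: float
    nucleus_offset: tuple[float, float]
    cyto_level: float  # multiplicative attenuation in (0, 1]
    nucleus_level: float
    texture_amp: float

    def radius(self, theta: np.ndarray) -> np.ndarray:
        """Cytoplasm boundary radius at cell-frame angles ``theta``."""
        ct, st = np.cos(theta), np.sin(theta)
        base = (self.ax * self.ay) / np.sqrt((self.ay * ct) ** 2 + (self.ax * st) ** 2)
        mod = np.ones_like(theta)
        for k, (a, ph) in enumerate(zip(self.perturb_amp, self.perturb_phase), start=2):
            mod += a * np.cos(k * theta + ph)
        return base * np.maximum(mod, 0.1)

    def outline(self, n: int = 256) -> np.ndarray:
        """(n, 2) closed cytoplasm contour in the cell frame, (x, y)."""
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = self.radius(th)
        return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)

    def contains(self, x: np.ndarray, y: np.ndarray, cx: float, cy: float) -> np.ndarray:
        """Pixel-centre inclusion test for the cytoplasm placed at (cx, cy)."""
        dx, dy = x - cx, y - cy
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        u = ca * dx + sa * dy
        v = -sa * dx + ca * dy
        rho = np.hypot(u, v)
        theta = np.arctan2(v, u)
        return rho <= self.radius(theta)

    def nucleus_contains(self, x: np.ndarray, y: np.ndarray, cx: float, cy: float) -> np.ndarray:
        ox, oy = self.nucleus_offset
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        # offset expressed in the cell frame, then rotated to image frame
        ncx = cx + ca * ox - sa * oy
        ncy = cy + sa * ox + ca * oy
        dx, dy = x - ncx, y - ncy
        u = ca * dx + sa * dy
        v = -sa * dx + ca * dy
        s = self.nucleus_scale
        return (u / (s * self.ax)) ** 2 + (v / (s * self.ay)) ** 2 <= 1.0


@dataclass
class SynthConfig:
    """Scene-generation parameters.

    Defaults match the synthetic challenge set being emulated: 512x512
    images with 2–10 cells and a target mean overlap rate in [0, 0.5].
    """

    image_size: int = 512
    n_cells_range: tuple[int, int] = (2, 10)
    target_overlap_rate: float = 0.25
    background_level: float = 0.92  # bright field, in [0, 1]
    brightness_jitter: float = 0.03
    blend_opacity: float = 1.0  # weight of each cell's attenuation layer
    cell_radius_frac: tuple[float, float] = (0.10, 0.18)  # of image side
    noise_sigma: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.n_cells_range
        if lo < 1 or hi < lo:
            raise ValueError("n_cells_range must be a nonempty interval with min >= 1")
        if not 0.0 <= self.target_overlap_rate <= 0.5:
            raise ValueError("target_overlap_rate must be in [0, 0.5]")
        if not 0.0 < self.blend_opacity <= 1.0:
            raise ValueError("blend_opacity must be in (0, 1]")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")


@dataclass
class InstanceMaskSet:
    """Ordered per-instance binary masks of one image; masks may overlap."""

    masks: list[np.ndarray] = field(default_factory=list)
    ignore_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        shapes = {m.shape for m in self.masks}
        if len(shapes) > 1:
            raise ValueError("all masks must share one height x width")
        for i, m in enumerate(self.masks):
            if not m.any():
                raise ValueError(f"mask {i} is empty")
        if self.ignore_mask is not None:
            self.ignore_mask = np.asarray(self.ignore_mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks[0].shape if self.masks else (0, 0)

    def bounding_boxes(self) -> list[tuple[int, int, int, int]]:
        """Tight half-open (x1, y1, x2, y2) box of each mask."""
        out = []
        for m in self.masks:
            rows = np.flatnonzero(m.any(axis=1))
            cols = np.flatnonzero(m.any(axis=0))
            out.append((int(cols[0]), int(rows[0]), int(cols[-1] + 1), int(rows[-1] + 1)))
        return out


def sample_cell(
    rng: np.random.Generator,
    radius_range: tuple[float, float] = (20.0, 40.0),
    aspect_range: tuple[float, float] = (0.7, 1.0),
    perturb_range: tuple[float, float] = (0.0, 0.08),
    nucleus_scale_range: tuple[float, float] = (0.22, 0.35),
    cyto_level_range: tuple[float, float] = (0.72, 0.88),
    nucleus_level_range: tuple[float, float] = (0.35, 0.55),
    texture_amp_range: tuple[float, float] = (0.0, 0.03),
) -> CellTemplate:
    """Draw a random isolated-cell template; deterministic given ``rng``."""
    for name, (lo, hi) in [
        ("radius_range", radius_range),
        ("aspect_range", aspect_range),
        ("perturb_range", perturb_range),
        ("nucleus_scale_range", nucleus_scale_range),
    ]:
        if lo > hi or lo < 0:
            raise ValueError(f"invalid {name}: ({lo}, {hi})")
    r = rng.uniform(*radius_range)
    aspect = rng.uniform(*aspect_range)
    amp = rng.uniform(*perturb_range)
    n_harm = 3  # harmonics k = 2..4: smooth, simple outlines
    amps = amp * rng.dirichlet(np.ones(n_harm))
    nscale = rng.uniform(*nucleus_scale_range)
    # keep nucleus strictly inside even under boundary perturbation
    max_off = r * aspect * (1.0 - nscale) * 0.5
    off = rng.uniform(-max_off, max_off, size=2)
    return CellTemplate(
        ax=r,
        ay=r * aspect,
        angle=rng.uniform(0, np.pi),
        perturb_amp=amps,
        perturb_phase=rng.uniform(0, 2 * np.pi, size=n_harm),
        nucleus_scale=nscale,
        nucleus_offset=(float(off[0]), float(off[1])),
        cyto_level=rng.uniform(*cyto_level_range),
        nucleus_level=rng.uniform(*nucleus_level_range),
        texture_amp=rng.uniform(*texture_amp_range),
    )


def measure_overlap_rate(masks: InstanceMaskSet | list[np.ndarray]) -> float:
    """Mean per-cell fraction of area shared with at least one other cell.

    For each cell i: |pixels of i covered by some j != i| / |pixels of i|;
    the scene's overlap rate is the mean over cells. 0 when all masks are
    disjoint (or there is a single mask).
    """
    ms = list(masks.masks if isinstance(masks, InstanceMaskSet) else masks)
    if not ms:
        raise ValueError("overlap rate of an empty mask set is undefined")
    if len(ms) == 1:
        return 0.0
    stack = np.stack([m.astype(np.int32) for m in ms])
    cover = stack.sum(axis=0)
    rates = []
    for m in ms:
        area = m.sum()
        shared = np.count_nonzero(m & (cover >= 2))
        rates.append(shared / area)
    return float(np.mean(rates))


def _rasterize(cells, centres, size) -> list[np.ndarray]:
    xs = np.arange(size) + 0.5
    gx, gy = np.meshgrid(xs, xs)
    return [c.contains(gx, gy, cx, cy) for c, (cx, cy) in zip(cells, centres)]


def _place_centres(cells, config, rng) -> tuple[list[tuple[float, float]], list[np.ndarray]]:
    """Choose cell centres whose achieved overlap approximates the target.

    Centres are spread on a jittered ring around the image centre; a global
    contraction factor is bisected against the measured overlap rate
    (overlap increases monotonically as the clump contracts).
    """
    size = config.image_size
    n = len(cells)
    c0 = size / 2.0
    mean_r = float(np.mean([c.ax for c in cells]))
    angles = rng.uniform(0, 2 * np.pi) + np.arange(n) * (2 * np.pi / n)
    angles += rng.normal(0, 0.15, size=n)
    radial = 1.0 + rng.uniform(-0.2, 0.2, size=n)

    def centres_at(spread: float):
        pts = []
        for a, rr in zip(angles, radial):
            d = spread * rr * mean_r
            x = np.clip(c0 + d * np.cos(a), mean_r, size - mean_r)
            y = np.clip(c0 + d * np.sin(a), mean_r, size - mean_r)
            pts.append((float(x), float(y)))
        return pts

    if n == 1:
        pts = [(float(rng.uniform(mean_r, size - mean_r)), float(rng.uniform(mean_r, size - mean_r)))]
        return pts, _rasterize(cells, pts, size)

    if config.target_overlap_rate == 0.0:
        # spread out until disjoint, with bounded retries
        spread = 2.5
        for _ in range(12):
            pts = centres_at(spread)
            masks = _rasterize(cells, pts, size)
            if measure_overlap_rate(masks) == 0.0:
                return pts, masks
            spread *= 1.25
        warnings.warn("could not achieve a fully disjoint placement", stacklevel=3)
        return pts, masks

    lo, hi = 0.0, 3.5  # contraction bisection bounds (spread in mean radii)
    best = None
    for _ in range(14):
        mid = (lo + hi) / 2.0
        pts = centres_at(mid)
        masks = _rasterize(cells, pts, size)
        rate = measure_overlap_rate(masks)
        if best is None or abs(rate - config.target_overlap_rate) < abs(best[2] - config.target_overlap_rate):
            best = (pts, masks, rate)
        if abs(rate - config.target_overlap_rate) < 0.01:
            break
        if rate > config.target_overlap_rate:
            lo = mid  # too much overlap -> spread out
        else:
            hi = mid
    pts, masks, rate = best
    if abs(rate - config.target_overlap_rate) > 0.1:
        warnings.warn(
            f"achieved overlap rate {rate:.3f} outside +-0.1 of target "
            f"{config.target_overlap_rate:.3f}; reporting achieved value",
            stacklevel=3,
        )
    return pts, masks


def compose_image(
    cells: list[CellTemplate], config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, InstanceMaskSet, dict]:
    """Composite cell templates into one scene.

    Returns ``(image, masks, meta)``: a float image in [0, 1], one binary
    cytoplasm mask per cell, and metadata with the achieved overlap rate.
    Rendering multiplies the bright background by each cell's attenuation
    layer, so stacked (overlapping) cytoplasm is darker — translucent
    blending. Placement is best-effort toward the configured overlap rate;
    the achieved value is reported, never forced.
    """
    if not cells:
        raise ValueError("compose_image requires at least one cell")
    size = config.image_size
    centres, masks = _place_centres(cells, config, rng)
    bg = config.background_level + rng.uniform(-config.brightness_jitter, config.brightness_jitter)
    img = np.full((size, size), np.clip(bg, 0.05, 1.0), dtype=np.float64)
    xs = np.arange(size) + 0.5
    gx, gy = np.meshgrid(xs, xs)
    for cell, mask, (cx, cy) in zip(cells, masks, centres):
        layer = np.ones((size, size))
        att = cell.cyto_level
        if cell.texture_amp > 0:
            att = att + cell.texture_amp * np.sin(0.35 * gx + 0.27 * gy + cx)
        layer = np.where(mask, att, layer)
        nuc = cell.nucleus_contains(gx, gy, cx, cy)
        layer = np.where(nuc, cell.nucleus_level, layer)
        # blend_opacity < 1 weakens each layer toward transparency
        layer = 1.0 - config.blend_opacity * (1.0 - layer)
        img *= layer
    if config.noise_sigma > 0:
        img = img + rng.normal(0, config.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    mask_set = InstanceMaskSet(masks)
    meta = {
        "n_cells": len(cells),
        "achieved_overlap_rate": measure_overlap_rate(mask_set),
        "target_overlap_rate": config.target_overlap_rate,
        "centres": [list(c) for c in centres],
    }
    return img, mask_set, meta


def augment(
    image: np.ndarray, masks: InstanceMaskSet, rng: np.random.Generator,
    scale_range: tuple[float, float] = (0.85, 1.15),
) -> tuple[np.ndarray, InstanceMaskSet]:
    """Random rotation / flips / scaling applied identically to image+masks.

    A subset of {k*90-degree rotation, horizontal flip, vertical flip,
    bounded rescale} is selected and applied at random; masks stay binary,
    and any instance a transform empties is dropped with a warning.
    """
    if image.shape[:2] != masks.shape:
        raise ValueError("image and masks must share dimensions")
    img = image.copy()
    ms = [m.copy() for m in masks.masks]

    k = int(rng.integers(0, 4))
    if k:
        img = np.rot90(img, k)
        ms = [np.rot90(m, k) for m in ms]
    if rng.random() < 0.5:
        img = np.fliplr(img)
        ms = [np.fliplr(m) for m in ms]
    if rng.random() < 0.5:
        img = np.flipud(img)
        ms = [np.flipud(m) for m in ms]
    if rng.random() < 0.5:
        s = float(rng.uniform(*scale_range))
        img = _rescale_to(img, s, order=1)
        ms = [_rescale_to(m.astype(np.float64), s, order=0) > 0.5 for m in ms]

    keep, kept_masks = [], []
    for i, m in enumerate(ms):
        if m.any():
            keep.append(i)
            kept_masks.append(np.ascontiguousarray(m))
        else:
            log.warning("augmentation emptied instance %d; dropped", i)
    return np.ascontiguousarray(img), InstanceMaskSet(kept_masks)


def _rescale_to(arr: np.ndarray, s: float, order: int) -> np.ndarray:
    """Rescale by factor s, then centre-crop / pad back to original shape."""
    h, w = arr.shape
    out = rescale(arr, s, order=order, preserve_range=True, anti_aliasing=False)
    oh, ow = out.shape
    res = np.zeros_like(arr) if order else np.full_like(arr, float(np.median(arr)))
    y0, x0 = (oh - h) // 2, (ow - w) // 2
    if s >= 1.0:
        res = out[y0 : y0 + h, x0 : x0 + w]
    else:
        y1, x1 = (h - oh) // 2, (w - ow) // 2
        res[y1 : y1 + oh, x1 : x1 + ow] = out
    return res


def generate_scene(config: SynthConfig, seed: int) -> tuple[np.ndarray, InstanceMaskSet, dict]:
    """One fully seeded scene: sample templates, compose, report metadata."""
    rng = np.random.default_rng(seed)
    lo, hi = config.n_cells_range
    n = int(rng.integers(lo, hi + 1))
    r_lo = config.cell_radius_frac[0] * config.image_size
    r_hi = config.cell_radius_frac[1] * config.image_size
    cells = [sample_cell(rng, radius_range=(r_lo, r_hi)) for _ in range(n)]
    img, masks, meta = compose_image(cells, config, rng)
    meta["seed"] = seed
    return img, masks, meta


def generate_dataset(config: SynthConfig, n_images: int, seed: int, overlap_spread: bool = True):
    """A list of scenes; per-scene targets sweep [0, max] when requested."""
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n_images):
        cfg = config
        if overlap_spread:
            t = float(rng.uniform(0.0, config.target_overlap_rate))
            cfg = replace(config, target_overlap_rate=round(t, 3))
        scene_seed = int(rng.integers(0, 2**31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scenes.append(generate_scene(cfg, scene_seed))
    return scenes
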