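"""Geometry and sampling kernels: bilinear interpolation, RoI align,
uncertainty scoring and point selection.

Coordinate convention (package-wide)
------------------------------------
A feature grid of stride ``s`` places node ``(i, j)`` (row, col) at image
point ``(x, y) = ((j + 0.5) * s, (i + 0.5) * s)``; pixel centres sit at
half-integer image coordinates, boxes are half-open, and continuous
sampling uses align-corners = ``False`` semantics. Samples outside the
convex hull of node centres are clamped to the border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridFeature",
    "PointSet",
    "Box",
    "bilinear_weights",
    "bilinear_sample",
    "roi_align",
    "roi_sample_points",
    "uncertainty",
    "select_points",
    "upsample2x",
]


@dataclass
class GridFeature:
    """An ``H x W x C`` grid of real values with a pixel stride.

    ``values`` may also be 2-D (``H x W``), treated as a single channel.
    """

    values: np.ndarray
    stride: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("GridFeature values must be HxW or HxWxC")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("grid must be at least 2x2 for interpolation")
        if self.stride <= 0:
            raise ValueError("stride must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class PointSet:
    """Real-valued sample points tagged with their coordinate frame.

    ``coords`` is ``(N, 2)`` with columns ``(x, y)``. ``frame`` is either
    ``"normalized"`` (unit square of a box) or ``"absolute"`` (image pixels).
    """

    coords: np.ndarray
    frame: str = "absolute"

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.float64))
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (N, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("point coordinates must be finite")
        if self.frame not in ("normalized", "absolute"):
            raise ValueError(f"unknown frame tag {self.frame!r}")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def to_absolute(self, box: "Box") -> "PointSet":
        """Map normalized box coordinates into absolute image coordinates."""
        if self.frame == "absolute":
            return self
        xy = np.empty_like(self.coords)
        xy[:, 0] = box.x1 + self.coords[:, 0] * box.width
        xy[:, 1] = box.y1 + self.coords[:, 1] * box.height
        return PointSet(xy, "absolute")


@dataclass(frozen=True)
class Box:
    """Half-open axis-aligned box in image coordinates."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    def clip(self, image_hw: tuple[int, int]) -> "Box | None":
        """Clip to image bounds; ``None`` if nothing remains."""
        h, w = image_hw
        x1, y1 = max(self.x1, 0.0), max(self.y1, 0.0)
        x2, y2 = min(self.x2, float(w)), min(self.y2, float(h))
        if x2 <= x1 or y2 <= y1:
            return None
        return Box(x1, y1, x2, y2)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)


def bilinear_weights(
    grid_hw: tuple[int, int], xs: np.ndarray, ys: np.ndarray, stride: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices and convex weights of the 4-point bilinear stencil.

    ``xs, ys`` are absolute image coordinates. Returns ``(rows, cols, w)``
    each of shape ``(N, 4)``; weights are nonnegative and sum to 1. Points
    outside the node-centre hull are clamped to the border.
    """
    h, w = grid_hw
    # continuous grid coordinates: node j has centre x = (j + 0.5) * stride
    u = np.asarray(xs, dtype=np.float64) / stride - 0.5
    v = np.asarray(ys, dtype=np.float64) / stride - 0.5
    u = np.clip(u, 0.0, w - 1.0)
    v = np.clip(v, 0.0, h - 1.0)
    j0 = np.clip(np.floor(u).astype(np.int64), 0, w - 2)
    i0 = np.clip(np.floor(v).astype(np.int64), 0, h - 2)
    fu = u - j0
    fv = v - i0
    rows = np.stack([i0, i0, i0 + 1, i0 + 1], axis=-1)
    cols = np.stack([j0, j0 + 1, j0, j0 + 1], axis=-1)
    wts = np.stack(
        [(1 - fu) * (1 - fv), fu * (1 - fv), (1 - fu) * fv, fu * fv], axis=-1
    )
    return rows, cols, wts


def bilinear_sample(grid: GridFeature, points: PointSet) -> np.ndarray:
    """Sample a grid at real-valued points; returns ``(N, C)`` values.

    Each value is the convex combination of the four nearest node values;
    exact at node centres and exactly linear along grid axes. Points must
    be in the absolute frame (use :meth:`PointSet.to_absolute` first).
    """
    if points.frame != "absolute":
        raise ValueError("bilinear_sample expects absolute-frame points")
    h, w, _ = grid.shape
    xs, ys = points.coords[:, 0], points.coords[:, 1]
    lo_x, hi_x = 0.5 * grid.stride, (w - 0.5) * grid.stride
    lo_y, hi_y = 0.5 * grid.stride, (h - 0.5) * grid.stride
    if np.any((xs < lo_x) | (xs > hi_x) | (ys < lo_y) | (ys > hi_y)):
        warnings.warn("points outside grid node hull clamped to border", stacklevel=2)
    rows, cols, wts = bilinear_weights((h, w), xs, ys, grid.stride)
    vals = grid.values[rows, cols]  # (N, 4, C)
    return np.einsum("nk,nkc->nc", wts, vals)


def roi_sample_points(
    box: Box, out_size: int, sampling_ratio: int
) -> np.ndarray:
    """Absolute image coordinates of RoI-align sample points.

    Shape ``(out_size, out_size, sampling_ratio**2, 2)``: for each output
    cell, a regular ``r x r`` sub-grid of sample centres.
    """
    r = sampling_ratio
    bw = box.width / out_size
    bh = box.height / out_size
    off = (np.arange(r) + 0.5) / r  # sub-grid centre offsets in cell units
    jj = np.arange(out_size)
    cell_x = box.x1 + jj[:, None] * bw + off[None, :] * bw  # (out, r)
    cell_y = box.y1 + jj[:, None] * bh + off[None, :] * bh
    # combine: output cell (i, j) with sub-sample (a, b)
    xs = np.broadcast_to(cell_x[None, :, None, :], (out_size, out_size, r, r))
    ys = np.broadcast_to(cell_y[:, None, :, None], (out_size, out_size, r, r))
    pts = np.stack([xs, ys], axis=-1).reshape(out_size, out_size, r * r, 2)
    return pts


def roi_align(
    map: GridFeature, box: Box, out_size: int = 7, sampling_ratio: int = 2
) -> np.ndarray:
    """Continuous-coordinate crop of a feature map into ``out x out x C``.

    Each output cell is the mean of ``sampling_ratio**2`` bilinear samples
    placed on a regular sub-grid of the cell (no coordinate quantization).
    """
    if box.area <= 0:
        raise ValueError("roi_align requires a box with positive area")
    if out_size < 1 or sampling_ratio < 1:
        raise ValueError("out_size and sampling_ratio must be >= 1")
    pts = roi_sample_points(box, out_size, sampling_ratio)
    flat = PointSet(pts.reshape(-1, 2), "absolute")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # border clamping is intended here
        vals = bilinear_sample(map, flat)
    c = map.shape[2]
    vals = vals.reshape(out_size, out_size, sampling_ratio**2, c)
    return vals.mean(axis=2)


def uncertainty(prob: np.ndarray) -> np.ndarray:
    """Uncertainty score ``-|p - 0.5|`` — maximal (0) at p = 0.5.

    Points whose foreground probability is closest to 0.5 are the ones the
    refinement head re-predicts; the score is monotone in that closeness.
    """
    p = np.asarray(prob, dtype=np.float64)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return -np.abs(p - 0.5)


def upsample2x(prob: np.ndarray) -> np.ndarray:
    """Bilinear x2 upsampling of a 2-D grid (align-corners = False)."""
    h, w = prob.shape
    g = GridFeature(prob, stride=1.0)
    jj = (np.arange(2 * w) + 0.5) / 2.0  # image-frame x of output pixel centres
    ii = (np.arange(2 * h) + 0.5) / 2.0
    xs = np.broadcast_to(jj[None, :], (2 * h, 2 * w)).ravel()
    ys = np.broadcast_to(ii[:, None], (2 * h, 2 * w)).ravel()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = bilinear_sample(g, PointSet(np.stack([xs, ys], axis=1), "absolute"))
    return out[:, 0].reshape(2 * h, 2 * w)


def _grid_centres_normalized(h: int, w: int) -> np.ndarray:
    """(H*W, 2) pixel-centre coordinates of a grid in the unit square."""
    xs = (np.arange(w) + 0.5) / w
    ys = (np.arange(h) + 0.5) / h
    gx, gy = np.meshgrid(xs, ys)
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def select_points(
    prob: np.ndarray,
    n: int,
    strategy: str = "topk",
    rng: np.random.Generator | None = None,
    oversample: int = 3,
    importance_frac: float = 0.75,
) -> PointSet:
    """Choose ``n`` uncertain points on a probability grid.

    ``topk`` takes exactly the ``n`` highest-uncertainty pixel centres,
    ties broken by row-major index (fully deterministic). This is the
    inference default. ``oversample_random`` — the training strategy —
    draws ``oversample * n`` uniform candidates, keeps the
    ``importance_frac`` most uncertain of them (scored by bilinear
    interpolation of the uncertainty surface) and fills the rest with
    fresh uniform points; it requires ``rng``.

    Returns points in the normalized ``[0,1]^2`` box frame.
    """
    p = np.asarray(prob, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("prob must be a 2-D grid")
    h, w = p.shape
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return PointSet(np.empty((0, 2)), "normalized")
    if strategy == "topk":
        if n > p.size:
            raise ValueError(f"n={n} exceeds {p.size} candidate points")
        unc = uncertainty(p).ravel()
        # stable sort on -unc keeps row-major order among ties
        order = np.argsort(-unc, kind="stable")[:n]
        return PointSet(_grid_centres_normalized(h, w)[order], "normalized")
    if strategy == "oversample_random":
        if rng is None:
            raise ValueError("oversample_random requires an rng")
        k = max(int(oversample), 1)
        cand = rng.uniform(0.0, 1.0, size=(k * n, 2))
        g = GridFeature(uncertainty(p), stride=1.0)
        # candidate scores via bilinear interpolation of the uncertainty map
        abs_pts = PointSet(cand * np.array([w, h]), "absolute")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = bilinear_sample(g, abs_pts)[:, 0]
        n_imp = min(int(round(importance_frac * n)), n)
        keep = np.argsort(-scores, kind="stable")[:n_imp]
        coords = [cand[keep]]
        if n - n_imp > 0:
            coords.append(rng.uniform(0.0, 1.0, size=(n - n_imp, 2)))
        return PointSet(np.concatenate(coords, axis=0), "normalized")
    raise ValueError(f"unknown strategy {strategy!r}")
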