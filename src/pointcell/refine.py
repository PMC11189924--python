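"""Inference-time boundary refinement and full-image prediction.

The coarse 28x28 mask is bilinearly up-sampled pass by pass; at each pass
the most uncertain locations — foreground probability nearest 0.5, i.e.
boundary-adjacent pixels — are re-predicted by the point head from their
concatenated fine (P2) and coarse (RoI) point features, while every other
location keeps its interpolated value. The refined probability grid is
then pasted into the proposal box at image resolution and thresholded.

Two readings of the refinement schedule are supported: the default
iterative x2 subdivision (two passes, 28 -> 56 -> 112, with ``n_points``
re-selected per pass), and ``passes=1`` for a literal single-pass
refinement at one resolution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .model import ModelConfig, PointCellModel, TrainResult, propose
from .sampling import Box, GridFeature, PointSet, select_points, uncertainty, upsample2x
from .synth import InstanceMaskSet

log = logging.getLogger(__name__)

__all__ = ["DetectionResult", "refine_mask", "paste_mask", "predict", "predictions_to_masks"]


@dataclass
class DetectionResult:
    """One predicted cell instance at image resolution."""

    box: Box
    score: float
    mask_full: np.ndarray  # binary, image-sized
    mask_prob: np.ndarray  # refined probability grid in the box frame


def refine_mask(
    coarse_probs: np.ndarray,
    point_predictor,
    n_points: int,
    passes: int = 2,
    strategy: str = "topk",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Up-sample a coarse probability grid, re-predicting uncertain points.

    ``point_predictor(points: PointSet in the normalized box frame) ->
    probabilities`` is the trained point head bound to this RoI (or an
    oracle in tests). Per pass the grid is bilinearly doubled, ``n_points``
    highest-uncertainty pixels are selected and overwritten with the
    predictor's output; unselected pixels keep their interpolated values
    exactly. ``n_points=0`` degenerates to plain bilinear up-sampling.
    """
    prob = np.asarray(coarse_probs, dtype=np.float64).copy()
    for _ in range(passes):
        prob = upsample2x(prob)
        if n_points == 0:
            continue
        n = min(n_points, prob.size)
        pts = select_points(prob, n, strategy=strategy, rng=rng)
        new_p = np.asarray(point_predictor(pts), dtype=np.float64)
        h, w = prob.shape
        jj = np.clip((pts.coords[:, 0] * w - 0.5).round().astype(int), 0, w - 1)
        ii = np.clip((pts.coords[:, 1] * h - 0.5).round().astype(int), 0, h - 1)
        prob[ii, jj] = new_p
    return prob


def paste_mask(
    prob: np.ndarray, box: Box, image_hw: tuple[int, int], threshold: float = 0.5
) -> np.ndarray | None:
    """Resample a box-frame probability grid into the image and binarize.

    Bilinear resampling of ``prob`` over the box footprint, zero outside,
    threshold 0.5 by default. Returns ``None`` when the clipped box is
    empty or the pasted mask contains no foreground pixel (the detection
    is then dropped by the caller).
    """
    clipped = box.clip(image_hw)
    if clipped is None:
        return None
    h, w = image_hw
    out = np.zeros((h, w), dtype=bool)
    y0, y1 = int(np.floor(clipped.y1)), int(np.ceil(clipped.y2))
    x0, x1 = int(np.floor(clipped.x1)), int(np.ceil(clipped.x2))
    ys = np.arange(y0, y1) + 0.5
    xs = np.arange(x0, x1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    # pixel centres inside the (unclipped) box, in normalized box coords
    u = (gx - box.x1) / box.width
    v = (gy - box.y1) / box.height
    inside = (u >= 0) & (u < 1) & (v >= 0) & (v < 1)
    ph, pw = prob.shape
    g = GridFeature(prob, stride=1.0)
    pts = PointSet(np.stack([u[inside] * pw, v[inside] * ph], axis=1), "absolute")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from .sampling import bilinear_sample

        vals = bilinear_sample(g, pts)[:, 0]
    patch = np.zeros_like(u)
    patch[inside] = vals
    out[y0:y1, x0:x1] = (patch >= threshold) & inside
    if not out.any():
        return None
    return out


def predict(
    image: np.ndarray,
    result: TrainResult,
    gt: InstanceMaskSet | None = None,
    passes: int | None = None,
    use_point_head: bool | None = None,
) -> list[DetectionResult]:
    """Full inference: backbone -> proposals -> coarse mask -> refine -> paste.

    In ``gt_boxes`` (teacher-forced) proposal mode the ground truth supplies
    unjittered boxes, so ``gt`` must be given to produce detections; in
    ``learned_rpn`` mode proposals come from the RPN. Deterministic for a
    fixed checkpoint and image (top-k point selection).
    """
    model = result.model
    cfg = model.config
    if passes is None:
        passes = cfg.refine_passes
    if use_point_head is None:
        use_point_head = cfg.use_point_head
    img = np.asarray(image, dtype=np.float64)
    hw = img.shape[:2]
    if cfg.proposal_mode == "gt_boxes":
        boxes_scores = [(b, 1.0) for b in propose(img, gt, cfg, rng=None)]
    else:
        boxes_scores = model.rpn_propose(img)
    if not boxes_scores:
        return []
    pyramid = model.backbone(img)
    detections: list[DetectionResult] = []
    for box, prop_score in boxes_scores:
        roi = model.roi_feature(pyramid, box)
        mask_logits, coarse = model.mask_head(roi, box)
        cls_logit, _ = model.box_cls_head(roi)
        score = float(nn.sigmoid(cls_logit.data)[0, 0]) * prop_score
        if score < cfg.score_threshold:
            continue
        prob = coarse.probs
        if use_point_head and passes > 0:
            head_scale = float(np.abs(model.point_logit.weight.data).max())
            if head_scale == 0.0:
                log.warning("point head untrained (zero weights); refinement skipped")
            else:
                prob = refine_mask(
                    prob,
                    lambda pts: model.predict_points(pyramid, roi, box, pts),
                    cfg.beta_infer,
                    passes=passes,
                    strategy=cfg.infer_point_strategy,
                )
        else:
            for _ in range(passes):
                prob = upsample2x(prob)
        full = paste_mask(prob, box, hw, cfg.mask_threshold)
        if full is None:
            log.warning("detection produced an empty mask; dropped")
            continue
        detections.append(DetectionResult(box=box, score=score, mask_full=full, mask_prob=prob))
    return detections


def predictions_to_masks(dets: list[DetectionResult]) -> tuple[InstanceMaskSet | None, np.ndarray]:
    """Pack detections into an InstanceMaskSet + score vector for evaluation."""
    if not dets:
        return None, np.zeros(0)
    return InstanceMaskSet([d.mask_full for d in dets]), np.array([d.score for d in dets])
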