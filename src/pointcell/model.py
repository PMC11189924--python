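"""Two-stage instance-segmentation network with a point-refinement head.

Architecture
------------
A convolutional backbone with a feature pyramid (P2..P5, strides 4/8/16/32)
feeds three region branches, exactly as in the Mask R-CNN meta-architecture:

* box / category branch on 7x7 RoI-aligned features;
* mask branch: two 3x3 convs, then two stride-2 transposed convolutions
  (7 -> 14 -> 28) and a 1x1 projection to a single 28x28 logit grid;
* point head: a shared per-point MLP (equivalently, 1x1 convolutions over
  the point axis) of ``alpha`` layers x 256 channels applied to the
  concatenation F_fine ⊕ F_coarse of point-wise features — F_fine sampled
  bilinearly from P2, F_coarse from the RoI feature — predicting a
  foreground logit per sampled point.

The training loss is the unweighted four-term sum
``L = L_mask + L_point + L_box + L_cls``; the point term is mean binary
cross-entropy over the sampled uncertain points. Optimization is SGD with
momentum (defaults lr 0.002, momentum 0.9, batch of 2 images).

The reference-scale backbone in the field is a ResNet-101; here the tested
default is a small 4-stage CNN ("tiny") so the whole pipeline trains on a
CPU in minutes, with a deeper "resnet_like" variant available through the
same config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import nn
from .sampling import Box, GridFeature, PointSet, roi_align, select_points
from .synth import InstanceMaskSet, augment

log = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "CoarseMask",
    "PointBatch",
    "LossBreakdown",
    "PointCellModel",
    "propose",
    "tight_box",
    "mask_target",
    "point_labels",
    "point_loss",
    "total_loss",
    "train",
    "TrainResult",
    "save_checkpoint",
    "load_checkpoint",
]

FPN_STRIDES = {"P2": 4, "P3": 8, "P4": 16, "P5": 32}


@dataclass
class ModelConfig:
    backbone_spec: str = "tiny"
    widths: tuple[int, ...] = (16, 32, 64, 128)
    fpn_width: int = 32
    alpha: int = 3  # point-head depth
    beta_train: int = 196  # points sampled per RoI during training
    beta_infer: int = 784  # points re-predicted per refinement pass
    point_head_width: int = 256
    use_point_head: bool = True
    proposal_mode: str = "gt_boxes"  # or "learned_rpn"
    fine_source: str = "P2"
    mask_out: int = 28
    roi_out: int = 7
    sampling_ratio: int = 2
    lr: float = 0.002
    momentum: float = 0.9
    weight_decay: float = 0.0
    epochs: int = 50
    batch_size: int = 2
    box_jitter: float = 0.1
    score_threshold: float = 0.5
    mask_threshold: float = 0.5
    nms_iou: float = 0.5
    refine_passes: int = 2
    train_point_strategy: str = "oversample_random"
    infer_point_strategy: str = "topk"
    augment_train: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha not in (2, 3, 4):
            raise ValueError("alpha (point-head depth) must be one of {2, 3, 4}")
        if self.mask_out != 4 * self.roi_out:
            raise ValueError("mask_out must equal 4 * roi_out (two x2 upsamplings)")
        if self.beta_train < 1 or self.beta_infer < 1:
            raise ValueError("point counts must be >= 1")
        if self.proposal_mode not in ("gt_boxes", "learned_rpn"):
            raise ValueError(f"unknown proposal_mode {self.proposal_mode!r}")
        if self.backbone_spec == "resnet_like":
            # wider, deeper preset; same contract, not exercised in CI
            self.widths = (64, 128, 256, 512)
            self.fpn_width = 128


@dataclass
class CoarseMask:
    """Per-instance coarse mask prediction living in its proposal box."""

    logits: np.ndarray  # (mask_out, mask_out)
    box: Box

    @property
    def probs(self) -> np.ndarray:
        return nn.sigmoid(self.logits)


@dataclass
class PointBatch:
    """Sampled points with their features and predictions."""

    points: PointSet  # normalized box frame
    fine: np.ndarray  # (N, C_fine)
    coarse: np.ndarray  # (N, C_coarse)
    logits: np.ndarray | None = None  # (N,)
    labels: np.ndarray | None = None  # (N,) in {0,1}, training only

    @property
    def concat(self) -> np.ndarray:
        return np.concatenate([self.fine, self.coarse], axis=1)


@dataclass
class LossBreakdown:
    mask: float
    point: float
    box: float
    cls: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("mask", "point", "box", "cls"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise FloatingPointError(f"non-finite {name} loss component: {v}")
        self.total = self.mask + self.point + self.box + self.cls


def total_loss(mask: float, point: float, box: float, cls: float) -> LossBreakdown:
    """The model's unweighted four-term loss sum."""
    return LossBreakdown(mask=mask, point=point, box=box, cls=cls)


def tight_box(mask: np.ndarray) -> Box:
    """Tight half-open bounding box of a binary mask (pixel indices)."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return Box(float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1))


def propose(
    image: np.ndarray,
    gt: InstanceMaskSet | None,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
    model: "PointCellModel | None" = None,
) -> list[Box]:
    """Supply proposal boxes for one image.

    ``gt_boxes`` mode (teacher-forced): the tight boxes of the ground-truth
    masks, jittered by at most ``box_jitter`` of each side. ``learned_rpn``
    mode: scored single-anchor proposals from the RPN heads after NMS.
    """
    h, w = image.shape[:2]
    if config.proposal_mode == "gt_boxes":
        if gt is None:
            return []
        boxes = []
        for m in gt.masks:
            b = tight_box(m)
            if rng is not None and config.box_jitter > 0:
                jx = config.box_jitter * b.width
                jy = config.box_jitter * b.height
                d = rng.uniform(-1.0, 1.0, size=4)
                jit = Box(b.x1 + d[0] * jx, b.y1 + d[1] * jy, b.x2 + d[2] * jx, b.y2 + d[3] * jy)
                clipped = jit.clip((h, w))
                b = clipped if clipped is not None else b  # keep mask alignment
            else:
                b = b.clip((h, w)) or b
            boxes.append(b)
        return boxes
    if model is None:
        raise ValueError("learned_rpn proposals need the model")
    return [b for b, _ in model.rpn_propose(image)]


def mask_target(gt_mask: np.ndarray, box: Box, out: int = 28) -> np.ndarray:
    """GT mask cropped to the box and resampled to ``out x out``.

    Bilinear area sampling of the {0,1} mask followed by a 0.5 threshold.
    """
    g = GridFeature(gt_mask.astype(np.float64), stride=1.0)
    vals = roi_align(g, box, out_size=out, sampling_ratio=2)[:, :, 0]
    return (vals >= 0.5).astype(np.float64)


def point_labels(
    gt_mask: np.ndarray, box: Box, points: PointSet, mode: str = "nearest"
) -> np.ndarray:
    """{0,1} labels of real-valued points against a GT mask.

    ``nearest`` (default): the mask value of the pixel whose centre is
    nearest the point. ``bilinear``: interpolate the {0,1} field and
    threshold at 0.5.
    """
    pts = points.to_absolute(box).coords
    h, w = gt_mask.shape
    if mode == "nearest":
        ix = np.clip(np.floor(pts[:, 0]).astype(int), 0, w - 1)
        iy = np.clip(np.floor(pts[:, 1]).astype(int), 0, h - 1)
        return gt_mask[iy, ix].astype(np.float64)
    if mode == "bilinear":
        import warnings

        from .sampling import bilinear_sample

        g = GridFeature(gt_mask.astype(np.float64), stride=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = bilinear_sample(g, PointSet(pts, "absolute"))[:, 0]
        return (v >= 0.5).astype(np.float64)
    raise ValueError(f"unknown point-label mode {mode!r}")


def point_loss(logits: np.ndarray | nn.Tensor, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of the point head, stabilized."""
    t = logits if isinstance(logits, nn.Tensor) else nn.Tensor(np.asarray(logits, dtype=np.float64))
    return nn.bce_with_logits(t, np.asarray(labels, dtype=np.float64)).item()


class PointCellModel:
    """The network: backbone+FPN, box/cls, mask branch, point head, RPN."""

    ANCHOR_SCALE = 8  # anchor side = ANCHOR_SCALE * level stride

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.widths
        f = config.fpn_width
        self._named: list[tuple[str, nn.Tensor]] = []

        def reg(name, layer):
            for i, p in enumerate(layer.params()):
                self._named.append((f"{name}.{i}", p))
            return layer

        self.stem = reg("stem", nn.Conv2d(1, w[0], 3, stride=2, pad=1, rng=rng))
        self.stages = [
            reg("c2", nn.Conv2d(w[0], w[0], 3, stride=2, pad=1, rng=rng)),
            reg("c3", nn.Conv2d(w[0], w[1], 3, stride=2, pad=1, rng=rng)),
            reg("c4", nn.Conv2d(w[1], w[2], 3, stride=2, pad=1, rng=rng)),
            reg("c5", nn.Conv2d(w[2], w[3], 3, stride=2, pad=1, rng=rng)),
        ]
        self.lateral = [reg(f"lat{i}", nn.Conv2d(w[i], f, 1, rng=rng)) for i in range(4)]
        self.smooth = [reg(f"out{i}", nn.Conv2d(f, f, 3, pad=1, rng=rng)) for i in range(4)]
        # mask branch: 2 convs, 7->14->28 transposed convs, 1x1 logit proj
        self.mask_convs = [
            reg("m0", nn.Conv2d(f, f, 3, pad=1, rng=rng)),
            reg("m1", nn.Conv2d(f, f, 3, pad=1, rng=rng)),
        ]
        self.mask_up = [reg("mu0", nn.ConvT2x2(f, f, rng=rng)), reg("mu1", nn.ConvT2x2(f, f, rng=rng))]
        self.mask_logit = reg("ml", nn.Conv2d(f, 1, 1, rng=rng))
        # box / category branch on flattened RoI features
        self.bc_hidden = reg("bch", nn.Linear(f * config.roi_out**2, 128, rng=rng))
        self.cls_out = reg("cls", nn.Linear(128, 1, rng=rng))
        self.box_out = reg("box", nn.Linear(128, 4, rng=rng, zero_init=True))
        # point head: alpha layers x 256 (shared per-point MLP), final logit
        ph = []
        cin = 2 * f
        for i in range(config.alpha):
            ph.append(reg(f"ph{i}", nn.Linear(cin, config.point_head_width, rng=rng)))
            cin = config.point_head_width
        self.point_layers = ph
        self.point_logit = reg("phl", nn.Linear(cin, 1, rng=rng))
        # single-anchor RPN heads, shared across pyramid levels
        self.rpn_conv = reg("rpnc", nn.Conv2d(f, f, 3, pad=1, rng=rng))
        self.rpn_obj = reg("rpno", nn.Conv2d(f, 1, 1, rng=rng))
        self.rpn_delta = reg("rpnd", nn.Conv2d(f, 4, 1, rng=rng, ))

    # ---------------------------------------------------------------- params
    def params(self) -> list[nn.Tensor]:
        return [p for _, p in self._named]

    def named_params(self) -> list[tuple[str, nn.Tensor]]:
        return list(self._named)

    # -------------------------------------------------------------- backbone
    @staticmethod
    def _prepare(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 3:
            img = img.mean(axis=2)
        h, w = img.shape
        ph = (-h) % 32
        pw = (-w) % 32
        if ph or pw:
            log.warning("padding %sx%s image to a multiple of 32", h, w)
            img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
        return img

    def backbone(self, image: np.ndarray, requires_grad: bool = True) -> dict[str, nn.Tensor]:
        """image -> {P2..P5} feature pyramid (strides 4/8/16/32)."""
        img = self._prepare(image)
        x = nn.Tensor(img[None, :, :])
        x.requires_grad = False
        x = nn.relu(self.stem(x))
        feats = []
        for stage in self.stages:
            x = nn.relu(stage(x))
            feats.append(x)
        # top-down pathway with nearest x2 upsampling
        laterals = [lat(c) for lat, c in zip(self.lateral, feats)]
        tops = [None] * 4
        tops[3] = laterals[3]
        for i in (2, 1, 0):
            tops[i] = nn.add(laterals[i], nn.upsample2x_nearest(tops[i + 1]))
        pyramid = {f"P{i + 2}": self.smooth[i](tops[i]) for i in range(4)}
        return pyramid

    def pyramid_as_grids(self, pyramid: dict[str, nn.Tensor]) -> dict[str, GridFeature]:
        return {
            k: GridFeature(np.moveaxis(v.data, 0, -1), stride=FPN_STRIDES[k])
            for k, v in pyramid.items()
        }

    # ------------------------------------------------------------- branches
    def roi_feature(self, pyramid: dict[str, nn.Tensor], box: Box) -> nn.Tensor:
        """7x7 RoI-aligned feature from the configured fine-source level."""
        lvl = self.config.fine_source
        return nn.roi_align_t(
            pyramid[lvl], box, FPN_STRIDES[lvl], self.config.roi_out, self.config.sampling_ratio
        )

    def mask_head(self, roi_feat: nn.Tensor, box: Box) -> tuple[nn.Tensor, CoarseMask]:
        """7x7 RoI feature -> 28x28 mask logits (Tensor + detached view)."""
        if roi_feat.data.shape[1] != self.config.roi_out:
            raise ValueError("mask head expects roi_out-sized features")
        x = roi_feat
        for conv in self.mask_convs:
            x = nn.relu(conv(x))
        for up in self.mask_up:
            x = nn.relu(up(x))
        logits = self.mask_logit(x)  # (1, 28, 28)
        return logits, CoarseMask(logits=logits.data[0].copy(), box=box)

    def box_cls_head(self, roi_feat: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        flat = nn.Tensor(roi_feat.data.reshape(1, -1), parents=(roi_feat,))
        shape = roi_feat.data.shape

        def back(g, rf=roi_feat, shape=shape):
            if rf.requires_grad:
                rf._accumulate(g.reshape(shape))

        flat._backward = back
        h = nn.relu(self.bc_hidden(flat))
        return self.cls_out(h), self.box_out(h)

    def point_head(self, concat: nn.Tensor) -> nn.Tensor:
        """(N, 2F) concatenated point features -> (N,) logits."""
        x = concat
        for layer in self.point_layers:
            x = nn.relu(layer(x))
        return self.point_logit(x)

    def point_features(
        self,
        pyramid: dict[str, nn.Tensor],
        roi_feat: nn.Tensor,
        box: Box,
        points: PointSet,
    ) -> tuple[nn.Tensor, PointBatch]:
        """Build F_fine ⊕ F_coarse for points given in the normalized box frame."""
        if points.frame != "normalized":
            raise ValueError("point features expect normalized box coordinates")
        abs_pts = points.to_absolute(box).coords
        lvl = self.config.fine_source
        fine = nn.sample_points_t(pyramid[lvl], abs_pts[:, 0], abs_pts[:, 1], FPN_STRIDES[lvl])
        r = self.config.roi_out
        coarse = nn.sample_points_t(roi_feat, points.coords[:, 0] * r, points.coords[:, 1] * r, 1.0)
        concat = nn.concat_cols(fine, coarse)
        batch = PointBatch(points=points, fine=fine.data.copy(), coarse=coarse.data.copy())
        return concat, batch

    def predict_points(
        self, pyramid: dict[str, nn.Tensor], roi_feat: nn.Tensor, box: Box, points: PointSet
    ) -> np.ndarray:
        """Point-head foreground probabilities at normalized box points."""
        concat, _ = self.point_features(pyramid, roi_feat, box, points)
        return nn.sigmoid(self.point_head(concat).data[:, 0])

    # ------------------------------------------------------------------ RPN
    def rpn_forward(self, pyramid: dict[str, nn.Tensor], level: str):
        h = nn.relu(self.rpn_conv(pyramid[level]))
        return self.rpn_obj(h), self.rpn_delta(h)

    def rpn_propose(self, image: np.ndarray, pre_nms: int = 200, post_nms: int = 50):
        """Scored anchor proposals after NMS (inference path)."""
        pyramid = self.backbone(image)
        h, w = image.shape[:2]
        cands: list[tuple[Box, float]] = []
        for level, stride in FPN_STRIDES.items():
            obj, delta = self.rpn_forward(pyramid, level)
            score = nn.sigmoid(obj.data[0])
            side = self.ANCHOR_SCALE * stride
            hh, ww = score.shape
            for i in range(hh):
                for j in range(ww):
                    cx = (j + 0.5) * stride + delta.data[0, i, j] * side
                    cy = (i + 0.5) * stride + delta.data[1, i, j] * side
                    bw = side * np.exp(np.clip(delta.data[2, i, j], -2, 2))
                    bh = side * np.exp(np.clip(delta.data[3, i, j], -2, 2))
                    b = Box(cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2).clip((h, w))
                    if b is not None:
                        cands.append((b, float(score[i, j])))
        cands.sort(key=lambda t: -t[1])
        cands = cands[:pre_nms]
        kept: list[tuple[Box, float]] = []
        for b, s in cands:
            if all(_box_iou(b, kb) < self.config.nms_iou for kb, _ in kept):
                kept.append((b, s))
            if len(kept) >= post_nms:
                break
        return [(b, s) for b, s in kept if s >= self.config.score_threshold]


def _box_iou(a: Box, b: Box) -> float:
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    return inter / (a.area + b.area - inter) if inter else 0.0


def _box_deltas(proposal: Box, target: Box) -> np.ndarray:
    """Standard (dx, dy, dw, dh) regression target from proposal to target."""
    return np.array(
        [
            ((target.x1 + target.x2) - (proposal.x1 + proposal.x2)) / (2 * proposal.width),
            ((target.y1 + target.y2) - (proposal.y1 + proposal.y2)) / (2 * proposal.height),
            np.log(target.width / proposal.width),
            np.log(target.height / proposal.height),
        ]
    )


def _background_box(gt_boxes: list[Box], image_hw, rng, max_tries: int = 10) -> Box | None:
    h, w = image_hw
    for _ in range(max_tries):
        side = rng.uniform(0.1, 0.3) * min(h, w)
        x1 = rng.uniform(0, w - side)
        y1 = rng.uniform(0, h - side)
        b = Box(x1, y1, x1 + side, y1 + side)
        if all(_box_iou(b, g) < 0.2 for g in gt_boxes):
            return b
    return None


def scene_losses(
    model: PointCellModel,
    image: np.ndarray,
    gt: InstanceMaskSet,
    rng: np.random.Generator,
) -> tuple[nn.Tensor, LossBreakdown] | None:
    """Forward pass and four-term loss graph for one training scene.

    Region-branch supervision is always teacher-forced on jittered
    ground-truth boxes; in ``learned_rpn`` mode the RPN objectness and
    regression terms are additionally folded into the cls and box loss
    components, preserving the four-term total.
    """
    cfg = model.config
    gt_cfg = cfg if cfg.proposal_mode == "gt_boxes" else replace(cfg, proposal_mode="gt_boxes")
    boxes = propose(image, gt, gt_cfg, rng=rng)
    if not boxes:
        return None
    pyramid = model.backbone(image)
    mask_terms: list[nn.Tensor] = []
    point_terms: list[nn.Tensor] = []
    box_terms: list[nn.Tensor] = []
    cls_logits: list[nn.Tensor] = []
    cls_labels: list[float] = []
    tight = [tight_box(m) for m in gt.masks]
    for k, box in enumerate(boxes):
        roi = model.roi_feature(pyramid, box)
        mask_logits, coarse = model.mask_head(roi, box)
        target = mask_target(gt.masks[k], box, cfg.mask_out)
        mask_terms.append(nn.bce_with_logits(mask_logits, target[None, :, :]))
        cls_logit, box_pred = model.box_cls_head(roi)
        cls_logits.append(cls_logit)
        cls_labels.append(1.0)
        box_terms.append(nn.smooth_l1(box_pred, _box_deltas(box, tight[k])[None, :]))
        if cfg.use_point_head:
            pts = select_points(
                coarse.probs, cfg.beta_train, cfg.train_point_strategy, rng=rng
            )
            concat, _ = model.point_features(pyramid, roi, box, pts)
            logits = model.point_head(concat)
            labels = point_labels(gt.masks[k], box, pts)
            point_terms.append(nn.bce_with_logits(logits, labels[:, None]))
    bg = _background_box(tight, image.shape[:2], rng)
    if bg is not None:
        roi = model.roi_feature(pyramid, bg)
        cls_logit, _ = model.box_cls_head(roi)
        cls_logits.append(cls_logit)
        cls_labels.append(0.0)

    def mean_terms(terms: list[nn.Tensor]) -> nn.Tensor:
        if not terms:
            return nn.Tensor(0.0)
        acc = terms[0]
        for t in terms[1:]:
            acc = nn.add(acc, t)
        return _scale(acc, 1.0 / len(terms))

    l_mask = mean_terms(mask_terms)
    l_point = mean_terms(point_terms)
    l_box = mean_terms(box_terms)
    stacked = _stack_scalars(cls_logits)
    l_cls = nn.bce_with_logits(stacked, np.asarray(cls_labels)[:, None])
    if cfg.proposal_mode == "learned_rpn":
        rpn_obj, rpn_reg = _rpn_losses(model, pyramid, tight, image.shape[:2])
        l_cls = nn.add(l_cls, rpn_obj)
        l_box = nn.add(l_box, rpn_reg)
    graph = nn.add(nn.add(l_mask, l_point), nn.add(l_box, l_cls))
    breakdown = total_loss(l_mask.item(), l_point.item(), l_box.item(), l_cls.item())
    return graph, breakdown


def _rpn_losses(
    model: PointCellModel,
    pyramid: dict[str, nn.Tensor],
    gt_boxes: list[Box],
    image_hw: tuple[int, int],
) -> tuple[nn.Tensor, nn.Tensor]:
    """RPN objectness BCE + positive-anchor smooth-L1 regression terms."""
    obj_terms: list[nn.Tensor] = []
    reg_graphs: list[nn.Tensor] = []
    reg_targets: list[np.ndarray] = []
    h, w = image_hw
    for level, stride in FPN_STRIDES.items():
        obj, delta = model.rpn_forward(pyramid, level)
        hh, ww = obj.data.shape[1:]
        side = model.ANCHOR_SCALE * stride
        targets = np.zeros((1, hh, ww))
        pos: list[tuple[int, int, np.ndarray]] = []
        for i in range(hh):
            for j in range(ww):
                cx, cy = (j + 0.5) * stride, (i + 0.5) * stride
                anchor = Box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
                clipped = anchor.clip((h, w))
                if clipped is None:
                    continue
                ious = [_box_iou(clipped, g) for g in gt_boxes]
                if ious and max(ious) >= 0.3:
                    targets[0, i, j] = 1.0
                    pos.append((i, j, _box_deltas(anchor, gt_boxes[int(np.argmax(ious))])))
        obj_terms.append(nn.bce_with_logits(obj, targets))
        if pos:
            rows = np.array([p[0] for p in pos])
            cols = np.array([p[1] for p in pos])
            sel = _select_spatial(delta, rows, cols)  # (n_pos, 4)
            reg_graphs.append(sel)
            reg_targets.append(np.stack([p[2] for p in pos]))
    acc = obj_terms[0]
    for t in obj_terms[1:]:
        acc = nn.add(acc, t)
    obj_loss = _scale(acc, 1.0 / len(obj_terms))
    if reg_graphs:
        stacked_data = np.concatenate([g.data for g in reg_graphs], axis=0)
        stacked = nn.Tensor(stacked_data, parents=tuple(reg_graphs))
        sizes = [g.data.shape[0] for g in reg_graphs]

        def back(grad, graphs=reg_graphs, sizes=sizes):
            off = 0
            for g, s in zip(graphs, sizes):
                if g.requires_grad:
                    g._accumulate(grad[off : off + s])
                off += s

        stacked._backward = back
        reg_loss = nn.smooth_l1(stacked, np.concatenate(reg_targets, axis=0))
    else:
        reg_loss = nn.Tensor(0.0)
    return obj_loss, reg_loss


def _select_spatial(t: nn.Tensor, rows: np.ndarray, cols: np.ndarray) -> nn.Tensor:
    """Gather (C, i, j) columns of a (C, H, W) tensor -> (n, C)."""
    out = nn.Tensor(t.data[:, rows, cols].T, parents=(t,))

    def back(g):
        if t.requires_grad:
            gx = np.zeros_like(t.data)
            np.add.at(np.moveaxis(gx, 0, -1), (rows, cols), g)
            t._accumulate(gx)

    out._backward = back
    return out


def _scale(t: nn.Tensor, s: float) -> nn.Tensor:
    out = nn.Tensor(t.data * s, parents=(t,))

    def back(g):
        if t.requires_grad:
            t._accumulate(g * s)

    out._backward = back
    return out


def _stack_scalars(ts: list[nn.Tensor]) -> nn.Tensor:
    out = nn.Tensor(np.concatenate([t.data.reshape(1, 1) for t in ts], axis=0), parents=tuple(ts))

    def back(g):
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accumulate(g[i].reshape(t.data.shape))

    out._backward = back
    return out


@dataclass
class TrainResult:
    model: PointCellModel
    config: ModelConfig
    curves: list[LossBreakdown]

    @property
    def loss_curve(self) -> list[float]:
        return [c.total for c in self.curves]


def train(
    dataset: list[tuple[np.ndarray, InstanceMaskSet, dict]],
    config: ModelConfig,
    log_every: int = 10,
) -> TrainResult:
    """SGD training over synthetic scenes; fully seeded and reproducible.

    Aborts with a diagnostic if the total loss exceeds 10x its initial
    value for three consecutive epochs (divergence guard).
    """
    if len(dataset) < 2:
        raise ValueError("training needs at least 2 scenes")
    model = PointCellModel(config)
    opt = nn.SGD(model.params(), lr=config.lr, momentum=config.momentum, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    curves: list[LossBreakdown] = []
    initial_total = None
    bad_epochs = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        sums = np.zeros(4)
        count = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            any_loss = False
            for idx in batch:
                image, masks, _ = dataset[idx]
                if config.augment_train:
                    image, masks = augment(image, masks, rng)
                    if len(masks) == 0:
                        continue
                out = scene_losses(model, image, masks, rng)
                if out is None:
                    continue
                graph, breakdown = out
                graph.backward()
                sums += np.array([breakdown.mask, breakdown.point, breakdown.box, breakdown.cls])
                count += 1
                any_loss = True
            if any_loss:
                opt.step()
        if count == 0:
            raise RuntimeError("no usable scenes in epoch")
        epoch_loss = total_loss(*(sums / count))
        curves.append(epoch_loss)
        if initial_total is None:
            initial_total = epoch_loss.total
        bad_epochs = bad_epochs + 1 if epoch_loss.total > 10 * initial_total else 0
        if bad_epochs >= 3:
            raise RuntimeError(
                f"training diverged: total loss {epoch_loss.total:.3f} vs initial {initial_total:.3f}"
            )
        if log_every and epoch % log_every == 0:
            log.info("epoch %d: %s", epoch, epoch_loss)
    return TrainResult(model=model, config=config, curves=curves)


CHECKPOINT_VERSION = 1


def save_checkpoint(path, result: TrainResult) -> None:
    """Single-file archive: weights + config echo + seed + format version."""
    arrays = {name: p.data for name, p in result.model.named_params()}
    cfg = asdict(result.config)
    cfg["widths"] = list(cfg["widths"])
    meta = {
        "config": cfg,
        "version": CHECKPOINT_VERSION,
        "curves": [[c.mask, c.point, c.box, c.cls] for c in result.curves],
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> TrainResult:
    """Load a checkpoint, verifying config compatibility with the weights."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"incompatible checkpoint version {meta.get('version')}")
        cfg_d = dict(meta["config"])
        cfg_d["widths"] = tuple(cfg_d["widths"])
        config = ModelConfig(**cfg_d)
        model = PointCellModel(config)
        for name, p in model.named_params():
            if name not in z:
                raise ValueError(f"checkpoint missing parameter {name}")
            if z[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {z[name].shape} vs {p.data.shape}")
            p.data = z[name].astype(np.float64)
        curves = [LossBreakdown(*c) for c in meta.get("curves", [])]
    return TrainResult(model=model, config=config, curves=curves)
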