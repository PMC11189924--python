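"""The overlapping-cytology challenge evaluation protocol.

Instance matching by Dice similarity (DSC) above a threshold, object-level
false-negative rate (FNRo), pixel-level true/false positive rates
(TPRp/FPRp) computed per matched ground-truth/prediction pair with the
exclusion rule — a ground-truth cell with no prediction above the DSC
threshold contributes to no pixel metric — plus COCO-style mask average
precision and reports stratified by cell count and overlap rate.

Conventions, documented because the protocol leaves them open:

* matching is greedy on the full gt x pred DSC matrix in descending DSC
  order, each side used at most once, ties broken by lower indices; an
  optimal-assignment alternative is available via ``method="hungarian"``;
* "above a specific threshold" is read as ``>=``; ``strict=True`` gives
  strict ``>``;
* aggregates are mean ± std over matched cells pooled across the dataset
  (a per-image breakdown is also emitted);
* TN is the full-image complement of the pair's union;
* pixels of an ``ignore_mask`` are excluded from all four pixel counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .synth import InstanceMaskSet

__all__ = [
    "MatchResult",
    "EvalReport",
    "dsc",
    "match_instances",
    "pixel_metrics",
    "fnr_object",
    "mask_iou",
    "coco_ap",
    "evaluate_scene",
    "evaluate_dataset",
    "stratified_report",
    "plot_strata_heatmap",
]


@dataclass
class MatchResult:
    """Outcome of DSC-threshold instance matching for one image."""

    pairs: list[tuple[int, int, float]]  # (gt index, pred index, dsc)
    unmatched_gt: list[int]
    unmatched_pred: list[int]
    threshold: float


@dataclass
class EvalReport:
    """Dataset-level metric summary (mean ± std over matched cells)."""

    dsc_mean: float = float("nan")
    dsc_std: float = float("nan")
    tprp_mean: float = float("nan")
    tprp_std: float = float("nan")
    fprp_mean: float = float("nan")
    fprp_std: float = float("nan")
    fnro_mean: float = float("nan")
    fnro_std: float = float("nan")
    ap: float = float("nan")
    ap50: float = float("nan")
    ap75: float = float("nan")
    threshold: float = 0.7
    n_images: int = 0
    n_gt_cells: int = 0
    per_image: list[dict] = field(default_factory=list)
    strata: dict[tuple[int, int], dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "dsc_mean", "dsc_std", "tprp_mean", "tprp_std", "fprp_mean",
                "fprp_std", "fnro_mean", "fnro_std", "ap", "ap50", "ap75",
                "threshold", "n_images", "n_gt_cells",
            )
        }
        d["strata"] = {f"{k[0]}cells_overlap{k[1] / 10:.1f}": v for k, v in self.strata.items()}
        d["per_image"] = self.per_image
        return d


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A| + |B|)`` of two masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        warnings.warn("DSC of two empty masks defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def _dsc_matrix(gt: InstanceMaskSet, pred: InstanceMaskSet) -> np.ndarray:
    """Full gt x pred DSC matrix via stacked intersections."""
    if len(gt) == 0 or len(pred) == 0:
        return np.zeros((len(gt), len(pred)))
    g = np.stack([m.ravel() for m in gt.masks]).astype(np.float64)
    p = np.stack([m.ravel() for m in pred.masks]).astype(np.float64)
    inter = g @ p.T
    areas = g.sum(axis=1)[:, None] + p.sum(axis=1)[None, :]
    return 2.0 * inter / areas


def match_instances(
    gt: InstanceMaskSet,
    pred: InstanceMaskSet,
    threshold: float = 0.7,
    strict: bool = False,
    method: str = "greedy",
) -> MatchResult:
    """Match predictions to ground-truth cells at a DSC threshold.

    Greedy: repeatedly accept the highest-DSC unused (gt, pred) pair,
    rejecting pairs below the threshold; deterministic with ties broken by
    lower (gt, pred) indices. ``method="hungarian"`` instead maximizes the
    total DSC of accepted pairs.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    mat = _dsc_matrix(gt, pred)
    ok = (mat > threshold) if strict else (mat >= threshold)
    pairs: list[tuple[int, int, float]] = []
    if mat.size:
        if method == "greedy":
            cand = np.argwhere(ok)
            # sort by descending dsc, ties by (gt, pred) index
            order = sorted(range(len(cand)), key=lambda t: (-mat[tuple(cand[t])], cand[t][0], cand[t][1]))
            used_g: set[int] = set()
            used_p: set[int] = set()
            for t in order:
                i, j = map(int, cand[t])
                if i in used_g or j in used_p:
                    continue
                used_g.add(i)
                used_p.add(j)
                pairs.append((i, j, float(mat[i, j])))
        elif method == "hungarian":
            cost = np.where(ok, -mat, 1.0)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if ok[i, j]:
                    pairs.append((int(i), int(j), float(mat[i, j])))
        else:
            raise ValueError(f"unknown matching method {method!r}")
    pairs.sort(key=lambda t: t[0])
    matched_g = {i for i, _, _ in pairs}
    matched_p = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_gt=[i for i in range(len(gt)) if i not in matched_g],
        unmatched_pred=[j for j in range(len(pred)) if j not in matched_p],
        threshold=threshold,
    )


def pixel_metrics(
    match: MatchResult, gt: InstanceMaskSet, pred: InstanceMaskSet
) -> tuple[list[float], list[float]]:
    """Per-matched-pair TPRp and FPRp lists.

    For a matched pair (gt_i, det_j): TP = |gt_i ∩ det_j|,
    FN = |gt_i − det_j|, FP = |det_j − gt_i|, TN = |complement of
    gt_i ∪ det_j| over the whole image. TPRp = TP/(TP+FN),
    FPRp = FP/(FP+TN). Unmatched ground-truth cells are excluded
    entirely; ignore-mask pixels are removed from every count.
    """
    tprs: list[float] = []
    fprs: list[float] = []
    valid = None
    if gt.ignore_mask is not None:
        valid = ~gt.ignore_mask
    for i, j, _ in match.pairs:
        g = gt.masks[i]
        p = pred.masks[j]
        if g.shape != p.shape:
            raise ValueError("gt and pred masks must share a shape")
        if valid is not None:
            g = g & valid
            p = p & valid
        tp = int((g & p).sum())
        fn = int((g & ~p).sum())
        fp = int((~g & p).sum())
        total = int(valid.sum()) if valid is not None else g.size
        tn = total - tp - fn - fp
        tprs.append(tp / (tp + fn) if tp + fn else 0.0)
        fprs.append(fp / (fp + tn) if fp + tn else 0.0)
    return tprs, fprs


def fnr_object(match: MatchResult, n_gt: int) -> float:
    """Object-level false-negative rate: unmatched gt cells / all gt cells."""
    if n_gt < 1:
        raise ValueError("FNRo undefined for zero ground-truth cells")
    return len(match.unmatched_gt) / n_gt


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int((a | b).sum())
    return int((a & b).sum()) / union if union else 0.0


def coco_ap(
    gt_scenes: list[InstanceMaskSet],
    pred_scenes: list[InstanceMaskSet],
    scores: list[np.ndarray],
) -> tuple[float, float, float]:
    """COCO-style mask average precision: (AP, AP50, AP75).

    Per IoU threshold in 0.50:0.05:0.95, predictions are matched per image
    in descending score order to the not-yet-taken ground-truth mask of
    highest IoU >= threshold; the dataset-pooled precision-recall curve is
    summarized by 101-point interpolated AP. AP is the mean over the ten
    thresholds.
    """
    if len(gt_scenes) != len(pred_scenes) or len(pred_scenes) != len(scores):
        raise ValueError("gt, pred and score lists must align")
    for p, s in zip(pred_scenes, scores):
        if len(p) != len(np.atleast_1d(s)):
            raise ValueError("every prediction needs a score")
    n_gt_total = sum(len(g) for g in gt_scenes)
    thresholds = np.arange(0.5, 1.0, 0.05)
    aps = []
    for thr in thresholds:
        rows = []  # (score, is_tp)
        for gt, pred, sc in zip(gt_scenes, pred_scenes, scores):
            sc = np.atleast_1d(np.asarray(sc, dtype=np.float64))
            order = np.argsort(-sc, kind="stable")
            if len(gt) and len(pred):
                ious = np.array([[mask_iou(g, p) for p in pred.masks] for g in gt.masks])
            else:
                ious = np.zeros((len(gt), len(pred)))
            taken = np.zeros(len(gt), dtype=bool)
            for j in order:
                best_i, best_iou = -1, thr
                for i in range(len(gt)):
                    if not taken[i] and ious[i, j] >= best_iou:
                        best_i, best_iou = i, ious[i, j]
                if best_i >= 0:
                    taken[best_i] = True
                    rows.append((sc[j], True))
                else:
                    rows.append((sc[j], False))
        aps.append(_ap_from_rows(rows, n_gt_total))
    ap = float(np.mean(aps))
    return ap, float(aps[0]), float(aps[5])


def _ap_from_rows(rows: list[tuple[float, bool]], n_gt: int) -> float:
    """101-point interpolated AP from pooled (score, tp) detections."""
    if n_gt == 0 or not rows:
        return 0.0
    rows.sort(key=lambda t: -t[0])
    tp = np.cumsum([r[1] for r in rows])
    fp = np.cumsum([not r[1] for r in rows])
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope, then sample at 101 recall points
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    rec_points = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, rec_points, side="left")
    sampled = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
    return float(sampled.mean())


def evaluate_scene(
    gt: InstanceMaskSet, pred: InstanceMaskSet, threshold: float = 0.7, **match_kw
) -> dict:
    """All matched-pair metrics for one image."""
    match = match_instances(gt, pred, threshold, **match_kw)
    tprs, fprs = pixel_metrics(match, gt, pred)
    return {
        "dsc": [d for _, _, d in match.pairs],
        "tprp": tprs,
        "fprp": fprs,
        "fnro": fnr_object(match, len(gt)) if len(gt) else float("nan"),
        "n_gt": len(gt),
        "n_matched": len(match.pairs),
        "match": match,
    }


def _mean_std(vals: list[float]) -> tuple[float, float]:
    if not vals:
        return float("nan"), float("nan")
    arr = np.asarray(vals, dtype=np.float64)
    return float(arr.mean()), float(arr.std())


def evaluate_dataset(
    gt_scenes: list[InstanceMaskSet],
    pred_scenes: list[InstanceMaskSet],
    scores: list[np.ndarray] | None = None,
    threshold: float = 0.7,
    **match_kw,
) -> EvalReport:
    """Pool per-cell metrics across a dataset into an EvalReport."""
    all_dsc: list[float] = []
    all_tpr: list[float] = []
    all_fpr: list[float] = []
    fnros: list[float] = []
    per_image: list[dict] = []
    n_gt_cells = 0
    for gt, pred in zip(gt_scenes, pred_scenes):
        res = evaluate_scene(gt, pred, threshold, **match_kw)
        all_dsc.extend(res["dsc"])
        all_tpr.extend(res["tprp"])
        all_fpr.extend(res["fprp"])
        if np.isfinite(res["fnro"]):
            fnros.append(res["fnro"])
        n_gt_cells += res["n_gt"]
        per_image.append(
            {
                "n_gt": res["n_gt"],
                "n_matched": res["n_matched"],
                "dsc_mean": _mean_std(res["dsc"])[0],
                "fnro": res["fnro"],
            }
        )
    rep = EvalReport(threshold=threshold, n_images=len(gt_scenes), n_gt_cells=n_gt_cells)
    rep.dsc_mean, rep.dsc_std = _mean_std(all_dsc)
    rep.tprp_mean, rep.tprp_std = _mean_std(all_tpr)
    rep.fprp_mean, rep.fprp_std = _mean_std(all_fpr)
    rep.fnro_mean, rep.fnro_std = _mean_std(fnros)
    rep.per_image = per_image
    if scores is not None:
        rep.ap, rep.ap50, rep.ap75 = coco_ap(gt_scenes, pred_scenes, scores)
    return rep


def stratified_report(
    gt_scenes: list[InstanceMaskSet],
    pred_scenes: list[InstanceMaskSet],
    metadata: list[dict],
    scores: list[np.ndarray] | None = None,
    threshold: float = 0.7,
) -> EvalReport:
    """EvalReport with per-(cell count, overlap-rate bin) strata.

    Overlap-rate bins are width 0.1 over [0, 0.5]; strata keys are
    ``(cell_count, bin_index)``. Scenes lacking metadata land in an
    "unknown" stratum; empty strata are absent, never zero-filled.
    """
    rep = evaluate_dataset(gt_scenes, pred_scenes, scores, threshold)
    groups: dict[tuple[int, int] | str, list[int]] = {}
    for idx, meta in enumerate(metadata):
        if meta is None or "n_cells" not in meta or "achieved_overlap_rate" not in meta:
            warnings.warn(f"scene {idx} lacks stratification metadata", stacklevel=2)
            groups.setdefault("unknown", []).append(idx)
            continue
        r = float(meta["achieved_overlap_rate"])
        b = min(int(r / 0.1), 4)  # bins [0,0.1) .. [0.4,0.5]
        groups.setdefault((int(meta["n_cells"]), b), []).append(idx)
    strata: dict = {}
    for key, idxs in groups.items():
        sub = evaluate_dataset(
            [gt_scenes[i] for i in idxs],
            [pred_scenes[i] for i in idxs],
            [scores[i] for i in idxs] if scores is not None else None,
            threshold,
        )
        strata[key] = {
            "dsc_mean": sub.dsc_mean, "dsc_std": sub.dsc_std,
            "tprp_mean": sub.tprp_mean, "tprp_std": sub.tprp_std,
            "fprp_mean": sub.fprp_mean, "fprp_std": sub.fprp_std,
            "fnro_mean": sub.fnro_mean, "fnro_std": sub.fnro_std,
            "n_images": sub.n_images, "n_gt_cells": sub.n_gt_cells,
        }
    rep.strata = {k: v for k, v in strata.items() if isinstance(k, tuple)}
    if "unknown" in strata:
        rep.strata[(-1, -1)] = strata["unknown"]
    return rep


def plot_strata_heatmap(report: EvalReport, metric: str = "dsc_mean", path: str | None = None):
    """Render the (cell count x overlap bin) stratum table as a heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = [k for k in report.strata if k != (-1, -1)]
    if not keys:
        raise ValueError("report has no strata to plot")
    counts = sorted({k[0] for k in keys})
    bins = sorted({k[1] for k in keys})
    grid = np.full((len(counts), len(bins)), np.nan)
    for (c, b), vals in report.strata.items():
        if (c, b) == (-1, -1):
            continue
        grid[counts.index(c), bins.index(b)] = vals[metric]
    fig, ax = plt.subplots(figsize=(1.2 * len(bins) + 2, 0.6 * len(counts) + 2))
    im = ax.imshow(grid, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(bins)), [f"[{b / 10:.1f},{(b + 1) / 10:.1f})" for b in bins])
    ax.set_yticks(range(len(counts)), [str(c) for c in counts])
    ax.set_xlabel("overlap-rate bin")
    ax.set_ylabel("cells per image")
    ax.set_title(metric)
    fig.colorbar(im, ax=ax)
    if path:
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
    return fig
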