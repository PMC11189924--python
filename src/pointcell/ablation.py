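"""Hyperparameter ablation: point-head depth x point count x head on/off.

Re-trains and evaluates the model over a grid of (alpha, beta) settings —
alpha the number of point-head layers, beta the per-RoI point count — plus
an optional "without point head" baseline, all from one shared seed, and
tabulates DSC/TPRp/FPRp/FNRo (mean ± std) per grid cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .evaluation import EvalReport, evaluate_dataset
from .model import ModelConfig, train
from .refine import predict, predictions_to_masks
from .synth import InstanceMaskSet

log = logging.getLogger(__name__)

__all__ = ["AblationRow", "ablate", "evaluate_model"]


@dataclass
class AblationRow:
    alpha: int
    beta: int
    point_head: bool
    report: EvalReport | None
    failed: bool = False
    error: str = ""

    def label(self) -> str:
        if not self.point_head:
            return "without point head"
        return f"alpha={self.alpha}, beta={self.beta}"


def evaluate_model(result, eval_scenes, threshold: float = 0.7) -> EvalReport:
    """Run inference on held-out scenes and score the detections."""
    gt_sets, pred_sets, scores = [], [], []
    for image, masks, _ in eval_scenes:
        dets = predict(image, result, gt=masks)
        pred, sc = predictions_to_masks(dets)
        if pred is None:
            # an all-miss image still counts: represent with a 1-px dummy-free
            # empty set by scoring against zero predictions
            pred = InstanceMaskSet([])
            sc = np.zeros(0)
        gt_sets.append(masks)
        pred_sets.append(pred)
        scores.append(sc)
    return evaluate_dataset(gt_sets, pred_sets, scores, threshold=threshold)


def ablate(
    base_config: ModelConfig,
    train_scenes,
    eval_scenes,
    alphas: tuple[int, ...] = (2, 3, 4),
    betas: tuple[int, ...] = (196, 784),
    include_no_point_head: bool = True,
    threshold: float = 0.7,
) -> list[AblationRow]:
    """Train + evaluate each grid cell with a shared seed.

    A failing cell is marked failed and the run continues.
    """
    grid: list[tuple[int, int, bool]] = [(a, b, True) for a in alphas for b in betas]
    if include_no_point_head:
        grid.append((base_config.alpha, base_config.beta_train, False))
    rows: list[AblationRow] = []
    for alpha, beta, head_on in grid:
        cfg = replace(
            base_config,
            alpha=alpha,
            beta_train=beta,
            beta_infer=beta,
            use_point_head=head_on,
            seed=base_config.seed,
        )
        try:
            result = train(train_scenes, cfg, log_every=0)
            report = evaluate_model(result, eval_scenes, threshold=threshold)
            rows.append(AblationRow(alpha, beta, head_on, report))
        except Exception as e:  # noqa: BLE001 — keep the grid running
            log.warning("ablation cell (%s, %s, head=%s) failed: %s", alpha, beta, head_on, e)
            rows.append(AblationRow(alpha, beta, head_on, None, failed=True, error=str(e)))
    return rows


def format_table(rows: list[AblationRow]) -> str:
    lines = [f"{'setting':<24}{'DSC':>16}{'TPRp':>16}{'FPRp':>18}{'FNRo':>16}"]
    for r in rows:
        if r.failed or r.report is None:
            lines.append(f"{r.label():<24}{'FAILED: ' + r.error}")
            continue
        rep = r.report
        lines.append(
            f"{r.label():<24}"
            f"{rep.dsc_mean:7.3f}±{rep.dsc_std:5.3f} "
            f"{rep.tprp_mean:7.3f}±{rep.tprp_std:5.3f} "
            f"{rep.fprp_mean:8.4f}±{rep.fprp_std:6.4f} "
            f"{rep.fnro_mean:7.3f}±{rep.fnro_std:5.3f}"
        )
    return "\n".join(lines)
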