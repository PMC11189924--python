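# pointcell

Instance segmentation of **overlapping cervical cells** in cytology images,
with PointRend-style boundary refinement, a synthetic overlapping-cell scene
generator, and the overlapping-cytology challenge evaluation protocol
(DSC / TPRp / FPRp / FNRo and COCO-style mask AP).

Cervical cytology (Pap) micrographs show translucent cells whose cytoplasm
regions overlap inside clumps, so a prediction must be a *set of
per-instance binary masks that may share pixels* — a label image cannot
represent the ground truth, and the hard part is the cytoplasm *boundary*
inside clumps. `pointcell` is aimed at people building or studying
segmentation pipelines for this kind of data who want a self-contained,
CPU-scale, fully tested implementation of the whole loop: data synthesis →
training → point-refined inference → challenge-protocol scoring.

## The method

A two-stage network in the Mask R-CNN mould with a point-refinement head:

* a convolutional backbone with a feature pyramid `P2..P5` (strides
  4/8/16/32);
* per-proposal features via **RoI align** (bilinear sampling at continuous
  coordinates, 7×7 output);
* a **mask branch** that upsamples 7×7 → 28×28 by two stride-2 transposed
  convolutions and predicts a coarse cytoplasm probability grid;
* a **point head**: for sample points `(x, y)` whose predicted probability
  is closest to 0.5 (the uncertain, boundary-adjacent ones), a shared MLP
  of `α` layers × 256 channels re-predicts the label from the concatenated
  point-wise features `F_fine ⊕ F_coarse` — `F_fine` interpolated from
  `P2`, `F_coarse` from the RoI feature. `β = 196` points are sampled per
  RoI during training, `784` per refinement pass at inference;
* training minimises the unweighted sum
  `L = L_mask + L_point + L_box + L_cls`, with the point term the mean
  binary cross-entropy `−[yₙ log σ(xₙ) + (1−yₙ) log(1−σ(xₙ))]`, by SGD
  (lr 0.002, momentum 0.9, 2 images per batch).

Evaluation follows the overlapping-cytology challenge protocol: a
ground-truth cell counts as segmented when some prediction reaches DSC
`2|A∩B|/(|A|+|B|)` above a threshold (0.7 or 0.8); `FNRo` is the fraction
of undetected cells; `TPRp = TP/(TP+FN)` and `FPRp = FP/(FP+TN)` are
computed per matched pair only (undetected cells are excluded from the
pixel metrics), with TN the full-image complement of the pair's union.

Everything runs on one CPU: the network is built on a small numpy
reverse-mode autodiff engine (`pointcell.nn`) and the tested default
backbone is a 4-stage tiny CNN. No external data is needed — the
`synth` module generates 2–10-cell scenes with mean overlap rates in
[0, 0.5] and exact per-cell ground truth.

## Worked example

```python
import numpy as np
import pointcell as pc
from pointcell.ablation import evaluate_model

synth = pc.SynthConfig(image_size=64, n_cells_range=(2, 6),
                       target_overlap_rate=0.3, cell_radius_frac=(0.13, 0.2), seed=1)
train_scenes = pc.generate_dataset(synth, 48, seed=2)
eval_scenes  = pc.generate_dataset(synth, 16, seed=3)

cfg = pc.ModelConfig(widths=(8, 16, 32, 64), fpn_width=16, epochs=40, seed=4)
result = pc.train(train_scenes, cfg)
print(f"loss {result.loss_curve[0]:.3f} -> {result.loss_curve[-1]:.3f}")

report = evaluate_model(result, eval_scenes, threshold=0.7)
print(f"DSC {report.dsc_mean:.3f}±{report.dsc_std:.3f}  TPRp {report.tprp_mean:.3f}  "
      f"FPRp {report.fprp_mean:.4f}  FNRo {report.fnro_mean:.3f}  AP50 {report.ap50:.3f}")
```

On the seed shown in `scripts/acceptance.py --seed 1` this pipeline prints

```
trained 40 epochs: total loss 2.066 -> 0.772
DSC 0.934  TPRp 0.962  FPRp 0.0075  FNRo 0.000  AP50 1.000
```

i.e. the trained model finds every held-out cell (FNRo 0) and overlaps
each ground-truth cytoplasm at mean Dice 0.93; FPRp stays below 1% of the
background. The `examples/` directory holds short narrative scripts for
each capability, and the same pipeline is exposed as a CLI:

```sh
pointcell synth --n-images 20 --image-size 64 --cells 2,6 --overlap 0.3 --seed 1 --out data/
pointcell train --data data/ --out model.npz --epochs 40
pointcell predict --ckpt model.npz --in data/ --out pred/
pointcell evaluate --gt data/ --pred pred/ --threshold 0.7 --out report.json
pointcell ablate --data data/ --eval-data data/ --out ablation.json
```

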