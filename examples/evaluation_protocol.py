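"""Walk through the challenge metrics on hand-built masks.

Small, fully inspectable inputs: a 10x10 image with a 4x4 ground-truth
square and the same square shifted by one pixel, so every TP/FN/FP/TN
count can be verified by hand.
"""

import numpy as np

import pointcell as pc

gt_mask = np.zeros((10, 10), bool)
gt_mask[3:7, 3:7] = True          # 16 pixels
pred_mask = np.zeros((10, 10), bool)
pred_mask[3:7, 4:8] = True        # shifted right by 1: 12 shared pixels

gt = pc.InstanceMaskSet([gt_mask])
pred = pc.InstanceMaskSet([pred_mask])

print(f"DSC = 2*12/(16+16) = {pc.dsc(gt_mask, pred_mask):.3f}  (matched at threshold 0.7)")
match = pc.match_instances(gt, pred, threshold=0.7)
tprs, fprs = pc.pixel_metrics(match, gt, pred)
print(f"TPRp = TP/(TP+FN) = 12/16 = {tprs[0]:.3f}")
print(f"FPRp = FP/(FP+TN) = 4/84  = {fprs[0]:.4f}  (TN spans the whole image)")
print(f"FNRo = {pc.fnr_object(match, len(gt)):.2f}  (every cell was detected)")

# add an undetected cell: the exclusion rule keeps pixel metrics unchanged
lonely = np.zeros((10, 10), bool)
lonely[0:2, 0:2] = True
gt2 = pc.InstanceMaskSet([gt_mask, lonely])
match2 = pc.match_instances(gt2, pred, threshold=0.7)
tprs2, _ = pc.pixel_metrics(match2, gt2, pred)
print(f"\nwith an undetected cell: TPRp still {tprs2[0]:.3f}, "
      f"but FNRo = {pc.fnr_object(match2, 2):.2f} "
      "(missed cells change FNRo only — the exclusion rule)")

ap, ap50, ap75 = pc.coco_ap([gt2], [pred], [np.ones(1)])
print(f"COCO mask AP50 = {ap50:.3f} (one of two cells found, precision 1 to recall 0.5)")
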