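"""Metric definitions, fold aggregation and comparison arithmetic.

DSC = 2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN), and the identity
DSC = 2*IoU/(1+IoU) ties the two together.  Fold summaries use the
population (divide-by-n) standard deviation.
"""

import numpy as np

from imau_seg import (
    ConfusionCounts, MetricReport, aggregate_folds, dice, dice_from_jaccard,
    external_validation_report, hd95, jaccard, paired_t_test,
)

c = ConfusionCounts(tp=3, fp=1, fn=1, tn=11)
print(f"counts tp=3 fp=1 fn=1:  Dice {dice(c):.2f}, IoU {jaccard(c):.2f}")
print(f"identity: IoU 0.8483 -> Dice {dice_from_jaccard(0.8483):.4f}")

a = np.zeros((10, 10), np.uint8); a[3, 2] = 1
b = np.zeros((10, 10), np.uint8); b[3, 7] = 1
print(f"HD95 of two pixels 5 px apart: {hd95(a, b):.1f} px")

folds = [0.9156, 0.9192, 0.9145, 0.9208, 0.9194]
summary = aggregate_folds([MetricReport(dice=d) for d in folds])
print(f"5-fold Dice: {summary.mean['dice']:.4f} ± {summary.std['dice']:.4f} "
      "(population std)")

rival = [0.9031, 0.9062, 0.9014, 0.9078, 0.9055]  # a weaker model's folds
t = paired_t_test(folds, rival)
print(f"paired t vs the weaker model: t={t.statistic:.1f}, p={t.p_value:.2e}")

rep = external_validation_report(MetricReport(dice=0.9179, auc=0.9783),
                                 MetricReport(dice=0.8745, auc=0.9542))
print(f"zero-shot domain shift: Dice drop {rep.dice_drop:.4f} "
      f"({rep.dice_drop_pct_points:.2f} pp), AUC drop {rep.auc_drop:.4f}")
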