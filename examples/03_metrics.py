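"""Diagnostic metrics from a confusion matrix, in the reporting style used
for PI-RADS risk classifiers.

The example matrix is a 586-slice test set with 303 true positives, 262 true
negatives, 13 false positives and 8 false negatives; sensitivity is the
recall of the high-suspicion class, specificity the recall of the low-
suspicion class.
"""

from dsanet import ConfusionMatrix, classification_metrics, roc_curve_auc
from dsanet.evaluation import as_percent, report_table

cm = ConfusionMatrix(tp=303, tn=262, fp=13, fn=8)
report = classification_metrics(cm)
print(report_table(report))
print(f"sensitivity {as_percent(report.sensitivity)}, "
      f"specificity {as_percent(report.specificity)}, "
      f"accuracy {as_percent(report.accuracy)}")

labels = [1, 1, 0, 0, 1, 0]
scores = [0.95, 0.60, 0.70, 0.30, 0.75, 0.20]
_, auc = roc_curve_auc(labels, scores)
print(f"\nranking example: AUC {auc:.3f} "
      "(probability a random positive outranks a random negative)")
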