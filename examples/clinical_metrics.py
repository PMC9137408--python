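"""Derive the five performance metrics from a per-cell validation tally.

A clinical validation of a CTC detector is summarized by a confusion
matrix over labeled cells.  This example feeds a 1,067-cell tally
(209 TP, 788 TN, 21 FP, 49 FN — 258 true CTCs against 809
leukocytes/other) through the metrics module and prints the five
standard figures of merit.
"""

from ctcdetect import ConfusionMatrix, compute_metrics

cm = ConfusionMatrix(tp=209, fp=21, tn=788, fn=49)
print(f"cells: {cm.total}  (CTC: {cm.tp + cm.fn}, non-CTC: {cm.tn + cm.fp})")
print(compute_metrics(cm).format_text())
print()
print("Sensitivity is the fraction of true CTCs recovered; specificity the "
      "fraction of non-CTCs correctly rejected.")
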