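"""The paired count/percentage confusion report on a published example.

Expands the six-activity benchmark count table (handcrafted-feature
pipeline, 2947 test windows) into label vectors, tallies them through the
metrics module, and renders the full (NC+1) x (NC+1) report: inner cells
pair each count with its share of the test set, the last column holds
per-predicted-class precision (and its complement), the last row per-true-
class recall, and the corner the overall accuracy / error pair.
"""

import celearn as ce
from celearn.reference import ACTIVITY_NAMES, HANDCRAFTED_COUNTS, counts_to_labels

y_true, y_pred = counts_to_labels(HANDCRAFTED_COUNTS)
cm = ce.confusion_matrix(y_true, y_pred, 6, class_names=ACTIVITY_NAMES)

print(ce.render_confusion(cm))
print()
print(f"samples scored (P):        {cm.total}")
print(f"overall accuracy:          {100 * cm.accuracy:.2f}%")
print(f"walking precision/recall:  {100 * cm.precision[0]:.2f}% / "
      f"{100 * cm.recall[0]:.2f}%")
print("(precision reads along a predicted-class row; "
      "recall down a true-class column)")
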