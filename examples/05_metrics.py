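"""Classification metrics on a worked confusion-matrix example.

With malignant as the positive class: 50 melanomas and 42 benign
lesions classified correctly, 3 false alarms, 5 missed melanomas.
"""

from dermao.metrics import (
    ConfusionMatrix, accuracy, as_percent, f1, precision, roc_auc,
    sensitivity, specificity,
)

cm = ConfusionMatrix(tp=50, tn=42, fp=3, fn=5)
print(cm.render())
print(f"accuracy:    {as_percent(accuracy(cm), 1)}%   (all correct / all cases)")
print(f"sensitivity: {as_percent(sensitivity(cm), 1)}%   (melanomas detected)")
print(f"specificity: {as_percent(specificity(cm), 1)}%   (benign correctly cleared)")
print(f"precision:   {as_percent(precision(cm), 1)}%   (malignant calls that were right)")
print(f"f1:          {as_percent(f1(cm), 1)}%   (harmonic mean of precision and recall)")

scores = [0.95, 0.9, 0.8, 0.7, 0.6, 0.3, 0.2, 0.1]
y_true = [1, 1, 1, 0, 1, 0, 0, 0]
print(f"\nrank-based AUC on an 8-case score list: {roc_auc(scores, y_true):.3f}"
      " (probability a random melanoma outscores a random benign lesion)")
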