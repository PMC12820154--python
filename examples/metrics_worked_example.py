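"""Classification metrics from confusion counts.

Evaluates the standard binary metrics on the held-out-test confusion counts
of a federated run (624 chest X-rays, 390 pneumonia) and of a centralized
baseline, then shows ROC/Youden analysis on synthetic scores.
"""

import numpy as np

from fedlora import (
    ConfusionMatrix,
    classification_metrics,
    pr_average_precision,
    roc_auc,
    youden_threshold,
)

for name, cm in [
    ("federated", ConfusionMatrix(tp=384, fn=6, fp=66, tn=168)),
    ("centralized", ConfusionMatrix(tp=247, fn=143, fp=82, tn=152)),
]:
    r = classification_metrics(cm)
    print(f"{name} model (TP={cm.tp}, FN={cm.fn}, FP={cm.fp}, TN={cm.tn}):")
    print(f"  accuracy            {r.percent('pneumonia', 'accuracy'):6.2f}%")
    print(f"  pneumonia recall    {r.percent('pneumonia', 'recall'):6.2f}%")
    print(f"  pneumonia precision {r.percent('pneumonia', 'precision'):6.2f}%")
    print(f"  pneumonia F1        {r.percent('pneumonia', 'f1'):6.2f}%")
    print(f"  normal recall       {r.percent('normal', 'recall'):6.2f}%")
    print(f"  normal precision    {r.percent('normal', 'precision'):6.2f}%")
    print()

# threshold analysis on synthetic well-separated scores
rng = np.random.default_rng(0)
labels = np.r_[np.zeros(50, int), np.ones(50, int)]
scores = np.clip(np.r_[rng.normal(0.3, 0.15, 50), rng.normal(0.8, 0.15, 50)], 0, 1)
t, j = youden_threshold(scores, labels)
print(f"synthetic scores: AUC {roc_auc(scores, labels):.4f}, "
      f"AP {pr_average_precision(scores, labels):.4f}, "
      f"Youden J {j:.3f} at threshold {t:.3f}")
# Youden's J picks the cutoff maximizing sensitivity + specificity - 1.
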