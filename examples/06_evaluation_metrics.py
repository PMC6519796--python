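"""The evaluation toolkit on a worked set of predictions.

AUC with a Wilson interval, the Brier score, classification at the 7.5%
treatment threshold, and the net reclassification index between two
models — the same statistics the study battery reports.
"""

import numpy as np
from scipy.special import expit

from prognopipe.evaluation import (
    auc_roc,
    brier_score,
    confusion_at_threshold,
    net_reclassification_index,
    wilson_interval,
)

rng = np.random.default_rng(3)
n = 20_000
signal = rng.standard_normal(n)
risk_true = expit(1.2 * signal - 4.5)        # ~1% prevalence
labels = (rng.random(n) < risk_true).astype(int)
model_a = expit(1.2 * signal - 4.5)          # well-specified model
noisy = 0.6 * signal + 0.8 * rng.standard_normal(n)
model_b = expit(1.2 * noisy - 4.5)           # weaker model: degraded signal

for tag, p in (("model A", model_a), ("model B", model_b)):
    auc = auc_roc(p, labels)
    lo, hi = wilson_interval(auc, int(labels.sum()))
    print(f"{tag}: AUC {auc:.3f} (95% Wilson {lo:.3f}-{hi:.3f}), "
          f"Brier {brier_score(p, labels):.4f}")

cs = confusion_at_threshold(model_a, labels, 0.075)
print(f"\nat the 7.5% threshold, model A flags {cs.tp + cs.fp} participants: "
      f"sensitivity {cs.sensitivity:.1%}, PPV {cs.ppv:.1%}")

nri = net_reclassification_index(model_a, model_b, labels, 0.075)
print(f"NRI of A over B at 7.5%: {100 * nri:+.1f}% "
      f"(net correct movement across the threshold)")
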