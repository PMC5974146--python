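"""Evaluation toolkit: curves, AUC, bootstrap comparison, and recovering a
full metric set from printed sensitivity/specificity rates.

Published comparisons often print only sensitivity and specificity at known
class sizes; counts_from_rates rebuilds the integer confusion matrix
(round-half-up), from which every derived metric follows exactly.
"""

import numpy as np

from plantmito import evaluation as ev

# metric reconstruction at class sizes 100/100
rep = ev.metrics(ev.counts_from_rates(sensitivity=0.60, specificity=0.88,
                                      n_pos=100, n_neg=100))
print(f"sens 0.60 / spec 0.88 at 100/100 -> accuracy {rep.accuracy:.3f}, "
      f"precision {rep.precision:.3f}, F1 {rep.f1:.3f}, MCC {rep.mcc:.3f}")

# ROC/AUC and a paired bootstrap comparison of two scorers
rng = np.random.default_rng(4)
labels = np.repeat([0, 1], 100)
good = labels + rng.normal(0, 0.45, 200)
weak = labels + rng.normal(0, 1.5, 200)
print(f"AUC(good) = {ev.roc_auc(labels, good):.3f}, "
      f"AUC(weak) = {ev.roc_auc(labels, weak):.3f}")
p = ev.bootstrap_auc_compare(good, weak, labels, n_boot=2000, seed=0)
print(f"one-sided bootstrap p-value that the stronger scorer ranks better: {p:.4f}")
print("p below 0.05 rejects equal ranking performance in favor of the "
      "first scorer.")
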