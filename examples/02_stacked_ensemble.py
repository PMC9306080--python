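"""Chemical-space hit identification with the stacked ensemble.

Trains random forest + gradient boosting base learners with 10-fold
cross-validation, feeds their out-of-fold probabilities to the network
super learner, and evaluates on a held-out 30%.  Printed numbers: held-out
accuracy / sensitivity / specificity / AUC / BCR (the balance-penalized
rate) and the ensemble diversity entropy E of the base learners.
"""

import numpy as np

from ahiot.cs_stack import (classification_metrics, ensemble_entropy,
                            predict_stacked, train_stacked)
from ahiot.io_prep import DescriptorMatrix
from ahiot.synthetic import DescriptorGenSpec, gen_descriptor_matrix

matrix, _ = gen_descriptor_matrix(DescriptorGenSpec(
    n=200, p=16, class_sep=2.0, n_informative=5, seed=1))
rng = np.random.default_rng(1)
order = rng.permutation(matrix.n)
tr, te = order[:140], order[140:]

def subset(idx):
    return DescriptorMatrix(ids=[matrix.ids[i] for i in idx],
                            feature_names=list(matrix.feature_names),
                            values=matrix.values[idx], labels=matrix.labels[idx])

model, level_one = train_stacked(subset(tr), J=10, seed=1)
proba, pred = predict_stacked(model, subset(te))
m = classification_metrics(matrix.labels[te], proba)
diversity = ensemble_entropy((level_one.z >= 0.5).astype(int), level_one.y)

print(f"held-out accuracy={m.accuracy:.3f} Se={m.sensitivity:.3f} "
      f"Sp={m.specificity:.3f} AUC={m.auc:.3f} BCR={m.bcr:.3f}")
print(f"base-learner diversity entropy E={diversity:.3f} "
      "(0 = identical errors, 1 = maximal disagreement)")
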