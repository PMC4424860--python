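"""Train the RBF-SVM component classifier and apply it to a held-out set.

Generates two independent synthetic decompositions (50 training components,
30 test components), extracts and conditions the five features, trains with
cost 100 and the sigma-quantile heuristic, then classifies the held-out set
and prints agreement with the generator's truth labels.
"""

import numpy as np

import icsift as ic
from icsift.svm import metrics

train_cfg = ic.GeneratorConfig(n_rfn=17, n_art=33, seed=11)
test_cfg = ic.GeneratorConfig(n_rfn=10, n_art=20, seed=23)
gm, _, _ = ic.make_templates(train_cfg)

train_set, train_labels = ic.make_ica_set(train_cfg)
test_set, test_labels = ic.make_ica_set(test_cfg)

table = ic.extract_feature_table(train_set, gm)
y = np.array([1 if train_labels[i] == ic.RFN else 0 for i in table.index])
model = ic.fit_conditioned(table, y, seed=5)
print(f"trained: {model.n_support} support vectors, sigma = {model.sigma:.3f}, C = {model.cost:g}")

pred, counts = ic.classify_set(model, test_set, gm)
confusion, m = metrics(pred, test_labels)
print(f"held-out set: N_RFN = {counts.n_rfn}, N_ART = {counts.n_art} of NIC = {counts.nic}")
print(f"tp={confusion.tp} fp={confusion.fp} tn={confusion.tn} fn={confusion.fn}")
print(
    f"precision={m.precision:.2f} sensitivity={m.sensitivity:.2f} "
    f"specificity={m.specificity:.2f} accuracy={m.accuracy:.2f}"
)
# sensitivity is the fraction of true networks kept (the class the asymmetric
# cost protects); specificity is the fraction of artifacts correctly removed.
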