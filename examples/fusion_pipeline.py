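"""Joint fusion of the WSI score with clinical covariates.

Trains the image arm with leakage-free out-of-fold scoring, the clinical
arm with a grid-searched SVM, then the fused model on the concatenated
features, and compares the three on the held-out test split.
"""

import numpy as np

from milfusion import clinical as cl
from milfusion.evaluation import auc
from milfusion.fusion import (build_fused_features, compute_oof_wsi_scores,
                              ensemble_wsi_scores)
from milfusion.mil import MILConfig
from milfusion.synthetic import SyntheticConfig, generate_cohort

cohort = generate_cohort(SyntheticConfig(n_cases=200, seed=2))
tr, te = cohort.subset("train"), cohort.subset("test")
bags, labels = tr.bags(), tr.labels()

mil_config = MILConfig(feature_dim=64, hidden_dim=64, attention_dim=32,
                       max_epochs=20, patience=8, seed=0)
oof = compute_oof_wsi_scores(bags, labels, mil_config, k=5, seed=0)
oof.assert_no_leakage()
wsi_te = ensemble_wsi_scores(oof.models, te.bags())
print(f"WSI-only test AUC:      {auc(wsi_te, te.labels()):.3f}")

Xtr = cl.encode_features(tr.records(), "two")
Xte = cl.encode_features(te.records(), "two")
folds = cl.stratified_folds(labels, k=5, seed=0)
best, _ = cl.grid_search_cv(Xtr, labels, cl.default_grid("SVM"), folds, seed=0)
clin = cl.fit(Xtr, labels, "SVM", best, seed=0)
print(f"clinical-only test AUC: {auc(cl.predict_proba(clin, Xte), te.labels()):.3f} "
      f"(SVM {best})")

ids_tr = [r.case_id for r in tr.records()]
fused_tr = build_fused_features(Xtr, cl.FEATURE_SETS["two"], ids_tr, oof.scores, ids_tr)
best_f, _ = cl.grid_search_cv(fused_tr.matrix, labels, cl.default_grid("SVM"),
                              folds, seed=0)
fused_model = cl.fit(fused_tr.matrix, labels, "SVM", best_f, seed=0)
ids_te = [r.case_id for r in te.records()]
fused_te = build_fused_features(Xte, cl.FEATURE_SETS["two"], ids_te, wsi_te, ids_te)
fused_auc = auc(cl.predict_proba(fused_model, fused_te.matrix), te.labels())
print(f"fused test AUC:         {fused_auc:.3f}")
print("fusion should match or beat the best single modality: the image arm "
      "sees patch morphology, the clinical arm sees slide-level factors "
      "(DOI, pT) that patches cannot carry.")
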