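"""Feature-table modeling: split, scale, select, fit, evaluate, nomogram.

Uses the planted-feature generator (3 informative of 100 features) to run
the canonical radiomics pipeline and report threshold-free and
decision-analytic metrics.
"""

import numpy as np

from imquant import modeling as M
from imquant.phantoms import make_feature_dataset

df, truth = make_feature_dataset(n=300, p=100, n_informative=3,
                                 effect_size=1.5, seed=0)
print(f"dataset: {len(df)} subjects, 100 features, "
      f"informative = {truth['informative']}")

split = M.split_data(df, M.SplitSpec("random_proportion", 0.7, seed=0))
train, test = df[(split == "train").to_numpy()], df[(split == "test").to_numpy()]
train_s, test_s, _ = M.standardize(train, test, M.ScalerSpec("zscore"))
sel = M.select_features(train_s, "lasso", seed=0)
print(f"LASSO kept {len(sel.selected)} features; "
      f"all informative recovered: {set(truth['informative']) <= set(sel.selected)}")

train_f, test_f = sel.transform(train_s), sel.transform(test_s)
clf = M.fit_classifier(train_f, M.ClassifierSpec("logistic_regression"))
scores = clf.predict_proba(test_f[M.feature_columns(test_f)].to_numpy())[:, 1]
rep = M.evaluate_classifier(scores, test_f["label"].to_numpy())
print(f"held-out AUC {rep.auc:.3f} (95% CI {rep.auc_ci[0]:.3f}-{rep.auc_ci[1]:.3f}), "
      f"sensitivity {rep.sensitivity:.2f}, specificity {rep.specificity:.2f}")

dc = M.decision_curve(scores, test_f["label"].to_numpy())
t20 = np.argmin(np.abs(dc.thresholds - 0.2))
print(f"net benefit at risk threshold 0.20: model {dc.net_benefit_model[t20]:.3f} "
      f"vs treat-all {dc.net_benefit_all[t20]:.3f} "
      "(higher = more clinically useful)")

# nomogram over the two strongest predictors
cols = sel.selected[:2]
import sklearn.linear_model as lm

sub = train_f[cols].to_numpy()
logit = lm.LogisticRegression().fit(sub, train_f["label"])
nm = M.build_nomogram(dict(zip(cols, logit.coef_[0])), float(logit.intercept_[0]),
                      {c: (train_f[c].min(), train_f[c].max()) for c in cols})
sample = {c: float(test_f[c].iloc[0]) for c in cols}
pts, prob = M.nomogram_score(nm, sample)
print(f"nomogram for first test subject: {pts:.1f} points -> "
      f"predicted probability {prob:.3f}")
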