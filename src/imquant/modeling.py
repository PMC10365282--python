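"""Tabular modeling layer: grouping, scaling, selection, classifiers, and
classification/regression evaluation including decision-analytic curves.

A sample table is a pandas ``DataFrame`` with a ``subject_id`` column, a
``label`` column and named feature columns. Scalers and selectors are
always fitted on training rows only. The classifier zoo dispatches 13
algorithm names onto scikit-learn (and xgboost) estimators with seeded
determinism; probabilities are class-1 probabilities in [0, 1].

Authored here rather than delegated: the DeLong AUC confidence interval,
decision and clinical-impact curves, and the nomogram point system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA, FactorAnalysis, FastICA
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              GradientBoostingClassifier, RandomForestClassifier)
from sklearn.feature_selection import SelectKBest, VarianceThreshold, f_classif
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LassoCV, LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import (MaxAbsScaler, MinMaxScaler, Normalizer,
                                   PowerTransformer, QuantileTransformer,
                                   StandardScaler)
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec", "ScalerSpec", "ClassifierSpec", "CLASSIFIER_NAMES",
    "split_data", "standardize", "select_features", "SelectionResult",
    "fit_classifier", "evaluate_classifier", "ClassificationReport",
    "decision_curve", "DecisionCurves", "evaluate_regressor",
    "RegressionReport", "build_nomogram", "nomogram_score", "NomogramModel",
    "delong_ci",
]

FEATURE_EXCLUDE = ("subject_id", "label", "group")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in FEATURE_EXCLUDE]


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    method: Literal["custom", "random_proportion", "cross_validation"] = "random_proportion"
    proportion: float = 0.7  # training fraction
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.proportion < 1:
            raise ValueError("proportion must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")


def split_data(table: pd.DataFrame, spec: SplitSpec):
    """Train/test assignment (Series 'train'/'test') or list of k folds.

    Random and cross-validation grouping are stratified by class and
    deterministic for a fixed seed; custom grouping reproduces the
    table's ``group`` column verbatim.
    """
    if "label" not in table.columns:
        raise ValueError("table must have a 'label' column")
    y = table["label"].to_numpy()
    if spec.method == "custom":
        if "group" not in table.columns:
            raise ValueError("custom grouping requires a 'group' column")
        assignment = table["group"].astype(str)
    elif spec.method == "random_proportion":
        idx_train, idx_test = train_test_split(
            np.arange(len(table)), train_size=spec.proportion,
            random_state=spec.seed, stratify=y)
        assignment = pd.Series("test", index=table.index, name="group")
        assignment.iloc[idx_train] = "train"
    else:
        skf = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
        return [(tr, te) for tr, te in skf.split(np.zeros(len(table)), y)]
    train_labels = set(y[(assignment == "train").to_numpy()])
    if set(y) - train_labels:
        raise ValueError("a class is absent from the training split")
    return assignment


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

_SCALERS = {
    "zscore": StandardScaler,
    "min_max": MinMaxScaler,
    "quantile": QuantileTransformer,
    "yeojohnson": lambda: PowerTransformer("yeo-johnson"),
    "boxcox": lambda: PowerTransformer("box-cox"),
    "l1_norm": lambda: Normalizer("l1"),
    "l2_norm": lambda: Normalizer("l2"),
    "max_abs": MaxAbsScaler,
}


@dataclass(frozen=True)
class ScalerSpec:
    method: Literal["zscore", "min_max", "quantile", "yeojohnson", "boxcox",
                    "l1_norm", "l2_norm", "max_abs"] = "zscore"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _SCALERS:
            raise ValueError(f"unknown scaler {self.method!r}")


def standardize(train: pd.DataFrame, test: pd.DataFrame | None,
                spec: ScalerSpec = ScalerSpec()):
    """Fit the scaler on the training rows only and apply it to both."""
    cols = feature_columns(train)
    if spec.method == "boxcox" and (train[cols].to_numpy() <= 0).any():
        raise ValueError("boxcox requires strictly positive feature values")
    if spec.method == "zscore":
        zero_var = [c for c in cols if train[c].std(ddof=0) == 0]
        if zero_var:
            logger.warning("zscore: %d zero-variance columns left at 0", len(zero_var))
    factory = _SCALERS[spec.method]
    scaler = factory()
    if spec.method == "quantile":
        scaler.set_params(n_quantiles=min(len(train), 1000), random_state=spec.seed)
    scaler.fit(train[cols].to_numpy())

    def apply(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out[cols] = scaler.transform(df[cols].to_numpy())
        return out

    return apply(train), (apply(test) if test is not None else None), scaler


# ---------------------------------------------------------------------------
# Feature selection / dimension reduction
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    method: str
    selected: list[str] | None          # named columns kept (selectors)
    transformer: object | None          # fitted transformer (reductions)
    report: dict = field(default_factory=dict)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = feature_columns(table)
        keep = [c for c in table.columns if c not in cols]
        if self.selected is not None:
            return table[keep + self.selected].copy()
        scores = self.transformer.transform(table[cols].to_numpy())  # type: ignore[union-attr]
        out = table[keep].copy()
        for j in range(scores.shape[1]):
            out[f"{self.method}_{j}"] = scores[:, j]
        return out


def select_features(train: pd.DataFrame,
                    method: Literal["variance_threshold", "kbest_univariate",
                                    "lasso", "pca", "ica", "lda",
                                    "factor_analysis"] = "kbest_univariate",
                    threshold: float = 0.0, k: int = 10,
                    alpha: float | None = None, n_components: int = 2,
                    seed: int = 0) -> SelectionResult:
    """Fit a selector/reduction on the training rows.

    Selectors return named columns (variance threshold, univariate F-test
    k-best, LASSO with internal CV when no penalty is given); reductions
    (PCA/ICA/LDA/factor analysis) return fitted transformers producing
    component scores.
    """
    cols = feature_columns(train)
    X = train[cols].to_numpy()
    y = train["label"].to_numpy() if "label" in train else None

    if method == "variance_threshold":
        sel = VarianceThreshold(threshold=threshold).fit(X)
        keep = [c for c, m in zip(cols, sel.get_support()) if m]
        return SelectionResult(method, keep, None, {"threshold": threshold})
    if method == "kbest_univariate":
        if k > len(cols):
            raise ValueError(f"k={k} exceeds feature count {len(cols)}")
        sel = SelectKBest(f_classif, k=k).fit(X, y)
        keep = [c for c, m in zip(cols, sel.get_support()) if m]
        scores = dict(zip(cols, sel.scores_))
        return SelectionResult(method, keep, None, {"f_scores": scores})
    if method == "lasso":
        if alpha is None:
            model = LassoCV(cv=5, random_state=seed).fit(X, y)
        else:
            from sklearn.linear_model import Lasso

            model = Lasso(alpha=alpha).fit(X, y)
        keep = [c for c, w in zip(cols, model.coef_) if w != 0.0]
        return SelectionResult(method, keep, None,
                               {"alpha": float(getattr(model, "alpha_", alpha or 0.0)),
                                "coef": dict(zip(cols, model.coef_))})
    if method in ("pca", "ica", "factor_analysis"):
        cls = {"pca": PCA, "ica": FastICA, "factor_analysis": FactorAnalysis}[method]
        tr = cls(n_components=n_components, random_state=seed).fit(X)
        return SelectionResult(method, None, tr, {"n_components": n_components})
    if method == "lda":
        if y is None or len(np.unique(y)) < 2:
            raise ValueError("LDA requires at least two classes")
        tr = LinearDiscriminantAnalysis(
            n_components=min(n_components, len(np.unique(y)) - 1)).fit(X, y)
        return SelectionResult(method, None, tr, {})
    raise ValueError(f"unknown selection method {method!r}")


# ---------------------------------------------------------------------------
# Classifier zoo
# ---------------------------------------------------------------------------

CLASSIFIER_NAMES = (
    "adaboost", "bagging_tree", "decision_tree", "gaussian_process", "gbdt",
    "knn", "random_forest", "logistic_regression", "xgboost", "sgd", "svm",
    "qda", "plsda",
)


class PLSDAClassifier:
    """Partial least squares discriminant analysis with a logistic link.

    PLS regression on the 0/1 label; the latent prediction is mapped to a
    class-1 probability through a logistic function calibrated on the
    training scores (location = 0.5 on the regression scale).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.classes_ = np.unique(y).astype(int)
        nc = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        self._pls = PLSRegression(n_components=nc).fit(X, y)
        raw = self._pls.predict(X).ravel()
        self._scale = max(raw.std(), 1e-6)
        return self

    def predict_proba(self, X):
        raw = self._pls.predict(np.asarray(X, dtype=float)).ravel()
        p1 = 1.0 / (1.0 + np.exp(-(raw - 0.5) / self._scale))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def get_params(self, deep=True):
        return {"n_components": self.n_components}

    def set_params(self, **p):
        self.n_components = p.get("n_components", self.n_components)
        return self


@dataclass(frozen=True)
class ClassifierSpec:
    algorithm: str = "logistic_regression"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; valid names: "
                + ", ".join(CLASSIFIER_NAMES))


def _make_estimator(spec: ClassifierSpec):
    s = spec.seed
    base = {
        "adaboost": lambda: AdaBoostClassifier(random_state=s),
        "bagging_tree": lambda: BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=s), random_state=s),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=s),
        "gaussian_process": lambda: GaussianProcessClassifier(random_state=s),
        "gbdt": lambda: GradientBoostingClassifier(random_state=s),
        "knn": lambda: KNeighborsClassifier(),
        "random_forest": lambda: RandomForestClassifier(random_state=s),
        "logistic_regression": lambda: LogisticRegression(max_iter=2000),
        "sgd": lambda: SGDClassifier(loss="log_loss", random_state=s),
        "svm": lambda: SVC(probability=True, random_state=s),
        "qda": lambda: QuadraticDiscriminantAnalysis(),
        "plsda": lambda: PLSDAClassifier(),
    }
    if spec.algorithm == "xgboost":
        from xgboost import XGBClassifier

        est = XGBClassifier(random_state=s, n_estimators=100, verbosity=0,
                            eval_metric="logloss")
    else:
        est = base[spec.algorithm]()
    if spec.hyperparameters:
        est = clone(est).set_params(**spec.hyperparameters) \
            if not isinstance(est, PLSDAClassifier) else est.set_params(**spec.hyperparameters)
    return est


def fit_classifier(train: pd.DataFrame, spec: ClassifierSpec):
    """Fit one of the 13 algorithms; returns an estimator with predict_proba."""
    y = train["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    X = train[feature_columns(train)].to_numpy()
    est = _make_estimator(spec)
    est.fit(X, y)
    return est


# ---------------------------------------------------------------------------
# Classification evaluation
# ---------------------------------------------------------------------------

def delong_ci(scores: np.ndarray, labels: np.ndarray,
              level: float = 0.95) -> tuple[float, float, float]:
    """AUC with its DeLong asymptotic confidence interval.

    Uses the structural-components formulation: V10[i] is the probability
    (with tie credit 1/2) that positive i outranks a random negative, V01[j]
    symmetrically; Var(AUC) = S10/m + S01/n.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    cmp_ = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp_.mean())
    v10 = cmp_.mean(axis=1)
    v01 = cmp_.mean(axis=0)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


@dataclass
class ClassificationReport:
    auc: float
    auc_ci: tuple[float, float]
    f1: float
    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    confusion: dict[str, int]
    calibration: pd.DataFrame
    threshold: float

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["calibration"] = self.calibration.to_dict(orient="list")
        return d


def evaluate_classifier(scores, labels, threshold: float = 0.5,
                        calibration_bins: int = 10) -> ClassificationReport:
    """Threshold-free (AUC + DeLong CI) and thresholded classification metrics.

    AUC is the trapezoidal area under the empirical ROC curve; calibration
    is mean predicted vs observed event rate in equal-count score bins.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    auc, lo, hi = delong_ci(scores, labels)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0

    ranks = pd.qcut(pd.Series(scores).rank(method="first"),
                    min(calibration_bins, len(scores)), labels=False)
    cal = pd.DataFrame({"score": scores, "label": labels, "bin": ranks}) \
        .groupby("bin").agg(mean_predicted=("score", "mean"),
                            observed_rate=("label", "mean"),
                            n=("label", "size")).reset_index()
    return ClassificationReport(
        auc=auc, auc_ci=(lo, hi), f1=f1, precision=prec, sensitivity=sens,
        specificity=spec, accuracy=(tp + tn) / len(labels),
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        calibration=cal, threshold=threshold)


@dataclass
class DecisionCurves:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray
    high_risk_per_1000: np.ndarray
    events_per_1000: np.ndarray


def decision_curve(scores, labels, thresholds=None) -> DecisionCurves:
    """Net benefit and clinical impact across risk thresholds.

    ``NB(t) = TP(t)/n - FP(t)/n * t/(1-t)`` classifying positive when the
    score reaches t; treat-all and treat-none reference curves included.
    The clinical impact curve reports, per 1000 subjects, the number
    classified high-risk and the true events among them.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds <= 0).any() or (thresholds >= 1).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(labels)
    prev = labels.mean()
    odds = thresholds / (1.0 - thresholds)
    nb_model, high, events = [], [], []
    for t in thresholds:
        sel = scores >= t
        tp = float((sel & (labels == 1)).sum())
        fp = float((sel & (labels == 0)).sum())
        nb_model.append(tp / n - fp / n * t / (1 - t))
        high.append(sel.sum() / n * 1000.0)
        events.append(tp / n * 1000.0)
    nb_all = prev - (1 - prev) * odds
    return DecisionCurves(thresholds, np.asarray(nb_model), nb_all,
                          np.zeros_like(thresholds), np.asarray(high),
                          np.asarray(events))


# ---------------------------------------------------------------------------
# Regression evaluation
# ---------------------------------------------------------------------------

@dataclass
class RegressionReport:
    mae: float
    mse: float
    r2: float | None
    pearson_r: float | None


def evaluate_regressor(predictions, targets) -> RegressionReport:
    """MAE, MSE, R^2 and Pearson r; the latter two are None for constant targets."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least 2 samples")
    mae = float(np.abs(p - t).mean())
    mse = float(((p - t) ** 2).mean())
    if np.allclose(t, t[0]):
        logger.warning("constant targets: R^2 and Pearson r undefined")
        return RegressionReport(mae, mse, None, None)
    r2 = float(skm.r2_score(t, p))
    r = float(stats.pearsonr(p, t).statistic) if p.std() > 0 else None
    return RegressionReport(mae, mse, r2, r)


# ---------------------------------------------------------------------------
# Nomogram
# ---------------------------------------------------------------------------

@dataclass
class NomogramModel:
    """Point-based rendering of a fitted logistic model.

    Each variable's contribution is rescaled so the variable with the
    largest |coefficient * observed range| spans exactly [0, 100] points;
    reference values are chosen per variable so points are non-negative
    over the observed range.
    """

    coefficients: dict[str, float]
    intercept: float
    ranges: dict[str, tuple[float, float]]
    references: dict[str, float] = field(init=False)
    scale: float = field(init=False)

    def __post_init__(self) -> None:
        spans = {v: abs(b) * (self.ranges[v][1] - self.ranges[v][0])
                 for v, b in self.coefficients.items()}
        self.scale = max(spans.values())
        if self.scale == 0:
            raise ValueError("all coefficients are zero over their ranges")
        self.references = {
            v: (self.ranges[v][0] if b >= 0 else self.ranges[v][1])
            for v, b in self.coefficients.items()
        }

    def points(self, variable: str, value: float) -> float:
        b = self.coefficients[variable]
        return 100.0 * b * (value - self.references[variable]) / self.scale


def build_nomogram(coefficients: dict[str, float], intercept: float,
                   ranges: dict[str, tuple[float, float]]) -> NomogramModel:
    missing = set(coefficients) - set(ranges)
    if missing:
        raise ValueError(f"no observed range for: {sorted(missing)}")
    return NomogramModel(dict(coefficients), float(intercept), dict(ranges))


def nomogram_score(model: NomogramModel,
                   sample: dict[str, float]) -> tuple[float, float]:
    """Total points and predicted probability for one sample.

    The probability comes from the underlying logistic model, so the point
    map and the probability map are mutually consistent by construction.
    """
    missing = set(model.coefficients) - set(sample)
    if missing:
        raise ValueError(f"missing variables: {sorted(missing)}")
    total = sum(model.points(v, sample[v]) for v in model.coefficients)
    lin = model.intercept + sum(b * sample[v] for v, b in model.coefficients.items())
    prob = 1.0 / (1.0 + np.exp(-lin))
    return float(total), float(prob)
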