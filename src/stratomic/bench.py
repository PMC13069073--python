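"""The five classifier families behind one probabilistic interface.

NB (Gaussian naive Bayes), LSVM (linear SVM with sigmoid-calibrated
probabilities), RF (random forest), ETC (extremely randomized trees) and
AB (AdaBoost on stumps).  Every fitted model emits class-probability
vectors summing to one.  Evaluation is repeated stratified k-fold CV with
percentile confidence intervals over repetitions; significance against
label shuffling uses an add-one permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .datatypes import GROUPS, ConfigError, CVScheme, DataError

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "build_classifiers",
    "cross_val_oof",
    "MetricReport",
    "evaluate_models",
    "PermutationTestResult",
    "permutation_test",
    "consensus_importance",
]

MODEL_NAMES = ("NB", "LSVM", "RF", "ETC", "AB")

_DEFAULTS: dict[str, dict] = {
    "NB": {},
    "LSVM": {"C": 1.0, "max_iter": 5000},
    "RF": {"n_estimators": 100},
    "ETC": {"n_estimators": 100},
    "AB": {"n_estimators": 50},
}

_IMPORTANCE_MODE = {
    "NB": "fallback_F",
    "LSVM": "coefficient",
    "RF": "impurity",
    "ETC": "impurity",
    "AB": "impurity",
}


@dataclass(frozen=True)
class ModelSpec:
    """Constructor recipe for one classifier family."""

    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ConfigError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")

    @property
    def importance_mode(self) -> str:
        return _IMPORTANCE_MODE[self.name]

    @property
    def probability_mode(self) -> str:
        return "calibrated" if self.name == "LSVM" else "native"

    def _base(self, seed: int):
        hp = {**_DEFAULTS[self.name], **dict(self.hyperparameters)}
        if self.name == "NB":
            return GaussianNB(**hp)
        if self.name == "LSVM":
            svc = LinearSVC(random_state=seed, **hp)
            # a linear margin alone gives no probabilities; sigmoid-calibrate
            # inside the training data
            return CalibratedClassifierCV(svc, method="sigmoid", cv=3)
        if self.name == "RF":
            return RandomForestClassifier(random_state=seed, **hp)
        if self.name == "ETC":
            return ExtraTreesClassifier(random_state=seed, **hp)
        return AdaBoostClassifier(random_state=seed, **hp)

    def make(self, seed: int = 0) -> Pipeline:
        """Estimator with per-fit standardization (fitted on training data only)."""
        return Pipeline([("scale", StandardScaler()), ("clf", self._base(seed))])

    def make_importance_estimator(self, seed: int = 0):
        """Raw estimator exposing importances/coefficients; None for NB (F fallback)."""
        if self.name == "NB":
            return None
        if self.name == "LSVM":
            hp = {**_DEFAULTS["LSVM"], **dict(self.hyperparameters)}
            return LinearSVC(random_state=seed, **hp)
        return self._base(seed)


def build_classifiers(config: Mapping[str, Mapping[str, object]] | None = None) -> list[ModelSpec]:
    """The five families, in fixed order, with optional hyperparameter overrides."""
    config = dict(config or {})
    unknown = set(config) - set(MODEL_NAMES)
    if unknown:
        raise ConfigError(f"unknown model names in config: {sorted(unknown)}")
    return [ModelSpec(name, config.get(name, {})) for name in MODEL_NAMES]


def _class_order(y: np.ndarray) -> list:
    classes = list(pd.unique(pd.Series(y)))
    if set(classes) <= set(GROUPS):
        return [g for g in GROUPS if g in classes]
    return sorted(classes)


def cross_val_oof(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    scheme: CVScheme,
    seed: int = 0,
) -> tuple[list, np.ndarray, np.ndarray]:
    """Out-of-fold predictions under the repeated-CV scheme.

    Returns ``(classes, pred, proba)`` where ``pred`` is (n_repeats, n)
    predicted labels (as class indices) and ``proba`` is
    (n_repeats, n, n_classes) with columns in ``classes`` order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = _class_order(y)
    class_idx = {c: i for i, c in enumerate(classes)}
    n = len(y)
    pred = np.full((scheme.n_repeats, n), -1, dtype=int)
    proba = np.full((scheme.n_repeats, n, len(classes)), np.nan)
    for repeat, fold, tr, te in scheme.split(y):
        est = spec.make(seed + 1000 * repeat + fold)
        est.fit(X[tr], y[tr])
        p = est.predict_proba(X[te])
        # align estimator columns onto the fixed class order
        cols = [class_idx[c] for c in est.classes_]
        aligned = np.zeros((len(te), len(classes)))
        aligned[:, cols] = p
        proba[repeat, te] = aligned
        pred[repeat, te] = np.argmax(aligned, axis=1)
    return classes, pred, proba


def _macro_ovr_auc(y_idx: np.ndarray, proba: np.ndarray, n_classes: int) -> float:
    if n_classes == 2:
        return float(roc_auc_score(y_idx, proba[:, 1]))
    return float(
        roc_auc_score(y_idx, proba, multi_class="ovr", average="macro", labels=list(range(n_classes)))
    )


@dataclass
class MetricReport:
    """Point estimates with 95% percentile intervals over CV repetitions."""

    table: pd.DataFrame  # columns: model, metric, value, lo, hi

    def value(self, model: str, metric: str) -> float:
        row = self.table[(self.table["model"] == model) & (self.table["metric"] == metric)]
        return float(row["value"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


METRICS = ("accuracy", "precision_macro", "recall_micro", "f1", "auc_macro_ovr")


def _repetition_metrics(y_idx, pred_r, proba_r, n_classes) -> dict[str, float]:
    labels = list(range(n_classes))
    return {
        "accuracy": accuracy_score(y_idx, pred_r),
        "precision_macro": precision_score(y_idx, pred_r, average="macro", labels=labels, zero_division=0),
        "recall_micro": recall_score(y_idx, pred_r, average="micro", labels=labels, zero_division=0),
        "f1": f1_score(y_idx, pred_r, average="macro", labels=labels, zero_division=0),
        "auc_macro_ovr": _macro_ovr_auc(y_idx, proba_r, n_classes),
    }


def evaluate_models(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    panel_features: Sequence[str] | None,
    scheme: CVScheme,
    specs: Sequence[ModelSpec] | None = None,
    seed: int = 0,
) -> MetricReport:
    """Repeated stratified CV benchmark of all model families on a panel.

    Metrics are computed per repetition from pooled out-of-fold predictions;
    the point estimate is the mean over repetitions and the 95% interval the
    2.5/97.5 percentiles.
    """
    specs = list(specs) if specs is not None else build_classifiers()
    if panel_features is not None:
        if len(panel_features) == 0:
            raise DataError("panel is empty")
        X = X.loc[:, list(panel_features)]
    y = np.asarray(y)
    classes = _class_order(y)
    y_idx = np.array([classes.index(c) for c in y])
    rows = []
    for spec in specs:
        _, pred, proba = cross_val_oof(X.to_numpy(dtype=float), y, spec, scheme, seed=seed)
        per_rep = [
            _repetition_metrics(y_idx, pred[r], proba[r], len(classes))
            for r in range(scheme.n_repeats)
        ]
        for metric in METRICS:
            vals = np.array([m[metric] for m in per_rep])
            rows.append(
                {
                    "model": spec.name,
                    "metric": metric,
                    "value": float(vals.mean()),
                    "lo": float(np.percentile(vals, 2.5)),
                    "hi": float(np.percentile(vals, 97.5)),
                }
            )
    return MetricReport(pd.DataFrame(rows))


@dataclass
class PermutationTestResult:
    observed_auc: float
    null_aucs: np.ndarray

    @property
    def mean_null_auc(self) -> float:
        return float(np.mean(self.null_aucs))

    @property
    def p_value(self) -> float:
        return (1.0 + float(np.sum(self.null_aucs >= self.observed_auc))) / (
            1.0 + len(self.null_aucs)
        )


def _cv_auc(X: np.ndarray, y: np.ndarray, spec: ModelSpec, scheme: CVScheme, seed: int) -> float:
    classes = _class_order(y)
    y_idx = np.array([classes.index(c) for c in y])
    _, _, proba = cross_val_oof(X, y, spec, scheme, seed=seed)
    aucs = [
        _macro_ovr_auc(y_idx, proba[r], len(classes)) for r in range(scheme.n_repeats)
    ]
    return float(np.mean(aucs))


def permutation_test(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    spec: ModelSpec,
    scheme: CVScheme,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Label-shuffling significance test of the cross-validated macro AUC.

    p = (1 + #{null >= observed}) / (1 + n_shuffles); the floor is therefore
    1/(n_shuffles+1), so p < 0.001 needs at least 1000 shuffles.
    """
    if n_shuffles < 1:
        raise ConfigError("n_shuffles must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("y has a single class")
    observed = _cv_auc(X, y, spec, scheme, seed=seed)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_shuffles)
    for b in range(n_shuffles):
        y_perm = rng.permutation(y)
        nulls[b] = _cv_auc(X, y_perm, spec, scheme, seed=seed + b + 1)
    return PermutationTestResult(observed, nulls)


def _fold_importance(spec: ModelSpec, X_tr: np.ndarray, y_tr: np.ndarray, seed: int) -> np.ndarray:
    est = spec.make_importance_estimator(seed)
    if est is None:  # NB: univariate F fallback
        f, _ = f_classif(X_tr, y_tr)
        imp = np.abs(np.nan_to_num(f))
    else:
        scaler = StandardScaler().fit(X_tr)
        est.fit(scaler.transform(X_tr), y_tr)
        if hasattr(est, "feature_importances_"):
            imp = np.asarray(est.feature_importances_, dtype=float)
        else:
            imp = np.mean(np.abs(est.coef_), axis=0)
    total = imp.sum()
    if total <= 0:
        return np.full_like(imp, 1.0 / len(imp))
    return imp / total


def consensus_importance(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    panel_features: Sequence[str],
    scheme: CVScheme,
    specs: Sequence[ModelSpec] | None = None,
    seed: int = 0,
    attribution: bool = False,
    attribution_samples: int = 20,
) -> pd.DataFrame:
    """Per-model normalized importances averaged over folds, plus mean-rank consensus.

    RF/ETC/AB use impurity importances, LSVM mean |coefficient| over
    one-vs-rest components, NB an absolute univariate F statistic.  Each
    model's vector is normalized to sum 1 before fold-averaging.  When
    ``attribution`` is set, a sampling-based additive-attribution score is
    reported alongside; it never alters the consensus rank.
    """
    specs = list(specs) if specs is not None else build_classifiers()
    Xp = X.loc[:, list(panel_features)].to_numpy(dtype=float)
    y = np.asarray(y)
    per_model: dict[str, list[np.ndarray]] = {s.name: [] for s in specs}
    for repeat, fold, tr, _ in scheme.split(y):
        for spec in specs:
            per_model[spec.name].append(
                _fold_importance(spec, Xp[tr], y[tr], seed + 1000 * repeat + fold)
            )
    out = pd.DataFrame(index=list(panel_features))
    ranks = []
    for spec in specs:
        mean_imp = np.mean(per_model[spec.name], axis=0)
        out[f"importance_{spec.name}"] = mean_imp
        r = pd.Series(-mean_imp, index=out.index).rank(method="average")
        out[f"rank_{spec.name}"] = r
        ranks.append(r)
    out["consensus_rank"] = pd.concat(ranks, axis=1).mean(axis=1)
    if attribution:
        out["attribution"] = _additive_attribution(
            Xp, y, specs, seed=seed, n_samples=attribution_samples
        )
    return out.sort_values("consensus_rank")


def _additive_attribution(
    X: np.ndarray, y: np.ndarray, specs: Sequence[ModelSpec], seed: int, n_samples: int
) -> np.ndarray:
    """Monte-Carlo additive attribution of the true-class probability.

    Marginal contributions of each feature over random feature orderings,
    with absent features held at the column mean, averaged over models and
    samples.  Small-scale interpretability aid only.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    baseline = X.mean(axis=0)
    scores = np.zeros(p)
    classes = _class_order(y)
    y_idx = np.array([classes.index(c) for c in y])
    for spec in specs:
        est = spec.make(seed)
        est.fit(X, y)
        take = rng.choice(n, size=min(n, 10), replace=False)
        for s in take:
            for _ in range(n_samples):
                order = rng.permutation(p)
                cur = baseline.copy()
                prev = est.predict_proba(cur[None, :])[0][y_idx[s]]
                for f in order:
                    cur[f] = X[s, f]
                    now = est.predict_proba(cur[None, :])[0][y_idx[s]]
                    scores[f] += abs(now - prev)
                    prev = now
    total = scores.sum()
    return scores / total if total > 0 else np.full(p, 1.0 / p)
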