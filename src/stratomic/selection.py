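"""Consensus feature selection.

Repeated stratified CV on the outside, stratified bootstrap resampling
inside each training fold.  Per bootstrap, one selector per model family
(RFE guided by coefficients or impurity importances; univariate F ranking
as the NB fallback) keeps the top ``target_fraction`` of features; a
feature counts as selected in that bootstrap when chosen by at least 3 of
the 5 selectors.  Features retained in >= 60% of bootstraps are flagged for
the fold; the consensus panel keeps features flagged in >= 20% of folds,
then collapses correlated clusters (|Spearman rho| >= 0.85) to their most
frequently selected representative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.feature_selection import RFE, SelectKBest, f_classif
from sklearn.preprocessing import StandardScaler

from .bench import MODEL_NAMES, ModelSpec, build_classifiers
from .datatypes import ConfigError, CVScheme, DataError

__all__ = [
    "FeaturePanel",
    "default_selector_specs",
    "bootstrap_fold_selection",
    "select_consensus_features",
    "dedup_correlated",
]


def default_selector_specs() -> list[ModelSpec]:
    """Lighter ensembles for selection: ranking stability, not prediction,
    is what matters inside the bootstrap loop."""
    return build_classifiers(
        {"RF": {"n_estimators": 30}, "ETC": {"n_estimators": 30}, "AB": {"n_estimators": 25}}
    )


@dataclass
class FeaturePanel:
    """Ordered selected features with selection-frequency provenance.

    ``table`` is indexed by feature name with columns ``fold_freq`` (fraction
    of CV folds flagging the feature), ``boot_freq`` (mean within-fold
    bootstrap selection frequency) and ``cluster_members`` (';'-joined
    features this one represents after correlation dedup).
    """

    table: pd.DataFrame

    @property
    def features(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "feature"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeaturePanel":
        table = pd.read_csv(path, index_col="feature")
        table["cluster_members"] = table["cluster_members"].fillna("")
        return cls(table)

    def to_json(self, path: str | Path) -> None:
        payload = {
            f: {
                "fold_freq": float(r["fold_freq"]),
                "boot_freq": float(r["boot_freq"]),
                "cluster_members": [m for m in str(r["cluster_members"]).split(";") if m],
            }
            for f, r in self.table.iterrows()
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _ordered(table: pd.DataFrame) -> pd.DataFrame:
    """Panel order: fold frequency desc, mean bootstrap frequency desc, name."""
    key = table.assign(_name=table.index)
    key = key.sort_values(
        ["fold_freq", "boot_freq", "_name"], ascending=[False, False, True]
    )
    return key.drop(columns="_name")


def _selector_mask(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, k: int, rfe_step: float, seed: int
) -> np.ndarray:
    est = spec.make_importance_estimator(seed)
    if est is None:  # NB has neither coefficients nor importances
        sel = SelectKBest(f_classif, k=k).fit(X, y)
        return sel.get_support()
    sel = RFE(est, n_features_to_select=k, step=rfe_step).fit(X, y)
    return sel.get_support()


def bootstrap_fold_selection(
    X_train: pd.DataFrame | np.ndarray,
    y_train: Sequence,
    specs: Sequence[ModelSpec] | None = None,
    n_bootstrap: int = 50,
    retain_fraction: float = 0.60,
    target_fraction: float = 0.25,
    rfe_step: float = 0.1,
    min_selectors: int = 3,
    seed: int = 0,
    max_retries: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """One training fold's bootstrap selection round.

    Returns ``(flags, boot_freq)``: a boolean per feature (bootstrap
    selection frequency >= ``retain_fraction``, boundary inclusive) and the
    underlying frequencies.
    """
    if not 0.0 < retain_fraction <= 1.0:
        raise ConfigError("retain_fraction must lie in (0, 1]")
    specs = list(specs) if specs is not None else default_selector_specs()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DataError("training fold has a single class")
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    k = max(1, int(round(target_fraction * p)))
    counts = np.zeros(p)
    by_class = {c: np.where(y == c)[0] for c in classes}
    for b in range(n_bootstrap):
        for attempt in range(max_retries):
            idx = np.concatenate(
                [rng.choice(members, size=len(members), replace=True) for members in by_class.values()]
            )
            if len(np.unique(y[idx])) == len(classes):
                break
        else:  # pragma: no cover - stratified resampling keeps every class
            raise DataError("bootstrap resample kept losing a class after retries")
        Xb = StandardScaler().fit_transform(X[idx])
        yb = y[idx]
        votes = np.zeros(p, dtype=int)
        for j, spec in enumerate(specs):
            votes += _selector_mask(spec, Xb, yb, k, rfe_step, seed + 97 * b + j)
        counts += votes >= min_selectors
    boot_freq = counts / n_bootstrap
    return boot_freq >= retain_fraction, boot_freq


def select_consensus_features(
    X: pd.DataFrame,
    y: Sequence,
    scheme: CVScheme,
    fold_threshold: float = 0.20,
    n_bootstrap: int = 50,
    target_fraction: float = 0.25,
    rfe_step: float = 0.1,
    rho_threshold: float = 0.85,
    specs: Sequence[ModelSpec] | None = None,
    seed: int = 0,
) -> FeaturePanel:
    """Run bootstrap selection in every training fold and take the consensus.

    Features flagged in >= ``fold_threshold`` of folds (boundary inclusive)
    are retained, correlated clusters are collapsed, and the panel is
    ordered by fold frequency, then mean bootstrap frequency, then name.
    """
    y_arr = np.asarray(y)
    features = list(X.columns)
    flags_per_fold = []
    freq_per_fold = []
    for repeat, fold, tr, _ in scheme.split(y_arr):
        flags, freqs = bootstrap_fold_selection(
            X.iloc[tr],
            y_arr[tr],
            specs=specs,
            n_bootstrap=n_bootstrap,
            target_fraction=target_fraction,
            rfe_step=rfe_step,
            seed=seed + 10_000 * repeat + 100 * fold,
        )
        flags_per_fold.append(flags)
        freq_per_fold.append(freqs)
    fold_freq = np.mean(flags_per_fold, axis=0)
    boot_freq = np.mean(freq_per_fold, axis=0)
    table = pd.DataFrame(
        {"fold_freq": fold_freq, "boot_freq": boot_freq, "cluster_members": ""},
        index=features,
    )
    retained = table[table["fold_freq"] >= fold_threshold]
    panel = FeaturePanel(_ordered(retained))
    return dedup_correlated(panel, X, rho_threshold=rho_threshold)


def dedup_correlated(
    panel: FeaturePanel, X: pd.DataFrame, rho_threshold: float = 0.85
) -> FeaturePanel:
    """Collapse |Spearman rho| >= threshold clusters (single linkage).

    Each cluster keeps its most frequently selected member (fold frequency,
    then mean bootstrap frequency, then lexicographic); the others are
    recorded under ``cluster_members``.
    """
    feats = panel.features
    missing = [f for f in feats if f not in X.columns]
    if missing:
        raise DataError(f"panel features {missing} absent from the reference data")
    if len(feats) <= 1:
        return FeaturePanel(panel.table.copy())
    sub = X.loc[:, feats].to_numpy(dtype=float)
    res = stats.spearmanr(sub)
    if len(feats) == 2:  # scipy returns a scalar for two columns
        r = float(res.statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(res.statistic)
    with np.errstate(invalid="ignore"):
        rho = np.nan_to_num(rho, nan=0.0)
    adj = (np.abs(rho) >= rho_threshold) & ~np.eye(len(feats), dtype=bool)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    ordered = _ordered(panel.table)  # representative = best-ranked member
    rows = []
    seen: set[int] = set()
    for f in ordered.index:
        comp = labels[feats.index(f)]
        if comp in seen:
            continue
        seen.add(comp)
        members = [g for g in ordered.index if labels[feats.index(g)] == comp and g != f]
        row = ordered.loc[f].copy()
        row["cluster_members"] = ";".join(sorted(members))
        rows.append((f, row))
    table = pd.DataFrame({name: row for name, row in rows}).T
    table = table.astype({"fold_freq": float, "boot_freq": float})
    return FeaturePanel(_ordered(table))
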