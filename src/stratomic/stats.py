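"""Univariate and panel-level statistics.

Binary ROC/AUC with Youden-index cutoffs, the dual-comparison AUC > 0.7
biomarker filter, the within-group |Spearman R| > 0.6 correlation screen,
and the baseline group-comparison tests (Kruskal-Wallis with Dunn post hoc,
Pearson chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import DataError

__all__ = [
    "RocResult",
    "binary_auc",
    "roc_coordinates",
    "filter_panel_by_auc",
    "spearman_screen",
    "group_tests",
    "mad_outlier_flags",
]


@dataclass(frozen=True)
class RocResult:
    identifier: str
    comparison: tuple[str, str]  # (positive group, negative group)
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def binary_auc(
    values: Sequence[float],
    labels: Sequence[bool],
    identifier: str = "",
    comparison: tuple[str, str] = ("pos", "neg"),
) -> RocResult:
    """Rank-statistic AUC (ties half) and the Youden-optimal cutoff.

    The decision rule is ``value >= cutoff -> positive``; candidate cutoffs
    are midpoints between adjacent distinct values (plus open ends); ties
    in J are broken toward higher sensitivity.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if not np.isfinite(v).all():
        raise DataError("values must be finite")
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes must be present")
    ranks = sps.rankdata(v)
    auc = (ranks[lab].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    distinct = np.unique(v)
    if len(distinct) == 1:
        cuts = np.array([distinct[0]])
    else:
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        lo = distinct[0] - (distinct[1] - distinct[0]) / 2.0
        hi = distinct[-1] + (distinct[-1] - distinct[-2]) / 2.0
        cuts = np.concatenate([[lo], mids, [hi]])
    best = None
    for c in cuts:
        called = v >= c
        sens = (called & lab).sum() / n_pos
        spec = (~called & ~lab).sum() / n_neg
        j = sens + spec - 1.0
        # strictly-better J wins; equal J resolved toward higher sensitivity
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and sens > best[1]):
            best = (j, sens, spec, c)
    _, sens, spec, cutoff = best
    return RocResult(identifier, comparison, float(auc), float(cutoff), float(sens), float(spec))


def roc_coordinates(values: Sequence[float], labels: Sequence[bool]) -> pd.DataFrame:
    """(fpr, tpr, threshold) table under the ``value >= threshold`` rule."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    thresholds = np.concatenate([[np.inf], np.unique(v)[::-1]])
    rows = []
    for thr in thresholds:
        called = v >= thr
        rows.append(
            {
                "fpr": (called & ~lab).sum() / max((~lab).sum(), 1),
                "tpr": (called & lab).sum() / max(lab.sum(), 1),
                "threshold": thr,
            }
        )
    return pd.DataFrame(rows)


def filter_panel_by_auc(
    X: pd.DataFrame,
    groups: pd.Series,
    candidate_features: Sequence[str],
    threshold: float = 0.7,
) -> tuple[list[str], dict[str, list[RocResult]]]:
    """Keep features discriminating AT from both DLP and CTRL.

    A feature is retained iff ``max(AUC, 1 - AUC) > threshold`` (strict) in
    both AT-vs-DLP and AT-vs-CTRL.  The orientation-free criterion admits
    both up- and down-regulated markers.
    """
    groups = groups.reindex(X.index)
    for g in ("AT", "DLP", "CTRL"):
        if not (groups == g).any():
            raise DataError(f"group {g!r} absent from labels")
    missing = [f for f in candidate_features if f not in X.columns]
    if missing:
        raise DataError(f"candidate features {missing} absent from the data")
    retained: list[str] = []
    results: dict[str, list[RocResult]] = {}
    for feat in candidate_features:
        per_feature = []
        ok = True
        for neg in ("DLP", "CTRL"):
            mask = (groups == "AT") | (groups == neg)
            r = binary_auc(
                X.loc[mask, feat], (groups[mask] == "AT"), identifier=feat, comparison=("AT", neg)
            )
            per_feature.append(r)
            if max(r.auc, 1.0 - r.auc) <= threshold:
                ok = False
        results[feat] = per_feature
        if ok:
            retained.append(feat)
    return retained, results


def spearman_screen(
    X: pd.DataFrame, group_mask: Sequence[bool] | None = None, r_threshold: float = 0.6
) -> pd.DataFrame:
    """All within-group feature pairs with |Spearman R| strictly above threshold.

    Pairs involving a constant feature are reported once with an
    ``undefined`` flag and excluded from selection.  Output is sorted by
    |R| descending.
    """
    sub = X if group_mask is None else X.loc[np.asarray(group_mask, dtype=bool)]
    if len(sub) < 3:
        raise DataError("need at least 3 samples in the group")
    feats = list(sub.columns)
    vals = sub.to_numpy(dtype=float)
    constant = [f for j, f in enumerate(feats) if np.nanstd(vals[:, j]) == 0]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        res = sps.spearmanr(vals)
    rho = np.asarray(res.statistic) if len(feats) > 2 else np.array(
        [[1.0, float(res.statistic)], [float(res.statistic), 1.0]]
    )
    rows = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            undefined = feats[i] in constant or feats[j] in constant
            r = float(rho[i, j]) if not undefined else np.nan
            if undefined or abs(r) > r_threshold:
                rows.append(
                    {
                        "feature_i": feats[i],
                        "feature_j": feats[j],
                        "R": r,
                        "undefined": undefined,
                        "selected": (not undefined) and abs(r) > r_threshold,
                    }
                )
    out = pd.DataFrame(rows, columns=["feature_i", "feature_j", "R", "undefined", "selected"])
    if len(out):
        out = out.reindex(out["R"].abs().sort_values(ascending=False, na_position="last").index)
        out = out.reset_index(drop=True)
    return out


def _dunn_posthoc(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn pairwise z tests with tie correction, Bonferroni-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append(
                {
                    "group_i": a,
                    "group_j": b,
                    "z": float(z),
                    "p": float(min(1.0, p * n_pairs)),
                }
            )
    return pd.DataFrame(rows)


def group_tests(
    values_by_group: Mapping[str, Sequence[float]] | None = None,
    contingency: pd.DataFrame | np.ndarray | None = None,
) -> dict:
    """Baseline group-comparison tests.

    Continuous data (``values_by_group``): tie-corrected Kruskal-Wallis H
    with Dunn pairwise post hoc (Bonferroni).  Categorical data
    (``contingency``, groups x categories counts): Pearson chi-square.
    """
    if (values_by_group is None) == (contingency is None):
        raise DataError("pass exactly one of values_by_group / contingency")
    if values_by_group is not None:
        groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
        if any(len(v) == 0 for v in groups.values()):
            raise DataError("empty group")
        if len(groups) < 2:
            raise DataError("need at least 2 groups")
        h, p = sps.kruskal(*groups.values())
        return {
            "test": "kruskal",
            "H": float(h),
            "p": float(p),
            "posthoc": _dunn_posthoc(groups),
        }
    table = np.asarray(contingency, dtype=float)
    if (table.sum(axis=1) == 0).any():
        raise DataError("empty group in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return {"test": "chi2", "chi2": float(chi2), "p": float(p), "dof": int(dof)}


def mad_outlier_flags(values: Sequence[float], threshold: float = 3.5) -> np.ndarray:
    """Robust MAD-based outlier flags (optional helper, off by default).

    A documented substitute for proprietary robust-regression outlier
    detection: flags |x - median| / (1.4826 * MAD) above ``threshold``.
    """
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return np.zeros(len(v), dtype=bool)
    return np.abs(v - med) / (1.4826 * mad) > threshold
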