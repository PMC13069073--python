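"""Clinical-table preparation: kNN imputation and leakage-safe scaling.

Imputation uses inverse-distance-weighted k-nearest neighbours with a
partial-observation Euclidean distance (mutually present features only,
rescaled by the fraction of features used).  Standardization is fitted on a
training index set and only then applied, so held-out samples never
influence the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, DataError

__all__ = ["knn_impute", "Standardizer", "fit_standardizer", "apply_standardizer"]


def _partial_distances(values: np.ndarray, target: int) -> np.ndarray:
    """Distances from row ``target`` to every row, over mutually present features.

    d(x, y) = sqrt( (p / p_used) * sum over mutually present features (x-y)^2 )
    where p is the total feature count.  Pairs with no mutually present
    feature get distance +inf.
    """
    n, p = values.shape
    x = values[target]
    present_x = ~np.isnan(x)
    diffs = values - x[None, :]
    both = present_x[None, :] & ~np.isnan(values)
    sq = np.where(both, diffs**2, 0.0)
    used = both.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(sq.sum(axis=1) * (p / used))
    d[used == 0] = np.inf
    return d


def knn_impute(t: ClinicalTable, k: int = 5, standardize: bool = True) -> ClinicalTable:
    """Impute missing clinical cells from the k nearest samples.

    For a missing cell (sample s, feature f) the candidates are all other
    samples with f present; the k nearest (partial Euclidean distance, see
    :func:`_partial_distances`) contribute their f values with weight 1/d.
    Exact matches (d = 0) short-circuit to the plain mean of the
    zero-distance neighbours, reproducing a duplicate row exactly.

    Distances are computed on globally standardized features by default
    (clinical units are incommensurable); imputed values are mapped back to
    the original scale.  Present values are never touched.
    """
    data = t.data
    n_present = data.notna().sum(axis=0)
    short = n_present.index[n_present < k]
    if len(short):
        raise DataError(
            f"features {list(short)} have fewer than k={k} present samples"
        )
    if data.notna().sum(axis=1).min() < 1:
        raise DataError("every sample needs at least one present feature")
    if not data.isna().any().any():
        return ClinicalTable(data.copy(), t.meta.copy())

    values = data.to_numpy(dtype=float)
    if standardize:
        center = np.nanmean(values, axis=0)
        scale = np.nanstd(values, axis=0, ddof=1)
        scale[~(scale > 0)] = 1.0
        work = (values - center) / scale
    else:
        work = values

    # distances come from the (optionally standardized) working copy, but the
    # weighted mean is taken on original-scale values — affine-equivalent, and
    # it reproduces a zero-distance duplicate bit-exactly
    result = values.copy()
    missing_rows = np.where(np.isnan(values).any(axis=1))[0]
    for s in missing_rows:
        d = _partial_distances(work, s)
        d[s] = np.inf
        for f in np.where(np.isnan(values[s]))[0]:
            cand = np.where(~np.isnan(values[:, f]) & np.isfinite(d))[0]
            order = cand[np.argsort(d[cand], kind="stable")]
            nearest = order[:k]
            dn = d[nearest]
            if (dn == 0).any():
                result[s, f] = values[nearest[dn == 0], f].mean()
            else:
                result[s, f] = np.average(values[nearest, f], weights=1.0 / dn)
    df = pd.DataFrame(result, index=data.index, columns=data.columns)
    return ClinicalTable(df, t.meta.copy())


@dataclass
class Standardizer:
    """Per-feature center/scale learned from a training index set.

    Features with zero training variance are flagged in ``degenerate`` and
    passed through unscaled (center 0, scale 1).
    """

    center: pd.Series
    scale: pd.Series
    degenerate: tuple[str, ...] = ()

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        return (data - self.center) / self.scale


def fit_standardizer(t: ClinicalTable | pd.DataFrame, train_index) -> Standardizer:
    """Learn training mean/SD per feature; leakage-safe by construction."""
    data = t.data if isinstance(t, ClinicalTable) else t
    train_index = list(train_index)
    if len(train_index) == 0:
        raise DataError("train_index is empty")
    train = data.loc[train_index]
    center = train.mean()
    scale = train.std(ddof=1)
    degenerate = tuple(scale.index[~(scale > 0)])
    center[list(degenerate)] = 0.0
    scale[list(degenerate)] = 1.0
    center = center.fillna(0.0)
    scale = scale.fillna(1.0)
    return Standardizer(center, scale, degenerate)


def apply_standardizer(s: Standardizer, t: ClinicalTable | pd.DataFrame):
    """Transform all samples with training parameters only."""
    if isinstance(t, ClinicalTable):
        return ClinicalTable(s.transform(t.data), t.meta.copy())
    return s.transform(t)
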