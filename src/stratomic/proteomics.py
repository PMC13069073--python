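"""LFQ intensity post-processing and differential testing.

The chain is fixed: log2 transform, valid-value filtering, per-sample
downshifted-normal imputation, quantile normalization, then a two-sample
t-test with a permutation-estimated FDR.  Each step consumes and emits a
:class:`~stratomic.datatypes.ProteinMatrix` whose ``state`` flag enforces
the order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigError, DataError, ProteinMatrix

__all__ = [
    "COMPARISONS",
    "FilterReport",
    "DifferentialResult",
    "log2_transform",
    "filter_valid_fraction",
    "impute_downshifted_normal",
    "quantile_normalize",
    "permutation_fdr_ttest",
    "run_differential_suite",
]

#: The three pairwise group comparisons, as (test group, reference group).
COMPARISONS = (("AT", "CTRL"), ("AT", "DLP"), ("DLP", "CTRL"))


def log2_transform(m: ProteinMatrix) -> ProteinMatrix:
    """Base-2 logarithm of every present value; missingness unchanged."""
    if m.state != "raw":
        raise DataError(f"log2_transform expects state 'raw', got {m.state!r}")
    return m.advanced(np.log2(m.data), "log2")


@dataclass(frozen=True)
class FilterReport:
    retained: tuple[str, ...]
    dropped: tuple[str, ...]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def filter_valid_fraction(
    m: ProteinMatrix, min_fraction: float = 0.70
) -> tuple[ProteinMatrix, FilterReport]:
    """Keep proteins quantified in at least ``min_fraction`` of all samples.

    The boundary is inclusive ("at least 70%"), the denominator is the full
    sample set regardless of group.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ConfigError("min_fraction must lie in (0, 1]")
    if m.n_samples == 0 or m.n_proteins == 0:
        raise DataError("cannot filter an empty matrix")
    frac = m.data.notna().mean(axis=0)
    keep = frac.index[frac >= min_fraction]
    drop = frac.index[frac < min_fraction]
    return m.filtered(keep), FilterReport(tuple(keep), tuple(drop))


def impute_downshifted_normal(
    m: ProteinMatrix,
    shift_sd: float = 1.8,
    width_sd: float = 0.3,
    seed: int = 0,
) -> ProteinMatrix:
    """Per-sample imputation from a downshifted, narrowed normal.

    Missing entries of sample *s* are drawn from
    ``Normal(mean_s - shift_sd * sd_s, (width_sd * sd_s)^2)`` where the mean
    and SD are computed over the sample's present values.  This mimics the
    detection-limit interpretation of DIA missingness: absent proteins sit
    in the low tail of the sample's intensity distribution.
    """
    if m.state != "log2":
        raise DataError(f"imputation expects state 'log2', got {m.state!r}")
    rng = np.random.default_rng(seed)
    data = m.data.copy()
    n_present = data.notna().sum(axis=1)
    if (n_present < 2).any():
        bad = n_present.index[n_present < 2].tolist()
        raise DataError(f"samples {bad} have fewer than 2 present values; SD undefined")
    for sid in data.index:
        row = data.loc[sid]
        missing = row.isna()
        if not missing.any():
            continue
        mu, sd = row.mean(), row.std(ddof=1)
        draws = rng.normal(mu - shift_sd * sd, width_sd * sd, size=int(missing.sum()))
        data.loc[sid, missing[missing].index] = draws
    return m.advanced(data, "imputed")


def quantile_normalize(m: ProteinMatrix) -> ProteinMatrix:
    """Force every sample onto the mean-of-order-statistics reference.

    Ties within a sample receive the mean of the reference values they span.
    Requires a complete matrix (impute first).
    """
    if m.state != "imputed":
        raise DataError(f"quantile normalization expects state 'imputed', got {m.state!r}")
    vals = m.data.to_numpy()
    if np.isnan(vals).any():
        raise DataError("matrix has missing values; impute before quantile normalization")
    n, p = vals.shape
    reference = np.sort(vals, axis=1).mean(axis=0)  # averaged order statistics
    cum_ref = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(vals)
    for i in range(n):
        lo = stats.rankdata(vals[i], method="min").astype(int)
        hi = stats.rankdata(vals[i], method="max").astype(int)
        out[i] = (cum_ref[hi] - cum_ref[lo - 1]) / (hi - lo + 1)
    return m.advanced(pd.DataFrame(out, index=m.data.index, columns=m.data.columns), "normalized")


@dataclass
class DifferentialResult:
    """Per-protein differential-abundance calls for one comparison."""

    comparison: tuple[str, str]
    table: pd.DataFrame  # index protein; columns log2_diff, t, q, significant, degenerate
    alpha: float = 0.05

    def significant_proteins(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def to_csv(self, path: str | Path, mode: str = "w", header: bool = True) -> None:
        out = self.table.copy()
        out.insert(0, "comparison", f"{self.comparison[0]}_vs_{self.comparison[1]}")
        out.index.name = "protein"
        out.to_csv(path, mode=mode, header=header)


def _pooled_t(values: np.ndarray, mask1: np.ndarray, mask2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sample t over columns; nan where degenerate."""
    x1, x2 = values[mask1], values[mask2]
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t[sp2 <= 0] = np.nan
    return t, m1 - m2


def permutation_fdr_ttest(
    m: ProteinMatrix,
    groups: pd.Series,
    comparison: tuple[str, str],
    n_permutations: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
) -> DifferentialResult:
    """Two-sample t-test with a permutation-based FDR.

    Per protein the observed statistic is a pooled-variance two-sided t.
    The null is built from ``n_permutations`` label shuffles (the same
    shuffle reused across all proteins).  For a threshold ``t*``,

        FDR(t*) = mean_b #{j : |t_b,j| >= t*}  /  #{j : |t_j| >= t*}

    and a protein's q-value is the minimum FDR over all observed thresholds
    it passes, clipped to [0, 1] — non-increasing in |t| by construction.
    Zero pooled variance makes t undefined: q is set to 1 with a
    ``degenerate`` flag and the protein is never significant.
    """
    g1, g2 = comparison
    if m.state != "normalized":
        raise DataError(f"differential testing expects state 'normalized', got {m.state!r}")
    groups = groups.reindex(m.data.index)
    mask1 = (groups == g1).to_numpy()
    mask2 = (groups == g2).to_numpy()
    if mask1.sum() < 3 or mask2.sum() < 3:
        raise DataError(f"comparison {g1} vs {g2}: both groups need >= 3 samples")
    sel = mask1 | mask2
    values = m.data.to_numpy()[sel]
    n1 = int(mask1.sum())
    n_sel = values.shape[0]
    base1 = np.zeros(n_sel, dtype=bool)
    base1[:n1] = True
    # reorder rows so the first n1 belong to g1
    idx1 = np.where(mask1[sel])[0]
    idx2 = np.where(mask2[sel])[0]
    values = values[np.concatenate([idx1, idx2])]

    t_obs, diff = _pooled_t(values, base1, ~base1)
    degenerate = np.isnan(t_obs)

    rng = np.random.default_rng(seed)
    abs_null_parts = []
    for _ in range(n_permutations):
        perm = rng.permutation(n_sel)
        pmask = np.zeros(n_sel, dtype=bool)
        pmask[perm[:n1]] = True
        t_null, _ = _pooled_t(values, pmask, ~pmask)
        abs_null_parts.append(np.abs(t_null[np.isfinite(t_null)]))
    abs_null = np.sort(np.concatenate(abs_null_parts)) if abs_null_parts else np.array([])

    abs_obs = np.abs(t_obs)
    finite = ~degenerate
    q = np.ones_like(abs_obs)
    if finite.any() and n_permutations > 0:
        obs_sorted = np.sort(abs_obs[finite])
        thresholds = abs_obs[finite]
        # counts at each observed threshold
        null_ge = len(abs_null) - np.searchsorted(abs_null, thresholds, side="left")
        obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, thresholds, side="left")
        fdr = (null_ge / n_permutations) / np.maximum(obs_ge, 1)
        # q_i = min FDR over thresholds t* <= |t_i| (calls that still include
        # protein i); a running minimum in ascending |t| order, which also
        # makes q non-increasing in |t|
        asc = np.argsort(thresholds)
        fdr_asc = fdr[asc]
        run = np.minimum.accumulate(fdr_asc)
        q_f = np.empty_like(fdr)
        q_f[asc] = run
        q[finite] = np.clip(q_f, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "log2_diff": diff,
            "t": t_obs,
            "q": q,
            "significant": (q < alpha) & ~degenerate,
            "degenerate": degenerate,
        },
        index=m.data.columns,
    )
    return DifferentialResult(comparison, table, alpha=alpha)


def run_differential_suite(
    m: ProteinMatrix,
    groups: pd.Series,
    n_permutations: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[tuple[str, str], DifferentialResult]:
    """All three pairwise comparisons with per-comparison seeds."""
    out = {}
    for k, comparison in enumerate(COMPARISONS):
        out[comparison] = permutation_fdr_ttest(
            m, groups, comparison, n_permutations=n_permutations, alpha=alpha, seed=seed + k
        )
    return out
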