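import numpy as np
import pandas as pd
import pytest

from stratomic.datatypes import DataError, ProteinMatrix
from stratomic.proteomics import (
    filter_valid_fraction,
    impute_downshifted_normal,
    log2_transform,
    permutation_fdr_ttest,
    quantile_normalize,
)

from conftest import make_protein_matrix


# -- log2 -------------------------------------------------------------------

def test_log2_exact_values():
    m = make_protein_matrix([[8.0, 1.0]], state="raw")
    out = log2_transform(m)
    assert out.state == "log2"
    assert out.data.iloc[0, 0] == 3.0
    assert out.data.iloc[0, 1] == 0.0


def test_log2_elementwise_oracle(rng):
    vals = rng.uniform(0.5, 1e6, size=(3, 2))
    out = log2_transform(make_protein_matrix(vals, state="raw"))
    expected = np.log(vals) / np.log(2.0)  # independent route
    assert np.allclose(out.data.to_numpy(), expected, atol=1e-12)


def test_log2_preserves_missingness(rng):
    vals = rng.uniform(1, 100, size=(4, 3))
    vals[1, 2] = np.nan
    out = log2_transform(make_protein_matrix(vals, state="raw"))
    assert out.data.isna().to_numpy().sum() == 1
    assert np.isnan(out.data.iloc[1, 2])


def test_nonpositive_raw_value_names_cell():
    vals = [[2.0, -1.0]]
    with pytest.raises(DataError, match="P1"):
        make_protein_matrix(vals, state="raw")


def test_log2_requires_raw_state():
    m = make_protein_matrix([[1.0, 2.0]], state="log2")
    with pytest.raises(DataError):
        log2_transform(m)


# -- valid-value filter -----------------------------------------------------

def _matrix_with_valid_counts(counts, n_samples=10):
    cols = {}
    for j, c in enumerate(counts):
        col = np.full(n_samples, np.nan)
        col[:c] = 5.0 + j
        cols[f"P{j}"] = col
    df = pd.DataFrame(cols, index=[f"S{i}" for i in range(n_samples)])
    return ProteinMatrix(df, state="log2")


def test_filter_inclusive_boundary():
    m = _matrix_with_valid_counts([7, 6])
    out, report = filter_valid_fraction(m, 0.70)
    assert out.protein_ids == ["P0"]  # 7/10 kept, 6/10 dropped
    assert report.n_retained == 1 and report.n_dropped == 1


def test_filter_counting_oracle(rng):
    vals = rng.normal(size=(12, 30))
    vals[rng.random(vals.shape) < 0.4] = np.nan
    m = make_protein_matrix(vals)
    out, _ = filter_valid_fraction(m, 0.65)
    expected = [
        f"P{j}" for j in range(30) if np.sum(~np.isnan(vals[:, j])) >= 0.65 * 12
    ]
    assert out.protein_ids == expected


def test_filter_monotone_in_fraction(rng):
    vals = rng.normal(size=(10, 25))
    vals[rng.random(vals.shape) < 0.5] = np.nan
    m = make_protein_matrix(vals)
    previous = None
    for frac in (0.2, 0.4, 0.6, 0.8, 1.0):
        kept = set(filter_valid_fraction(m, frac)[0].protein_ids)
        if previous is not None:
            assert kept <= previous
        previous = kept


def test_filter_empty_matrix_rejected():
    m = make_protein_matrix(np.empty((0, 0)))
    with pytest.raises(DataError):
        filter_valid_fraction(m)


# -- downshifted-normal imputation -----------------------------------------

def test_impute_complete_matrix_unchanged(rng):
    m = make_protein_matrix(rng.normal(20, 2, size=(4, 6)))
    out = impute_downshifted_normal(m, seed=0)
    pd.testing.assert_frame_equal(out.data, m.data)
    assert out.state == "imputed"


def test_impute_distribution_monte_carlo():
    # one sample: present values [18, 20, 22] (mean 20, SD 2), 10000 missing
    n_miss = 10_000
    row = np.concatenate([[18.0, 20.0, 22.0], np.full(n_miss, np.nan)])
    m = make_protein_matrix(row[None, :])
    out = impute_downshifted_normal(m, shift_sd=1.8, width_sd=0.3, seed=123)
    imputed = out.data.to_numpy()[0, 3:]
    target_mean = 20 - 1.8 * 2  # 16.4
    target_sd = 0.3 * 2  # 0.6
    se_mean = target_sd / np.sqrt(n_miss)
    assert abs(imputed.mean() - target_mean) <= 3 * se_mean
    se_sd = target_sd / np.sqrt(2 * (n_miss - 1))
    assert abs(imputed.std(ddof=1) - target_sd) <= 3 * se_sd


def test_impute_seed_reproducible(rng):
    vals = rng.normal(20, 2, size=(5, 8))
    vals[rng.random(vals.shape) < 0.3] = np.nan
    m = make_protein_matrix(vals)
    a = impute_downshifted_normal(m, seed=9)
    b = impute_downshifted_normal(m, seed=9)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_impute_rejects_sparse_sample():
    vals = np.array([[20.0, np.nan, np.nan], [19.0, 21.0, 18.0]])
    with pytest.raises(DataError, match="S0"):
        impute_downshifted_normal(make_protein_matrix(vals), seed=0)


def test_impute_leaves_present_values():
    vals = np.array([[20.0, np.nan, 22.0], [19.0, 21.0, 18.0]])
    out = impute_downshifted_normal(make_protein_matrix(vals), seed=1)
    assert out.data.iloc[0, 0] == 20.0
    assert out.data.iloc[0, 2] == 22.0
    assert not out.data.isna().any().any()


# -- quantile normalization -------------------------------------------------

def _qn_oracle(vals):
    """Sort-average-reassign reference implementation (no ties)."""
    ref = np.sort(vals, axis=1).mean(axis=0)
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        order = np.argsort(vals[i])
        out[i, order] = ref
    return out


def test_quantile_normalize_two_samples():
    m = make_protein_matrix([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], state="imputed")
    out = quantile_normalize(m)
    expected = np.array([[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])
    assert np.allclose(out.data.to_numpy(), expected)
    assert out.state == "normalized"


def test_quantile_normalize_identical_samples_unchanged():
    row = [3.0, 1.0, 2.0]
    m = make_protein_matrix([row, row, row], state="imputed")
    out = quantile_normalize(m)
    assert np.allclose(out.data.to_numpy(), np.array([row, row, row]))


def test_quantile_normalize_matches_oracle(rng):
    vals = rng.normal(size=(6, 5))
    out = quantile_normalize(make_protein_matrix(vals, state="imputed"))
    assert np.allclose(out.data.to_numpy(), _qn_oracle(vals), atol=1e-12)
    # every sample shares the same sorted values
    sorted_rows = np.sort(out.data.to_numpy(), axis=1)
    assert np.allclose(sorted_rows, sorted_rows[0])


def test_quantile_normalize_ties_get_spanned_mean():
    m = make_protein_matrix([[1.0, 1.0, 5.0], [2.0, 4.0, 6.0]], state="imputed")
    out = quantile_normalize(m)
    ref = np.sort(m.data.to_numpy(), axis=1).mean(axis=0)  # [1.5, 2.5, 5.5]
    assert np.allclose(out.data.iloc[0].to_numpy(), [ref[:2].mean(), ref[:2].mean(), ref[2]])


def test_quantile_normalize_idempotent(rng):
    vals = rng.normal(size=(8, 12))
    once = quantile_normalize(make_protein_matrix(vals, state="imputed"))
    twice = quantile_normalize(ProteinMatrix(once.data, state="imputed"))
    assert np.allclose(once.data.to_numpy(), twice.data.to_numpy(), atol=1e-10)


def test_quantile_normalize_rejects_missing():
    vals = np.array([[1.0, np.nan], [2.0, 3.0]])
    with pytest.raises(DataError):
        quantile_normalize(make_protein_matrix(vals, state="imputed"))


# -- permutation-FDR t-test -------------------------------------------------

def _balanced_groups(n_per=10):
    ids = [f"S{i}" for i in range(3 * n_per)]
    groups = ["AT"] * n_per + ["CTRL"] * n_per + ["DLP"] * n_per
    return pd.Series(groups, index=ids)


def _normalized(vals):
    df = pd.DataFrame(
        vals, index=[f"S{i}" for i in range(vals.shape[0])],
        columns=[f"P{j}" for j in range(vals.shape[1])],
    )
    return ProteinMatrix(df, state="normalized")


def test_degenerate_protein_never_significant(rng):
    vals = rng.normal(size=(30, 3))
    vals[:, 0] = 7.0  # constant in both groups
    m = _normalized(vals)
    res = permutation_fdr_ttest(m, _balanced_groups(), ("AT", "CTRL"), n_permutations=50, seed=0)
    assert res.table.loc["P0", "degenerate"]
    assert res.table.loc["P0", "q"] == 1.0
    assert not res.table.loc["P0", "significant"]


def test_injected_effect_detected(rng):
    n_per = 20
    vals = rng.normal(size=(3 * n_per, 40))
    vals[:n_per, 0] += 3.0  # 3 SD shift in AT for protein 0
    groups = _balanced_groups(n_per)
    res = permutation_fdr_ttest(_normalized(vals), groups, ("AT", "CTRL"), n_permutations=250, seed=1)
    assert res.table.loc["P0", "significant"]
    assert res.table.loc["P0", "q"] < 0.05
    # cross-check: the classical t-test agrees this is overwhelming evidence
    from scipy import stats

    t, p = stats.ttest_ind(vals[:n_per, 0], vals[n_per : 2 * n_per, 0])
    assert p < 1e-6
    assert np.isclose(res.table.loc["P0", "t"], t, atol=1e-10)


def test_q_values_monotone_in_abs_t(rng):
    vals = rng.normal(size=(24, 60))
    res = permutation_fdr_ttest(_normalized(vals), _balanced_groups(8), ("AT", "DLP"), n_permutations=100, seed=4)
    t = res.table["t"].abs().to_numpy()
    q = res.table["q"].to_numpy()
    order = np.argsort(t)
    assert np.all(np.diff(q[order]) <= 1e-12)


def test_small_groups_rejected(rng):
    vals = rng.normal(size=(5, 4))
    groups = pd.Series(["AT", "AT", "CTRL", "CTRL", "DLP"], index=[f"S{i}" for i in range(5)])
    with pytest.raises(DataError):
        permutation_fdr_ttest(_normalized(vals), groups, ("AT", "CTRL"))


def test_state_transitions_enforced(rng):
    raw = make_protein_matrix(rng.uniform(1, 10, (4, 4)), state="raw")
    with pytest.raises(DataError):
        quantile_normalize(raw)  # skipping the chain is an error
    with pytest.raises(DataError):
        impute_downshifted_normal(raw, seed=0)
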