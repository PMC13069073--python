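import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stratomic.datatypes import DataError
from stratomic.stats import (
    binary_auc,
    filter_panel_by_auc,
    group_tests,
    mad_outlier_flags,
    roc_coordinates,
    spearman_screen,
)


# -- binary AUC / Youden ----------------------------------------------------

def test_perfect_separation():
    r = binary_auc([1, 2, 3, 4], [False, False, True, True])
    assert r.auc == 1.0
    assert r.cutoff == 2.5
    assert r.sensitivity == 1.0 and r.specificity == 1.0


def test_inverted_labels_give_zero_auc():
    r = binary_auc([1, 2, 3, 4], [True, True, False, False])
    assert r.auc == 0.0


def _auc_pair_counting(values, labels):
    """Exhaustive pair-concordance oracle, ties count half."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _youden_scan(values, labels):
    """Exhaustive threshold scan; ties toward higher sensitivity."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    lo = distinct[0] - (distinct[1] - distinct[0]) / 2.0
    hi = distinct[-1] + (distinct[-1] - distinct[-2]) / 2.0
    best = None
    for c in np.concatenate([[lo], mids, [hi]]):
        called = v >= c
        sens = (called & lab).sum() / lab.sum()
        spec = (~called & ~lab).sum() / (~lab).sum()
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and sens > best[1]):
            best = (j, sens, c)
    return best[2]


def test_eight_point_toy_with_tie_matches_oracles():
    values = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 7.0]
    labels = [False, False, True, False, True, True, False, True]
    r = binary_auc(values, labels)
    assert r.auc == pytest.approx(_auc_pair_counting(values, labels), abs=1e-12)
    assert r.cutoff == pytest.approx(_youden_scan(values, labels), abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.integers(min_value=-5, max_value=5), min_size=4, max_size=10),
    st.data(),
)
def test_auc_flip_identity_and_oracle(vals, data):
    n = len(vals)
    labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
    if not (any(labels) and not all(labels)):
        labels[0], labels[-1] = True, False
    values = [float(v) for v in vals]
    r = binary_auc(values, labels)
    flipped = binary_auc(values, [not l for l in labels])
    assert r.auc + flipped.auc == pytest.approx(1.0, abs=1e-12)
    assert r.auc == pytest.approx(_auc_pair_counting(values, labels), abs=1e-12)


def test_auc_invariant_under_monotone_transform(rng):
    values = rng.normal(size=20)
    labels = rng.random(20) < 0.5
    labels[0], labels[1] = True, False
    a = binary_auc(values, labels).auc
    b = binary_auc(np.exp(3 * values), labels).auc
    assert a == pytest.approx(b, abs=1e-12)


def test_single_class_rejected():
    with pytest.raises(DataError):
        binary_auc([1.0, 2.0], [True, True])


def test_roc_coordinates_monotone(rng):
    values = rng.normal(size=30)
    labels = np.concatenate([np.ones(15, bool), np.zeros(15, bool)])
    coords = roc_coordinates(values, labels)
    assert (coords["fpr"].diff().dropna() >= 0).all()
    assert (coords["tpr"].diff().dropna() >= 0).all()


# -- panel AUC filter -------------------------------------------------------

def _grouped_frame(rng, n_per=25):
    groups = pd.Series(
        ["CTRL"] * n_per + ["DLP"] * n_per + ["AT"] * n_per,
        index=[f"S{i}" for i in range(3 * n_per)],
    )
    X = pd.DataFrame(
        rng.normal(size=(3 * n_per, 4)),
        index=groups.index,
        columns=["strong_up", "strong_down", "ctrl_only", "noise"],
    )
    at = (groups == "AT").to_numpy()
    X.loc[at, "strong_up"] += 3.0
    X.loc[at, "strong_down"] -= 3.0
    X.loc[(groups == "CTRL").to_numpy(), "ctrl_only"] -= 3.0  # separates CTRL, not DLP
    return X, groups


def test_panel_filter_directions_and_exclusions(rng):
    X, groups = _grouped_frame(rng)
    retained, results = filter_panel_by_auc(X, groups, list(X.columns), threshold=0.7)
    assert "strong_up" in retained
    assert "strong_down" in retained  # direction-agnostic
    assert "ctrl_only" not in retained  # fails AT vs DLP
    assert "noise" not in retained
    assert {r.comparison for r in results["strong_up"]} == {("AT", "DLP"), ("AT", "CTRL")}


def test_panel_filter_monotone_in_threshold(rng):
    X, groups = _grouped_frame(rng, n_per=15)
    prev = None
    for thr in (0.5, 0.7, 0.9, 0.999):
        retained, _ = filter_panel_by_auc(X, groups, list(X.columns), threshold=thr)
        if prev is not None:
            assert set(retained) <= prev
        prev = set(retained)


def test_panel_filter_strict_inequality():
    # a feature with AUC exactly at the threshold in one comparison is excluded
    values = np.array([0.0, 1.0, 2.0, 3.0] * 3)
    groups = pd.Series(
        ["CTRL"] * 4 + ["DLP"] * 4 + ["AT"] * 4, index=[f"S{i}" for i in range(12)]
    )
    X = pd.DataFrame({"f": values}, index=groups.index)
    r = filter_panel_by_auc(X, groups, ["f"], threshold=0.5)
    assert r[0] == []  # AUC is exactly 0.5 in both comparisons; strict > fails


def test_panel_filter_missing_candidate_rejected(rng):
    X, groups = _grouped_frame(rng, n_per=10)
    with pytest.raises(DataError):
        filter_panel_by_auc(X, groups, ["ghost"])


# -- Spearman screen --------------------------------------------------------

def test_monotone_pair_selected(rng):
    x = rng.normal(size=15)
    X = pd.DataFrame({"a": x, "b": np.exp(x), "c": rng.normal(size=15)})
    out = spearman_screen(X)
    row = out[(out.feature_i == "a") & (out.feature_j == "b")]
    assert row["R"].iloc[0] == pytest.approx(1.0)
    assert row["selected"].iloc[0]


def test_strict_boundary_not_selected(rng):
    x = rng.normal(size=50)
    y = x + rng.normal(size=50)
    rho = pd.Series(x).corr(pd.Series(y), method="spearman")
    X = pd.DataFrame({"a": x, "b": y})
    out = spearman_screen(X, r_threshold=abs(rho))  # threshold == |R| -> strict fails
    assert len(out[out["selected"]]) == 0


def test_screen_matches_rank_pearson_oracle(rng):
    X = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
    out = spearman_screen(X, r_threshold=0.0)
    for _, row in out[~out["undefined"]].iterrows():
        ri = X[row.feature_i].rank()
        rj = X[row.feature_j].rank()
        assert row["R"] == pytest.approx(ri.corr(rj), abs=1e-10)
    # sorted by |R| descending
    assert (out["R"].abs().diff().dropna() <= 1e-12).all()


def test_constant_feature_flagged(rng):
    X = pd.DataFrame({"a": np.ones(10), "b": rng.normal(size=10)})
    out = spearman_screen(X, r_threshold=0.0)
    assert out["undefined"].iloc[0]
    assert not out["selected"].any()


def test_screen_needs_three_samples(rng):
    X = pd.DataFrame(rng.normal(size=(2, 3)))
    with pytest.raises(DataError):
        spearman_screen(X)


# -- group tests ------------------------------------------------------------

def test_identical_groups_kruskal_p_one():
    vals = [1.0, 2.0, 3.0, 4.0, 5.0]
    res = group_tests(values_by_group={"a": vals, "b": vals, "c": vals})
    assert res["p"] > 0.99
    assert res["H"] == pytest.approx(0.0, abs=1e-10)


def test_chi_square_on_reported_sex_counts():
    # 33/66 female vs 9/60 female
    table = np.array([[33, 33], [9, 51]])
    res = group_tests(contingency=table)
    assert res["p"] < 0.001


def _kruskal_oracle(groups):
    """Rank-sum formula with tie correction."""
    pooled = np.concatenate(groups)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def test_kruskal_matches_rank_sum_oracle(rng):
    groups = [rng.normal(size=5), rng.normal(size=5) + 1, rng.normal(size=5)]
    res = group_tests(values_by_group={"a": groups[0], "b": groups[1], "c": groups[2]})
    assert res["H"] == pytest.approx(_kruskal_oracle(groups), abs=1e-10)
    posthoc = res["posthoc"]
    assert len(posthoc) == 3
    assert posthoc["p"].between(0, 1).all()


def test_group_tests_errors():
    with pytest.raises(DataError):
        group_tests(values_by_group={"a": [1.0, 2.0], "b": []})
    with pytest.raises(DataError):
        group_tests()
    with pytest.raises(DataError):
        group_tests(contingency=np.array([[0, 0], [1, 2]]))


def test_mad_outliers():
    vals = np.concatenate([np.zeros(20) + np.arange(20) * 0.01, [50.0]])
    flags = mad_outlier_flags(vals)
    assert flags[-1] and flags[:-1].sum() == 0
    assert not mad_outlier_flags(np.ones(10)).any()
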