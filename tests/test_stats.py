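"""Marker statistics: normalization, Kruskal-Wallis, PLS-DA VIP, PCA."""

import numpy as np
import pandas as pd
import pytest

from mitomarkers.io_formats import MarkerTable
from mitomarkers.stats import (
    NormalizedMatrix, kruskal_wallis, normalize, pca, plsda_vip, top_markers,
)


def make_table(values, groups, markers=None):
    markers = markers or [f"m{j}" for j in range(np.shape(values)[1])]
    idx = pd.Index([f"s{i}" for i in range(len(values))], name="sample")
    return MarkerTable(pd.DataFrame(values, index=idx, columns=markers),
                       pd.Series(groups, index=idx, name="group"))


def kruskal_oracle(groups_values):
    """Brute-force H with explicit mid-ranks and tie correction."""
    pooled = np.concatenate(groups_values)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    i = 0
    s = pooled[order]
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2
        i = j
    N = len(pooled)
    at = 0
    rank_sums = []
    for g in groups_values:
        rank_sums.append(ranks[at:at + len(g)].sum())
        at += len(g)
    H = 12 / (N * (N + 1)) * sum(
        R * R / len(g) for R, g in zip(rank_sums, groups_values)) - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (N**3 - N)
    return H / correction if correction > 0 else 0.0


def test_normalize_autoscaling_invariant():
    rng = np.random.default_rng(0)
    table = make_table(rng.uniform(1, 50, (12, 6)),
                       ["A"] * 6 + ["B"] * 6)
    norm = normalize(table)
    means = norm.values.mean(axis=0)
    sds = norm.values.std(axis=0, ddof=1)
    assert np.allclose(means, 0, atol=1e-9)
    assert np.allclose(sds, 1, atol=1e-9)


def test_normalize_single_marker_degenerates_to_zero():
    table = make_table([[2.0], [8.0]], ["A", "B"])
    norm = normalize(table)
    assert np.allclose(norm.values.to_numpy(), 0.0)


def test_normalize_row_scale_invariance():
    rng = np.random.default_rng(1)
    raw = rng.uniform(1, 10, (6, 4))
    t1 = make_table(raw, ["A"] * 3 + ["B"] * 3)
    scaled = raw.copy()
    scaled[2] *= 10.0
    t2 = make_table(scaled, ["A"] * 3 + ["B"] * 3)
    n1, n2 = normalize(t1), normalize(t2)
    assert np.allclose(n1.values.to_numpy(), n2.values.to_numpy(), atol=1e-9)


def test_normalize_errors_and_imputation():
    with pytest.raises(ValueError, match="all-zero"):
        normalize(make_table([[0.0, 0.0], [1.0, 2.0]], ["A", "B"]))
    table = make_table([[1.0, np.nan], [2.0, 4.0], [3.0, 8.0]],
                       ["A", "B", "B"])
    norm = normalize(table)
    assert norm.imputed_cells == [("s0", "m1")]
    assert np.isfinite(norm.values.to_numpy()).all()


def test_kruskal_hand_ranked_fixture():
    table = make_table([[1], [2], [3], [4], [5], [6], [7], [8], [9]],
                       ["a"] * 3 + ["b"] * 3 + ["c"] * 3, ["m"])
    H, df, p = kruskal_wallis(table)["m"]
    assert H == pytest.approx(7.2)
    assert df == 2
    assert 0 < p < 0.05


def test_kruskal_all_identical_H0_p1():
    table = make_table([[5.0]] * 6, ["a"] * 3 + ["b"] * 3, ["m"])
    H, df, p = kruskal_wallis(table)["m"]
    assert H == 0.0 and p == 1.0


def test_kruskal_matches_brute_force_with_ties():
    rng = np.random.default_rng(2)
    for _ in range(50):
        sizes = rng.integers(3, 7, rng.integers(2, 5))
        values = [np.round(rng.uniform(0, 5, s), 0) for s in sizes]  # many ties
        if np.ptp(np.concatenate(values)) == 0:
            continue
        col = np.concatenate(values)[:, None]
        groups = sum(([f"g{k}"] * s for k, s in enumerate(sizes)), [])
        H, df, _ = kruskal_wallis(make_table(col, groups, ["m"]))["m"]
        assert H == pytest.approx(kruskal_oracle(values), abs=1e-9)
        assert df == len(sizes) - 1


def _informative_matrix(rng, n_per_group=6, noise_sd=0.05):
    groups = ["A"] * n_per_group + ["B"] * n_per_group
    indicator = np.array([0.0] * n_per_group + [1.0] * n_per_group)
    X = rng.normal(0, 1, (2 * n_per_group, 10))
    X[:, 0] = indicator + rng.normal(0, noise_sd, 2 * n_per_group)
    idx = pd.Index([f"s{i}" for i in range(2 * n_per_group)], name="sample")
    values = pd.DataFrame(X, index=idx, columns=[f"m{j}" for j in range(10)])
    from mitomarkers.stats import autoscale

    return NormalizedMatrix(autoscale(values),
                            pd.Series(groups, index=idx, name="group"))


def test_vip_identity_and_informative_marker():
    rng = np.random.default_rng(3)
    norm = _informative_matrix(rng)
    res = plsda_vip(norm, n_components=2)
    assert float((res.vip**2).sum()) == pytest.approx(10.0, abs=1e-6)
    assert res.vip.idxmax() == "m0"
    assert res.vip["m0"] > 1.0


def test_vip_single_group_rejected():
    rng = np.random.default_rng(4)
    norm = _informative_matrix(rng)
    with pytest.raises(ValueError, match="2 groups"):
        plsda_vip(norm, groups=pd.Series(["A"] * 12, index=norm.values.index))


def test_vip_ordering_matches_mean_difference_one_component():
    """With one component and two balanced groups, VIP ordering equals the
    ordering by absolute autoscaled group-mean difference."""
    rng = np.random.default_rng(5)
    norm = _informative_matrix(rng, noise_sd=0.0)
    res = plsda_vip(norm, n_components=1)
    groups = norm.groups
    diffs = (norm.values[groups == "B"].mean() -
             norm.values[groups == "A"].mean()).abs()
    assert list(res.vip.sort_values(ascending=False).index) == \
        list(diffs.sort_values(ascending=False).index)


def test_vip_duplicating_a_sample_keeps_ordering():
    rng = np.random.default_rng(6)
    norm = _informative_matrix(rng)
    order1 = list(plsda_vip(norm, n_components=2).vip
                  .sort_values(ascending=False).index[:3])
    dup_vals = pd.concat([norm.values, norm.values.iloc[[0]]
                          .rename(index={"s0": "s0b"})])
    dup_groups = pd.concat([norm.groups,
                            pd.Series({"s0b": norm.groups.iloc[0]})])
    from mitomarkers.stats import autoscale

    dup = NormalizedMatrix(autoscale(dup_vals), dup_groups)
    order2 = list(plsda_vip(dup, n_components=2).vip
                  .sort_values(ascending=False).index[:3])
    assert order1[0] == order2[0] == "m0"


def test_pca_variance_accounting():
    rng = np.random.default_rng(7)
    norm = _informative_matrix(rng)
    res = pca(norm)
    assert res.variance_pct.sum() == pytest.approx(100.0, abs=1e-6)
    assert (res.variance_pct >= 0).all()
    two = NormalizedMatrix(norm.values.iloc[:2], norm.groups.iloc[:2])
    assert pca(two).variance_pct[0] == pytest.approx(100.0)


def test_pca_rank_one_matrix_single_component():
    rng = np.random.default_rng(8)
    u = rng.normal(0, 1, 8)
    v = rng.normal(0, 1, 5)
    X = np.outer(u, v)
    idx = pd.Index([f"s{i}" for i in range(8)], name="sample")
    values = pd.DataFrame(X, index=idx, columns=[f"m{j}" for j in range(5)])
    norm = NormalizedMatrix(values, pd.Series(["A"] * 4 + ["B"] * 4, index=idx))
    res = pca(norm)
    assert res.variance_pct[0] == pytest.approx(100.0, abs=1e-9)


def test_pca_scores_invariant_under_sample_reordering():
    rng = np.random.default_rng(9)
    norm = _informative_matrix(rng)
    res1 = pca(norm)
    perm = rng.permutation(len(norm.values))
    shuffled = NormalizedMatrix(norm.values.iloc[perm], norm.groups.iloc[perm])
    res2 = pca(shuffled)
    for k in range(2):
        a = res1.scores.iloc[perm, k].to_numpy()
        b = res2.scores.iloc[:, k].to_numpy()
        assert np.allclose(a, b, atol=1e-9) or np.allclose(a, -b, atol=1e-9)


def test_pca_group_collapsing():
    rng = np.random.default_rng(10)
    norm = _informative_matrix(rng)
    res = pca(norm, collapse_groups=True)
    assert list(res.group_scores.index) == ["A", "B"]
    manual = res.scores.groupby(norm.groups).mean()
    assert np.allclose(res.group_scores.to_numpy(), manual.to_numpy())


def test_top_markers_ranking_rules():
    rng = np.random.default_rng(11)
    norm = _informative_matrix(rng)
    kw = kruskal_wallis(norm)
    vip = plsda_vip(norm, n_components=2)
    ranked = top_markers(kw, vip, 5)
    assert ranked[0] == "m0"
    assert top_markers(kw, vip, 0) == []
    assert len(top_markers(kw, vip, 99)) == 10
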