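import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dysrisk as dr
from dysrisk.model import ValidationError
from .conftest import euclidean_dm

counts_strategy = st.lists(st.integers(0, 50), min_size=1, max_size=40)


# ---------------------------------------------------------------------------
# alpha estimators

@pytest.mark.parametrize("counts,bias_corrected,expected", [
    ([3, 4, 5], True, 3.0),            # no singletons/doubletons -> observed
    ([1, 1, 2, 2, 5], True, 5 + 2 * 1 / (2 * 3)),   # 5.3333...
    ([1, 1, 2, 2, 5], False, 5 + 4 / (2 * 2)),      # 6.0 classic
    ([], True, 0.0),
    ([0, 0, 0], True, 0.0),
])
def test_chao1_closed_forms(counts, bias_corrected, expected):
    assert dr.chao1(counts, bias_corrected=bias_corrected) == pytest.approx(
        expected, abs=1e-9
    )


def test_chao1_classic_f2_zero_falls_back():
    # singletons but no doubletons: classic form undefined, bias-corrected used
    assert dr.chao1([1, 1, 3], bias_corrected=False) == pytest.approx(3 + 2 / 2)


def test_chao1_rejects_relative_abundances():
    with pytest.raises(ValidationError, match="non-integer|relative"):
        dr.chao1([0.5, 0.5])


def test_chao1_matches_skbio():
    from skbio.diversity.alpha import chao1 as sk_chao1

    rng = np.random.default_rng(0)
    for _ in range(20):
        c = rng.integers(0, 6, size=30)
        if c.sum() == 0:
            continue
        assert dr.chao1(c) == pytest.approx(sk_chao1(c, bias_corrected=True))


@pytest.mark.parametrize("counts,expected", [
    ([7], 0.0),
    ([5, 5, 5, 5], np.log(4)),
    ([1, 1, 2], -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))),
])
def test_shannon_closed_forms(counts, expected):
    assert dr.shannon(counts) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("counts,expected", [
    ([7], 0.0),
    ([5, 5, 5, 5], 0.75),
    ([1, 1, 2], 0.625),
])
def test_simpson_closed_forms(counts, expected):
    assert dr.simpson(counts) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("fn", [dr.shannon, dr.simpson])
def test_entropy_rejects_empty(fn):
    with pytest.raises(ValidationError):
        fn([0, 0])


@settings(max_examples=60, derandomize=True)
@given(counts_strategy)
def test_alpha_invariants(counts):
    """chao1 >= observed (equal when F1 = 0); shannon <= ln(observed)."""
    c = np.array(counts)
    if c.sum() == 0:
        assert dr.chao1(c) == 0.0
        return
    observed = int((c > 0).sum())
    est = dr.chao1(c)
    assert est >= observed - 1e-12
    if (c == 1).sum() == 0:
        assert est == pytest.approx(observed)
    assert dr.shannon(c) <= np.log(observed) + 1e-12
    assert 0 <= dr.simpson(c) < 1


# ---------------------------------------------------------------------------
# phylum summaries

def test_phylum_abundance_conservation(count_table):
    rel = dr.phylum_abundance(count_table)
    np.testing.assert_allclose(rel.sum(axis=1), 1.0)
    assert "Unclassified" in rel.columns
    # sample a: t4 (unclassified) has 2 of 10 reads
    assert rel.loc["a", "Unclassified"] == pytest.approx(0.2)
    assert rel.loc["a", "Firmicutes"] == pytest.approx(0.8)


def test_phylum_abundance_single_phylum():
    t = dr.CountTable(
        ["s1"], ["t1", "t2"], np.array([[3, 7]]),
        {"t1": "k__B; p__Firmicutes", "t2": "k__B; p__Firmicutes"},
    )
    rel = dr.phylum_abundance(t)
    assert rel.loc["s1", "Firmicutes"] == pytest.approx(1.0)


def test_phylum_abundance_zero_read_sample_named():
    t = dr.CountTable(
        ["s1", "empty"], ["t1"], np.array([[3], [0]]), {"t1": "k__B; p__Firmicutes"}
    )
    with pytest.raises(ValidationError, match="empty"):
        dr.phylum_abundance(t)


def test_fb_ratio_values_and_zero_flagging():
    rel = pd.DataFrame(
        {"Firmicutes": [0.4, 0.3, 0.5], "Bacteroidetes": [0.4, 0.6, 0.0]},
        index=["a", "b", "c"],
    )
    with pytest.warns(UserWarning, match="zero"):
        ratio, summary = dr.fb_ratio(rel)
    assert ratio["a"] == pytest.approx(1.0)
    assert ratio["b"] == pytest.approx(0.5)
    assert np.isnan(ratio["c"])
    assert summary.loc["all", "n"] == 2


def test_fb_ratio_missing_phylum_lists_available():
    rel = pd.DataFrame({"Firmicutes": [0.5]}, index=["a"])
    with pytest.raises(ValidationError, match="Firmicutes"):
        dr.fb_ratio(rel)


# ---------------------------------------------------------------------------
# JSD

def test_jsd_identical_and_disjoint():
    t = dr.CountTable(
        ["a", "b", "c"], ["t1", "t2"], np.array([[5, 5], [10, 10], [7, 0]])
    )
    dm = dr.jsd_matrix(t)
    assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)
    t2 = dr.CountTable(["a", "b"], ["t1", "t2"], np.array([[9, 0], [0, 4]]))
    assert dr.jsd_matrix(t2).d[0, 1] == pytest.approx(np.log(2), abs=1e-12)


def test_jsd_matches_bruteforce_kl():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 30, size=(5, 12))
    x[:, 0] += 1
    t = dr.CountTable([f"s{i}" for i in range(5)], [f"t{j}" for j in range(12)], x)
    dm = dr.jsd_matrix(t)
    p = x / x.sum(axis=1, keepdims=True)

    def kl(a, b):
        m = a > 0
        return float((a[m] * np.log(a[m] / b[m])).sum())

    for i in range(5):
        for j in range(5):
            mid = (p[i] + p[j]) / 2
            expected = 0.5 * kl(p[i], mid) + 0.5 * kl(p[j], mid)
            assert dm.d[i, j] == pytest.approx(expected, abs=1e-12)
    # bounded, symmetric, zero diagonal
    assert (dm.d <= np.log(2) + 1e-12).all()
    np.testing.assert_allclose(dm.d, dm.d.T)
    assert np.diag(dm.d).max() == 0.0


def test_jsd_sqrt_variant():
    t = dr.CountTable(["a", "b"], ["t1", "t2"], np.array([[9, 1], [1, 9]]))
    plain = dr.jsd_matrix(t).d[0, 1]
    root = dr.jsd_matrix(t, sqrt=True).d[0, 1]
    assert root == pytest.approx(np.sqrt(plain))


def test_jsd_zero_total_sample_errors():
    t = dr.CountTable(["a", "b"], ["t1"], np.array([[0], [3]]))
    with pytest.raises(ValidationError, match="a"):
        dr.jsd_matrix(t)


# ---------------------------------------------------------------------------
# PERMANOVA

def test_permanova_separated_clusters_limit(clustered_dm):
    dm, groups = clustered_dm
    res = dr.permanova(dm, groups, n_permutations=99, seed=0)
    assert res.r2 > 0.999
    assert res.p_raw == pytest.approx(1 / 100)


def test_permanova_matches_direct_summation():
    """Pseudo-F on a 6-sample fixture equals an independent direct evaluation."""
    pts = np.array([[0.0, 0], [0.1, 0.2], [0.3, 0], [2.0, 2], [2.2, 1.9], [1.9, 2.4]])
    dm = euclidean_dm(pts)
    groups = ["A", "A", "A", "B", "B", "B"]
    res = dr.permanova(dm, groups, n_permutations=99, seed=1)

    d2 = dm.d ** 2
    n = 6
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in ("A", "B"):
        idx = [i for i, gi in enumerate(groups) if gi == g]
        ss_within += sum(
            d2[i, j] for i in idx for j in idx if i < j
        ) / len(idx)
    ss_between = ss_total - ss_within
    f_direct = (ss_between / 1) / (ss_within / 4)
    assert res.pseudo_f == pytest.approx(f_direct, rel=1e-12)
    assert res.r2 == pytest.approx(ss_between / ss_total, rel=1e-12)


def test_permanova_matches_skbio():
    from skbio.stats.distance import DistanceMatrix as SkDM
    from skbio.stats.distance import permanova as sk_permanova

    rng = np.random.default_rng(2)
    pts = rng.normal(size=(12, 3))
    pts[6:] += 1.0
    dm = euclidean_dm(pts)
    groups = ["A"] * 6 + ["B"] * 6
    mine = dr.permanova(dm, groups, n_permutations=9, seed=0)
    theirs = sk_permanova(SkDM(dm.d, dm.sample_ids), groups, permutations=9)
    assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)


def test_permanova_invariant_to_distance_scaling():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(10, 2))
    dm = euclidean_dm(pts)
    groups = ["A"] * 5 + ["B"] * 5
    r1 = dr.permanova(dm, groups, n_permutations=49, seed=3)
    scaled = dr.DistanceMatrix(dm.sample_ids, dm.d * 7.5)
    r2 = dr.permanova(scaled, groups, n_permutations=49, seed=3)
    assert r1.pseudo_f == pytest.approx(r2.pseudo_f, rel=1e-10)
    assert r1.r2 == pytest.approx(r2.r2, rel=1e-10)
    assert r1.p_raw == r2.p_raw


def test_permanova_input_validation(clustered_dm):
    dm, _ = clustered_dm
    with pytest.raises(ValidationError, match="size"):
        dr.permanova(dm, ["A"] * 15 + ["B"], 9)
    with pytest.raises(ValidationError, match="two groups"):
        dr.permanova(dm, ["A"] * 16, 9)


def test_permanova_seeded_determinism(clustered_dm):
    dm, groups = clustered_dm
    a = dr.permanova(dm, groups, n_permutations=99, seed=42)
    b = dr.permanova(dm, groups, n_permutations=99, seed=42)
    assert a.p_raw == b.p_raw


def test_bh_adjustment_battery():
    adj = dr.diversity.adjust_bh([0.01, 0.04, 0.03, 0.8])
    assert adj[3] == pytest.approx(0.8)
    assert (np.asarray(adj) >= [0.01, 0.04, 0.03, 0.8]).all()


# ---------------------------------------------------------------------------
# betadisper

def test_betadisper_detects_dispersion_difference():
    rng = np.random.default_rng(9)
    pts = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(0, 5, (15, 2))])
    dm = euclidean_dm(pts)
    res = dr.betadisper_test(dm, ["A"] * 15 + ["B"] * 15, n_permutations=999, seed=0)
    assert res["p"] < 0.01


def test_betadisper_single_group_errors():
    dm = euclidean_dm(np.random.default_rng(0).normal(size=(6, 2)))
    with pytest.raises(ValidationError):
        dr.betadisper_test(dm, ["A"] * 6, 9)


# ---------------------------------------------------------------------------
# PCoA

def test_pcoa_recovers_euclidean_geometry():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(8, 2))
    dm = euclidean_dm(pts)
    res = dr.pcoa(dm, k=2)
    rec = np.sqrt(
        ((res.coordinates[:, None, :] - res.coordinates[None, :, :]) ** 2).sum(-1)
    )
    np.testing.assert_allclose(rec, dm.d, atol=1e-8)
    assert res.explained[0] >= res.explained[1] > 0


def test_pcoa_collinear_points_single_axis():
    pts = np.array([[0.0], [1.0], [3.0]])
    dm = euclidean_dm(pts)
    with pytest.warns(UserWarning, match="truncating"):
        res = dr.pcoa(dm, k=2)
    assert res.coordinates.shape[1] == 1
    spacing = np.sort(res.coordinates[:, 0])
    np.testing.assert_allclose(np.diff(spacing), [1.0, 2.0], atol=1e-8)


def test_pcoa_identical_samples_zero_coordinates():
    dm = dr.DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
    with pytest.warns(UserWarning):
        res = dr.pcoa(dm, k=2)
    assert res.coordinates.shape[1] == 0
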