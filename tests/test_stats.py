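"""Kruskal–Wallis, Dunn/BH, UPGMA clustering, summaries and GLG indices."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import kruskal, norm, rankdata

from orcascape import (
    GLGProfile,
    benjamini_hochberg,
    cophenetic_matrix,
    cut_tree,
    dunn_posthoc,
    group_summary,
    kruskal_wallis,
    parse_newick,
    standardize_profile,
    to_newick,
    upgma_cluster,
    upgma_from_values,
    within_tooth_index,
)
from orcascape.stats import DegenerateDataError, InsufficientDataError


# ---------- Kruskal–Wallis ----------

def test_kw_hand_computed_example():
    """Groups {1,2} vs {3,4}: rank sums 3 and 7 give H = 2.4."""
    res = kruskal_wallis([[1, 2], [3, 4]])
    assert res.H == pytest.approx(2.4, abs=1e-12)
    assert res.df == 1 and res.group_sizes == (2, 2)


def test_kw_symmetric_groups_give_zero():
    res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
    assert res.H == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_kw_degenerate_data_rejected():
    with pytest.raises(DegenerateDataError):
        kruskal_wallis([[5, 5], [5, 5, 5]])


@settings(derandomize=True, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_kw_matches_scipy_with_ties(seed):
    rng = np.random.default_rng(seed)
    groups = [list(rng.integers(0, 6, size=rng.integers(3, 9))) for _ in range(4)]
    if np.ptp(np.concatenate(groups)) == 0:
        groups[0][0] += 1
    ours = kruskal_wallis(groups)
    ref_h, ref_p = kruskal(*groups)
    assert ours.H == pytest.approx(ref_h, abs=1e-10)
    assert ours.p_value == pytest.approx(ref_p, abs=1e-10)


def test_kw_formula_oracle():
    """Independent implementation of the tie-corrected formula."""
    rng = np.random.default_rng(7)
    groups = [list(rng.integers(0, 10, size=n)) for n in (5, 6, 4, 7)]
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    n_tot = pooled.size
    start, h = 0, 0.0
    for g in groups:
        h += ranks[start:start + len(g)].sum() ** 2 / len(g)
        start += len(g)
    h = 12 / (n_tot * (n_tot + 1)) * h - 3 * (n_tot + 1)
    _, counts = np.unique(pooled, return_counts=True)
    h /= 1 - (counts**3 - counts).sum() / (n_tot**3 - n_tot)
    assert kruskal_wallis(groups).H == pytest.approx(h, abs=1e-10)


@settings(derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_kw_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    groups = [list(rng.normal(size=5)), list(rng.normal(1, 1, size=6)), list(rng.normal(size=4))]
    base = kruskal_wallis(groups).H
    transformed = [[math.exp(v) for v in g] for g in groups]
    assert kruskal_wallis(transformed).H == pytest.approx(base, abs=1e-10)


def test_kw_tie_correction_is_identity_without_duplicates():
    groups = [[1.5, 2.25, 9.0], [3.125, 7.0], [0.5, 4.75, 6.5]]
    pooled = np.concatenate(groups)
    assert len(np.unique(pooled)) == pooled.size
    res = kruskal_wallis(groups)
    ranks = rankdata(pooled)
    start, h = 0, 0.0
    for g in groups:
        h += ranks[start:start + len(g)].sum() ** 2 / len(g)
        start += len(g)
    h = 12 / (pooled.size * (pooled.size + 1)) * h - 3 * (pooled.size + 1)
    assert res.H == pytest.approx(h, abs=1e-12)


# ---------- Dunn + BH ----------

def test_dunn_identical_groups():
    res = dunn_posthoc([[1, 2, 3], [1, 2, 3]], adjust="none")
    (_, _, z, p_raw, p_adj), = res.pairs
    assert z == pytest.approx(0.0, abs=1e-12)
    assert p_raw == pytest.approx(1.0) and p_adj == p_raw


def test_dunn_formula_oracle():
    """Hand-coded z statistic on integer data with ties, all pairs."""
    groups = {"a": [1, 2, 2, 5], "b": [3, 3, 4], "c": [6, 7, 2]}
    res = dunn_posthoc(groups, adjust="none")
    pooled = np.concatenate(list(groups.values()))
    ranks = rankdata(pooled)
    n_tot = pooled.size
    bounds, start = {}, 0
    for k, v in groups.items():
        bounds[k] = ranks[start:start + len(v)]
        start += len(v)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n_tot - 1))
    for ga, gb, z, p_raw, _ in res.pairs:
        se = math.sqrt((n_tot * (n_tot + 1) / 12 - tie_term) * (1 / len(groups[ga]) + 1 / len(groups[gb])))
        z_ref = (bounds[ga].mean() - bounds[gb].mean()) / se
        assert z == pytest.approx(z_ref, abs=1e-10)
        assert p_raw == pytest.approx(2 * norm.sf(abs(z_ref)), abs=1e-10)


def test_dunn_reports_each_unordered_pair_once():
    res = dunn_posthoc({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
    pairs = {frozenset((a, b)) for a, b, *_ in res.pairs}
    assert len(res.pairs) == 3 == len(pairs)
    assert all(pa >= pr for _, _, _, pr, pa in res.pairs)


def test_bh_step_up_definition():
    assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    # step-up: p_adj(i) = min over j >= i of p(j) * m / j
    p = [0.005, 0.041, 0.02, 0.9]
    expected = []
    srt = sorted(p)
    for v in p:
        i = srt.index(v)
        expected.append(min(min(srt[j] * 4 / (j + 1) for j in range(i, 4)), 1.0))
    assert np.allclose(benjamini_hochberg(p), expected)


@settings(derandomize=True, max_examples=30)
@given(seed=st.integers(0, 10_000), m=st.integers(1, 12))
def test_bh_monotone_and_bounded(seed, m):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, m)
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in the order statistics


# ---------- UPGMA ----------

def test_upgma_three_point_hand_example():
    tree = upgma_from_values(["a", "b", "c"], [0.0, 1.0, 5.0])
    (m1, m2) = tree.merges
    assert m1[2] == pytest.approx(1.0)  # {a,b} first
    assert m2[2] == pytest.approx(4.5)  # mean of |5-0| and |5-1|
    assert tree.monotone


def test_upgma_two_leaves():
    tree = upgma_from_values(["a", "b"], [2.0, 3.5])
    assert tree.merges == ((0, 1, 1.5),)


@settings(derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_upgma_matches_scipy_average_linkage(seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 2, 8)
    tree = upgma_from_values([f"s{i}" for i in range(8)], vals)
    ours = cophenetic_matrix(tree)
    z = linkage(vals[:, None], method="average", metric="euclidean")
    ref = squareform(cophenet(z))
    assert np.allclose(ours, ref, atol=1e-10)


def test_upgma_brute_force_heights():
    """O(n³) agglomeration oracle recomputing average linkage from scratch."""
    rng = np.random.default_rng(3)
    vals = list(rng.normal(0, 1, 8))
    tree = upgma_from_values([f"s{i}" for i in range(8)], vals)
    clusters = [[i] for i in range(8)]
    heights = []
    while len(clusters) > 1:
        best = (math.inf, None)
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([abs(vals[i] - vals[j]) for i in clusters[a] for j in clusters[b]])
            if d < best[0]:
                best = (d, (a, b))
        d, (a, b) = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    assert np.allclose(sorted(h for _, _, h in tree.merges), sorted(heights), atol=1e-10)


def test_fixture_tree_cut_at_three(fixture_records):
    tree = upgma_cluster(fixture_records)
    parts = cut_tree(tree, 3)
    sizes = sorted(len(p) for p in parts)
    assert sizes == [1, 4, 17]
    by_size = {len(p): set(p) for p in parts}
    assert by_size[1] == {"NWA-BP-1998"}
    assert by_size[4] == {"ECA-CS-1977-3", "ECA-RB-2009", "NWA-CB-1971-1", "NWA-CB-1971-2"}


def test_cut_tree_bounds(fixture_records):
    tree = upgma_cluster(fixture_records)
    assert len(cut_tree(tree, 1)) == 1 and len(cut_tree(tree, 1)[0]) == 22
    assert all(len(g) == 1 for g in cut_tree(tree, 22))
    with pytest.raises(ValueError):
        cut_tree(tree, 0)
    with pytest.raises(ValueError):
        cut_tree(tree, 23)


def test_upgma_needs_two_records(fixture_records):
    with pytest.raises(InsufficientDataError):
        upgma_cluster(fixture_records[:1])


def test_newick_roundtrip(fixture_records):
    tree = upgma_cluster(fixture_records)
    back = parse_newick(to_newick(tree))
    assert set(back.leaves) == set(tree.leaves)
    # same tree ⇔ same cophenetic distances between the same leaf names
    idx_t = {n: i for i, n in enumerate(tree.leaves)}
    perm = [idx_t[n] for n in back.leaves]
    ct = cophenetic_matrix(tree)[np.ix_(perm, perm)]
    assert np.allclose(cophenetic_matrix(back), ct, atol=1e-9)


# ---------- summaries and GLG profiles ----------

def test_group_summary_published_values(fixture_records):
    groups = {}
    for r in fixture_records:
        groups.setdefault(r.region, []).append(r.d18O_p)
    summary = {g.label: g for g in group_summary(groups)}
    assert (round(summary["ECA"].mean, 2), round(summary["ECA"].sd, 2)) == (17.21, 1.11)
    assert (round(summary["NWA"].mean, 2), round(summary["NWA"].sd, 2)) == (18.45, 1.81)
    assert summary["Denmark"].n == 3


def test_group_summary_singleton_sd_missing():
    (g,) = group_summary({"solo": [17.0]})
    assert g.sd is None and g.n == 1


def test_standardize_profile():
    p = GLGProfile("X", ((1, -13.0, -14.0), (2, -12.0, -13.5), (3, -14.0, None)))
    s = standardize_profile(p, "d18O_sc")
    assert s.analyte("d18O_sc") == [0.0, 1.0, -1.0]
    assert s.analyte("d13C_sc") == [-14.0, -13.5, None]  # other analyte untouched
    # additive shift preserves pairwise differences
    orig = p.analyte("d18O_sc")
    new = s.analyte("d18O_sc")
    assert new[2] - new[1] == pytest.approx(orig[2] - orig[1])


def test_standardize_profile_missing_first_value():
    p = GLGProfile("X", ((1, None, -14.0), (2, -12.0, -13.5)))
    with pytest.raises(InsufficientDataError):
        standardize_profile(p, "d18O_sc")


def test_within_tooth_index():
    const = GLGProfile("X", ((1, -13.0, None), (2, -13.0, None)))
    assert within_tooth_index(const) == (0.0, 0.0)
    p = GLGProfile("Y", ((1, 0.0, None), (2, 1.0, None), (3, 2.0, None)))
    sd, rng_ = within_tooth_index(p)
    assert sd == pytest.approx(1.0) and rng_ == pytest.approx(2.0)


def test_within_tooth_index_matches_two_pass_oracle():
    rng = np.random.default_rng(11)
    vals = rng.normal(-13, 0.8, 9)
    p = GLGProfile("Z", tuple((i + 1, float(v), None) for i, v in enumerate(vals)))
    sd, spread = within_tooth_index(p)
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    assert sd == pytest.approx(math.sqrt(var), abs=1e-12)
    assert spread == pytest.approx(max(vals) - min(vals), abs=1e-12)


def test_within_tooth_index_insufficient_data():
    p = GLGProfile("X", ((1, -13.0, None),))
    with pytest.raises(InsufficientDataError):
        within_tooth_index(p)
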