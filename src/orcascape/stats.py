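"""Cohort statistics: Kruskal–Wallis, Dunn's post-hoc with Benjamini–Hochberg,
UPGMA clustering of δ¹⁸O_P, group summaries and within-tooth GLG indices.

The nonparametric machinery is implemented here directly (midranks, the
tie-corrected H statistic, Dunn's z, the BH step-up) rather than delegated,
so every formula is inspectable and testable against independent oracles:

    H = [ 12/(N(N+1)) Σ R_i²/n_i − 3(N+1) ] / ( 1 − Σ(t³−t)/(N³−N) )

with group rank sums R_i, group sizes n_i, pooled size N and tie-run lengths
t; H is referred to a χ² distribution with k−1 degrees of freedom.  Dunn's
pairwise statistic divides mean-rank differences by the tie-corrected
standard error and uses two-sided normal p-values, adjusted by BH across all
k(k−1)/2 pairs.

Clustering is agglomerative average linkage (UPGMA) on pairwise |Δδ¹⁸O_P|
(Euclidean distance in one dimension).  Ties between merge candidates are
broken by the earliest smallest leaf (input order) so dendrograms are
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2, norm

from .specimens import GLGProfile, SpecimenRecord

__all__ = [
    "KWResult",
    "DunnResult",
    "ClusterTree",
    "GroupSummary",
    "DegenerateDataError",
    "InsufficientDataError",
    "kruskal_wallis",
    "dunn_posthoc",
    "benjamini_hochberg",
    "upgma_cluster",
    "upgma_from_values",
    "cut_tree",
    "cophenetic_matrix",
    "to_newick",
    "parse_newick",
    "group_summary",
    "standardize_profile",
    "within_tooth_index",
]


class DegenerateDataError(ValueError):
    """All pooled values identical: the tie correction divides by zero."""


class InsufficientDataError(ValueError):
    """Too few usable observations for the requested statistic."""


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class DunnResult:
    """All unordered group pairs with z, raw and adjusted two-sided p."""

    pairs: tuple[tuple[str, str, float, float, float], ...]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sd: float | None
    n: int


def _midranks(pooled: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Midranks of the pooled sample and the tie-run lengths."""
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(pooled.size, dtype=float)
    ties: list[int] = []
    i = 0
    s = pooled[order]
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and s[j + 1] == s[i]:
            j += 1
        # tied run occupies ranks i+1..j+1 → midrank (i+j)/2 + 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        ties.append(j - i + 1)
        i = j + 1
    return ranks, ties


def _check_groups(groups: Sequence[Sequence[float]]):
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise InsufficientDataError("empty group")
    pooled = np.concatenate(arrs)
    if pooled.size < 3:
        raise InsufficientDataError("need total N >= 3")
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all pooled values are identical")
    return arrs, pooled


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal–Wallis rank-sum test with χ²_{k−1} p-value."""
    arrs, pooled = _check_groups(groups)
    N = pooled.size
    ranks, ties = _midranks(pooled)
    sizes = [a.size for a in arrs]
    h = 0.0
    start = 0
    for n_i in sizes:
        r_i = ranks[start : start + n_i].sum()
        h += r_i**2 / n_i
        start += n_i
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    correction = 1.0 - sum(t**3 - t for t in ties) / (N**3 - N)
    h /= correction
    df = len(arrs) - 1
    return KWResult(H=float(h), df=df, p_value=float(chi2.sf(h, df)), group_sizes=tuple(sizes))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values: p_adj(i) = min_{j>=i} p(j)·m/j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    adjust: str = "bh",
) -> DunnResult:
    """Dunn's pairwise mean-rank comparisons after a Kruskal–Wallis test.

    ``groups`` may be a label→values mapping or a plain sequence (labelled
    ``g0``, ``g1``, …).  ``adjust`` is ``"bh"`` or ``"none"``.
    """
    if adjust not in ("bh", "none"):
        raise ValueError("adjust must be 'bh' or 'none'")
    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        seqs = [groups[k] for k in labels]
    else:
        labels = [f"g{i}" for i in range(len(groups))]
        seqs = list(groups)
    arrs, pooled = _check_groups(seqs)
    N = pooled.size
    ranks, ties = _midranks(pooled)
    mean_ranks = []
    start = 0
    for a in arrs:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    tie_term = sum(t**3 - t for t in ties) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    zs, praw, pair_idx = [], [], []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            se = math.sqrt(base_var * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            zs.append(z)
            praw.append(2.0 * norm.sf(abs(z)))
            pair_idx.append((i, j))
    padj = benjamini_hochberg(praw) if adjust == "bh" else np.asarray(praw)
    pairs = tuple(
        (labels[i], labels[j], float(z), float(pr), float(pa))
        for (i, j), z, pr, pa in zip(pair_idx, zs, praw, padj)
    )
    return DunnResult(pairs=pairs)


@dataclass(frozen=True)
class ClusterTree:
    """UPGMA dendrogram: leaves plus an ordered merge list.

    Nodes are numbered scipy-style: leaf ``i`` is node ``i``; the ``k``-th
    merge creates node ``n + k``.  ``monotone`` is False if merge heights
    ever decreased (cannot happen for average linkage on a metric, checked
    anyway).
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]
    monotone: bool = True

    def __post_init__(self):
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError("a binary tree over n leaves has exactly n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


def upgma_from_values(ids: Sequence[str], values: Sequence[float]) -> ClusterTree:
    """Average-linkage agglomeration on 1-D values (Euclidean = |Δ|).

    Tie-break: among candidate pairs at the minimal distance, merge the pair
    whose smallest member leaf (by input order) is earliest; further ties by
    the other cluster's smallest leaf.
    """
    n = len(ids)
    if n < 2:
        raise InsufficientDataError("need at least 2 records to cluster")
    if len(set(ids)) != n:
        raise ValueError("duplicate specimen ids")
    x = np.asarray(values, dtype=float)
    # active clusters: node id -> (min leaf index, size)
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = abs(x[i] - x[j])
    active: dict[int, tuple[int, int]] = {i: (i, 1) for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    monotone = True
    last_height = -math.inf
    next_node = n
    while len(active) > 1:
        best_key = None
        best = (math.inf, math.inf, math.inf)
        for (a, b), d in dist.items():
            mins = sorted((active[a][0], active[b][0]))
            cand = (d, mins[0], mins[1])
            if cand < best:
                best = cand
                best_key = (a, b)
        a, b = best_key
        d = dist.pop((a, b))
        if d < last_height - 1e-12:
            monotone = False
        last_height = max(last_height, d)
        size_a, size_b = active[a][1], active[b][1]
        new_min = min(active[a][0], active[b][0])
        # average linkage: weighted mean of distances to the two children
        for c in list(active):
            if c in (a, b):
                continue
            d_a = dist.pop(tuple(sorted((a, c))))
            d_b = dist.pop(tuple(sorted((b, c))))
            dist[tuple(sorted((next_node, c)))] = (size_a * d_a + size_b * d_b) / (size_a + size_b)
        del active[a], active[b]
        active[next_node] = (new_min, size_a + size_b)
        merges.append((a, b, float(d)))
        next_node += 1
    return ClusterTree(leaves=tuple(ids), merges=tuple(merges), monotone=monotone)


def upgma_cluster(records: Sequence[SpecimenRecord]) -> ClusterTree:
    """UPGMA tree over specimens' whole-tooth/bone δ¹⁸O_P values."""
    usable = [r for r in records if r.d18O_p is not None]
    if len(usable) < 2:
        raise InsufficientDataError("need at least 2 records with d18O_p")
    return upgma_from_values([r.specimen_id for r in usable], [r.d18O_p for r in usable])


def cut_tree(tree: ClusterTree, k: int) -> list[list[str]]:
    """Partition the leaves into k groups by undoing the k−1 highest merges.

    Groups are returned in order of their earliest leaf (input order).
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    drop = set(
        idx
        for idx, _ in sorted(enumerate(tree.merges), key=lambda t: (t[1][2], t[0]))[len(tree.merges) - (k - 1):]
    )
    parent = list(range(n + len(tree.merges)))

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for idx, (a, b, _) in enumerate(tree.merges):
        node = n + idx
        if idx in drop:
            continue
        parent[find(a)] = node
        parent[find(b)] = node
    groups: dict[int, list[str]] = {}
    for i, leaf in enumerate(tree.leaves):
        groups.setdefault(find(i), []).append(leaf)
    return sorted(groups.values(), key=lambda g: tree.leaves.index(g[0]))


def cophenetic_matrix(tree: ClusterTree) -> np.ndarray:
    """Pairwise merge heights between leaves (tree-equality invariant)."""
    n = tree.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    out = np.zeros((n, n))
    for idx, (a, b, h) in enumerate(tree.merges):
        for i in members[a]:
            for j in members[b]:
                out[i, j] = out[j, i] = h
        members[n + idx] = members.pop(a) + members.pop(b)
    return out


def to_newick(tree: ClusterTree) -> str:
    """Newick string with branch lengths equal to merge-height differences."""
    height: dict[int, float] = {i: 0.0 for i in range(tree.n_leaves)}
    text: dict[int, str] = {i: name for i, name in enumerate(tree.leaves)}
    n = tree.n_leaves
    for idx, (a, b, h) in enumerate(tree.merges):
        node = n + idx
        la, lb = h - height[a], h - height[b]
        text[node] = f"({text[a]}:{la!r},{text[b]}:{lb!r})"
        height[node] = h
    root = n + len(tree.merges) - 1
    return text[root] + ";"


def parse_newick(s: str) -> ClusterTree:
    """Parse a binary ultrametric newick string back into a :class:`ClusterTree`.

    Merge order is by height (ties by position), so ``parse_newick(to_newick(t))``
    has the same leaves and cophenetic matrix as ``t``.
    """
    s = s.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0

    def parse_node():
        # returns (leaf names in subtree, subtree height, merge list of (left names, right names, height))
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            left = parse_clade()
            assert s[pos] == ","
            pos += 1
            right = parse_clade()
            assert s[pos] == ")"
            pos += 1
            (ln, lh, lm), (llen,) = left[:3], left[3:]
            (rn, rh, rm), (rlen,) = right[:3], right[3:]
            h = lh + llen
            if abs((rh + rlen) - h) > 1e-9 * max(1.0, abs(h)):
                raise ValueError("tree is not ultrametric")
            return ln + rn, h, lm + rm + [(ln, rn, h)]
        start = pos
        while pos < len(s) and s[pos] not in ":,()":
            pos += 1
        return [s[start:pos]], 0.0, []

    def parse_clade():
        nonlocal pos
        names, h, merges = parse_node()
        length = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            length = float(s[start:pos])
        return names, h, merges, length

    names, _, merges = parse_node()
    leaves = tuple(names)
    index = {name: i for i, name in enumerate(leaves)}
    merges_sorted = sorted(enumerate(merges), key=lambda t: (t[1][2], t[0]))
    node_of: dict[frozenset, int] = {frozenset([name]): index[name] for name in leaves}
    out: list[tuple[int, int, float]] = []
    nxt = len(leaves)
    for _, (ln, rn, h) in merges_sorted:
        a, b = node_of[frozenset(ln)], node_of[frozenset(rn)]
        out.append((a, b, h))
        node_of[frozenset(ln) | frozenset(rn)] = nxt
        nxt += 1
    return ClusterTree(leaves=leaves, merges=tuple(out))


def group_summary(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Arithmetic mean, sample SD (n−1; None for singletons) and n per group."""
    out = []
    for label, vals in groups.items():
        v = np.asarray(list(vals), dtype=float)
        if v.size == 0:
            raise InsufficientDataError(f"group {label!r} is empty")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else None
        out.append(GroupSummary(label=label, mean=float(v.mean()), sd=sd, n=int(v.size)))
    return out


def standardize_profile(profile: GLGProfile, analyte: str = "d18O_sc") -> GLGProfile:
    """Express a per-GLG series relative to its first layer (first value → 0).

    Only the requested analyte is shifted; the other analyte column is
    carried through unchanged.
    """
    col = {"d18O_sc": 1, "d13C_sc": 2}[analyte]
    first = profile.values[0][col]
    if first is None:
        raise InsufficientDataError(f"{profile.specimen_id}: first GLG {analyte} is missing")
    new = []
    for row in profile.values:
        row = list(row)
        if row[col] is not None:
            row[col] = row[col] - first
        new.append(tuple(row))
    return GLGProfile(profile.specimen_id, tuple(new))


def within_tooth_index(profile: GLGProfile, analyte: str = "d18O_sc") -> tuple[float, float]:
    """(sample SD, max − min) of a tooth's per-GLG series — the within-tooth
    variation index used to gauge interannual variability in distribution."""
    vals = [v for v in profile.analyte(analyte) if v is not None]
    if len(vals) < 2:
        raise InsufficientDataError(f"{profile.specimen_id}: need >= 2 {analyte} values")
    v = np.asarray(vals, dtype=float)
    return float(np.std(v, ddof=1)), float(np.ptp(v))
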