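"""Community-comparison statistics between spores and plants.

Dissimilarities: Jaccard on presence/absence (jclass) and Yue & Clayton's
theta on relative abundances (thetayc).  Significance machinery: weighted
and unweighted UniFrac with read-relabelling permutation tests,
distance-based AMOVA (molecular analysis of variance on squared
distances) and HOMOVA (a Bartlett-style homogeneity test on within-group
mean squared distances), and the two-sample Kolmogorov-Smirnov test on
allele abundance distributions.  A neighbor-joining helper builds the
tree UniFrac needs when none is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations > 0 and self.p_value < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("p-value below permutation floor")


# ---------------------------------------------------------------------------
# dissimilarities


def jclass(counts_a: Sequence[int], counts_b: Sequence[int]) -> float:
    """Jaccard dissimilarity on observed richness: 1 - S12/(SA + SB - S12)."""
    a = np.asarray(counts_a) > 0
    b = np.asarray(counts_b) > 0
    if a.shape != b.shape:
        raise ValueError("abundance vectors must share one allele indexing")
    if not a.any() and not b.any():
        raise ValueError("both communities are empty")
    shared = int((a & b).sum())
    union = int(a.sum() + b.sum() - shared)
    return 1.0 - shared / union


def thetayc(counts_a: Sequence[int], counts_b: Sequence[int]) -> float:
    """Yue & Clayton dissimilarity between community structures."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("abundance vectors must share one allele indexing")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both communities must be non-empty")
    a = a / a.sum()
    b = b / b.sum()
    num = float(np.sum(a * b))
    den = float(np.sum(a**2) + np.sum(b**2) - np.sum(a * b))
    theta = num / den if den > 0 else 1.0
    return 1.0 - theta


# ---------------------------------------------------------------------------
# UniFrac


def _branch_tip_masses(
    tree: TreeNode, counts: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch (length, descendant mass) for one sample's tip counts."""
    lengths, masses = [], []
    total = float(sum(counts.values()))
    for node in tree.postorder(include_self=False):
        if node.length is None:
            continue
        if node.is_tip():
            m = float(counts.get(node.name, 0.0))
            node._mass = m
        else:
            node._mass = sum(getattr(c, "_mass", 0.0) for c in node.children)
        lengths.append(float(node.length))
        masses.append(node._mass / total if total > 0 else 0.0)
    return np.asarray(lengths), np.asarray(masses)


def unifrac_statistic(
    tree: TreeNode,
    counts_a: Mapping[str, float],
    counts_b: Mapping[str, float],
    weighted: bool = True,
) -> float:
    """UniFrac distance between two samples whose reads sit on tree tips.

    Weighted: sum_b l_b |a_b - b_b| normalised by sum_b l_b (a_b + b_b),
    with a_b the fraction of sample A's reads below branch b.  Unweighted:
    branch length unique to one sample over branch length covered by
    either.
    """
    tips = {t.name for t in tree.tips()}
    for name in set(counts_a) | set(counts_b):
        if name not in tips:
            raise KeyError(f"allele {name!r} has no tip in the tree")
    la, ma = _branch_tip_masses(tree, counts_a)
    lb, mb = _branch_tip_masses(tree, counts_b)
    lengths = la  # identical traversal order
    if weighted:
        den = float(np.sum(lengths * (ma + mb)))
        if den == 0:
            return 0.0
        return float(np.sum(lengths * np.abs(ma - mb)) / den)
    pa, pb = ma > 0, mb > 0
    den = float(np.sum(lengths[pa | pb]))
    if den == 0:
        return 0.0
    return float(np.sum(lengths[pa ^ pb]) / den)


def unifrac(
    tree: TreeNode,
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    weighted: bool = True,
    n_perms: int = 1000,
    seed: int = 0,
) -> TestResult:
    """UniFrac with a read-relabelling permutation test.

    Under the null, each read's sample label is exchangeable: reads are
    pooled per tip and re-split at random keeping both sample sizes fixed.
    """
    observed = unifrac_statistic(tree, counts_a, counts_b, weighted=weighted)
    tips = sorted(set(counts_a) | set(counts_b))
    a = np.array([counts_a.get(t, 0) for t in tips], dtype=int)
    b = np.array([counts_b.get(t, 0) for t in tips], dtype=int)
    pooled = np.repeat(np.arange(len(tips)), a + b)
    n_a = int(a.sum())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perms):
        perm = rng.permutation(pooled)
        ca = np.bincount(perm[:n_a], minlength=len(tips))
        cb = np.bincount(perm[n_a:], minlength=len(tips))
        stat = unifrac_statistic(
            tree,
            {t: int(c) for t, c in zip(tips, ca)},
            {t: int(c) for t, c in zip(tips, cb)},
            weighted=weighted,
        )
        if stat >= observed - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perms + 1)
    return TestResult(statistic=observed, p_value=p, n_permutations=n_perms, seed=seed)


# ---------------------------------------------------------------------------
# AMOVA / HOMOVA


def _check_groups(dm: DistanceMatrix, groups: Sequence[str]) -> np.ndarray:
    labels = np.asarray(groups)
    if labels.size != dm.shape[0]:
        raise ValueError("one group label per distance-matrix row required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("at least two groups required")
    if np.any(counts < 2):
        raise ValueError("every group needs at least two members")
    return labels


def _amova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = d2.shape[0]
    uniq = np.unique(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = uniq.size - 1
    df_within = n - uniq.size
    ms_within = ss_within / df_within
    if ms_within == 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / df_among) / ms_within


def amova(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perms: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Distance-based analysis of molecular variance.

    Sums of squares come from squared pairwise distances; significance by
    permuting group labels.
    """
    labels = _check_groups(dm, groups)
    d2 = np.asarray(dm.data) ** 2
    observed = _amova_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perms):
        if _amova_f(d2, rng.permutation(labels)) >= observed - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perms + 1)
    return TestResult(statistic=float(observed), p_value=p,
                      n_permutations=n_perms, seed=seed)


def _homova_b(d2: np.ndarray, labels: np.ndarray) -> float:
    uniq = np.unique(labels)
    n = d2.shape[0]
    ss_w, dfs, variances = 0.0, [], []
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss = sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        var = ss / (idx.size - 1)
        ss_w += ss
        dfs.append(idx.size - 1)
        variances.append(var)
    df_total = n - uniq.size
    pooled = ss_w / df_total
    if pooled <= 0 or any(v <= 0 for v in variances):
        return 0.0
    return float(df_total * np.log(pooled)
                 - sum(df * np.log(v) for df, v in zip(dfs, variances)))


def homova(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perms: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Distance-based Bartlett test for homogeneity of molecular variance."""
    labels = _check_groups(dm, groups)
    d2 = np.asarray(dm.data) ** 2
    observed = _homova_b(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perms):
        if _homova_b(d2, rng.permutation(labels)) >= observed - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perms + 1)
    return TestResult(statistic=float(observed), p_value=p,
                      n_permutations=n_perms, seed=seed)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


def ks_two_sample(abund_a: Sequence[float], abund_b: Sequence[float]) -> TestResult:
    """Two-sample KS test on allele abundance distributions."""
    a = np.asarray(abund_a, dtype=float)
    b = np.asarray(abund_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("abundance vectors must be non-empty")
    res = stats.ks_2samp(a, b)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n_permutations=0)


# ---------------------------------------------------------------------------
# neighbor joining


def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree with negative branch lengths clamped to zero,
    the clipped length being moved onto the sibling edge so that tip-to-tip
    path lengths are preserved where possible."""
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = nj(dm)
    for node in tree.postorder(include_self=False):
        if node.length is not None and node.length < 0:
            deficit = -node.length
            node.length = 0.0
            siblings = [s for s in node.parent.children if s is not node]
            if siblings and siblings[0].length is not None:
                siblings[0].length += deficit
    return tree


def difference_distance_matrix(sequences: Sequence[str],
                               ids: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """Pairwise-difference distances between aligned sequences."""
    from .denoise import pairwise_diffs

    n = len(sequences)
    ids = list(ids) if ids is not None else [f"a{i}" for i in range(n)]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_diffs(sequences[i], sequences[j])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance level under Bonferroni correction."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests
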