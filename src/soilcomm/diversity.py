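"""Alpha/beta diversity, permutation tests and derived plant leaf traits.

Alpha diversity: observed richness, Shannon entropy (natural log) and Faith's
phylogenetic diversity in the rooted convention (the branch path from the
root to every present tip is counted, so a single-taxon community has
positive PD). Beta diversity uses Bray-Curtis dissimilarity. PERMANOVA and
the Mantel test are implemented with explicit seed control and the +1
permutation correction, p = (1 + #{perm stat >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from ._util import as_count_frame, rng_for

__all__ = [
    "observed_richness",
    "shannon_index",
    "faith_pd",
    "alpha_diversity",
    "bray_curtis",
    "permanova_pseudo_f",
    "permanova",
    "mantel",
    "derive_leaf_traits",
]


def observed_richness(counts) -> int:
    """Number of taxa with a positive count."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return int((counts > 0).sum())


def shannon_index(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over taxa with p_i > 0 (natural log)."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def faith_pd(counts, taxa, tree: TreeNode) -> float:
    """Faith's PD: total branch length of the minimal rooted subtree
    spanning the present taxa (the root path is included).
    """
    counts = np.asarray(counts, dtype=float)
    present = {t for t, c in zip(taxa, counts) if c > 0}
    if not present:
        return 0.0
    tip_names = {t.name for t in tree.tips()}
    missing = present - tip_names
    if missing:
        raise KeyError(f"taxa not found in tree: {sorted(missing)}")

    keep = {}  # id(node) -> subtree contains a present tip
    total = 0.0
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            keep[id(node)] = node.name in present
        else:
            keep[id(node)] = any(keep[id(c)] for c in node.children)
        if keep[id(node)] and node.parent is not None:
            total += node.length
    return total


def alpha_diversity(table, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample observed richness, Shannon index and (with a tree) Faith's PD."""
    df = as_count_frame(table)
    out = pd.DataFrame(index=df.index)
    out["observed"] = [observed_richness(row) for row in df.to_numpy()]
    out["shannon"] = [shannon_index(row) for row in df.to_numpy()]
    if tree is not None:
        out["faith_pd"] = [
            faith_pd(row, df.columns, tree) for row in df.to_numpy()
        ]
    return out


def bray_curtis(table) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC(a, b) = sum|a-b| / sum(a+b)."""
    df = as_count_frame(table)
    if len(df) < 2:
        raise ValueError("need at least 2 samples")
    zero_rows = df.index[df.sum(axis=1) == 0]
    if len(zero_rows) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero samples: {list(zero_rows)}"
        )
    condensed = pdist(df.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(df.index))


def _grouping_array(dist: DistanceMatrix, grouping) -> np.ndarray:
    grouping = pd.Series(grouping)
    if not set(dist.ids) <= set(grouping.index):
        # positional grouping (plain array aligned with the matrix)
        if len(grouping) != len(dist.ids):
            raise ValueError("grouping does not align with distance matrix")
        return grouping.to_numpy()
    return grouping.reindex(list(dist.ids)).to_numpy()


def permanova_pseudo_f(sq_dist: np.ndarray, codes: np.ndarray) -> float:
    """PERMANOVA pseudo-F from squared distances and integer group codes.

    SS_total = sum of squared distances / n; SS_within pools each group's
    internal squared distances / group size; F = (SS_among / (a - 1)) /
    (SS_within / (n - a)).
    """
    n = len(codes)
    groups = np.unique(codes)
    ss_total = sq_dist.sum() / (2 * n)
    ss_within = 0.0
    for g in groups:
        mask = codes == g
        ss_within += sq_dist[np.ix_(mask, mask)].sum() / (2 * mask.sum())
    ss_among = ss_total - ss_within
    a = len(groups)
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0
):
    """One-factor PERMANOVA on a distance matrix.

    Returns (pseudo_F, p). The p-value is permutational with the +1
    correction, so its floor is 1 / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = _grouping_array(dist, grouping)
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    sq = np.asarray(dist.data, dtype=float) ** 2
    _, codes = np.unique(labels, return_inverse=True)
    observed = permanova_pseudo_f(sq, codes)

    rng = rng_for(seed, "permanova")
    hits = 0
    for _ in range(n_perm):
        hits += permanova_pseudo_f(sq, rng.permutation(codes)) >= observed
    return float(observed), (1 + hits) / (1 + n_perm)


def mantel(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int = 0
):
    """Mantel correlation between two distance matrices on the same samples.

    r is the Pearson correlation of the upper triangles; significance is
    assessed two-sidedly by jointly permuting rows and columns of ``d2``.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share identical labels in order")
    n = len(d1.ids)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    iu = np.triu_indices(n, k=1)
    x = np.asarray(d1.data, dtype=float)[iu]
    m2 = np.asarray(d2.data, dtype=float)
    observed = stats.pearsonr(x, m2[iu]).statistic

    rng = rng_for(seed, "mantel")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = stats.pearsonr(x, m2[np.ix_(perm, perm)][iu]).statistic
        hits += abs(r) >= abs(observed) - 1e-12
    return float(observed), (1 + hits) / (1 + n_perm)


def derive_leaf_traits(leaf_area, leaf_dry_weight, leaf_fresh_weight):
    """Specific leaf area and leaf dry-matter content from raw leaf measures.

    SLA = leaf area per unit dry mass; LDMC = dry weight per unit fresh
    weight. All inputs must be strictly positive; LDMC <= 1 whenever dry
    weight does not exceed fresh weight.
    """
    la = np.asarray(leaf_area, dtype=float)
    ldw = np.asarray(leaf_dry_weight, dtype=float)
    lfw = np.asarray(leaf_fresh_weight, dtype=float)
    if (la <= 0).any() or (ldw <= 0).any() or (lfw <= 0).any():
        raise ValueError("leaf measurements must be strictly positive")
    sla = la / ldw
    ldmc = ldw / lfw
    if sla.ndim == 0:
        return float(sla), float(ldmc)
    return sla, ldmc
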