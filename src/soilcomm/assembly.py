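"""Null-model analysis of community assembly.

The phylogenetic turnover between each sample pair (abundance-weighted
beta-MNTD) is standardized against a null distribution obtained by shuffling
taxa across the phylogeny's tips, giving the beta nearest taxon index
(betaNTI). Pairs with |betaNTI| > 2 are attributed to deterministic selection
(variable selection when betaNTI > +2, homogeneous selection when < -2).
The remaining pairs are split by the abundance-based Raup-Crick metric on
Bray-Curtis (RCbray): RC > +0.95 indicates dispersal limitation, RC < -0.95
homogenizing dispersal, and everything else drift/undominated. The share of
pairs in the two selection classes is the determinism fraction; the other
three classes make up the stochasticity fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import as_count_frame, rng_for

__all__ = [
    "VARIABLE_SELECTION",
    "HOMOGENEOUS_SELECTION",
    "DISPERSAL_LIMITATION",
    "HOMOGENIZING_DISPERSAL",
    "DRIFT",
    "patristic_distances",
    "mntd_mpd",
    "beta_mntd",
    "beta_mntd_matrix",
    "beta_nti",
    "rc_score",
    "raup_crick_bray",
    "classify_processes",
    "process_fractions",
    "AssemblyResult",
    "assembly_analysis",
]

VARIABLE_SELECTION = "variable selection"
HOMOGENEOUS_SELECTION = "homogeneous selection"
DISPERSAL_LIMITATION = "dispersal limitation"
HOMOGENIZING_DISPERSAL = "homogenizing dispersal"
DRIFT = "drift/undominated"

PROCESSES = (
    VARIABLE_SELECTION,
    HOMOGENEOUS_SELECTION,
    DISPERSAL_LIMITATION,
    HOMOGENIZING_DISPERSAL,
    DRIFT,
)


def patristic_distances(tree: TreeNode):
    """Tip-to-tip patristic distance matrix. Returns (matrix, tip names)."""
    dm = tree.tip_tip_distances()
    return np.asarray(dm.data, dtype=float), list(dm.ids)


def _weights(counts: np.ndarray, weighted: bool) -> np.ndarray:
    present = counts > 0
    w = np.where(present, counts if weighted else 1.0, 0.0).astype(float)
    return w / w.sum()


def mntd_mpd(counts, dist: np.ndarray, weighted: bool = True):
    """Within-sample mean nearest taxon distance and mean pairwise distance.

    Abundance-weighted by default: MNTD = sum_i f_i min_{j != i} d_ij and
    MPD = sum_{i != j} f_i f_j d_ij / sum_{i != j} f_i f_j, with f the
    relative abundances among present taxa. Returns (nan, nan) when fewer
    than two taxa are present.
    """
    counts = np.asarray(counts, dtype=float)
    idx = np.flatnonzero(counts > 0)
    if len(idx) < 2:
        return float("nan"), float("nan")
    f = _weights(counts, weighted)[idx]
    sub = dist[np.ix_(idx, idx)].astype(float)
    np.fill_diagonal(sub, np.inf)
    mntd = float((f * sub.min(axis=1)).sum())
    pair_w = np.outer(f, f)
    np.fill_diagonal(pair_w, 0.0)
    finite = np.where(np.isfinite(sub), sub, 0.0)
    mpd = float((pair_w * finite).sum() / pair_w.sum())
    return mntd, mpd


def _beta_mntd_indexed(fa, ia, fb, ib, dist):
    sub = dist[np.ix_(ia, ib)]
    return 0.5 * ((fa * sub.min(axis=1)).sum() + (fb * sub.min(axis=0)).sum())


def beta_mntd(counts_a, counts_b, dist: np.ndarray, weighted: bool = True) -> float:
    """Between-sample mean nearest taxon distance (beta-MNTD).

    Average over both directions of each present taxon's weight times its
    patristic distance to the closest taxon present in the other sample; a
    taxon shared by both samples contributes zero. Symmetric by construction.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("beta-MNTD undefined for an empty sample")
    ia, ib = np.flatnonzero(a > 0), np.flatnonzero(b > 0)
    fa = _weights(a, weighted)[ia]
    fb = _weights(b, weighted)[ib]
    return float(_beta_mntd_indexed(fa, ia, fb, ib, dist))


def _aligned_distance(table: pd.DataFrame, tree: TreeNode):
    dist, tips = patristic_distances(tree)
    missing = set(table.columns) - set(tips)
    if missing:
        raise KeyError(f"taxa not found in tree: {sorted(missing)}")
    order = [tips.index(t) for t in table.columns]
    return dist[np.ix_(order, order)]


def beta_mntd_matrix(table, tree: TreeNode, weighted: bool = True) -> pd.DataFrame:
    """Observed beta-MNTD for every sample pair."""
    df = as_count_frame(table)
    dist = _aligned_distance(df, tree)
    n = len(df)
    counts = df.to_numpy(dtype=float)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = beta_mntd(counts[i], counts[j], dist, weighted)
    return pd.DataFrame(out, index=df.index, columns=df.index)


def beta_nti(
    table,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
    return_observed: bool = False,
):
    """Beta nearest taxon index for every sample pair.

    For each pair the null distribution of beta-MNTD is generated by
    permuting taxon labels across the phylogeny's tips (each sample keeps
    its taxa and abundances; only the tip positions move) ``n_null`` times;
    betaNTI = (observed - null mean) / null sd. Pairs whose null is
    degenerate (sd = 0, e.g. on an equidistant star tree) are NaN and
    flagged in the result's ``attrs["degenerate"]`` matrix.

    Null draws use per-pair substreams derived from ``seed`` and the pair
    index, so results are independent of pair processing order.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    df = as_count_frame(table)
    dist = _aligned_distance(df, tree)
    n, d = df.shape
    counts = df.to_numpy(dtype=float)
    idx = [np.flatnonzero(c > 0) for c in counts]
    wts = [_weights(c, weighted)[i] for c, i in zip(counts, idx)]

    bnti = np.full((n, n), np.nan)
    observed = np.zeros((n, n))
    degenerate = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(bnti, 0.0)
    pair = 0
    for i in range(n):
        for j in range(i + 1, n):
            obs = _beta_mntd_indexed(wts[i], idx[i], wts[j], idx[j], dist)
            observed[i, j] = observed[j, i] = obs
            rng = rng_for(seed, "beta_nti", pair)
            perms = np.vstack([rng.permutation(d) for _ in range(n_null)])
            sub = dist[perms[:, idx[i], None], perms[:, None, idx[j]]]
            nulls = 0.5 * (
                (wts[i] * sub.min(axis=2)).sum(axis=1)
                + (wts[j] * sub.min(axis=1)).sum(axis=1)
            )
            sd = nulls.std(ddof=0)
            if sd < 1e-12:
                degenerate[i, j] = degenerate[j, i] = True
            else:
                z = (obs - nulls.mean()) / sd
                bnti[i, j] = bnti[j, i] = z
            pair += 1

    result = pd.DataFrame(bnti, index=df.index, columns=df.index)
    result.attrs["degenerate"] = pd.DataFrame(
        degenerate, index=df.index, columns=df.index
    )
    if return_observed:
        return result, pd.DataFrame(observed, index=df.index, columns=df.index)
    return result


def _bray_curtis_pair(a: np.ndarray, b: np.ndarray) -> float:
    return np.abs(a - b).sum() / (a + b).sum()


def rc_score(observed_bc: float, null_bc) -> float:
    """Raup-Crick score of an observed dissimilarity against its null draws.

    RC = 2 (B + E/2) / n - 1 with B the null values below the observed one
    and E the ties; -1 when the observed dissimilarity undercuts every null,
    +1 when it exceeds every null, 0 when every null ties it exactly.
    """
    null_bc = np.asarray(null_bc, dtype=float)
    ties = np.isclose(null_bc, observed_bc, rtol=0, atol=1e-10)
    below = (null_bc < observed_bc) & ~ties
    return float(2.0 * (below.sum() + 0.5 * ties.sum()) / len(null_bc) - 1.0)


def _null_sample(rng, richness, total, occ_p, abund_p, d):
    chosen = rng.choice(d, size=richness, replace=False, p=occ_p)
    null = np.zeros(d)
    null[chosen] = 1.0
    remaining = total - richness
    if remaining > 0:
        p = abund_p[chosen]
        null[chosen] += rng.multinomial(remaining, p / p.sum())
    return null


def raup_crick_bray(table, n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """Abundance-based Raup-Crick metric on Bray-Curtis dissimilarity.

    For each sample pair, null communities preserve each sample's observed
    richness and total abundance: taxa are drawn from the regional pool with
    probability proportional to occurrence frequency, then individuals are
    distributed proportionally to mean relative abundance. With B = number
    of null Bray-Curtis values below the observed one and E the ties,
    RC = 2 (B + E/2) / n_null - 1, bounded in [-1, 1].
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    df = as_count_frame(table)
    if len(df) < 2:
        raise ValueError("need at least 2 samples")
    counts = df.to_numpy(dtype=float)
    d = counts.shape[1]
    occ = (counts > 0).sum(axis=0).astype(float)
    if (occ > 0).sum() < 2:
        raise ValueError("regional pool is degenerate (fewer than 2 taxa occur)")
    occ_p = occ / occ.sum()
    rel = counts / counts.sum(axis=1, keepdims=True)
    abund = rel.mean(axis=0)
    abund_p = abund / abund.sum()

    n = len(df)
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1).astype(int)
    rc = np.zeros((n, n))
    pair = 0
    for i in range(n):
        for j in range(i + 1, n):
            obs = _bray_curtis_pair(counts[i], counts[j])
            rng = rng_for(seed, "raup_crick", pair)
            nulls = np.empty(n_null)
            for k in range(n_null):
                na = _null_sample(rng, richness[i], totals[i], occ_p, abund_p, d)
                nb = _null_sample(rng, richness[j], totals[j], occ_p, abund_p, d)
                nulls[k] = _bray_curtis_pair(na, nb)
            rc[i, j] = rc[j, i] = rc_score(obs, nulls)
            pair += 1
    return pd.DataFrame(rc, index=df.index, columns=df.index)


def classify_processes(
    bnti: pd.DataFrame,
    rc: pd.DataFrame,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> pd.DataFrame:
    """Assign each sample pair to one of the five assembly processes.

    betaNTI > +threshold: variable selection; < -threshold: homogeneous
    selection; otherwise RC > +rc_threshold: dispersal limitation;
    RC < -rc_threshold: homogenizing dispersal; else drift/undominated.
    Pairs with NaN betaNTI are labelled ``undetermined`` and excluded from
    process fractions.
    """
    if list(bnti.index) != list(rc.index) or list(bnti.columns) != list(rc.columns):
        raise ValueError("betaNTI and RC matrices are not aligned")
    rows = []
    ids = list(bnti.index)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            b = bnti.iloc[i, j]
            r = rc.iloc[i, j]
            if np.isnan(b):
                label = "undetermined"
            elif b > bnti_threshold:
                label = VARIABLE_SELECTION
            elif b < -bnti_threshold:
                label = HOMOGENEOUS_SELECTION
            elif r > rc_threshold:
                label = DISPERSAL_LIMITATION
            elif r < -rc_threshold:
                label = HOMOGENIZING_DISPERSAL
            else:
                label = DRIFT
            rows.append((ids[i], ids[j], b, r, label))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "bnti", "rc", "process"]
    )


def process_fractions(labels) -> pd.Series:
    """Relative contribution of the five processes plus the
    determinism/stochasticity split, over classified pairs only.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels["process"]
    labels = pd.Series(labels)
    classified = labels[labels.isin(PROCESSES)]
    if len(classified) == 0:
        raise ValueError("no classified pairs")
    frac = classified.value_counts(normalize=True).reindex(PROCESSES, fill_value=0.0)
    frac["determinism"] = frac[VARIABLE_SELECTION] + frac[HOMOGENEOUS_SELECTION]
    frac["stochasticity"] = 1.0 - frac["determinism"]
    frac["n_classified"] = float(len(classified))
    frac["n_undetermined"] = float((labels == "undetermined").sum())
    return frac


@dataclass
class AssemblyResult:
    """Bundle of the pairwise null-model outputs for one community table."""

    beta_mntd: pd.DataFrame
    bnti: pd.DataFrame
    rc: pd.DataFrame
    pairs: pd.DataFrame
    fractions: pd.Series


def assembly_analysis(
    table,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> AssemblyResult:
    """Run the full betaNTI + RCbray five-process partitioning."""
    bnti, observed = beta_nti(
        table, tree, n_null=n_null, seed=seed, weighted=weighted, return_observed=True
    )
    rc = raup_crick_bray(table, n_null=n_null, seed=seed)
    pairs = classify_processes(bnti, rc, bnti_threshold, rc_threshold)
    fractions = process_fractions(pairs)
    return AssemblyResult(observed, bnti, rc, pairs, fractions)
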