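"""Cross-kingdom co-occurrence networks.

Core ASVs (prevalence > 60% of samples and mean relative abundance > 0.1%,
both strict) are correlated with SparCC — the log-ratio variance approach
that sidesteps the compositional artefacts of plain correlation on relative
abundances — and edges are kept where |r| > 0.6 and the bootstrap pseudo
p < 0.01. Downstream: topology metrics, greedy modularity modules, node
roles in the within-module degree z-score / participation coefficient plane
(hubs, connectors, peripherals at Z = 2.5, C = 0.62), and robustness as the
decay of natural connectivity under random node removal.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._util import as_count_frame, rng_for

__all__ = [
    "classify_role",
    "filter_core_asvs",
    "combine_kingdoms",
    "sparcc_correlations",
    "sparcc_pvalues",
    "build_network",
    "topology_metrics",
    "detect_modules",
    "node_roles",
    "natural_connectivity",
    "robustness_curve",
]

NODE_ROLES = ("network hub", "module hub", "connector", "peripheral")


def classify_role(z: float, c: float, z_threshold: float = 2.5,
                  c_threshold: float = 0.62) -> str:
    """Topological role from the within-module degree z-score (Z) and
    participation coefficient (C): network hub (Z > 2.5, C > 0.62), module
    hub (Z > 2.5, C < 0.62), connector (Z < 2.5, C > 0.62), peripheral
    (Z < 2.5, C < 0.62).
    """
    if z > z_threshold:
        return "network hub" if c > c_threshold else "module hub"
    return "connector" if c > c_threshold else "peripheral"


def filter_core_asvs(
    table, prevalence: float = 0.60, mean_rel_abund: float = 0.001
) -> pd.DataFrame:
    """Keep core taxa: prevalence and mean relative abundance strictly above
    the thresholds (defaults: shared by >60% of samples, mean >0.1%).
    """
    if not (0 < prevalence < 1) or not (0 < mean_rel_abund < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    df = as_count_frame(table)
    totals = df.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero samples cannot be converted to relative abundance")
    rel = df.div(totals, axis=0)
    prev = (df > 0).mean(axis=0)
    keep = (prev > prevalence) & (rel.mean(axis=0) > mean_rel_abund)
    if not keep.any():
        warnings.warn("no taxa pass the core-ASV filter", UserWarning, stacklevel=2)
    return df.loc[:, keep]


def combine_kingdoms(
    tables: dict, prevalence: float = 0.60, mean_rel_abund: float = 0.001
):
    """Core-filter per kingdom, convert to relative abundance, and join on
    shared samples into one cross-kingdom table.

    Taxon ids are prefixed with their kingdom to stay unique. Returns
    (table, kingdom_map) where kingdom_map maps each kept taxon to its
    kingdom tag.
    """
    filtered = {}
    shared = None
    for kingdom, table in tables.items():
        core = filter_core_asvs(table, prevalence, mean_rel_abund)
        rel = core.div(as_count_frame(table).sum(axis=1), axis=0)
        rel.columns = [f"{kingdom}:{t}" for t in core.columns]
        filtered[kingdom] = rel
        shared = rel.index if shared is None else shared.intersection(rel.index)
    if shared is None or len(shared) < 4:
        raise ValueError("fewer than 4 samples shared across kingdoms")
    combined = pd.concat([f.loc[shared] for f in filtered.values()], axis=1)
    kingdom_map = {
        taxon: kingdom for kingdom, f in filtered.items() for taxon in f.columns
    }
    return combined, kingdom_map


def _log_ratio_variance(log_f: np.ndarray) -> np.ndarray:
    """T_ij = var(log f_i - log f_j) from per-sample log fractions."""
    cov = np.cov(log_f.T, ddof=1)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(
    t_mat: np.ndarray, exclusion_rounds: int, exclusion_threshold: float
):
    """Solve the SparCC basis-variance system with iterative pair exclusion.

    The approximation sum_j T_ij ~ (d - 2) t_i + sum_j t_j gives the linear
    system M t = rowsum(T) with M = 1 1' + (d - 2) I. The most strongly
    correlated pair above the exclusion threshold is removed from the system
    (its T term dropped, M decremented) for up to ``exclusion_rounds``
    rounds, guarding the basis estimate against a few dominant pairs.
    """
    d = t_mat.shape[0]
    include = ~np.eye(d, dtype=bool)

    def solve():
        # row i: sum_{j in inc(i)} T_ij = k_i t_i + sum_{j in inc(i)} t_j
        m_mat = np.where(include, 1.0, 0.0)
        np.fill_diagonal(m_mat, include.sum(axis=1))
        row = np.where(include, t_mat, 0.0).sum(axis=1)
        t_basis = np.linalg.solve(m_mat, row)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = 2.0 * np.sqrt(np.outer(t_basis, t_basis))
            corr = (t_basis[:, None] + t_basis[None, :] - t_mat) / denom
        return t_basis, corr

    t_basis, corr = solve()
    for _ in range(exclusion_rounds):
        trial = np.where(include, np.abs(corr), 0.0)
        np.fill_diagonal(trial, 0.0)
        i, j = np.unravel_index(np.nanargmax(trial), trial.shape)
        if not np.isfinite(trial[i, j]) or trial[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
        t_basis, corr = solve()

    bad = ~np.isfinite(t_basis) | (t_basis <= 0)
    corr = np.clip(corr, -1.0, 1.0)
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr, np.flatnonzero(bad)


def sparcc_correlations(
    table,
    n_inner_iter: int = 20,
    exclusion_rounds: int = 10,
    exclusion_threshold: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """SparCC correlation matrix for a samples x taxa count table.

    Each of ``n_inner_iter`` iterations draws per-sample fractions from
    Dirichlet(counts + 1), forms the log-ratio variance matrix T, solves the
    basis-variance system (with strong-pair exclusion) and converts basis
    variances to correlations r_ij = (t_i + t_j - T_ij) / (2 sqrt(t_i t_j));
    the final matrix is the average over iterations, symmetric with unit
    diagonal, clipped to [-1, 1]. Taxa whose basis variance is non-positive
    or non-finite are reported in ``attrs["excluded_taxa"]`` with NaN rows.
    """
    df = as_count_frame(table)
    n, d = df.shape
    if d < 4:
        raise ValueError("SparCC needs at least 4 taxa")
    if n_inner_iter < 1:
        raise ValueError("n_inner_iter must be >= 1")
    counts = df.to_numpy(dtype=float)
    rng = rng_for(seed, "sparcc")
    stack = np.empty((n_inner_iter, d, d))
    excluded = set()
    for it in range(n_inner_iter):
        fracs = np.vstack([rng.dirichlet(row + 1.0) for row in counts])
        t_mat = _log_ratio_variance(np.log(fracs))
        corr, bad = _basis_correlations(t_mat, exclusion_rounds, exclusion_threshold)
        stack[it] = corr
        excluded.update(df.columns[b] for b in bad)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_corr = np.nanmean(stack, axis=0)
    mean_corr = np.clip((mean_corr + mean_corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(mean_corr, 1.0)
    out = pd.DataFrame(mean_corr, index=df.columns, columns=df.columns)
    out.attrs["excluded_taxa"] = sorted(excluded)
    return out


def sparcc_pvalues(
    table,
    observed_r: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
    **sparcc_kwargs,
) -> pd.DataFrame:
    """Two-sided bootstrap pseudo p-values for SparCC correlations.

    Each bootstrap permutes every taxon's counts across samples
    independently (destroying all true co-variation while keeping marginal
    distributions), recomputes SparCC, and counts |r_boot| >= |r_obs|;
    p = (1 + hits) / (1 + n_boot), so the floor is 1 / (n_boot + 1).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = as_count_frame(table)
    obs = np.abs(observed_r.loc[df.columns, df.columns].to_numpy(dtype=float))
    counts = df.to_numpy(dtype=float)
    rng = rng_for(seed, "sparcc_boot")
    hits = np.zeros_like(obs)
    for b in range(n_boot):
        shuffled = np.column_stack(
            [rng.permutation(counts[:, k]) for k in range(counts.shape[1])]
        )
        boot_r = sparcc_correlations(
            pd.DataFrame(shuffled, index=df.index, columns=df.columns),
            seed=int(rng.integers(2**31 - 1)),
            **sparcc_kwargs,
        ).to_numpy()
        hits += np.abs(boot_r) >= obs - 1e-12
    p = (1.0 + hits) / (1.0 + n_boot)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=df.columns, columns=df.columns)


def build_network(
    corr: pd.DataFrame,
    p: pd.DataFrame,
    r_threshold: float = 0.6,
    p_threshold: float = 0.01,
    kingdom_map: dict | None = None,
) -> nx.Graph:
    """Threshold correlations into an undirected signed co-occurrence graph.

    An edge requires |r| strictly greater than ``r_threshold`` AND p strictly
    below ``p_threshold``. Isolated nodes are dropped. Edge attributes:
    ``weight`` (signed r), ``abs_weight``, ``sign``, ``p``. The graph-level
    attribute ``negative_edge_ratio`` is the share of negative edges.
    """
    if list(corr.index) != list(p.index) or list(corr.columns) != list(p.columns):
        raise ValueError("correlation and p matrices are not aligned")
    graph = nx.Graph()
    taxa = list(corr.index)
    n_neg = 0
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            r = corr.iloc[i, j]
            pv = p.iloc[i, j]
            if np.isfinite(r) and abs(r) > r_threshold and pv < p_threshold:
                sign = "positive" if r > 0 else "negative"
                n_neg += sign == "negative"
                graph.add_edge(
                    taxa[i], taxa[j],
                    weight=float(r), abs_weight=float(abs(r)),
                    sign=sign, p=float(pv),
                )
    if kingdom_map is not None:
        nx.set_node_attributes(
            graph, {n: kingdom_map.get(n, "unknown") for n in graph}, "kingdom"
        )
    graph.graph["negative_edge_ratio"] = (
        n_neg / graph.number_of_edges() if graph.number_of_edges() else float("nan")
    )
    if graph.number_of_edges() == 0:
        warnings.warn("no edges survived thresholding", UserWarning, stacklevel=2)
    return graph


def detect_modules(net: nx.Graph, seed: int = 0):
    """Greedy modularity maximization on |r| edge weights.

    Returns (modules, Q) where modules maps node -> module id. The greedy
    agglomeration is deterministic; ``seed`` is accepted for interface
    uniformity.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    communities = nx.community.greedy_modularity_communities(net, weight="abs_weight")
    modules = {
        node: mid for mid, comm in enumerate(communities) for node in sorted(comm)
    }
    q = nx.community.modularity(net, communities, weight="abs_weight")
    return modules, float(q)


def topology_metrics(net: nx.Graph, modules: dict | None = None) -> dict:
    """Standard topology summary of a co-occurrence network.

    Vertex/edge counts, mean degree, density 2E/(N(N-1)), negative-edge
    ratio, per-node degree/betweenness/closeness centralities, and the
    modularity Q of the detected (or supplied) partition.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    e = net.number_of_edges()
    if modules is None:
        modules, q = detect_modules(net)
    else:
        comms = {}
        for node, mid in modules.items():
            comms.setdefault(mid, set()).add(node)
        q = nx.community.modularity(net, comms.values(), weight="abs_weight")
    centralities = pd.DataFrame(
        {
            "degree": dict(net.degree()),
            "betweenness": nx.betweenness_centrality(net),
            "closeness": nx.closeness_centrality(net),
        }
    )
    return {
        "n_nodes": n,
        "n_edges": e,
        "mean_degree": 2.0 * e / n,
        "density": 2.0 * e / (n * (n - 1)) if n > 1 else float("nan"),
        "negative_edge_ratio": net.graph.get("negative_edge_ratio", float("nan")),
        "modularity": float(q),
        "node_centralities": centralities,
    }


def node_roles(net: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z-score (Z) and participation coefficient (C)
    with the four-role classification.

    Z standardizes a node's within-module degree against its module's mean
    and sd; C = 1 - sum_m (k_im / k_i)^2 over modules m. Roles: network hub
    (Z > 2.5, C > 0.62), module hub (Z > 2.5, C <= 0.62), connector
    (Z <= 2.5, C > 0.62), peripheral otherwise. Nodes in single-node
    modules or modules with zero degree spread get Z = 0 with a flag.
    """
    if not modules:
        raise ValueError("module assignment is empty")
    nodes = list(net.nodes)
    k_in_module = {}
    for node in nodes:
        per_mod = {}
        for nbr in net.neighbors(node):
            per_mod[modules[nbr]] = per_mod.get(modules[nbr], 0) + 1
        k_in_module[node] = per_mod

    by_module = {}
    for node in nodes:
        by_module.setdefault(modules[node], []).append(node)

    rows = []
    for node in nodes:
        own = modules[node]
        k_own = np.array(
            [k_in_module[m].get(own, 0) for m in by_module[own]], dtype=float
        )
        mine = k_in_module[node].get(own, 0)
        sd = k_own.std(ddof=0)
        flagged = len(k_own) < 2 or sd == 0
        z = 0.0 if flagged else (mine - k_own.mean()) / sd
        k_total = net.degree(node)
        c = (
            0.0
            if k_total == 0
            else 1.0 - sum((k / k_total) ** 2 for k in k_in_module[node].values())
        )
        rows.append((node, own, k_total, z, c, classify_role(z, c), flagged))
    return pd.DataFrame(
        rows, columns=["node", "module", "degree", "Z", "C", "role", "z_degenerate"]
    ).set_index("node")


def natural_connectivity(net: nx.Graph) -> float:
    """Natural connectivity: ln of the mean of exp(eigenvalues) of the
    unweighted adjacency matrix — a spectral index of path redundancy.
    Zero for an edgeless graph; grows with redundant connectivity.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity needs at least one node")
    adjacency = nx.to_numpy_array(net, weight=None)
    eigenvalues = np.linalg.eigvalsh(adjacency)
    return float(logsumexp(eigenvalues) - np.log(n))


def robustness_curve(
    net: nx.Graph,
    fractions=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    n_reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Natural-connectivity decay under uniform random node removal.

    For each removal fraction, ``n_reps`` random node subsets of that size
    are deleted (without replacement) and natural connectivity of the
    remainder is averaged. Fraction 0 returns the intact value exactly.
    Result has columns fraction / mean_nc / sd_nc and ``attrs`` recording
    n_reps and seed.
    """
    fractions = list(fractions)
    if any(f < 0 or f >= 1 for f in fractions):
        raise ValueError("removal fractions must lie in [0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    nodes = list(net.nodes)
    n = len(nodes)
    rng = rng_for(seed, "robustness")
    rows = []
    for frac in fractions:
        k = int(round(frac * n))
        if k == 0:
            value = natural_connectivity(net)
            rows.append((frac, value, 0.0))
            continue
        values = []
        for _ in range(n_reps):
            drop = rng.choice(n, size=k, replace=False)
            sub = net.copy()
            sub.remove_nodes_from([nodes[i] for i in drop])
            values.append(natural_connectivity(sub) if sub.number_of_nodes() else 0.0)
        rows.append((frac, float(np.mean(values)), float(np.std(values, ddof=0))))
    out = pd.DataFrame(rows, columns=["fraction", "mean_nc", "sd_nc"])
    out.attrs["n_reps"] = n_reps
    out.attrs["seed"] = seed
    return out
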