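"""Synthetic community generator for the factorial floodplain-style design.

Produces the downstream products a soil-microbiome survey would yield —
balanced factorial sample designs, rooted phylogenies, per-kingdom ASV count
tables, ecosystem-function matrices and count tables with planted correlation
structure — with the statistical signals (environmental filtering, dispersal
limitation, seasonal shifts, compositional correlations) that the assembly,
multifunctionality and network analyses are designed to detect.

Every generator is a pure function of its arguments and a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import rng_for

__all__ = [
    "DEFAULT_TREATMENTS",
    "DEFAULT_VEGETATIONS",
    "DEFAULT_SEASONS",
    "DEFAULT_FUNCTION_NAMES",
    "SimulationConfig",
    "generate_design",
    "generate_phylogeny",
    "generate_community_counts",
    "generate_function_matrix",
    "generate_correlated_counts",
]

DEFAULT_TREATMENTS = ("CK", "G", "N", "GN")
DEFAULT_VEGETATIONS = ("Phragmites", "Tamarix", "Cynodon")
DEFAULT_SEASONS = ("summer", "autumn")

#: Enzyme activities, soil C/N, available nutrients, pH and respiration —
#: the canonical 20-variable ecosystem-function panel.
DEFAULT_FUNCTION_NAMES = (
    "AG", "BG", "BX", "NAG", "ALP", "BCE", "TC", "TN", "AK", "ACa",
    "AMg", "ANa", "ACu", "AFe", "AMn", "AZn", "AP", "pH", "RS", "RH",
)


@dataclass
class SimulationConfig:
    """Parameters shared by the community and function-matrix generators.

    Parameters
    ----------
    n_taxa : int
        Number of ASVs (must equal the phylogeny's tip count when a tree is
        supplied).
    depth : int
        Sequencing depth; every simulated sample's counts sum to this.
    assembly_mode : {"selection", "neutral"}
        ``selection`` filters taxa by a phylogenetically conserved trait
        against a group-specific environment (deterministic assembly);
        ``neutral`` draws all samples from one metacommunity with
        dispersal-limited local drift (stochastic assembly).
    filtering_strength : float
        Selection intensity; the Gaussian environmental filter has width
        ``1/filtering_strength`` (0 disables filtering entirely).
    dispersal : float in [0, 1]
        Neutral mode: weight of the shared metacommunity in each sample's
        sampling probabilities (1 = unlimited dispersal, identical pools).
    season_effect : array of float
        Per-function downward shift applied to autumn samples; its length
        sets the number of function variables (default: 0.5 for all 20).
    noise_sd : float
        Gaussian measurement noise on function variables.
    planted_edges : sequence of (i, j, sign, magnitude)
        Ground-truth log-scale correlations for ``generate_correlated_counts``;
        sign is ``"+"``/``"-"`` (or +1/-1), magnitude in [0, 1].
    seed : int
        Master seed; identical configs give identical outputs.
    """

    n_taxa: int = 200
    depth: int = 10_000
    assembly_mode: str = "selection"
    filtering_strength: float = 1.0
    dispersal: float = 0.8
    season_effect: np.ndarray = field(
        default_factory=lambda: np.full(len(DEFAULT_FUNCTION_NAMES), 0.5)
    )
    noise_sd: float = 0.5
    planted_edges: tuple = ()
    seed: int = 0

    def __post_init__(self):
        self.season_effect = np.asarray(self.season_effect, dtype=float)
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.assembly_mode not in ("selection", "neutral"):
            raise ValueError(f"unknown assembly_mode {self.assembly_mode!r}")
        if self.filtering_strength < 0:
            raise ValueError("filtering_strength must be non-negative")
        if not 0.0 <= self.dispersal <= 1.0:
            raise ValueError("dispersal must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for edge in self.planted_edges:
            i, j, sign, mag = edge
            if not (0 <= i < self.n_taxa and 0 <= j < self.n_taxa) or i == j:
                raise ValueError(f"invalid planted edge taxa ({i}, {j})")
            if _edge_sign(sign) == 0:
                raise ValueError(f"invalid edge sign {sign!r}")
            if not 0.0 <= mag <= 1.0:
                raise ValueError("edge magnitude must be in [0, 1]")


def _edge_sign(sign) -> int:
    if sign in ("+", "positive", 1, +1.0):
        return 1
    if sign in ("-", "negative", -1, -1.0):
        return -1
    return 0


def generate_design(
    replicates: int = 4,
    treatments=DEFAULT_TREATMENTS,
    vegetations=DEFAULT_VEGETATIONS,
    seasons=DEFAULT_SEASONS,
) -> pd.DataFrame:
    """Fully crossed, balanced factorial design table.

    The default arguments reproduce the 96-sample layout
    (4 replicates x 4 treatments x 3 vegetation covers x 2 seasons).

    Returns a DataFrame indexed by ``sample_id`` with columns
    ``replicate``, ``treatment``, ``vegetation``, ``season``.
    """
    treatments, vegetations, seasons = list(treatments), list(vegetations), list(seasons)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for name, levels in (
        ("treatments", treatments),
        ("vegetations", vegetations),
        ("seasons", seasons),
    ):
        if len(levels) == 0:
            raise ValueError(f"{name} must have at least one level")
        if len(set(levels)) != len(levels):
            raise ValueError(f"{name} levels must be unique")

    rows = [
        (season, veg, trt, rep)
        for season, veg, trt, rep in itertools.product(
            seasons, vegetations, treatments, range(1, replicates + 1)
        )
    ]
    design = pd.DataFrame(rows, columns=["season", "vegetation", "treatment", "replicate"])
    design.index = pd.Index(
        [f"S{i:03d}" for i in range(1, len(design) + 1)], name="sample_id"
    )
    return design[["replicate", "treatment", "vegetation", "season"]]


def generate_phylogeny(n_tips: int, seed: int = 0) -> TreeNode:
    """Random rooted, strictly bifurcating phylogeny with positive branch lengths.

    Topology follows a pure-birth (Yule) process: starting from a root split,
    a uniformly chosen extant lineage bifurcates until ``n_tips`` lineages
    exist. Every branch length is an independent Exp(1) draw. Tips are
    labelled ``ASV_1 .. ASV_n``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = rng_for(seed, "phylogeny")

    root = TreeNode()
    leaves = []
    for _ in range(2):
        child = TreeNode(parent=root)
        root.append(child)
        leaves.append(child)
    while len(leaves) < n_tips:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            child = TreeNode(parent=parent)
            parent.append(child)
            leaves.append(child)

    for idx, tip in enumerate(root.tips(), start=1):
        tip.name = f"ASV_{idx}"
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(1.0))
    root.length = None
    return root


def _metacommunity(n_taxa: int, seed: int) -> np.ndarray:
    """Shared regional species-abundance distribution.

    Log-normal with sigma = 2 on the natural-log scale: microbial
    abundance distributions are strongly uneven, and the resulting rare
    tail yields the structural zeros (partial community overlap) that the
    phylogenetic and Raup-Crick null models require to be informative.
    """
    rng = rng_for(seed, "metacommunity")
    m = rng.lognormal(mean=0.0, sigma=2.0, size=n_taxa)
    return m / m.sum()


def _brownian_trait(tree: TreeNode, seed: int) -> pd.Series:
    """Brownian-motion trait on the tree; variance accrues with branch length."""
    rng = rng_for(seed, "trait")
    values = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(node.length))
        values[id(node)] = values[id(node.parent)] + step
    trait = pd.Series({tip.name: values[id(tip)] for tip in tree.tips()})
    sd = trait.std(ddof=0)
    if sd > 0:
        trait = (trait - trait.mean()) / sd
    return trait


def generate_community_counts(
    phylogeny: TreeNode, design: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate a samples x ASVs count table over the design.

    In ``selection`` mode each (vegetation, season) group has its own
    environmental optimum on a Brownian trait axis; taxon sampling weight is
    the metacommunity abundance times a Gaussian filter
    ``exp(-filtering_strength^2 (trait - env)^2 / 2)``, which yields
    phylogenetically clustered turnover between groups. In ``neutral`` mode
    every sample draws from ``dispersal * metacommunity + (1 - dispersal) *
    local``, where the local pool is a Dirichlet perturbation of the
    metacommunity — drift plus dispersal limitation, no selection.

    Rows always sum to ``config.depth``.
    """
    tips = [t.name for t in phylogeny.tips()]
    if len(tips) != config.n_taxa:
        raise ValueError(
            f"config.n_taxa ({config.n_taxa}) != phylogeny tip count ({len(tips)})"
        )
    taxa = sorted(tips, key=lambda s: (len(s), s))
    m = pd.Series(_metacommunity(config.n_taxa, config.seed), index=taxa)

    if config.assembly_mode == "selection":
        trait = _brownian_trait(phylogeny, config.seed)[taxa]
        groups = sorted(
            {(v, s) for v, s in zip(design["vegetation"], design["season"])}
        )
        optima = dict(
            zip(groups, np.linspace(-1.5, 1.5, len(groups)) if len(groups) > 1 else [0.0])
        )

    counts = np.empty((len(design), config.n_taxa), dtype=np.int64)
    for row, (sample_id, meta) in enumerate(design.iterrows()):
        rng = rng_for(config.seed, "counts", sample_id)
        if config.assembly_mode == "selection":
            env = optima[(meta["vegetation"], meta["season"])]
            if config.filtering_strength > 0:
                fitness = np.exp(
                    -0.5 * (config.filtering_strength * (trait.to_numpy() - env)) ** 2
                )
            else:
                fitness = np.ones(config.n_taxa)
            p = m.to_numpy() * fitness
        else:
            local = rng.dirichlet(m.to_numpy() * 50.0)
            p = config.dispersal * m.to_numpy() + (1.0 - config.dispersal) * local
        p = p / p.sum()
        counts[row] = rng.multinomial(config.depth, p)

    return pd.DataFrame(counts, index=design.index.copy(), columns=taxa)


def generate_function_matrix(
    design: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Samples x functions measurement matrix with a seasonal deficit.

    Each function has its own baseline level; autumn samples are shifted
    down by ``config.season_effect`` (per variable) and Gaussian noise of
    ``config.noise_sd`` is added everywhere. With the 20-variable default
    the columns carry the standard panel names (AG .. RH).
    """
    effect = np.asarray(config.season_effect, dtype=float)
    n_func = effect.size
    if n_func == len(DEFAULT_FUNCTION_NAMES):
        names = list(DEFAULT_FUNCTION_NAMES)
    else:
        names = [f"F{i + 1:02d}" for i in range(n_func)]

    rng = rng_for(config.seed, "functions")
    baseline = rng.normal(0.0, 1.0, size=n_func)
    values = np.tile(baseline, (len(design), 1))
    autumn = (design["season"].to_numpy() == "autumn").astype(float)
    values = values - np.outer(autumn, effect)
    values = values + rng.normal(0.0, 1.0, size=values.shape) * config.noise_sd
    return pd.DataFrame(values, index=design.index.copy(), columns=names)


def _planted_covariance(config: SimulationConfig):
    """Target log-scale covariance with planted pairwise correlations.

    Returns (covariance, projected) where ``projected`` is True when the
    target was not positive semi-definite and was projected to the nearest
    PSD matrix by eigenvalue clipping (then rescaled to unit diagonal).
    """
    d = config.n_taxa
    sigma = np.eye(d)
    for i, j, sign, mag in config.planted_edges:
        sigma[i, j] = sigma[j, i] = _edge_sign(sign) * float(mag)
    eigval, eigvec = np.linalg.eigh(sigma)
    projected = bool(eigval.min() < -1e-10)
    if projected:
        eigval = np.clip(eigval, 1e-8, None)
        sigma = (eigvec * eigval) @ eigvec.T
        scale = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(scale, scale)
    return sigma, projected


def generate_correlated_counts(config: SimulationConfig, n_samples: int):
    """Count table with known (planted) log-scale correlation structure.

    Basis abundances are log-normal with the requested pairwise log-scale
    correlations, closed to relative abundances, then multinomially sampled
    at ``config.depth`` — the compositional regime SparCC is built for.

    Returns
    -------
    counts : DataFrame (n_samples x n_taxa)
    truth : DataFrame with columns taxon_i, taxon_j, sign, magnitude
        The planted ground-truth edge list.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    sigma, projected = _planted_covariance(config)
    rng = rng_for(config.seed, "correlated")
    mu = rng.normal(0.0, 1.0, size=config.n_taxa)
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(config.n_taxa))
    log_basis = mu + rng.standard_normal((n_samples, config.n_taxa)) @ chol.T
    fractions = np.exp(log_basis)
    fractions /= fractions.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(config.depth, p) for p in fractions]
    )
    taxa = [f"ASV_{i + 1}" for i in range(config.n_taxa)]
    table = pd.DataFrame(
        counts,
        index=pd.Index([f"S{i:03d}" for i in range(1, n_samples + 1)], name="sample_id"),
        columns=taxa,
    )
    truth = pd.DataFrame(
        [
            (taxa[i], taxa[j], "+" if _edge_sign(s) > 0 else "-", float(m))
            for i, j, s, m in config.planted_edges
        ],
        columns=["taxon_i", "taxon_j", "sign", "magnitude"],
    )
    truth.attrs["psd_projected"] = projected
    return table, truth
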