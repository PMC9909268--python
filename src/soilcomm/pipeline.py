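"""End-to-end orchestration: simulate or load data, then run diversity,
multifunctionality, assembly, network and robustness stages in order,
writing TSV outputs plus a machine-readable run manifest.

All randomness flows from one master seed through named substreams (stage
name + index), so adding one stage never perturbs another stage's draws,
and the same config + seed reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assembly, diversity, io, multifunctionality, network
from . import simulate as sim

__all__ = ["RunConfig", "run_full_pipeline"]

KINGDOMS = ("bacteria", "fungi", "protist")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``count_tables`` (+ ``tree``) point at files on disk, or
    ``simulate`` is true and the simulation block generates them.
    """

    outdir: str = "soilcomm_out"
    seed: int = 0
    # --- inputs (used when simulate is False) ---
    count_tables: dict = field(default_factory=dict)  # kingdom -> path
    tree: str | None = None
    metadata: str | None = None
    function_matrix: str | None = None
    # --- simulation block ---
    simulate: bool = True
    replicates: int = 4
    n_taxa: int = 60
    depth: int = 10_000
    assembly_mode: str = "selection"
    filtering_strength: float = 3.0
    dispersal: float = 0.8
    season_effect: float = 0.5
    noise_sd: float = 0.5
    # --- analysis parameters ---
    n_null: int = 199
    n_boot: int = 100
    n_perm: int = 999
    assembly_max_samples: int = 24
    assembly_kingdom: str = "bacteria"
    prevalence: float = 0.60
    min_abund: float = 0.001
    r_threshold: float = 0.6
    p_threshold: float = 0.01
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    sparcc_iterations: int = 20
    robustness_fractions: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    robustness_reps: int = 20

    def __post_init__(self):
        for name, value, lo, hi in (
            ("prevalence", self.prevalence, 0, 1),
            ("min_abund", self.min_abund, 0, 1),
            ("r_threshold", self.r_threshold, 0, 1),
            ("p_threshold", self.p_threshold, 0, 1),
            ("rc_threshold", self.rc_threshold, 0, 1),
        ):
            if not lo < value < hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi})")
        if not self.simulate and not self.count_tables:
            raise ValueError("either simulate=True or count_tables must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("_comment", None)
        cfg = cls(**data)
        if isinstance(cfg.robustness_fractions, list):
            cfg.robustness_fractions = tuple(cfg.robustness_fractions)
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["robustness_fractions"] = list(self.robustness_fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _sha256(path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def _simulate_inputs(config: RunConfig, outdir: Path):
    design = sim.generate_design(config.replicates)
    tables, trees = {}, {}
    for k, kingdom in enumerate(KINGDOMS):
        tree = sim.generate_phylogeny(config.n_taxa, seed=config.seed * 8 + k)
        sim_cfg = sim.SimulationConfig(
            n_taxa=config.n_taxa,
            depth=config.depth,
            assembly_mode=config.assembly_mode,
            filtering_strength=config.filtering_strength,
            dispersal=config.dispersal,
            noise_sd=config.noise_sd,
            seed=config.seed * 8 + k,
        )
        tables[kingdom] = sim.generate_community_counts(tree, design, sim_cfg)
        trees[kingdom] = tree
        io.write_count_table(tables[kingdom], outdir / f"counts_{kingdom}.tsv")
        io.write_tree(tree, outdir / f"tree_{kingdom}.nwk")
    func_cfg = sim.SimulationConfig(
        n_taxa=config.n_taxa,
        depth=config.depth,
        season_effect=np.full(len(sim.DEFAULT_FUNCTION_NAMES), config.season_effect),
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    functions = sim.generate_function_matrix(design, func_cfg)
    io.write_table_tsv(design, outdir / "design.tsv")
    io.write_table_tsv(functions, outdir / "functions.tsv")
    return design, tables, trees, functions


def _load_inputs(config: RunConfig, manifest: dict):
    tables = {}
    for kingdom, path in config.count_tables.items():
        tables[kingdom] = io.read_count_table(path)
        manifest["inputs"][str(path)] = _sha256(path)
    trees = {}
    if config.tree:
        tree = io.read_tree(config.tree)
        manifest["inputs"][str(config.tree)] = _sha256(config.tree)
        trees = {k: tree for k in tables}
    design = None
    if config.metadata:
        design = io.read_table_tsv(config.metadata)
        manifest["inputs"][str(config.metadata)] = _sha256(config.metadata)
    functions = None
    if config.function_matrix:
        functions = io.read_table_tsv(config.function_matrix)
        manifest["inputs"][str(config.function_matrix)] = _sha256(config.function_matrix)
    if design is not None:
        shared = design.index
        for t in tables.values():
            shared = shared.intersection(t.index)
        if len(shared) < 4:
            raise ValueError("fewer than 4 samples shared between metadata and tables")
    return design, tables, trees, functions


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and write outputs + manifest to ``outdir``.

    Returns a bundle dict with the in-memory results. On stage failure the
    manifest is still written, recording the completed stages and the one
    that failed, before the exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "soilcomm_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "inputs": {},
        "stages": {},
    }
    bundle: dict = {}

    def record(stage, status):
        manifest["stages"][stage] = status
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    stage = "data"
    try:
        if config.simulate:
            design, tables, trees, functions = _simulate_inputs(config, outdir)
        else:
            design, tables, trees, functions = _load_inputs(config, manifest)
        bundle.update(design=design, tables=tables, trees=trees, functions=functions)
        record(stage, "complete")

        stage = "diversity"
        alpha = {}
        beta = {}
        for kingdom, table in tables.items():
            alpha[kingdom] = diversity.alpha_diversity(table, trees.get(kingdom))
            io.write_table_tsv(alpha[kingdom], outdir / f"alpha_{kingdom}.tsv")
            bc = diversity.bray_curtis(table)
            beta[kingdom] = bc
            io.write_table_tsv(
                pd.DataFrame(bc.data, index=list(bc.ids), columns=list(bc.ids)),
                outdir / f"bray_curtis_{kingdom}.tsv",
            )
        tests = []
        if design is not None and "season" in design:
            for kingdom, bc in beta.items():
                f_stat, p = diversity.permanova(
                    bc,
                    design["season"],
                    n_perm=config.n_perm,
                    seed=config.seed,
                )
                tests.append((kingdom, "permanova_season", f_stat, p))
        if functions is not None:
            from scipy.spatial.distance import pdist, squareform
            from skbio import DistanceMatrix

            env = DistanceMatrix(
                squareform(pdist(functions.to_numpy())), ids=list(functions.index)
            )
            for kingdom, bc in beta.items():
                r, p = diversity.mantel(
                    bc, env, n_perm=config.n_perm, seed=config.seed
                )
                tests.append((kingdom, "mantel_environment", r, p))
        tests_df = pd.DataFrame(
            tests, columns=["kingdom", "test", "statistic", "p"]
        )
        io.write_table_tsv(tests_df.set_index("kingdom"), outdir / "beta_tests.tsv")
        bundle.update(alpha=alpha, beta=beta, beta_tests=tests_df)
        record(stage, "complete")

        stage = "multifunctionality"
        if functions is None or design is None:
            record(stage, "skipped")
        else:
            std = multifunctionality.min_max_standardize(functions)
            emf = multifunctionality.multifunctionality_index(std)
            comparison = multifunctionality.compare_groups(emf, design["season"])
            io.write_table_tsv(std, outdir / "functions_standardized.tsv")
            io.write_table_tsv(emf.to_frame(), outdir / "multifunctionality.tsv")
            io.write_table_tsv(comparison.pairwise, outdir / "multifunctionality_tests.tsv")
            bundle.update(multifunctionality=emf, mf_comparison=comparison)
            record(stage, "complete")

        stage = "assembly"
        kingdom = config.assembly_kingdom
        table = tables[kingdom]
        tree = trees.get(kingdom)
        if tree is None:
            record(stage, "skipped")
        else:
            if len(table) > config.assembly_max_samples:
                step = len(table) / config.assembly_max_samples
                rows = sorted({int(i * step) for i in range(config.assembly_max_samples)})
                table = table.iloc[rows]
            table = table.loc[:, table.sum(axis=0) > 0]
            result = assembly.assembly_analysis(
                table,
                tree,
                n_null=config.n_null,
                seed=config.seed,
                bnti_threshold=config.bnti_threshold,
                rc_threshold=config.rc_threshold,
            )
            io.write_table_tsv(result.bnti, outdir / "bnti.tsv")
            io.write_table_tsv(result.rc, outdir / "rcbray.tsv")
            io.write_table_tsv(
                result.pairs.set_index("sample_a"), outdir / "assembly_pairs.tsv"
            )
            io.write_table_tsv(
                result.fractions.to_frame("fraction"), outdir / "assembly_fractions.tsv"
            )
            bundle["assembly"] = result
            record(stage, "complete")

        stage = "network"
        combined, kingdom_map = network.combine_kingdoms(
            tables, config.prevalence, config.min_abund
        )
        corr = network.sparcc_correlations(
            combined, n_inner_iter=config.sparcc_iterations, seed=config.seed
        )
        pvals = network.sparcc_pvalues(
            combined,
            corr,
            n_boot=config.n_boot,
            seed=config.seed,
            n_inner_iter=max(2, config.sparcc_iterations // 4),
        )
        graph = network.build_network(
            corr, pvals, config.r_threshold, config.p_threshold, kingdom_map
        )
        io.write_table_tsv(corr, outdir / "sparcc_correlations.tsv")
        io.write_table_tsv(pvals, outdir / "sparcc_pvalues.tsv")
        edges = pd.DataFrame(
            [
                (u, v, d["weight"], d["sign"], d["p"])
                for u, v, d in graph.edges(data=True)
            ],
            columns=["node1", "node2", "r", "sign", "p"],
        )
        io.write_table_tsv(edges.set_index("node1"), outdir / "edges.tsv")
        bundle.update(network=graph, correlations=corr, pvalues=pvals)
        if graph.number_of_nodes() > 0:
            modules, q = network.detect_modules(graph, seed=config.seed)
            roles = network.node_roles(graph, modules)
            metrics = network.topology_metrics(graph, modules)
            io.write_table_tsv(roles, outdir / "node_roles.tsv")
            summary = {k: v for k, v in metrics.items() if not isinstance(v, pd.DataFrame)}
            io.write_table_tsv(
                pd.Series(summary, name="value").to_frame(), outdir / "topology.tsv"
            )
            import networkx as nx

            nx.set_node_attributes(graph, modules, "module")
            nx.set_node_attributes(graph, roles["Z"].to_dict(), "Z")
            nx.set_node_attributes(graph, roles["C"].to_dict(), "C")
            nx.set_node_attributes(graph, roles["role"].to_dict(), "role")
            nx.write_graphml(graph, outdir / "network.graphml")
            bundle.update(modules=modules, modularity=q, roles=roles, topology=metrics)
        record(stage, "complete")

        stage = "robustness"
        if graph.number_of_nodes() == 0:
            record(stage, "skipped")
        else:
            curve = network.robustness_curve(
                graph,
                fractions=config.robustness_fractions,
                n_reps=config.robustness_reps,
                seed=config.seed,
            )
            io.write_table_tsv(curve.set_index("fraction"), outdir / "robustness.tsv")
            bundle["robustness"] = curve
            record(stage, "complete")
    except Exception:
        record(stage, "failed")
        raise

    return bundle
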