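# soilcomm

Community-ecology analyses for soil microbiome surveys: ecosystem
multifunctionality scoring, phylogenetic null-model partitioning of
community assembly, and cross-kingdom co-occurrence network inference with
robustness analysis — plus a synthetic-data generator that reproduces the
factorial structure of a field study (replicates × agronomic treatments ×
vegetation covers × seasons) so every stage can be exercised and validated
without any sequencing data.

It is aimed at microbial ecologists working with ASV count tables
(bacteria, fungi, protists), rooted phylogenies and per-sample
ecosystem-function measurements.

## What it computes

**Ecosystem multifunctionality.** Each function variable *X* (enzyme
activities, C/N pools, available nutrients, pH, respiration — a 20-variable
panel by default) is standardized across all samples,
`STD = (X − Xmin)/(Xmax − Xmin)`, and a sample's multifunctionality index
is the mean of its standardized values. Group contrasts use one-way ANOVA
and pairwise Welch *t*-tests.

**Community assembly (βNTI / RC_bray).** For each sample pair the
abundance-weighted between-community mean nearest taxon distance (βMNTD) is
standardized against a null distribution obtained by shuffling taxa across
the phylogeny's tips:

> βNTI = (βMNTD_obs − mean(βMNTD_null)) / sd(βMNTD_null)

|βNTI| > 2 indicates deterministic selection (variable selection above +2,
homogeneous selection below −2). Remaining pairs are split by the
abundance-based Raup–Crick metric on Bray–Curtis (RC > +0.95 dispersal
limitation, RC < −0.95 homogenizing dispersal, else drift/undominated).
The two selection classes form the *deterministic* fraction of turnover;
the other three the *stochastic* fraction.

**Co-occurrence networks.** Core ASVs (prevalence > 60 % of samples, mean
relative abundance > 0.1 %) from up to three kingdoms are correlated with
SparCC (log-ratio variances, basis-variance estimation, iterative exclusion
of dominant pairs, Dirichlet resampling); edges require |r| > 0.6 and
bootstrap pseudo *p* < 0.01. The package reports topology metrics, greedy
modularity modules, node roles in the (Zi, Pi) plane — network hubs, module
hubs, connectors, peripherals at Z = 2.5 and C = 0.62 — and robustness as
the decay of natural connectivity, ln(mean(exp(λᵢ))) over adjacency
eigenvalues, under random node removal.

Also included: observed richness, Shannon diversity, Faith's PD (rooted
convention), Bray–Curtis, seed-controlled PERMANOVA and Mantel permutation
tests, and leaf-trait derivations (SLA, LDMC).

## Worked example

```python
import numpy as np
from soilcomm import simulate as sim, multifunctionality as mf, assembly as asm

design = sim.generate_design()          # 4 reps x 4 treatments x 3 vegetation x 2 seasons
print("samples:", len(design))

cfg = sim.SimulationConfig(seed=1)
functions = sim.generate_function_matrix(design, cfg)
emf = mf.multifunctionality_index(mf.min_max_standardize(functions))
cmp_res = mf.compare_groups(emf, design["season"])
print(cmp_res.group_means.round(3).to_dict())
print("Welch t p-value:", f"{cmp_res.pairwise['p'].iloc[0]:.3g}")

tree = sim.generate_phylogeny(60, seed=1)
sub = sim.generate_design(4, ["CK"], ["A", "B", "C"], ["summer", "autumn"])
counts = sim.generate_community_counts(
    tree, sub, sim.SimulationConfig(n_taxa=60, assembly_mode="selection",
                                    filtering_strength=5.0, seed=1))
result = asm.assembly_analysis(counts, tree, n_null=199, seed=1)
print(result.fractions.round(3).to_string())
```

prints

```
samples: 96
{'summer': 0.61, 'autumn': 0.425}
Welch t p-value: 7.69e-42
process
variable selection          0.155
homogeneous selection       0.000
dispersal limitation        0.450
homogenizing dispersal      0.114
drift/undominated           0.280
determinism                 0.155
stochasticity               0.845
n_classified              271.000
n_undetermined              5.000
```

The 96 samples are the full crossed factorial; the simulated autumn
multifunctionality deficit (0.425 vs 0.610) is detected by the Welch test;
and communities simulated under strong environmental filtering show a
non-zero deterministic (selection) share of pairwise turnover, with the
rest partitioned among the stochastic classes. Five pairs had a degenerate
null (sd = 0) and are excluded from the fractions.

## Command line

`soilcomm` exposes `simulate`, `alpha`, `beta`, `permanova`, `mantel`,
`multifunc`, `assembly`, `network`, `robustness` and `all` (full pipeline
from a YAML config, writing TSV outputs and a JSON run manifest that
records the seed, thresholds and input digests). Exit codes: 0 success,
2 input error, 3 stage failure.

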