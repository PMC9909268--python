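# Methods

This note documents the models implemented in `soilcomm`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Ecosystem multifunctionality

Each function column is min-max standardized across **all** samples in the
input matrix — never per group — so that the column minimum maps to 0 and
the maximum to 1; the per-sample index is the unweighted mean of the
standardized values (the "averaging" multifunctionality approach; no
threshold-based or weighted variants are implemented). Conventions:

- A constant column would produce 0/0; it is mapped to all zeros with a
  warning, keeping the number of functions fixed.
- All variables are treated as "larger is more function", including pH.
  Direction-correcting non-monotone variables (reflecting pH around an
  optimum, say) is deliberately not done; users who need it should reflect
  columns before calling the standardizer.
- Group comparisons: one-way fixed-effects ANOVA plus pairwise Welch
  *t*-tests (unequal variances are the norm for soil measurements). If two
  groups are each constant, identical means give (t = 0, p = 1) and
  different means are reported as p = 0 with a degenerate-variance flag
  rather than failing.

## Diversity and permutation tests

- Shannon entropy uses the natural log, so the uniform community of S taxa
  attains ln S.
- Faith's PD uses the **rooted** convention: the branch path from the root
  to every present tip is counted, so a single-taxon community has
  positive PD (the sum of its root path). Conventions differ between
  packages; this one is stated prominently because it changes single- and
  few-taxon values.
- Bray–Curtis is Σ|a−b| / Σ(a+b); a pair of all-zero samples is an error,
  not a silent 0.
- PERMANOVA (one factor only) computes the pseudo-F from the
  among/within partition of squared distances; the Mantel statistic is the
  Pearson correlation of upper triangles with joint row/column permutation
  of the second matrix, two-sided. Both use the +1 permutation correction
  p = (1 + hits)/(1 + n_perm), so p is never exactly zero and its floor is
  1/(n_perm + 1). Both take explicit seeds; permutation engines were
  implemented in-package so that exhaustive-enumeration tests can control
  every draw (scikit-bio's implementations serve as independent
  cross-checks in the test suite).
- No rarefaction or relative-abundance normalization is applied before
  diversity computation.

## Community assembly null models

βMNTD between samples A and B is the two-direction average of each present
taxon's relative abundance times the patristic distance to its nearest
taxon in the other sample (a shared taxon contributes 0). It is
abundance-weighted by default; `weighted=False` gives the presence/absence
variant.

The βNTI null shuffles taxon labels across **all** tips of the phylogeny:
each sample keeps its taxa and abundances, only the tip positions are
permuted, preserving per-sample richness and abundance structure while
destroying phylogenetic signal. With 999 nulls by default (matching the
permutation count used for the other tests), βNTI is the z-score of the
observed βMNTD. If the null sd is 0 — e.g. on an equidistant star tree, or
when two communities contain exactly the same taxa so βMNTD is invariant
under relabeling — βNTI is undefined; the pair is flagged, reported as NaN
and excluded from (but counted next to) the process fractions.

RC_bray builds null communities that preserve each sample's observed
richness and total abundance: taxa enter with probability proportional to
occurrence frequency in the table, then individuals are distributed
multinomially in proportion to mean relative abundance.
RC = 2(B + E/2)/n − 1 with B the nulls below and E the ties (tolerance
1e−10), bounded in [−1, 1].

Process classification uses the conventional thresholds |βNTI| = 2 and
|RC| = 0.95, both strict and both configurable. Determinism is the summed
share of the two selection classes; stochasticity the other three.

Reproducibility: each pair draws from its own substream derived from
(master seed, pair index), so results do not depend on processing order
and parallelization cannot change them.

## SparCC

Correlations on compositional count data are estimated via log-ratio
variances: per iteration, fractions are drawn from Dirichlet(counts + 1),
T_ij = var(log f_i − log f_j) is formed, and basis variances t_i are
solved from the linear approximation Σ_{j∈inc(i)} T_ij ≈ k_i t_i +
Σ_{j∈inc(i)} t_j, where inc(i) is the set of partners still included.
Correlations are r_ij = (t_i + t_j − T_ij) / (2√(t_i t_j)). The most
strongly correlated pair above the exclusion threshold (default 0.8) is
removed from the system for up to 10 rounds, protecting the basis estimate
from a few dominant pairs. Defaults: 20 Dirichlet iterations, final matrix
is the **mean** across iterations (some implementations use the median;
the mean is the package's choice and all knobs are exposed), symmetric,
unit diagonal, clipped to [−1, 1]. Taxa with non-positive or non-finite
basis variance are reported and their correlations set to NaN. The
approximation is exact when true basis covariances vanish, which the test
suite exploits as an algebraic oracle.

Pseudo p-values: each bootstrap permutes every taxon's counts across
samples independently, recomputes SparCC, and counts |r_boot| ≥ |r_obs|;
p = (1 + hits)/(1 + n_boot) with 100 bootstraps by default.

## Networks

Edges require |r| > 0.6 **and** p < 0.01 (both strict). A 0.05 gate is
sometimes used for bootstrap pseudo p-values; 0.01 is the default here and
both thresholds are plain arguments. Cross-kingdom networks concatenate
per-kingdom core-filtered tables (prevalence > 60 %, mean relative
abundance > 0.1 %, strict) after per-sample relative-abundance conversion,
with taxon ids prefixed by kingdom.

Modules come from greedy modularity maximization on |r| weights (sign is
ignored for partitioning). Node roles use the within-module degree z-score
Z and participation coefficient C = 1 − Σ_m (k_im/k_i)²; thresholds
Z = 2.5 and C = 0.62 delimit network hubs, module hubs, connectors and
peripherals. Single-node modules or zero within-module degree spread give
Z = 0 with a flag.

Natural connectivity is ln(mean(exp(λ_i))) over the eigenvalues of the
**unweighted** adjacency matrix (robustness-literature convention;
computed via logsumexp for stability). The robustness curve removes a
fraction of nodes uniformly at random without replacement, recomputes
natural connectivity and averages over replicates; fraction 0 returns the
intact value exactly.

## Synthetic data

The generator emulates the downstream products of a factorial field
survey — by default 4 replicates × 4 treatments (control, glyphosate, N,
both) × 3 vegetation covers × 2 seasons = 96 samples — with the signals
the analyses are designed to detect:

- **Phylogeny:** pure-birth (Yule) topology, Exp(1) branch lengths; the
  simplest process giving strictly positive branch lengths and a rooted,
  strictly bifurcating tree.
- **Metacommunity:** log-normal species-abundance distribution with σ = 2
  on the natural-log scale. Microbial SADs are strongly uneven; the rare
  tail produces partial community overlap (structural zeros), without
  which βMNTD is invariant under tip relabeling and the assembly null
  models degenerate.
- **Selection mode:** a Brownian-motion trait evolves along the tree
  (variance ∝ branch length, standardized to unit sd); each
  (vegetation, season) group has an environmental optimum on that axis,
  evenly spaced over [−1.5, 1.5] sd, and taxon sampling weight is the
  metacommunity abundance times the Gaussian filter
  exp(−½ (filtering_strength · (trait − env))²) — i.e. filter width
  1/filtering_strength, with 0 disabling filtering. This produces the
  phylogenetically clustered turnover that βNTI detects.
- **Neutral mode:** each sample draws from dispersal · metacommunity +
  (1 − dispersal) · local, the local pool being a Dirichlet perturbation
  of the metacommunity (concentration 50 · m) — drift plus dispersal
  limitation, no selection. Counts are always multinomial at the
  configured depth (default 10 000 reads; default 200 taxa).
- **Function matrix:** per-column baselines with Gaussian noise
  (default sd 0.5) and a per-variable downward autumn shift
  (default 0.5), reproducing a seasonal multifunctionality deficit.
- **Planted correlations:** log-normal basis abundances with requested
  pairwise log-scale correlations, closed to compositions and multinomially
  sampled — the regime SparCC assumes. A non-PSD target covariance is
  projected by eigenvalue clipping (then rescaled to unit diagonal) and the
  projection is flagged on the returned ground truth.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomy, variable library sizes, overdispersion beyond the multinomial,
spatial autocorrelation between plots, and any coupling between the
community tables and the function matrix. Passing recovery tests therefore
demonstrates that the estimators detect the signals they target under
idealized sampling — not that field data meet these assumptions.

## Problem sizes and determinism

The test suite and the acceptance script run the stochastic analyses at
deliberately modest sizes — 60 taxa × 24 samples × 199 nulls for the
assembly recovery comparison, 20–50 taxa for SparCC recovery, 200
simulations for calibration checks — chosen so the full suite completes in
a few minutes while leaving the statistical conclusions unambiguous.
Defaults in the library itself (999 nulls, 200 taxa, depth 10 000) are the
conventional analysis settings. All stochastic stages take explicit seeds;
the pipeline derives per-stage, per-pair substreams from one master seed,
and identical configuration + seed reproduces every output byte for byte.

## Known limitations

- PERMANOVA is single-factor; no stratified or multi-factor designs.
- The assembly analysis classifies pairwise turnover globally; no
  per-clade binning.
- Sequencing depth and rarefaction policy are left to the user (a count
  table is taken at face value).
- SparCC settings (iterations, exclusion threshold, bootstrap count) are
  implementation choices exposed as arguments, not field-calibrated
  values.
- BIOM support covers the v2.1 HDF5 table layout (ids + CSR matrices),
  not observation/sample metadata.
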