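# Methods

This note documents the models, estimators and numerical choices behind
`mucohub`, and what the synthetic benchmark does and does not establish
about real data.

## Compositional correlation inference

Shotgun profiling yields relative abundances: each sample's counts are a
multinomial draw from taxon fractions, so naive correlations between
fractions are confounded by the unit-sum constraint. The inference
therefore works on log-ratios. For taxa i and j,

    t_ij = Var[ ln(x_i / x_j) ] = ω_i² + ω_j² − 2 ρ_ij ω_i ω_j,

where ω_i² is the variance of the latent absolute log-abundance (the
"basis variance") and ρ_ij the basis correlation — the quantity of
interest. Under the sparsity approximation (Σ_j ρ_ij ω_i ω_j ≈ 0 for
most i), the row sums t_i = Σ_j t_ij satisfy the linear system
t_i = (D−2) ω_i² + Σ_j ω_j², i.e. ((D−2)I + J) ω² = t, solved directly;
when pairs have been excluded the same relation restricted to allowed
partners is solved by least squares. ρ_ij then follows from the
displayed identity, clipped to [−1, 1].

Numerical choices:

- **Dirichlet resampling.** Per sample, fractions are drawn from
  Dirichlet(counts + 1) — a flat prior pseudocount of 1 keeps
  zero-count taxa strictly positive. The reported ρ is the elementwise
  median over 20 draws; the median is robust to the occasional skewed
  basis solution. Log-ratio variances use denominator n−1 and are
  computed in O(D²) from the covariance matrix of log fractions.
- **Iterative exclusion.** The sparsity approximation fails for
  strongly dependent pairs, so after each solve the strongest
  not-yet-excluded pair with |ρ| ≥ 0.1 is removed and the system
  re-solved, up to 10 rounds per draw. Exclusions are per-draw. If an
  exclusion makes the system rank-deficient it is rolled back.
- **Variance floor.** Basis variances are clipped at 1e−8; pairs
  involving a floored variance report ρ = 0 rather than a division
  artefact.
- **Significance.** Each permutation independently shuffles every
  taxon's counts across samples — destroying inter-taxon association
  while preserving marginals — and recomputes ρ with a single fraction
  draw (the null distribution of |ρ| does not need the posterior
  average). Two-sided pseudo p-values use the add-one estimator
  p = (1 + #{|ρ*| ≥ |ρ|}) / (1 + n_perm), so p ∈ (0, 1]. Default 100
  permutations; at least 4 taxa are required (the basis system is
  degenerate below that).

## Network, topology, hubs

An edge joins i and j iff |ρ_ij| > 0.4 **and** p_ij < 0.05, both strict;
the edge sign is sign(ρ). Isolated taxa are dropped by default,
matching edge-defined network drawings. Topology reports node/edge
counts, average degree 2E/N, transitivity (3 × triangles / connected
triples) and the mean local clustering coefficient (degree-<2 nodes
contribute 0), via networkx.

**Degree-model classification.** On degrees k ≥ k_min the discrete
power law p(k) ∝ k^(−α) is fitted with the MLE
α̂ = 1 + n [Σ ln(k_i/(k_min − ½))]⁻¹ and Hurwitz-zeta normalization; the
competitor is a Poisson truncated to the same support, λ̂ from Newton
iteration on the score equation. The model with the higher
small-sample-corrected (AICc) log-likelihood wins. `k_min` defaults to
the smallest positive observed degree: anchoring the power law below
the observed support wastes probability mass on degrees that never
occur and biases the comparison toward the Poisson (a
preferential-attachment graph with m = 2 has no degree-1 nodes). With
support matching, 20/20 Erdős–Rényi G(300, 0.02) replicates classify as
Poisson and 20/20 preferential-attachment (m = 2) replicates as
power-law. A degenerate all-equal degree sequence returns Poisson with
a warning.

**Hub rule.** q3 is the linear-interpolation (type-7) third quartile of
the degree multiset over network nodes; hubs are nodes with degree
strictly greater than q3. Type-7 is stated explicitly because quantile
conventions differ enough to move the hub boundary.

## Community statistics

Shannon H = −Σ p ln p (natural log, nats) and Gini–Simpson 1 − Σ p² on
raw counts without rarefaction. Bray–Curtis d = Σ|u−v| / Σ(u+v); PCoA
is classical scaling of −d²/2 after Gower double-centering, keeping
axes with eigenvalue > 1e−10 and reporting percent variance over the
positive spectrum only (no Cailliez/Lingoes correction — negative
eigenvalues are simply dropped). PERMANOVA is one-way:
SST = (1/n) Σ_{i<j} d_ij², SSW group-wise, pseudo-F with the add-one
permutation p. Calibration: 500 null replicates (one Gaussian cloud,
arbitrary 10+10 labels, 199 permutations) reject at α = 0.05 in 4% of
runs. Group summaries report median and type-7 IQR with a Mann–Whitney
p (exact enumeration for pooled n ≤ 10 without ties, tie-corrected
normal approximation otherwise).

## Differential screening

Counts are total-sum scaled to CPM per sample. A two-sided Mann–Whitney
test gates each feature at α = 0.05; passing features get
score = log10(|mean_A − mean_B| + 1) on CPM means with the direction of
enrichment, and features with score strictly above 1.5 are flagged.
This deterministic variant preserves the log10-effect-on-CPM semantics
of bootstrapped-LDA effect sizes while keeping tests exact; an optional
bootstrapped mode (seeded subsample replicates) is available. The
covariate-adjusted model is per-feature OLS of log(TSS + pseudocount)
on a group indicator plus one numeric covariate (e.g. body weight),
with a two-sided t test on the group coefficient and BH adjustment
across features. The pseudocount is half the feature's smallest nonzero
relative abundance; a constant covariate is dropped with a warning; a
zero-variance feature reports p = 1. Both raw p and BH q are exported
throughout, since thresholding conventions on raw vs adjusted p vary
between studies.

## Phenotype association

Spearman ρ is the Pearson correlation of mid-ranks; p comes from the
t approximation t = ρ√((n−2)/(1−ρ²)) (exact permutation enumeration
available for n ≤ 8; ρ = ±1 reports p = 0; constant input reports
ρ = 0, p = 1). Taxa enter as CPM — Spearman is rank-based, so any
monotone per-sample normalization yields identical ρ. BH runs across
all cells of the requested association table; restricting the table to
the taxa of interest (differential set, hub set) is the intended usage,
mirroring how such screens are reported.

## Synthetic study generator

The generator is the benchmark: two groups, a planted
preferential-attachment (scale-free) interaction graph in the control
condition and an Erdős–Rényi graph in the perturbed one, compositional
counts, and phenotypes coupled to hub taxa.

**Latent model.** Log-abundances are multivariate normal with a
correlation matrix that embeds each planted edge at ±c; samples are
exponentiated, normalized, and counted with a multinomial at fixed
depth. This is exactly the basis model the inference assumes, so
recovery failures measure estimation error, not model mismatch.

**Positive-definite embedding.** A correlation matrix cannot hold a
degree-k hub at correlation c with all k neighbours unless those
neighbours are mutually correlated at roughly (k c² − 1)/(k − 1): a hub
star's smallest eigenvalue is 1 − c√k. The embedding therefore pins
planted entries exactly at ±c by alternating projections (PSD-cone
eigenvalue clip at 1e−6, then restore planted entries and unit
diagonal), letting the off-network entries absorb the minimal fill-in
that positive definiteness forces. If a target is infeasible (e.g.
many mutually exclusive taxa at strong negative c), the final repair
moves planted entries; deviations beyond c/2 raise an error advising a
smaller c or a sparser graph. Edge signs derive from random per-node
signs (edge sign = product of endpoint signs, calibrated to a 30%
marginal negative-edge fraction, in line with the positive-edge
dominance of published co-occurrence networks): node-product signs are
consistent around every cycle, whereas independent per-edge signs
create frustrated cycles with no realizable correlation matrix.

**Defaults** (the study conditions for all tests): D = 60 taxa,
n = 20/group (a `n_per_group=5` paper-scale configuration remains
available to demonstrate small-n behaviour), depth 100,000 reads,
c = 0.6, control topology preferential attachment m = 2, perturbed
topology G(60, 0.08), per-taxon log-means uniform on (0, 3) and
log-variances on (0.3, 1.5), eight differential taxa at log2FC ±2
placed on peripheral (late-arriving) indices — differential species and
hub bacteria are distinct sets, and loading fold changes onto hub nodes
would confound the phenotype coupling. Phenotypes (permeability-like
FITC, ALT) couple negatively to a co-abundant guild of 5 hubs: the
guild is grown greedily from the top-degree hub by mutual positive
correlation, contributions are on standardized latents, and the noise
SD defaults to the SD of the deterministic signal (SNR 1). The body
weight covariate is drawn independently of the microbiome with the same
distribution in both groups. Ground-truth hub sets are computed with
the same strict-Q3 code path the inference uses.

**What passing tests do and do not show.** The generator's latent
Gaussian copula omits real-data features: taxonomic misclassification,
zero inflation beyond multinomial sampling, uneven sequencing depth,
and longitudinal structure. Passing recovery tests shows the estimators
are correct and well calibrated under the assumed model at desk scale;
it does not certify performance on real mucosal profiles.

**Known limitation — recovered-network density.** The PD-forced
fill-in sits near (k c²−1)/(k−1) ≈ 0.2–0.5 inside hub neighbourhoods.
With n = 20–40 samples, correlation estimates have SD ≈ 0.15, so a
fraction of fill entries crosses the 0.4 edge threshold: recovered
networks carry roughly twice the planted edge count, degree
distributions flatten (a recovered control network can classify as
Poisson even when its planted graph is clearly power-law), and the
planted-vs-recovered degree rank correlation saturates around 0.5–0.6.
This is a property of embedding strong hub correlations in any valid
correlation matrix, not of the estimator: an oracle given the true
latent log-abundances shows the same ceiling. Hub recovery through the
strict-Q3 rule is more robust (≈ 60% at n = 40) because it depends on
the upper tail of the degree ranking rather than the full ordering.

## Pipeline

`run()` executes community → differential → per-group network →
association, writing TSV/GML/JSON artifacts plus a run log; every
random stage's seed derives deterministically from the master seed, so
a rerun is byte-identical. Networks are inferred per group on that
group's samples only; differential analysis uses all samples. Stage
failures abort with the stage name and leave a `FAILED` marker beside
any partial outputs.

Problem sizes used by the test suite and acceptance script (null
control D = 30 × n = 50, recovery D = 60 × n = 40, 500 PERMANOVA
replicates, 200 association null replicates, 20 classifier replicates
per family) are desk-scale choices that keep the full suite around a
minute while leaving each check statistically interpretable.
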