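# mucohub

Co-occurrence network analysis of mucosal microbiome studies: who are the
hub bacteria, how does the network's shape change under a perturbation
such as a high-fat diet, and which taxa track host barrier-injury
phenotypes?

`mucohub` is a Python library (with a thin CLI) for two-condition
taxa-by-sample count studies. It covers the full analysis chain a
metagenomics group runs after taxonomic profiling:

- **Community structure** — Shannon/Simpson alpha diversity, Bray–Curtis
  dissimilarity, classical PCoA, and one-way PERMANOVA with seeded
  permutations.
- **Differential abundance** — Mann–Whitney screening with an
  LDA-style log10 effect score on the counts-per-million scale
  (features flagged at score > 1.5, p < 0.05), plus a covariate-adjusted
  per-feature linear model (log relative abundance ~ group + covariate,
  e.g. body weight) with Benjamini–Hochberg correction.
- **Compositional network inference** — the core. Sequencing counts are
  compositional, so correlations are inferred SparCC-style from
  log-ratio variances: t_ij = Var ln(x_i/x_j) decomposes as
  ω_i² + ω_j² − 2 ρ_ij ω_i ω_j, and under a sparsity assumption the row
  sums of T yield the basis variances ω² and hence the basis
  correlations ρ. Strongly correlated pairs are excluded iteratively,
  sampling noise is integrated over Dirichlet-posterior fraction draws,
  and significance comes from a per-pair permutation test. Edges with
  |ρ| > 0.4 and p < 0.05 form the co-occurrence network.
- **Topology & hubs** — node/edge counts, average degree, clustering
  coefficients, and a likelihood-based classification of the degree
  distribution as scale-free (discrete power law) versus random-graph
  (truncated Poisson). Hub taxa are nodes whose degree strictly exceeds
  the third quartile (Q3) of the network degree distribution.
- **Phenotype association** — Spearman rank correlation of taxa
  (differential and hub sets) with host phenotypes such as FITC-dextran
  intensity or ALT, with BH correction.
- **Synthetic studies** — a first-class generator that plants a
  scale-free interaction network in one condition and an Erdős–Rényi
  random network in the other, embeds the edges at correlation ±c in a
  positive-definite latent Gaussian copula, couples phenotypes
  negatively to a co-abundant hub guild, and records all ground truth —
  so every pipeline stage is testable without any sequencing data.

## Worked example

```python
from mucohub import SyntheticConfig, generate_study, sparcc, permutation_pvalues
from mucohub import build_network, topology_metrics, identify_hubs
from mucohub.netinfer import classify_degree_model

study = generate_study(SyntheticConfig(seed=0))          # 60 taxa, 20 mice/group
ctrl = study.table.subset_samples(study.metadata.samples_in_group("Ctrl"))

rho = sparcc(ctrl, seed=1)                                # basis correlations
pvals = permutation_pvalues(ctrl, rho, n_perm=100, seed=2)
net = build_network(rho, pvals, taxa=ctrl.feature_ids)    # |rho|>0.4, p<0.05
topo = topology_metrics(net)
hubs = identify_hubs(net)
planted = classify_degree_model(
    [k for _, k in study.planted_networks["Ctrl"].degree()]
).model
print(f"N={topo.n_nodes} E={topo.n_edges} <k>={topo.average_degree:.2f} "
      f"planted_model={planted} q3={hubs.q3} hubs={len(hubs.hubs)}")
```

prints

```
N=60 E=254 <k>=8.47 planted_model=power_law q3=11.0 hubs=14
```

All 60 taxa survive into the recovered control network, 14 of them
exceed the strict-Q3 hub rule (the planted graph has 15 strict-Q3
hubs), and the planted control topology is classified as power-law
(scale-free) while the same call on the `"HFD"` planted graph returns
Poisson. Note that the *recovered* network carries more edges than the
planted one (254 vs 116): embedding strong hub edges in a valid
correlation matrix necessarily induces secondary correlations among hub
neighbours, and at n = 20 samples per group some of those cross the 0.4
threshold — see `docs/methods.md` for why this is a property of the
compositional model, not an inference bug.

The same analysis end-to-end, from a shell:

```bash
mucohub synth --out data/ --seed 7                 # synthetic study + ground truth
mucohub network --table data/abundance.tsv --seed 1
mucohub run --config run.yaml                      # full pipeline -> report.json
```

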