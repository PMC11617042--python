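"""Two-condition synthetic studies with planted network structure.

Emulates the design of a diet-intervention mucosal-microbiome study:
two groups of mice whose latent log-abundance correlation structure
follows a planted interaction network — scale-free (preferential
attachment) in the control-like condition, Erdos-Renyi random in the
perturbed condition — with designated differential taxa and host
phenotypes (e.g. a gut-permeability marker) linearly coupled to
designated hub taxa.

Observation model: a latent Gaussian copula on log-abundances.  Per
sample, latent log-abundances are drawn from a multivariate normal whose
correlation matrix holds the planted edges exactly at magnitude c while
alternating projections find the minimal extra correlation ("fill-in")
that positive definiteness forces around hub nodes; the latents are
exponentiated, normalized to fractions, and counts drawn multinomially
at a fixed sequencing depth.  This is exactly the basis model that the
compositional correlation inference assumes, making parameter recovery a
fair test of the inference rather than of model mismatch.

Ground truth (planted graphs, strict-Q3 hub sets, differential taxa,
phenotype coefficients) is recorded so every downstream stage can be
scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .netinfer import HubSet, q3_hubs
from .tabio import AbundanceTable, StudyMetadata

__all__ = [
    "TopologySpec",
    "PhenotypeSpec",
    "SyntheticConfig",
    "SyntheticStudy",
    "generate_planted_network",
    "network_to_correlation",
    "generate_counts",
    "generate_study",
    "default_config",
]

PD_EIGEN_FLOOR = 1e-6  # eigenvalue clipping floor for the PD repair


@dataclass
class TopologySpec:
    """Planted-network family: ``scale_free`` (param = edges per new node)
    or ``random`` (param = edge probability)."""

    kind: str
    param: float


@dataclass
class PhenotypeSpec:
    """A host phenotype linearly coupled to designated taxa.

    value = intercept + sum_t coef_t * z_t + N(0, noise_sd), where z_t is
    the taxon's standardized latent log-abundance (centred and scaled by
    its configured basis mean and SD), so every designated taxon
    contributes on the same scale.  ``taxa`` may be explicit taxon names
    or the string "hubs:K" meaning a co-abundant guild of K planted hubs
    of the first group's network (seeded at the top-degree hub, grown by
    mutual positive correlation) — mirroring how barrier-injury markers
    track a mutually positively-associated set of hub bacteria rather
    than an arbitrary taxon collection.  ``noise_sd=None`` sets the
    noise SD equal to the empirical SD of the deterministic signal term
    (signal-to-noise ratio 1).
    """

    name: str
    taxa: list[str] | str = "hubs:5"
    coefficients: list[float] | float = -1.0
    noise_sd: float | None = None
    intercept: float = 0.0


@dataclass
class SyntheticConfig:
    """Study-shape parameters.

    Defaults mirror the two-condition mouse design scaled up for
    statistical power: 60 taxa, 20 samples per group, depth 100,000
    reads per sample, planted correlation magnitude 0.6.
    """

    n_taxa: int = 60
    n_per_group: int = 20
    group_labels: tuple[str, str] = ("Ctrl", "HFD")
    topology: dict[str, TopologySpec] = field(
        default_factory=lambda: {
            "Ctrl": TopologySpec("scale_free", 2),
            "HFD": TopologySpec("random", 0.08),
        }
    )
    edge_correlation: float = 0.6
    negative_edge_fraction: float = 0.3
    log_mean_range: tuple[float, float] = (0.0, 3.0)
    log_var_range: tuple[float, float] = (0.3, 1.5)
    depth: int = 100_000
    # taxon index -> log2 fold change applied in the second group.
    # Defaults sit on late-arriving (peripheral) taxa: differential species
    # and hub bacteria are largely distinct sets, and loading fold changes
    # onto hub nodes would confound the phenotype-hub coupling.
    differential: dict[int, float] = field(
        default_factory=lambda: {
            40: 2.0, 41: 2.0, 42: 2.0, 43: -2.0, 44: -2.0, 45: -2.0, 46: -2.0, 47: -2.0
        }
    )
    phenotypes: list[PhenotypeSpec] = field(
        default_factory=lambda: [
            PhenotypeSpec("FITC", taxa="hubs:5", coefficients=-1.0),
            PhenotypeSpec("ALT", taxa="hubs:5", coefficients=-1.0),
        ]
    )
    covariate_name: str = "body_weight"
    covariate_mean: float = 25.0
    covariate_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 10:
            raise ValueError("need at least 10 taxa")
        if self.n_per_group < 5:
            raise ValueError("need at least 5 samples per group")
        if not (0 < self.edge_correlation < 1):
            raise ValueError("edge correlation must lie in (0, 1)")
        labels = list(self.group_labels)
        if sorted(self.topology) != sorted(labels):
            raise ValueError("topology must name exactly the two group labels")


def default_config(**overrides) -> SyntheticConfig:
    return SyntheticConfig(**overrides)


@dataclass
class SyntheticStudy:
    table: AbundanceTable
    metadata: StudyMetadata
    planted_networks: dict[str, nx.Graph]
    planted_hubs: dict[str, HubSet]
    differential_taxa: dict[str, float]  # taxon name -> log2 fold change
    phenotype_coefficients: dict[str, dict[str, float]]
    latent_log_abundance: pd.DataFrame  # taxa x samples


def generate_planted_network(
    topology: str,
    n_taxa: int,
    param: float,
    seed: int | None = None,
    negative_edge_fraction: float = 0.3,
) -> nx.Graph:
    """Planted signed interaction graph.

    ``scale_free`` grows a preferential-attachment graph with ``param``
    edges per arriving node; ``random`` draws G(n, p).  Edge signs come
    from random per-node signs (edge sign = product of its endpoints'
    signs), calibrated so the marginal fraction of negative edges is
    ``negative_edge_fraction``.  Node-product signs are sign-consistent
    around every cycle, which keeps the signed correlation target
    realizable as a positive-definite matrix; independent per-edge signs
    would create frustrated cycles with no valid correlation matrix
    honouring them.
    """
    if topology == "scale_free":
        m = int(param)
        if m < 1 or m >= n_taxa:
            raise ValueError("edges per new node must satisfy 1 <= m < n_taxa")
        g = nx.barabasi_albert_graph(n_taxa, m, seed=seed)
    elif topology == "random":
        if not (0 < param < 1):
            raise ValueError("edge probability must lie in (0, 1)")
        g = nx.gnp_random_graph(n_taxa, param, seed=seed)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    if not (0 <= negative_edge_fraction <= 0.5):
        raise ValueError("negative_edge_fraction must lie in [0, 0.5] (node-product signs)")
    rng = np.random.default_rng(seed)
    # P(edge negative) = 2q(1-q) for node sign probability q
    q = (1.0 - np.sqrt(1.0 - 2.0 * negative_edge_fraction)) / 2.0
    for v in g.nodes:
        g.nodes[v]["sign"] = -1 if rng.random() < q else 1
    for u, v in g.edges:
        g.edges[u, v]["sign"] = g.nodes[u]["sign"] * g.nodes[v]["sign"]
    return g


def network_to_correlation(
    graph: nx.Graph, c: float, max_iter: int = 500
) -> np.ndarray:
    """Embed planted edges at magnitude c into a valid correlation matrix.

    Planted entries are held exactly at +/-c by alternating projections:
    project onto the positive-semidefinite cone (eigenvalue clipping at a
    small floor), then restore the planted entries and unit diagonal.
    The off-network entries are left free, so the procedure finds the
    minimal "fill-in" correlations that positive definiteness forces — a
    taxon correlated at c with k partners necessarily drags its partners
    into mutual correlation of about (k c^2 - 1)/(k - 1); no correlation
    matrix can plant strong hub edges without this fill.  If the
    projections have not converged a final clip-and-rescale guarantees
    positive definiteness; the result errors out if any planted entry
    then deviates from +/-c by more than c/2 (graph too dense for that
    correlation strength).
    """
    if not (0 < c < 1):
        raise ValueError("edge correlation magnitude must lie in (0, 1)")
    d = graph.number_of_nodes()
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    planted = np.zeros((d, d), dtype=bool)
    target = np.eye(d)
    for u, v, data in graph.edges(data=True):
        i, j = index[u], index[v]
        planted[i, j] = planted[j, i] = True
        target[i, j] = target[j, i] = c * data.get("sign", 1)
    current = target.copy()
    for iteration in range(max_iter):
        eigvals, eigvecs = np.linalg.eigh(current)
        if eigvals.min() >= PD_EIGEN_FLOOR and iteration > 0:
            break
        current = (eigvecs * np.maximum(eigvals, PD_EIGEN_FLOOR)) @ eigvecs.T
        current[planted] = target[planted]
        np.fill_diagonal(current, 1.0)
    if np.linalg.eigvalsh(current).min() < PD_EIGEN_FLOOR / 2:
        eigvals, eigvecs = np.linalg.eigh(current)
        current = (eigvecs * np.maximum(eigvals, PD_EIGEN_FLOOR)) @ eigvecs.T
        scale = 1.0 / np.sqrt(np.diag(current))
        current = current * np.outer(scale, scale)
        np.fill_diagonal(current, 1.0)
    deviation = float(np.max(np.abs(current[planted] - target[planted]), initial=0.0))
    if deviation > 0.5 * c:
        raise ValueError(
            f"positive-definite repair moved planted correlations by {deviation:.3f} "
            f"(> c/2 = {0.5 * c:.3f}); use a smaller c or a sparser graph"
        )
    return current


def generate_counts(
    correlation: np.ndarray,
    log_means: np.ndarray,
    log_vars: np.ndarray,
    n_samples: int,
    depth: int,
    log_shift: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent log-normal basis -> fractions -> multinomial counts.

    Per sample: latent log-abundance = log_means + log_shift +
    sqrt(log_vars) * z with z ~ MVN(0, correlation); fractions are the
    normalized exponentials and counts are multinomial at ``depth``.
    Returns (counts, latent log-abundances), both taxa x samples.
    """
    corr = np.asarray(correlation, dtype=float)
    d = corr.shape[0]
    if depth < 10 * d:
        warnings.warn(f"depth {depth} < 10 x {d} taxa: sparse counts will degrade inference")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    z = chol @ rng.standard_normal((d, n_samples))
    shift = np.zeros(d) if log_shift is None else np.asarray(log_shift, dtype=float)
    latent = (log_means + shift)[:, None] + np.sqrt(log_vars)[:, None] * z
    abundance = np.exp(latent)
    fractions = abundance / abundance.sum(axis=0, keepdims=True)
    counts = np.empty((d, n_samples), dtype=float)
    for j in range(n_samples):
        counts[:, j] = rng.multinomial(depth, fractions[:, j])
    return counts, latent


def _resolve_phenotype_taxa(
    spec: PhenotypeSpec,
    taxa_names: list[str],
    hubs_first_group: HubSet,
    first_corr: np.ndarray,
) -> tuple[list[str], list[float]]:
    if isinstance(spec.taxa, str):
        if not spec.taxa.startswith("hubs:"):
            raise KeyError(f"unknown taxa selector {spec.taxa!r}")
        k = int(spec.taxa.split(":")[1])
        ranked = sorted(hubs_first_group.hubs, key=lambda t: -hubs_first_group.degree[t])
        # grow a co-abundant hub guild: seed at the top-degree hub, then
        # repeatedly add the hub most positively correlated (on average)
        # with the guild so far.  A sign- or correlation-mixed hub set
        # cancels its own phenotype signal, which is not how barrier
        # markers track an interacting hub cluster.
        index = {t: i for i, t in enumerate(taxa_names)}
        taxa = ranked[:1]
        while len(taxa) < min(k, len(ranked)):
            rest = [t for t in ranked if t not in taxa]
            scores = [
                float(np.mean([first_corr[index[t], index[u]] for u in taxa])) for t in rest
            ]
            taxa.append(rest[int(np.argmax(scores))])
    else:
        missing = [t for t in spec.taxa if t not in set(taxa_names)]
        if missing:
            raise KeyError(f"phenotype taxa not in taxa list: {missing}")
        taxa = list(spec.taxa)
    coefs = spec.coefficients
    if np.isscalar(coefs):
        coefs = [float(coefs)] * len(taxa)
    if len(coefs) != len(taxa):
        raise ValueError("coefficient vector length must match designated taxa")
    return taxa, [float(cf) for cf in coefs]


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Build the full two-group synthetic study with recorded ground truth."""
    rng = np.random.default_rng(config.seed)
    d = config.n_taxa
    taxa_names = [f"sp{i:03d}" for i in range(d)]
    log_means = rng.uniform(*config.log_mean_range, size=d)
    log_vars = rng.uniform(*config.log_var_range, size=d)

    networks: dict[str, nx.Graph] = {}
    hubs: dict[str, HubSet] = {}
    corrs: dict[str, np.ndarray] = {}
    counts_by_group, latents_by_group, sample_ids = {}, {}, {}
    la, lb = config.group_labels
    shift_b = np.zeros(d)
    for idx, lfc in config.differential.items():
        shift_b[idx] = np.log(2.0) * lfc
    for label, shift in ((la, None), (lb, shift_b)):
        spec = config.topology[label]
        g = generate_planted_network(
            spec.kind,
            d,
            spec.param,
            seed=int(rng.integers(2**31 - 1)),
            negative_edge_fraction=config.negative_edge_fraction,
        )
        g = nx.relabel_nodes(g, dict(enumerate(taxa_names)))
        networks[label] = g
        hubs[label] = q3_hubs(dict(g.degree()))
        corr = network_to_correlation(g, config.edge_correlation)
        corrs[label] = corr
        counts, latent = generate_counts(
            corr,
            log_means,
            log_vars,
            config.n_per_group,
            config.depth,
            log_shift=shift,
            seed=int(rng.integers(2**31 - 1)),
        )
        counts_by_group[label] = counts
        latents_by_group[label] = latent
        sample_ids[label] = [f"{label}{j + 1:02d}" for j in range(config.n_per_group)]

    all_ids = sample_ids[la] + sample_ids[lb]
    counts = np.concatenate([counts_by_group[la], counts_by_group[lb]], axis=1)
    latent = np.concatenate([latents_by_group[la], latents_by_group[lb]], axis=1)
    table = AbundanceTable(taxa_names, all_ids, counts)
    latent_df = pd.DataFrame(latent, index=taxa_names, columns=all_ids)

    base_mean = dict(zip(taxa_names, log_means))
    base_sd = dict(zip(taxa_names, np.sqrt(log_vars)))
    pheno_cols: dict[str, np.ndarray] = {}
    pheno_coefs: dict[str, dict[str, float]] = {}
    for spec in config.phenotypes:
        taxa, coefs = _resolve_phenotype_taxa(spec, taxa_names, hubs[la], corrs[la])
        signal = spec.intercept + sum(
            cf * (latent_df.loc[t].to_numpy() - base_mean[t]) / base_sd[t]
            for t, cf in zip(taxa, coefs)
        )
        noise_sd = spec.noise_sd
        if noise_sd is None:
            noise_sd = float(np.std(signal)) or 1.0
        pheno_cols[spec.name] = signal + rng.normal(0.0, noise_sd, size=len(all_ids))
        pheno_coefs[spec.name] = dict(zip(taxa, coefs))

    covariate = rng.normal(config.covariate_mean, config.covariate_sd, size=len(all_ids))
    metadata = StudyMetadata(
        all_ids,
        pd.Series([la] * config.n_per_group + [lb] * config.n_per_group, index=all_ids),
        covariates=pd.DataFrame({config.covariate_name: covariate}, index=all_ids),
        phenotypes=pd.DataFrame(pheno_cols, index=all_ids),
    )
    differential_taxa = {taxa_names[i]: lfc for i, lfc in config.differential.items()}
    return SyntheticStudy(
        table, metadata, networks, hubs, differential_taxa, pheno_coefs, latent_df
    )
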