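"""Compositional co-occurrence network inference and topology analysis.

Sequencing counts carry only relative information, so naive correlations
between taxon fractions are spurious.  The inference here follows the
sparse log-ratio approach (SparCC): the variance of ln(x_i/x_j) between
two taxa decomposes as

    t_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j

where w_i^2 is the variance of the latent absolute log-abundance (the
"basis" variance) and rho_ij the basis correlation.  Under the sparsity
approximation (most pairs uncorrelated) the row sums of t give a linear
system for the basis variances, from which rho follows.  Strongly
correlated pairs, which violate the approximation, are excluded
iteratively and the system re-solved.  Sampling noise is handled by
averaging over Dirichlet-posterior fraction draws; significance by a
permutation test that destroys inter-taxon association while preserving
marginals.

Edges with |rho| above a threshold at a permutation p-value cutoff form
the co-occurrence network; hub taxa are nodes whose degree strictly
exceeds the third quartile (Q3) of the network's degree distribution.
Degree distributions are classified as scale-free (discrete power law)
versus random-graph-like (truncated Poisson) by maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import special, stats

from .tabio import AbundanceTable

__all__ = [
    "estimate_fractions",
    "logratio_variances",
    "solve_basis",
    "sparcc",
    "permutation_pvalues",
    "build_network",
    "topology_metrics",
    "classify_degree_model",
    "identify_hubs",
    "BasisEstimate",
    "CooccurrenceNetwork",
    "NetworkTopology",
    "HubSet",
]

MIN_TAXA = 4  # basis system is degenerate below 4 taxa
VARIANCE_FLOOR = 1e-8  # basis variances clipped here; floored pairs get rho = 0
DEFAULT_R_THRESHOLD = 0.4
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_N_DRAWS = 20
DEFAULT_EXCLUSION_THRESHOLD = 0.1
DEFAULT_MAX_EXCLUSION_ROUNDS = 10


# ---------------------------------------------------------------------------
# basis correlation inference
# ---------------------------------------------------------------------------

def _counts_matrix(counts) -> np.ndarray:
    if isinstance(counts, AbundanceTable):
        return counts.counts
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    return x


def estimate_fractions(counts, n_draws: int, seed: int | None = None) -> list[np.ndarray]:
    """Draw taxon fractions from the per-sample Dirichlet posterior.

    Each draw samples, independently per sample, fractions from
    Dirichlet(counts + 1) — a flat prior pseudocount of 1 on every taxon,
    so zero counts still get strictly positive fractions.  Returns
    ``n_draws`` matrices of shape (taxa, samples) whose columns sum to 1.
    """
    x = _counts_matrix(counts)
    d, n = x.shape
    if d < MIN_TAXA:
        raise ValueError(
            f"need at least {MIN_TAXA} taxa: the basis variance system is "
            f"degenerate for fewer (got {d})"
        )
    rng = np.random.default_rng(seed)
    alpha = x + 1.0
    draws = []
    for _ in range(n_draws):
        g = rng.standard_gamma(alpha)  # Dirichlet via normalized gammas
        draws.append(g / g.sum(axis=0, keepdims=True))
    return draws


def logratio_variances(fractions: np.ndarray) -> np.ndarray:
    """Matrix T of log-ratio variances t_ij = Var[ln(x_i/x_j)] (ddof 1).

    Computed from the covariance matrix of log fractions:
    t_ij = c_ii + c_jj - 2 c_ij, so the D*(D-1)/2 variances cost one
    covariance evaluation.
    """
    x = np.asarray(fractions, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fractions must be strictly positive")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples for log-ratio variances")
    c = np.cov(np.log(x), ddof=1)
    v = np.diag(c)
    t = v[:, None] + v[None, :] - 2.0 * c
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


@dataclass
class BasisEstimate:
    """Basis variances and correlations recovered from log-ratio variances."""

    omega_sq: np.ndarray
    rho: np.ndarray
    excluded_pairs: frozenset = field(default_factory=frozenset)


def solve_basis(t: np.ndarray, excluded_pairs=()) -> BasisEstimate:
    """Solve the sparsity-approximation system for basis variances.

    With row sums t_i over allowed partners and d_i allowed partners per
    taxon, solves t_i = d_i w_i^2 + sum_{j allowed} w_j^2 (the symmetric
    closed form is the (D-2)I + J system when nothing is excluded; least
    squares otherwise).  Non-positive solutions are clipped to a small
    floor, and rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j), clipped to
    [-1, 1]; pairs involving a floored variance get rho = 0.
    """
    t = np.asarray(t, dtype=float)
    d = t.shape[0]
    if d < MIN_TAXA:
        raise ValueError(f"need at least {MIN_TAXA} taxa")
    allowed = np.ones((d, d), dtype=bool)
    np.fill_diagonal(allowed, False)
    for i, j in excluded_pairs:
        allowed[i, j] = allowed[j, i] = False
    partners = allowed.sum(axis=1)
    a = allowed.astype(float)
    a[np.diag_indices(d)] = partners
    ti = (t * allowed).sum(axis=1)
    if np.linalg.matrix_rank(a) < d:
        raise np.linalg.LinAlgError(
            "basis system rank-deficient after exclusions; reduce the number "
            "of excluded pairs or the exclusion rounds"
        )
    if not excluded_pairs:
        omega_sq = np.linalg.solve(a, ti)
    else:
        omega_sq, *_ = np.linalg.lstsq(a, ti, rcond=None)
    floored = omega_sq < VARIANCE_FLOOR
    omega_sq = np.maximum(omega_sq, VARIANCE_FLOOR)
    w = np.sqrt(omega_sq)
    rho = (omega_sq[:, None] + omega_sq[None, :] - t) / (2.0 * np.outer(w, w))
    rho = np.clip(rho, -1.0, 1.0)
    if floored.any():
        rho[floored, :] = 0.0
        rho[:, floored] = 0.0
    np.fill_diagonal(rho, 1.0)
    return BasisEstimate(omega_sq, rho, frozenset(frozenset(p) for p in excluded_pairs))


def _sparcc_single(
    t: np.ndarray,
    exclusion_threshold: float,
    max_exclusion_rounds: int,
) -> np.ndarray:
    """One basis solve with iterative exclusion of the strongest pair."""
    d = t.shape[0]
    excluded: list[tuple[int, int]] = []
    est = solve_basis(t)
    for _ in range(max_exclusion_rounds):
        masked = np.abs(est.rho.copy())
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] < exclusion_threshold:
            break
        excluded.append((int(i), int(j)))
        try:
            est = solve_basis(t, excluded)
        except np.linalg.LinAlgError:
            excluded.pop()
            break
    return est.rho


def sparcc(
    counts,
    n_draws: int = DEFAULT_N_DRAWS,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    max_exclusion_rounds: int = DEFAULT_MAX_EXCLUSION_ROUNDS,
    seed: int | None = None,
) -> np.ndarray:
    """Basis correlation matrix from counts, median over posterior draws.

    Each Dirichlet fraction draw yields one basis solution with iterative
    strong-pair exclusion; the reported rho is the elementwise median
    across draws (robust to occasional skewed solutions), symmetrized
    with unit diagonal.
    """
    draws = estimate_fractions(counts, n_draws, seed=seed)
    rhos = np.stack(
        [
            _sparcc_single(logratio_variances(f), exclusion_threshold, max_exclusion_rounds)
            for f in draws
        ]
    )
    rho = np.median(rhos, axis=0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return rho


def permutation_pvalues(
    counts,
    observed_rho: np.ndarray,
    n_perm: int = 100,
    seed: int | None = None,
    n_draws: int = 1,
) -> np.ndarray:
    """Two-sided permutation pseudo p-values for each taxon pair.

    Each permutation independently shuffles every taxon's counts across
    samples (destroying inter-taxon association, preserving marginals)
    and recomputes rho — with a single fraction draw by default, which is
    sufficient for the null distribution of |rho|.  The add-one estimator
    p = (1 + #{|rho*| >= |rho|}) / (1 + n_perm) keeps p in (0, 1].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = _counts_matrix(counts)
    d, n = x.shape
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(observed_rho)
    exceed = np.zeros((d, d), dtype=int)
    for _ in range(n_perm):
        perm = np.empty_like(x)
        for i in range(d):
            perm[i] = x[i, rng.permutation(n)]
        rho_perm = sparcc(perm, n_draws=n_draws, seed=int(rng.integers(2**31 - 1)))
        exceed += np.abs(rho_perm) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.minimum(p, 1.0)
    p = np.minimum(p, p.T)
    np.fill_diagonal(p, 1.0)
    return p


# ---------------------------------------------------------------------------
# network construction, topology, hubs
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceNetwork:
    """Signed thresholded graph over taxa.

    Edges carry ``rho``, ``p`` and ``sign`` attributes; ``degree`` maps
    every node to its integer degree.
    """

    graph: nx.Graph
    r_threshold: float
    p_threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return [
            (u, v, d["rho"], d["p"], d["sign"]) for u, v, d in self.graph.edges(data=True)
        ]

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())


def build_network(
    rho: np.ndarray,
    pvals: np.ndarray,
    taxa: list[str] | None = None,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    keep_isolated: bool = False,
) -> CooccurrenceNetwork:
    """Threshold correlations into a signed co-occurrence network.

    An edge joins i and j iff |rho_ij| > r_threshold and p_ij <
    p_threshold (both strict, as the filtering rule is stated); the edge
    sign is the sign of rho.  Isolated taxa are excluded unless
    ``keep_isolated``.
    """
    rho = np.asarray(rho, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    if rho.shape != pvals.shape or rho.shape[0] != rho.shape[1]:
        raise ValueError("rho and pvals must be square matrices of equal shape")
    if not (0 < r_threshold < 1) or not (0 < p_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    d = rho.shape[0]
    if taxa is None:
        taxa = [f"t{i}" for i in range(d)]
    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(taxa)
    for i in range(d):
        for j in range(i + 1, d):
            if abs(rho[i, j]) > r_threshold and pvals[i, j] < p_threshold:
                g.add_edge(
                    taxa[i],
                    taxa[j],
                    rho=float(rho[i, j]),
                    p=float(pvals[i, j]),
                    sign=int(np.sign(rho[i, j])),
                )
    return CooccurrenceNetwork(g, r_threshold, p_threshold)


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    average_degree: float
    transitivity: float
    mean_local_clustering: float
    degree_histogram: list[int]
    power_law_alpha: float | None = None
    power_law_loglik: float | None = None
    poisson_lambda: float | None = None
    poisson_loglik: float | None = None
    degree_model: str | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def topology_metrics(network, k_min: int = 1) -> NetworkTopology:
    """Global topology summary plus the degree-model classification.

    Transitivity is 3 x triangles / connected triples; the mean local
    clustering coefficient counts nodes of degree < 2 as 0.  The degree
    model (power law vs truncated Poisson) is fitted when at least 10
    nodes have degree >= k_min, otherwise left unclassified.
    """
    g = network.graph if isinstance(network, CooccurrenceNetwork) else network
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return NetworkTopology(0, 0, 0.0, 0.0, 0.0, [])
    degrees = np.array([d for _, d in g.degree()], dtype=int)
    topo = NetworkTopology(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        transitivity=float(nx.transitivity(g)),
        mean_local_clustering=float(nx.average_clustering(g, count_zeros=True)),
        degree_histogram=np.bincount(degrees).tolist(),
    )
    if int((degrees >= k_min).sum()) >= 10:
        fit = classify_degree_model(degrees, k_min=k_min)
        topo.power_law_alpha = fit.alpha
        topo.power_law_loglik = fit.power_law_loglik
        topo.poisson_lambda = fit.lam
        topo.poisson_loglik = fit.poisson_loglik
        topo.degree_model = fit.model
    return topo


@dataclass
class DegreeModelFit:
    alpha: float
    lam: float
    model: str
    power_law_loglik: float
    poisson_loglik: float


def _power_law_loglik(ks: np.ndarray, alpha: float, k_min: int) -> float:
    # discrete power law p(k) = k^-alpha / zeta(alpha, k_min)
    return float(-alpha * np.log(ks).sum() - ks.size * np.log(special.zeta(alpha, k_min)))


def _truncated_poisson_loglik(ks: np.ndarray, lam: float, k_min: int) -> float:
    # Poisson restricted to k >= k_min (zero-truncated when k_min = 1)
    norm = stats.poisson.sf(k_min - 1, lam)
    return float(
        (ks * np.log(lam)).sum()
        - lam * ks.size
        - special.gammaln(ks + 1).sum()
        - ks.size * np.log(norm)
    )


def _truncated_poisson_mle(ks: np.ndarray, k_min: int, tol: float = 1e-10) -> float:
    """Newton iteration on the truncated-Poisson score equation.

    Score: mean(k)/lam - 1 - pmf(k_min-1; lam)/sf(k_min-1; lam) = 0,
    using d/dlam P(K >= k_min) = pmf(k_min - 1; lam).
    """
    mean_k = float(ks.mean())
    lam = max(mean_k - k_min + 0.5, 0.1)  # start below the truncated mean
    for _ in range(100):
        sf = stats.poisson.sf(k_min - 1, lam)
        pmf = stats.poisson.pmf(k_min - 1, lam)
        score = mean_k / lam - 1.0 - pmf / sf
        h = max(1e-6, 1e-6 * lam)
        sf2 = stats.poisson.sf(k_min - 1, lam + h)
        pmf2 = stats.poisson.pmf(k_min - 1, lam + h)
        score2 = mean_k / (lam + h) - 1.0 - pmf2 / sf2
        deriv = (score2 - score) / h
        if deriv == 0:
            break
        step = score / deriv
        lam_new = lam - step
        if lam_new <= 0:
            lam_new = lam / 2.0
        if abs(lam_new - lam) < tol * max(1.0, lam):
            lam = lam_new
            break
        lam = lam_new
    return float(lam)


def classify_degree_model(degrees, k_min: int | None = None) -> DegreeModelFit:
    """Fit and compare power-law and truncated-Poisson degree models.

    The discrete power-law MLE is
    alpha = 1 + n / sum(ln(k_i / (k_min - 0.5))) with the Hurwitz-zeta
    normalized log-likelihood; the Poisson competitor is truncated to the
    same support k >= k_min with lambda from Newton iteration.  The model
    with the higher small-sample AIC-corrected log-likelihood wins; a
    scale-free degree sequence has heavy right tail, a random graph's is
    concentrated near its mean.

    ``k_min`` defaults to the smallest positive observed degree, so both
    candidate distributions share exactly the support the data occupy —
    a power law anchored below the observed minimum wastes probability
    mass on degrees that never occur and biases the comparison toward
    the Poisson.
    """
    ks = np.asarray(degrees, dtype=int)
    if k_min is None:
        positive = ks[ks >= 1]
        if positive.size == 0:
            raise ValueError("no nodes with positive degree")
        k_min = int(positive.min())
    ks = ks[ks >= k_min]
    if ks.size < 10:
        raise ValueError("need at least 10 nodes with degree >= k_min")
    n = ks.size
    lam = _truncated_poisson_mle(ks, k_min)
    pois_ll = _truncated_poisson_loglik(ks, lam, k_min)
    if np.ptp(ks) == 0:
        warnings.warn("all degrees equal: power-law fit degenerate; classifying as poisson")
        alpha = 1.0 + n / float(np.log(ks / (k_min - 0.5)).sum())
        return DegreeModelFit(alpha, lam, "poisson", _power_law_loglik(ks, alpha, k_min), pois_ll)
    alpha = 1.0 + n / float(np.log(ks / (k_min - 0.5)).sum())
    pl_ll = _power_law_loglik(ks, alpha, k_min)
    # both models have one parameter; AICc correction 2k(k+1)/(n-k-1), k=1
    correction = 1.0 + 2.0 / (n - 2)
    model = "power_law" if pl_ll - correction >= pois_ll - correction else "poisson"
    return DegreeModelFit(float(alpha), float(lam), model, pl_ll, pois_ll)


@dataclass
class HubSet:
    """Hub taxa: degree strictly above the third quartile of all degrees."""

    q3: float
    hubs: list[str]
    degree: dict[str, int]


def q3_hubs(degree: dict[str, int]) -> HubSet:
    """Strict-Q3 hub rule on a degree map (type-7 interpolated quantile)."""
    if not degree:
        raise ValueError("empty degree map")
    values = np.array(list(degree.values()), dtype=float)
    q3 = float(np.quantile(values, 0.75))  # linear interpolation (type 7)
    hubs = [node for node, k in degree.items() if k > q3]
    return HubSet(q3, hubs, dict(degree))


def identify_hubs(network) -> HubSet:
    """Hub bacteria of a co-occurrence network (degree strictly > Q3)."""
    if isinstance(network, CooccurrenceNetwork):
        degree = network.degree
    else:
        degree = dict(network.degree())
    if len(degree) < MIN_TAXA:
        raise ValueError("need at least 4 network nodes for a quartile-based hub rule")
    return q3_hubs(degree)
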