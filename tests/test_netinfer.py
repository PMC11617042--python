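"""Compositional correlation inference, network construction, topology, hubs."""

import networkx as nx
import numpy as np
import pytest

from mucohub.netinfer import (
    build_network,
    classify_degree_model,
    estimate_fractions,
    identify_hubs,
    logratio_variances,
    permutation_pvalues,
    q3_hubs,
    solve_basis,
    sparcc,
    topology_metrics,
)


# ---------------------------------------------------------------- fractions

def test_fractions_sum_to_one_and_deterministic():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 200, size=(6, 10))
    draws1 = estimate_fractions(counts, n_draws=3, seed=42)
    draws2 = estimate_fractions(counts, n_draws=3, seed=42)
    for f1, f2 in zip(draws1, draws2):
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_allclose(f1.sum(axis=0), 1.0, atol=1e-12)
        assert (f1 > 0).all()


def test_fractions_prior_only_for_zero_sample():
    counts = np.zeros((5, 4))
    counts[:, 1:] = 50
    draws = np.stack([f[:, 0] for f in estimate_fractions(counts, n_draws=400, seed=1)])
    # flat Dirichlet(1,...,1) posterior: mean fraction 1/D per taxon
    np.testing.assert_allclose(draws.mean(axis=0), 0.2, atol=0.02)


def test_fractions_reject_too_few_taxa():
    with pytest.raises(ValueError, match="degenerate"):
        estimate_fractions(np.ones((3, 10)), n_draws=1, seed=0)


# ---------------------------------------------------------- logratio variances

def test_logratio_variance_hand_case():
    # ln(x0/x1) over samples = {0, 2, 1}  ->  sample variance 1.0
    x1 = np.array([0.5, 0.2, 0.3])
    x0 = x1 * np.exp([0.0, 2.0, 1.0])
    frac = np.vstack([x0, x1])
    t = logratio_variances(frac / frac.sum(axis=0))
    assert t[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert t[1, 0] == t[0, 1] and t[0, 0] == 0.0


def test_logratio_variance_proportional_taxa_is_zero():
    rng = np.random.default_rng(2)
    base = rng.uniform(0.1, 1.0, size=(4, 8))
    base[1] = base[0] * 3.7  # x1 proportional to x0
    t = logratio_variances(base / base.sum(axis=0))
    assert t[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_logratio_variance_needs_three_samples():
    with pytest.raises(ValueError):
        logratio_variances(np.full((4, 2), 0.25))


# ------------------------------------------------------------------- basis

def test_solve_basis_algebraic_oracle_d4():
    t = np.full((4, 4), 2.0)
    np.fill_diagonal(t, 0.0)
    t[0, 1] = t[1, 0] = 1.0
    est = solve_basis(t)
    np.testing.assert_allclose(est.omega_sq, [2 / 3, 2 / 3, 7 / 6, 7 / 6], atol=1e-9)
    assert est.rho[0, 1] == pytest.approx(0.25, abs=1e-9)


def test_solve_basis_matches_symmetric_closed_form():
    """No exclusions: the system is ((D-2)I + J) omega^2 = row sums of T."""
    rng = np.random.default_rng(3)
    d = 7
    a = rng.uniform(0.5, 2.0, size=(d, d))
    t = (a + a.T) / 2
    np.fill_diagonal(t, 0.0)
    est = solve_basis(t)
    system = (d - 2) * np.eye(d) + np.ones((d, d))
    expected = np.linalg.solve(system, t.sum(axis=1))
    np.testing.assert_allclose(est.omega_sq, np.maximum(expected, 1e-8), atol=1e-10)


def test_solve_basis_exchangeable_taxa_symmetry():
    t = np.full((5, 5), 1.3)
    np.fill_diagonal(t, 0.0)
    est = solve_basis(t)
    off = est.rho[~np.eye(5, dtype=bool)]
    assert np.allclose(off, off[0])


def test_solve_basis_null_simulation_recovers_independence():
    rng = np.random.default_rng(4)
    d, n = 12, 4000
    latent = rng.normal(0, 1, size=(d, n)) * rng.uniform(0.8, 1.4, size=(d, 1))
    frac = np.exp(latent)
    frac /= frac.sum(axis=0)
    est = solve_basis(logratio_variances(frac))
    off = np.abs(est.rho[~np.eye(d, dtype=bool)])
    assert off.mean() < 0.05


# ------------------------------------------------------------------- sparcc

def test_sparcc_deterministic_given_seed():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 500, size=(10, 20))
    r1 = sparcc(counts, n_draws=5, seed=7)
    r2 = sparcc(counts, n_draws=5, seed=7)
    np.testing.assert_array_equal(r1, r2)
    assert np.allclose(r1, r1.T) and np.allclose(np.diag(r1), 1.0)


def test_sparcc_scale_invariance():
    """Multiplying one sample's counts by a constant leaves rho unchanged
    up to the Dirichlet pseudocount (compositional contract), exactly so
    for the variance statistic on fixed fractions."""
    rng = np.random.default_rng(6)
    counts = rng.integers(1, 300, size=(8, 12)).astype(float)
    frac = counts / counts.sum(axis=0)
    t1 = logratio_variances(frac)
    scaled = counts.copy()
    scaled[:, 3] *= 50
    t2 = logratio_variances(scaled / scaled.sum(axis=0))
    np.testing.assert_allclose(t1, t2, atol=1e-12)


def test_sparcc_detects_planted_pair():
    rng = np.random.default_rng(7)
    d, n = 10, 60
    cov = np.eye(d)
    cov[0, 1] = cov[1, 0] = 0.8
    latent = np.linalg.cholesky(cov) @ rng.standard_normal((d, n)) + 2.0
    frac = np.exp(latent)
    frac /= frac.sum(axis=0)
    counts = np.vstack([rng.multinomial(50_000, frac[:, j]) for j in range(n)]).T
    rho = sparcc(counts, seed=8)
    off = np.abs(rho.copy())
    np.fill_diagonal(off, 0.0)
    assert np.unravel_index(np.argmax(off), off.shape) in {(0, 1), (1, 0)}


def test_permutation_pvalue_bounds():
    rng = np.random.default_rng(9)
    counts = rng.integers(1, 400, size=(6, 15))
    # observed rho of zero can never beat permuted magnitudes -> p = 1
    p_zero = permutation_pvalues(counts, np.zeros((6, 6)), n_perm=19, seed=0)
    off = ~np.eye(6, dtype=bool)
    assert np.allclose(p_zero[off], 1.0)
    # observed magnitude beyond anything attainable -> add-one floor 1/(n_perm+1)
    # (permuted estimates clip at |rho| = 1, so 1.5 is strictly unbeatable)
    p_floor = permutation_pvalues(counts, np.full((6, 6), 1.5), n_perm=19, seed=0)
    assert np.allclose(p_floor[off], 1 / 20)
    with pytest.raises(ValueError):
        permutation_pvalues(counts, np.zeros((6, 6)), n_perm=0, seed=0)


# ------------------------------------------------------------------ network

def test_build_network_edge_rule():
    rho = np.eye(3)
    rho[0, 1] = rho[1, 0] = 0.5
    rho[0, 2] = rho[2, 0] = 0.3
    rho[1, 2] = rho[2, 1] = 0.9
    p = np.full((3, 3), 0.01)
    p[1, 2] = p[2, 1] = 0.20
    net = build_network(rho, p, taxa=["a", "b", "c"])
    assert net.edges == [("a", "b", 0.5, 0.01, 1)]
    assert net.nodes == ["a", "b"]  # isolated c dropped by default


def test_build_network_negative_edge_and_empty():
    rho = np.eye(2)
    rho[0, 1] = rho[1, 0] = -0.45
    p = np.full((2, 2), 0.01)
    net = build_network(rho, p, taxa=["x", "y"])
    assert net.edges[0][4] == -1
    empty = build_network(np.eye(4), np.full((4, 4), 0.01), taxa=list("abcd"))
    assert empty.edges == [] and empty.nodes == []
    kept = build_network(np.eye(4), np.full((4, 4), 0.01), taxa=list("abcd"), keep_isolated=True)
    assert kept.nodes == list("abcd")


def test_build_network_monotone_in_thresholds():
    rng = np.random.default_rng(10)
    d = 12
    a = rng.uniform(-1, 1, size=(d, d))
    rho = (a + a.T) / 2
    np.fill_diagonal(rho, 1.0)
    p = np.abs((a - a.T) / 2)
    p = (p + p.T) / 2
    edges = [
        len(build_network(rho, p, r_threshold=r, p_threshold=0.3).edges)
        for r in (0.2, 0.4, 0.6, 0.8)
    ]
    assert edges == sorted(edges, reverse=True)
    with pytest.raises(ValueError):
        build_network(rho, p, r_threshold=1.5)


def test_topology_metrics_small_graphs():
    tri = topology_metrics(nx.complete_graph(3))
    assert (tri.n_nodes, tri.n_edges, tri.average_degree, tri.transitivity) == (3, 3, 2.0, 1.0)
    star = topology_metrics(nx.star_graph(3))  # 4 nodes, 3 edges
    assert star.transitivity == 0.0
    assert star.average_degree == pytest.approx(1.5)
    path = topology_metrics(nx.path_graph(3))
    assert path.transitivity == 0.0 and path.mean_local_clustering == 0.0
    empty = topology_metrics(nx.Graph())
    assert empty.n_nodes == 0 and empty.degree_histogram == []


# ------------------------------------------------------------ degree models

def test_power_law_mle_formula():
    fit = classify_degree_model([1, 1, 1, 10] * 3, k_min=1)
    expected = 1 + 12 / sum(np.log(2 * np.array([1, 1, 1, 10] * 3)))
    assert fit.alpha == pytest.approx(expected, abs=1e-9)
    assert fit.alpha == pytest.approx(1.788, abs=0.02)


def test_degree_model_simulation_oracles():
    rng = np.random.default_rng(11)
    pois = classify_degree_model(rng.poisson(5, 500))
    assert pois.model == "poisson"
    assert pois.lam == pytest.approx(5.0, abs=0.3)
    ba = nx.barabasi_albert_graph(300, 2, seed=12)
    assert classify_degree_model([d for _, d in ba.degree()]).model == "power_law"


def test_degree_model_degenerate_equal_degrees():
    with pytest.warns(UserWarning, match="degenerate"):
        fit = classify_degree_model([3] * 20)
    assert fit.model == "poisson"


def test_degree_model_needs_ten_nodes():
    with pytest.raises(ValueError):
        classify_degree_model([1, 2, 3])


# -------------------------------------------------------------------- hubs

def test_hub_rule_interpolated_quantile():
    degree = dict(zip("abcdefgh", [1, 1, 2, 2, 3, 3, 10, 12]))
    hs = q3_hubs(degree)
    assert hs.q3 == pytest.approx(4.75)
    assert sorted(hs.hubs) == ["g", "h"]

    hs2 = q3_hubs(dict(zip("abcd", [1, 2, 3, 100])))
    assert hs2.q3 == pytest.approx(27.25)
    assert hs2.hubs == ["d"]


def test_hub_rule_strictness_and_relabeling_invariance():
    assert q3_hubs({c: 4 for c in "abcdef"}).hubs == []  # nothing strictly exceeds q3
    degree = dict(zip("abcdefgh", [1, 1, 2, 2, 3, 3, 10, 12]))
    relabeled = {k.upper(): v for k, v in degree.items()}
    assert sorted(h.lower() for h in q3_hubs(relabeled).hubs) == sorted(q3_hubs(degree).hubs)


def test_identify_hubs_contract():
    g = nx.star_graph(5)
    hs = identify_hubs(g)
    degs = dict(g.degree())
    assert all(degs[h] > hs.q3 for h in hs.hubs)
    assert all(degs[n] <= hs.q3 for n in g.nodes if n not in hs.hubs)
    with pytest.raises(ValueError):
        identify_hubs(nx.path_graph(2))
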