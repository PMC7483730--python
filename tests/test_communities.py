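"""Multilayer modularity, Louvain optimisation, shuffled null and the
(gamma, omega) sweep, checked against independent brute-force oracles."""

import numpy as np
import pytest

from commdyn import (
    DynamicCommunityModel,
    GroundTruthSpec,
    exhaustive_best_partition,
    flexibility,
    generate_regional_bold,
    log_grid,
    louvain_optimize,
    multilayer_modularity,
    parameter_sweep,
    shuffle_null,
    windowed_band_coherence,
    zrand,
)
from commdyn.errors import ConfigError, ConvergenceError, DegenerateLayerError


def brute_force_q(layers, labels, gamma, omega):
    """Direct quadruple-sum evaluation of the quality function (test oracle,
    independent of the package's vectorised evaluator)."""
    layers = np.asarray(layers, float)
    labels = np.asarray(labels)
    L, N = layers.shape[:2]
    q = 0.0
    two_mu = 0.0
    for l in range(L):
        A = layers[l]
        k = A.sum(axis=1)
        two_m = k.sum()
        two_mu += two_m
        for i in range(N):
            for j in range(N):
                if labels[l, i] == labels[l, j]:
                    q += A[i, j] - gamma * k[i] * k[j] / two_m
    for l in range(L):
        for r in range(L):
            if abs(l - r) == 1:
                for i in range(N):
                    if labels[l, i] == labels[r, i]:
                        q += omega
    if L > 1:
        two_mu += 2.0 * omega * N * (L - 1)
    return q / two_mu


def random_stack(rng, n, n_layers):
    layers = []
    for _ in range(n_layers):
        w = rng.uniform(0, 1, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        layers.append(w)
    return np.stack(layers)


# ----------------------------------------------------------------------
# Q evaluator
# ----------------------------------------------------------------------

@pytest.mark.parametrize("seed,n,n_layers,gamma,omega", [
    (0, 5, 2, 1.0, 0.7),
    (1, 4, 3, 0.8, 1.5),
    (2, 6, 2, 1.3, 0.0),
])
def test_q_matches_brute_force_on_random_stacks(seed, n, n_layers, gamma, omega):
    rng = np.random.default_rng(seed)
    layers = random_stack(rng, n, n_layers)
    labels = rng.integers(1, 4, size=(n_layers, n))
    assert multilayer_modularity(layers, labels, gamma, omega) == pytest.approx(
        brute_force_q(layers, labels, gamma, omega), abs=1e-12
    )


def test_q_two_disconnected_cliques():
    A = np.zeros((8, 8))
    A[:4, :4] = 1.0
    A[4:, 4:] = 1.0
    np.fill_diagonal(A, 0.0)
    labels = np.array([[1, 1, 1, 1, 2, 2, 2, 2]])
    q = multilayer_modularity(A[None], labels, 1.0, 0.0)
    assert q == pytest.approx(brute_force_q(A[None], labels, 1.0, 0.0), abs=1e-12)
    assert q == pytest.approx(0.5)  # two equal disconnected blocks


def test_q_single_community_is_zero(rng):
    layers = random_stack(rng, 6, 1)
    labels = np.ones((1, 6), dtype=int)
    assert multilayer_modularity(layers, labels, 1.0, 0.0) == pytest.approx(0.0, abs=1e-12)


def test_q_duplicated_layers_with_zero_coupling_equals_single_layer(rng):
    layers = random_stack(rng, 5, 1)
    doubled = np.concatenate([layers, layers])
    labels = np.random.default_rng(3).integers(1, 3, size=(1, 5))
    both = np.vstack([labels, labels])
    q1 = multilayer_modularity(layers, labels, 1.0, 0.0)
    q2 = multilayer_modularity(doubled, both, 1.0, 0.0)
    assert q2 == pytest.approx(q1, abs=1e-12)
    assert q2 == pytest.approx(brute_force_q(doubled, both, 1.0, 0.0), abs=1e-12)


def test_degenerate_layer_rejected():
    layers = np.zeros((1, 4, 4))
    with pytest.raises(DegenerateLayerError):
        multilayer_modularity(layers, np.ones((1, 4), int), 1.0, 0.0)


# ----------------------------------------------------------------------
# Louvain
# ----------------------------------------------------------------------

def test_louvain_toy_stack_reaches_exhaustive_optimum():
    block = np.full((6, 6), 0.05)
    block[:3, :3] = 1.0
    block[3:, 3:] = 1.0
    np.fill_diagonal(block, 0.0)
    layers = np.stack([block, block])
    exact = exhaustive_best_partition(layers, 1.0, 0.5)
    best = max(
        louvain_optimize(layers, 1.0, 0.5, seed=s).q for s in range(20)
    )
    assert best == pytest.approx(exact.q, abs=1e-12)
    # the planted 2-block structure is the optimum
    assert exact.labels.shape == (2, 6)
    assert len(np.unique(exact.labels)) == 2


def test_louvain_same_seed_same_partition(planted_stack):
    stack, _, _ = planted_stack
    a = louvain_optimize(stack, 1.0, 1.0, seed=5)
    b = louvain_optimize(stack, 1.0, 1.0, seed=5)
    assert np.array_equal(a.labels, b.labels)
    assert a.q == b.q


def test_louvain_result_is_single_move_optimal(rng):
    """No single node-layer move to any other existing community improves Q
    (local optimality of the greedy fixed point)."""
    layers = random_stack(rng, 6, 2)
    part = louvain_optimize(layers, 1.0, 0.5, seed=9)
    base_q = part.q
    all_labels = np.unique(part.labels)
    for l in range(2):
        for i in range(6):
            for c in all_labels:
                if c == part.labels[l, i]:
                    continue
                trial = part.labels.copy()
                trial[l, i] = c
                assert multilayer_modularity(layers, trial, 1.0, 0.5) <= base_q + 1e-10


def test_louvain_seeded_from_planted_never_degrades(planted_stack):
    stack, planted, _ = planted_stack
    q_planted = multilayer_modularity(stack.layers, planted, 1.0, 1.0)
    part = louvain_optimize(stack, 1.0, 1.0, seed=2, initial_labels=planted)
    assert part.q >= q_planted - 1e-12


def test_louvain_recovers_planted_structure_above_permutation_null(planted_stack):
    stack, planted, _ = planted_stack
    part = louvain_optimize(stack, 1.0, 1.0, seed=0)
    z_obs = zrand(part.labels[0], planted[0])
    rng = np.random.default_rng(17)
    null = np.array([
        zrand(part.labels[0][rng.permutation(stack.n_nodes)], planted[0])
        for _ in range(1000)
    ])
    assert z_obs > np.quantile(null, 0.95)


def test_louvain_iteration_cap_raises(rng):
    layers = random_stack(rng, 8, 2)
    with pytest.raises(ConvergenceError):
        louvain_optimize(layers, 1.0, 0.5, seed=0, max_sweeps=1)


def test_exhaustive_guard_rails(rng):
    with pytest.raises(ConfigError):
        exhaustive_best_partition(random_stack(rng, 7, 1), 1.0, 0.0)
    with pytest.raises(ConfigError):
        exhaustive_best_partition(random_stack(rng, 4, 3), 1.0, 0.5)


# ----------------------------------------------------------------------
# shuffled null
# ----------------------------------------------------------------------

def test_shuffle_preserves_weight_multiset(planted_stack):
    stack, _, _ = planted_stack
    null = shuffle_null(stack, seed=0)
    iu = np.triu_indices(stack.n_nodes, k=1)
    for l in range(stack.n_layers):
        assert np.allclose(
            np.sort(stack.layers[l][iu]), np.sort(null.layers[l][iu])
        )
        assert np.allclose(null.layers[l], null.layers[l].T)
        assert np.all(np.diag(null.layers[l]) == 0)


def test_shuffle_is_uniform_over_permutations():
    """On a 3-node layer (3 edges) all 6 permutations occur equally often."""
    layer = np.zeros((1, 3, 3))
    vals = [1.0, 2.0, 3.0]
    iu = np.triu_indices(3, k=1)
    layer[0][iu] = vals
    layer[0] += layer[0].T
    counts = {}
    rng = np.random.default_rng(123)
    n_shuffles = 6000
    for _ in range(n_shuffles):
        out = shuffle_null(layer, seed=int(rng.integers(0, 2**31 - 1)))
        key = tuple(out[0][iu])
        counts[key] = counts.get(key, 0) + 1
    assert len(counts) == 6
    expected = n_shuffles / 6
    sigma = np.sqrt(n_shuffles * (1 / 6) * (5 / 6))
    for c in counts.values():
        assert abs(c - expected) < 3 * sigma


def test_shuffled_stack_has_lower_q_than_planted_structure(planted_stack):
    stack, _, _ = planted_stack
    q_obs = np.mean([louvain_optimize(stack, 1.0, 1.0, seed=s).q for s in range(3)])
    q_null = np.mean([
        louvain_optimize(shuffle_null(stack, seed=s), 1.0, 1.0, seed=s).q
        for s in range(3)
    ])
    assert q_obs > q_null


# ----------------------------------------------------------------------
# parameter sweep
# ----------------------------------------------------------------------

def test_log_grid_matches_printed_convention():
    g = log_grid()
    assert g.size == 20
    assert g[0] == pytest.approx(0.25, abs=0.005)
    assert g[-1] == pytest.approx(31.62, abs=0.005)
    ratios = g[1:] / g[:-1]
    assert np.allclose(ratios, ratios[0])


def test_sweep_self_null_difference_is_noise(planted_stack):
    stack, _, _ = planted_stack
    # observed stack is itself a shuffled stack: observed - null ~ 0
    pre_shuffled = shuffle_null(stack, seed=99)
    surface = parameter_sweep(
        [pre_shuffled],
        gamma_grid=np.array([0.8, 1.2]),
        omega_grid=np.array([0.5, 1.5]),
        runs_per_cell=8,
        seed=5,
    )
    # 1e-12 floor: cells where every run finds the identical optimum differ
    # only by floating-point accumulation order
    assert np.all(np.abs(surface.diff) <= 2 * surface.se_diff + 1e-12)


def test_sweep_optimum_recovers_planted_community_count(planted_stack):
    stack, _, _ = planted_stack
    surface = parameter_sweep(
        [stack],
        gamma_grid=np.geomspace(0.5, 2.0, 3),
        omega_grid=np.geomspace(0.5, 2.0, 3),
        runs_per_cell=2,
        seed=3,
    )
    g, o = surface.optimum
    part = louvain_optimize(stack, g, o, seed=0)
    frac_3 = np.mean([len(np.unique(row)) == 3 for row in part.labels])
    assert frac_3 >= 0.8


def test_sweep_empty_grid_rejected(planted_stack):
    stack, _, _ = planted_stack
    with pytest.raises(ConfigError):
        parameter_sweep([stack], gamma_grid=np.array([]), omega_grid=np.array([1.0]))


def test_more_temporal_coupling_never_raises_flexibility():
    spec = GroundTruthSpec(n_regions=12, n_communities=3, snr=1.0, n_runs=1, seed=44)
    ts, _ = generate_regional_bold(spec, 0, "sham")
    stack = windowed_band_coherence(ts, spec.window_length, spec.band)

    def mean_flex(omega):
        ens = DynamicCommunityModel(stack, 1.0, omega).fit_ensemble(5, seed=8)
        return np.mean([flexibility(r.labels).mean() for r in ens.runs])

    assert mean_flex(2.5) <= mean_flex(0.25) + 1e-9


# ----------------------------------------------------------------------
# model / results surface
# ----------------------------------------------------------------------

def test_model_results_surface(planted_stack):
    stack, _, _ = planted_stack
    model = DynamicCommunityModel(stack, gamma=1.0, omega=1.0)
    res = model.fit(seed=0)
    assert res.q == pytest.approx(model.evaluate(res.labels))
    assert "Q:" in res.summary()
    ens = model.fit_ensemble(n_runs=4, seed=1)
    assert ens.qs.shape == (4,)
    assert ens.best().q == ens.qs.max()
    cons, idx = ens.consensus()
    assert cons.shape == (stack.n_nodes,)
    assert "runs: 4" in ens.summary()
    flex = ens.mean_metric("flexibility")
    assert flex.shape == (stack.n_nodes,)
    assert np.all((flex >= 0) & (flex <= 1))
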