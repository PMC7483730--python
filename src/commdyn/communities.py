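"""Multilayer (temporal) community detection by modularity maximisation.

The quality function for an L-layer, N-node stack with labels g_il is

    Q = (1 / 2mu) * sum_ijlr [ (A_ijl - gamma * P_ijl) delta_lr
                               + delta_ij * omega * 1(|l - r| = 1) ] delta(g_il, g_jr)

with the weighted configuration (Newman-Girvan) intra-layer null
P_ijl = k_il k_jl / (2 m_l), ordinal inter-layer identity coupling of
uniform strength omega between adjacent layers only, and 2mu = total edge
weight plus total coupling weight.

Optimisation is a Louvain-style greedy on the sparse supra-modularity
matrix: randomised node sweeps that move one node-layer at a time to the
neighbouring community with the largest quality gain, followed by graph
aggregation, iterated to a fixed point.  The algorithm is stochastic in
the sweep order, hence non-deterministic across seeds; an ensemble of
restarts (study convention: 100) characterises the solution landscape.

The statsmodels-flavoured surface is :class:`DynamicCommunityModel`
(built from a :class:`~commdyn.coherence.CoherenceStack`) whose ``fit`` /
``fit_ensemble`` return results objects carrying labels, Q and metric
accessors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linear_sum_assignment

from . import metrics as _metrics
from .coherence import CoherenceStack
from .errors import ConfigError, ConvergenceError, DegenerateLayerError

__all__ = [
    "MultilayerPartition",
    "QSurface",
    "DynamicCommunityModel",
    "CommunityDetectionResults",
    "EnsembleResults",
    "multilayer_modularity",
    "louvain_optimize",
    "shuffle_null",
    "log_grid",
    "parameter_sweep",
    "exhaustive_best_partition",
]

_MOVE_TOL = 1e-12


def _layers_of(stack) -> np.ndarray:
    layers = stack.layers if isinstance(stack, CoherenceStack) else np.asarray(stack, float)
    if layers.ndim != 3 or layers.shape[1] != layers.shape[2]:
        raise ConfigError("stack must have shape (L, N, N)")
    return layers


def _layer_null(A: np.ndarray, l_idx: int) -> tuple[np.ndarray, float]:
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m <= 0:
        raise DegenerateLayerError(f"layer {l_idx} carries no weight")
    return np.outer(k, k) / two_m, two_m


def multilayer_modularity(stack, labels: np.ndarray, gamma: float, omega: float) -> float:
    """Evaluate Q for given labels by direct summation of the quality function."""
    layers = _layers_of(stack)
    labels = np.asarray(labels)
    L, N = layers.shape[:2]
    if labels.shape != (L, N):
        raise ConfigError(f"labels shape {labels.shape} does not match stack ({L}, {N})")
    q_sum = 0.0
    two_mu = 0.0
    for l_idx in range(L):
        A = layers[l_idx]
        P, two_m = _layer_null(A, l_idx)
        delta = labels[l_idx][:, None] == labels[l_idx][None, :]
        q_sum += (A - gamma * P)[delta].sum()
        two_mu += two_m
    if L > 1:
        persist = int((labels[1:] == labels[:-1]).sum())
        q_sum += 2.0 * omega * persist
        two_mu += 2.0 * omega * N * (L - 1)
    return float(q_sum / two_mu)


def supra_modularity_matrix(stack, gamma: float, omega: float):
    """Sparse supra-modularity matrix B (node-layer index l*N + i) and 2mu."""
    layers = _layers_of(stack)
    L, N = layers.shape[:2]
    blocks = []
    two_mu = 0.0
    for l_idx in range(L):
        A = layers[l_idx]
        P, two_m = _layer_null(A, l_idx)
        blocks.append(A - gamma * P)
        two_mu += two_m
    B = sparse.block_diag(blocks, format="csr")
    if L > 1 and omega != 0.0:
        coup = sparse.diags([np.full(N * (L - 1), omega)], [N], shape=(N * L, N * L))
        B = (B + coup + coup.T).tocsr()
    if L > 1:
        two_mu += 2.0 * omega * N * (L - 1)
    return B, two_mu


# ----------------------------------------------------------------------
# greedy sweep kernel (numba-compiled when available)
# ----------------------------------------------------------------------

def _sweep_py(indptr, indices, data, comm, order, nw, visited, touched):
    moves = 0
    for oi in range(order.size):
        i = order[oi]
        ci = comm[i]
        cnt = 0
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            if j == i:
                continue
            cj = comm[j]
            if not visited[cj]:
                visited[cj] = True
                touched[cnt] = cj
                cnt += 1
                nw[cj] = 0.0
            nw[cj] += data[k]
        if not visited[ci]:
            visited[ci] = True
            touched[cnt] = ci
            cnt += 1
            nw[ci] = 0.0
        best = ci
        best_w = nw[ci]
        for t in range(cnt):
            c = touched[t]
            if nw[c] > best_w + _MOVE_TOL:
                best = c
                best_w = nw[c]
        if best != ci:
            comm[i] = best
            moves += 1
        for t in range(cnt):
            visited[touched[t]] = False
    return moves


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _sweep = njit(cache=False)(_sweep_py)
except Exception:  # pragma: no cover
    _sweep = _sweep_py


def _louvain_labels(B: sparse.csr_matrix, rng: np.random.Generator,
                    max_sweeps: int = 1000, init: np.ndarray | None = None) -> np.ndarray:
    """Greedy node moves + aggregation on supra matrix B; returns labels per node."""
    n0 = B.shape[0]
    level_B = B.tocsr()
    if init is not None:
        _, comm = np.unique(np.asarray(init).ravel(), return_inverse=True)
        comm = comm.astype(np.int64)
        if comm.size != n0:
            raise ConfigError("initial labels do not match the supra node count")
    else:
        comm = np.arange(n0, dtype=np.int64)
    global_map = np.arange(n0, dtype=np.int64)  # original node -> level node
    total_sweeps = 0
    while True:
        n = level_B.shape[0]
        nw = np.zeros(n)
        visited = np.zeros(n, dtype=np.bool_)
        touched = np.empty(n, dtype=np.int64)
        moved_any = False
        while True:
            order = rng.permutation(n).astype(np.int64)
            moves = _sweep(level_B.indptr, level_B.indices, level_B.data,
                           comm, order, nw, visited, touched)
            total_sweeps += 1
            if total_sweeps > max_sweeps:
                raise ConvergenceError(
                    f"Louvain exceeded {max_sweeps} sweeps "
                    f"(level size {n}, last sweep moved {moves} nodes)"
                )
            if moves == 0:
                break
            moved_any = True
        _, comm = np.unique(comm, return_inverse=True)
        comm = comm.astype(np.int64)
        labels = comm[global_map]
        if not moved_any:
            return labels
        # aggregate communities into super-nodes and recurse
        k = int(comm.max()) + 1
        S = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), comm)), shape=(n, k)
        )
        level_B = (S.T @ level_B @ S).tocsr()
        global_map = labels
        comm = np.arange(k, dtype=np.int64)


@dataclass
class MultilayerPartition:
    """L x N community labels with globally persistent label identity."""

    labels: np.ndarray
    gamma: float
    omega: float
    q: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)

    @property
    def n_layers(self) -> int:
        return self.labels.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[1]

    def n_communities(self) -> int:
        return len(np.unique(self.labels))


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 1..k in order of first appearance (row-major)."""
    flat = labels.ravel()
    _, first = np.unique(flat, return_index=True)
    order = flat[np.sort(first)]
    lut = {c: r + 1 for r, c in enumerate(order)}
    return np.vectorize(lut.__getitem__)(labels)


def louvain_optimize(
    stack,
    gamma: float,
    omega: float,
    seed=None,
    initial_labels: np.ndarray | None = None,
    max_sweeps: int = 1000,
) -> MultilayerPartition:
    """One Louvain run on the stack; returns a locally optimal partition.

    `initial_labels` (L x N) seeds the first sweep level; by default every
    node-layer starts in its own community.  The achieved Q is evaluated by
    direct summation of the quality function on the returned labels.
    """
    layers = _layers_of(stack)
    L, N = layers.shape[:2]
    B, _ = supra_modularity_matrix(layers, gamma, omega)
    rng = np.random.default_rng(seed)
    init = None if initial_labels is None else np.asarray(initial_labels).reshape(L * N)
    supra_labels = _louvain_labels(B, rng, max_sweeps=max_sweeps, init=init)
    labels = _canonical_labels(supra_labels.reshape(L, N))
    q = multilayer_modularity(layers, labels, gamma, omega)
    return MultilayerPartition(labels=labels, gamma=gamma, omega=omega, q=q)


def shuffle_null(stack, seed=None):
    """Null stack: within each layer, permute the upper-triangle weights
    uniformly at random, restore symmetry, keep the zero diagonal.  The
    multiset of weights per layer is preserved exactly."""
    layers = _layers_of(stack).copy()
    rng = np.random.default_rng(seed)
    L, N = layers.shape[:2]
    iu, ju = np.triu_indices(N, k=1)
    for l_idx in range(L):
        vals = rng.permutation(layers[l_idx][iu, ju])
        layer = np.zeros((N, N))
        layer[iu, ju] = vals
        layer[ju, iu] = vals
        layers[l_idx] = layer
    if isinstance(stack, CoherenceStack):
        return CoherenceStack(
            layers=layers,
            window_length=stack.window_length,
            band=stack.band,
            region_names=list(stack.region_names),
        )
    return layers


def log_grid(lo: float = 0.25, hi: float = 31.62, num: int = 20) -> np.ndarray:
    """Logarithmically spaced resolution/coupling grid (default 0.25 .. 31.62, 20 steps)."""
    if num < 1 or lo <= 0 or hi < lo:
        raise ConfigError("invalid grid specification")
    return np.geomspace(lo, hi, num)


@dataclass
class QSurface:
    """Mean optimised Q over the (gamma, omega) grid, observed vs shuffled null."""

    gamma_grid: np.ndarray
    omega_grid: np.ndarray
    mean_q_observed: np.ndarray
    mean_q_null: np.ndarray
    se_diff: np.ndarray
    optimum: tuple[float, float]
    optimum_index: tuple[int, int]

    @property
    def diff(self) -> np.ndarray:
        return self.mean_q_observed - self.mean_q_null


def parameter_sweep(
    stacks,
    gamma_grid: np.ndarray | None = None,
    omega_grid: np.ndarray | None = None,
    runs_per_cell: int = 10,
    seed: int = 0,
    max_sweeps: int = 1000,
) -> QSurface:
    """Sweep (gamma, omega): mean optimised Q on the observed stacks vs on
    shuffled-null stacks; the optimum maximises the mean difference, ties
    broken toward smaller gamma then smaller omega."""
    if isinstance(stacks, (CoherenceStack, np.ndarray)):
        stacks = [stacks]
    gamma_grid = log_grid() if gamma_grid is None else np.asarray(gamma_grid, float)
    omega_grid = log_grid() if omega_grid is None else np.asarray(omega_grid, float)
    if gamma_grid.size == 0 or omega_grid.size == 0:
        raise ConfigError("empty parameter grid")
    G, O = gamma_grid.size, omega_grid.size
    q_obs = np.zeros((G, O))
    q_null = np.zeros((G, O))
    se = np.zeros((G, O))
    for gi, g in enumerate(gamma_grid):
        for oi, o in enumerate(omega_grid):
            obs, nul = [], []
            for s_idx, stack in enumerate(stacks):
                for r in range(runs_per_cell):
                    tag = [seed, gi, oi, s_idx, r]
                    obs.append(
                        louvain_optimize(stack, g, o, seed=tag + [0], max_sweeps=max_sweeps).q
                    )
                    null_stack = shuffle_null(stack, seed=tag + [1])
                    nul.append(
                        louvain_optimize(null_stack, g, o, seed=tag + [2],
                                         max_sweeps=max_sweeps).q
                    )
            obs = np.asarray(obs)
            nul = np.asarray(nul)
            q_obs[gi, oi] = obs.mean()
            q_null[gi, oi] = nul.mean()
            d = obs - nul
            se[gi, oi] = d.std(ddof=1) / np.sqrt(d.size) if d.size > 1 else np.nan
    diff = q_obs - q_null
    best = (0, 0)
    for gi in range(G):
        for oi in range(O):
            if diff[gi, oi] > diff[best]:
                best = (gi, oi)
    return QSurface(
        gamma_grid=gamma_grid,
        omega_grid=omega_grid,
        mean_q_observed=q_obs,
        mean_q_null=q_null,
        se_diff=se,
        optimum=(float(gamma_grid[best[0]]), float(omega_grid[best[1]])),
        optimum_index=best,
    )


# ----------------------------------------------------------------------
# exhaustive maximiser for tiny stacks (oracle-scale only)
# ----------------------------------------------------------------------

def _set_partitions(n: int):
    """All set partitions of range(n) as canonical label arrays (restricted
    growth strings: labels[0] = 0, labels[i] <= max(labels[:i]) + 1)."""
    out: list[np.ndarray] = []
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, n_used: int) -> None:
        if i == n:
            out.append(labels.copy())
            return
        for v in range(n_used + 1):
            labels[i] = v
            rec(i + 1, max(n_used, v + 1))

    if n == 1:
        out.append(labels.copy())
    else:
        rec(1, 1)
    return out


def exhaustive_best_partition(stack, gamma: float, omega: float,
                              max_nodes: int = 6, max_layers: int = 2) -> MultilayerPartition:
    """Globally optimal partition by enumeration (N <= 6, L <= 2).

    For L = 2 the search enumerates per-layer set partitions and, because
    the coupling reward omega >= 0 is maximised by the best identification
    of communities across layers, solves a linear assignment on the
    community-overlap matrix for each pair of layer partitions.
    """
    layers = _layers_of(stack)
    L, N = layers.shape[:2]
    if N > max_nodes or L > max_layers:
        raise ConfigError(f"exhaustive search limited to N <= {max_nodes}, L <= {max_layers}")
    if omega < 0:
        raise ConfigError("exhaustive search assumes omega >= 0")
    parts = _set_partitions(N)

    def intra(l_idx: int) -> np.ndarray:
        A = layers[l_idx]
        P, _ = _layer_null(A, l_idx)
        Bm = A - gamma * P
        return np.array([Bm[p[:, None] == p[None, :]].sum() for p in parts])

    two_mu = sum(_layer_null(layers[l_idx], l_idx)[1] for l_idx in range(L))
    if L == 1:
        scores = intra(0)
        best = int(np.argmax(scores))
        labels = (parts[best] + 1)[None, :]
        return MultilayerPartition(labels, gamma, omega, float(scores[best] / two_mu))

    two_mu += 2.0 * omega * N * (L - 1)
    intra1, intra2 = intra(0), intra(1)
    best_score = -np.inf
    best_combo = None
    for a, p1 in enumerate(parts):
        k1 = p1.max() + 1
        for b, p2 in enumerate(parts):
            k2 = p2.max() + 1
            overlap = np.bincount(p1 * k2 + p2, minlength=k1 * k2).reshape(k1, k2)
            ri, ci = linear_sum_assignment(-overlap)
            persist = overlap[ri, ci].sum()
            score = intra1[a] + intra2[b] + 2.0 * omega * persist
            if score > best_score + 1e-15:
                best_score = score
                best_combo = (a, b, ri.copy(), ci.copy())
    a, b, ri, ci = best_combo
    p1, p2 = parts[a], parts[b]
    k1 = p1.max() + 1
    # build persistent labels: layer-2 community ci[j] inherits layer-1 label ri[j]
    relabel2 = np.arange(p2.max() + 1) + k1  # default: fresh labels
    for r_c, c_c in zip(ri, ci):
        relabel2[c_c] = r_c
    labels = np.vstack([p1, relabel2[p2]])
    labels = _canonical_labels(labels)
    return MultilayerPartition(labels, gamma, omega, float(best_score / two_mu))


# ----------------------------------------------------------------------
# model / results surface
# ----------------------------------------------------------------------

class DynamicCommunityModel:
    """Time-resolved community structure of a coherence stack.

    Parameters
    ----------
    stack : CoherenceStack or (L, N, N) array
    gamma : float
        Structural resolution of the intra-layer null model.
    omega : float
        Inter-layer identity coupling between adjacent layers.
    """

    def __init__(self, stack, gamma: float = 1.0, omega: float = 1.0):
        self.stack = stack
        self.layers = _layers_of(stack)
        self.gamma = float(gamma)
        self.omega = float(omega)

    def fit(self, seed=None, initial_labels=None, max_sweeps: int = 1000):
        part = louvain_optimize(
            self.stack, self.gamma, self.omega, seed=seed,
            initial_labels=initial_labels, max_sweeps=max_sweeps,
        )
        return CommunityDetectionResults(self, part, seed)

    def fit_ensemble(self, n_runs: int = 100, seed=None, max_sweeps: int = 1000):
        root = np.random.default_rng(seed)
        seeds = root.integers(0, 2**31 - 1, size=n_runs)
        runs = [self.fit(seed=int(s), max_sweeps=max_sweeps) for s in seeds]
        return EnsembleResults(self, runs, seeds)

    def evaluate(self, labels: np.ndarray) -> float:
        """Q of arbitrary labels under this model's (gamma, omega)."""
        return multilayer_modularity(self.layers, labels, self.gamma, self.omega)

    def null(self, seed=None) -> "DynamicCommunityModel":
        """Same model on a shuffled-edge null stack."""
        return DynamicCommunityModel(shuffle_null(self.stack, seed), self.gamma, self.omega)


class CommunityDetectionResults:
    """One fitted multilayer partition with metric accessors."""

    def __init__(self, model: DynamicCommunityModel, partition: MultilayerPartition, seed):
        self.model = model
        self.partition = partition
        self.seed = seed

    @property
    def labels(self) -> np.ndarray:
        return self.partition.labels

    @property
    def q(self) -> float:
        return self.partition.q

    def flexibility(self) -> np.ndarray:
        return _metrics.flexibility(self.labels)

    def cohesion(self) -> tuple[np.ndarray, np.ndarray]:
        return _metrics.cohesion(self.labels)

    def promiscuity(self) -> np.ndarray:
        return _metrics.promiscuity(self.labels)

    def allegiance(self, denominator: str = "layers") -> np.ndarray:
        return _metrics.allegiance(self.labels, denominator=denominator)

    def summary(self) -> str:
        lab = self.labels
        per_layer = [len(np.unique(row)) for row in lab]
        lines = [
            "Dynamic community detection results",
            "===================================",
            f"nodes: {self.partition.n_nodes}   layers: {self.partition.n_layers}",
            f"gamma: {self.partition.gamma:.6g}   omega: {self.partition.omega:.6g}",
            f"Q: {self.q:.6f}",
            f"communities (total): {self.partition.n_communities()}",
            f"communities per layer: min {min(per_layer)}, "
            f"median {int(np.median(per_layer))}, max {max(per_layer)}",
            f"mean flexibility: {self.flexibility().mean():.4f}"
            if self.partition.n_layers > 1 else "mean flexibility: n/a (single layer)",
        ]
        return "\n".join(lines)


class EnsembleResults:
    """Ensemble of Louvain restarts at fixed (gamma, omega)."""

    def __init__(self, model, runs, seeds):
        self.model = model
        self.runs = list(runs)
        self.seeds = np.asarray(seeds)

    @property
    def qs(self) -> np.ndarray:
        return np.array([r.q for r in self.runs])

    @property
    def labels_stack(self) -> np.ndarray:
        """(n_runs, L, N) labels."""
        return np.stack([r.labels for r in self.runs])

    def best(self) -> CommunityDetectionResults:
        return self.runs[int(np.argmax(self.qs))]

    def mean_metric(self, name: str) -> np.ndarray:
        """Per-iteration metric averaged over the ensemble."""
        fn = getattr(_metrics, name)
        vals = [fn(r.labels) for r in self.runs]
        if name == "cohesion":
            vals = [v[1] for v in vals]
        return np.mean(vals, axis=0)

    def mean_allegiance(self, denominator: str = "layers") -> np.ndarray:
        return np.mean([r.allegiance(denominator) for r in self.runs], axis=0)

    def consensus(self) -> tuple[np.ndarray, int]:
        """Most representative single-layer partition over layers x runs."""
        parts = [row for r in self.runs for row in r.labels]
        return _metrics.consensus_partition(parts)

    def summary(self) -> str:
        qs = self.qs
        lines = [
            "Louvain ensemble",
            "================",
            f"runs: {len(self.runs)}   gamma: {self.model.gamma:.6g}   "
            f"omega: {self.model.omega:.6g}",
            f"Q: mean {qs.mean():.6f}, sd {qs.std(ddof=1) if qs.size > 1 else 0.0:.6f}, "
            f"max {qs.max():.6f}",
            f"mean flexibility: {self.mean_metric('flexibility').mean():.4f}",
        ]
        return "\n".join(lines)
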