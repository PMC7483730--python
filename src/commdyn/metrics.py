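"""Node-dynamics and allegiance metrics on multilayer partitions.

A partition is an L x N integer matrix: one row of community labels per
temporal layer, with label identity persistent across layers.  All metrics
are invariant to relabelling of the community integers.

Conventions adopted where the literature is loose:

* allegiance divides the co-assignment count by L (fraction of layers), so
  a permanently co-assigned pair scores exactly 1; the literal
  "per possible change" L - 1 denominator is available via
  ``denominator='changes'`` for compatibility.
* cohesion counts a pair as moving together only when BOTH nodes change
  label at the same step AND land in the same community.
* promiscuity's denominator is the number of distinct communities realised
  anywhere in the partition.
* within-module degree z-scores with the population standard deviation and
  maps zero-variance communities to 0.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .errors import ConfigError, DegenerateInputError, UndefinedMetricError

__all__ = [
    "flexibility",
    "cohesion",
    "promiscuity",
    "allegiance",
    "recruitment_integration",
    "zrand",
    "rand_similarity",
    "consensus_partition",
    "within_module_degree",
    "participation_coefficient",
    "classify_hubs_integrators",
]

logger = logging.getLogger(__name__)


def _as_labels(labels: np.ndarray, min_layers: int = 1) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ConfigError("labels must be an L x N matrix")
    if labels.shape[0] < min_layers:
        raise UndefinedMetricError(
            f"metric undefined for L = {labels.shape[0]} (< {min_layers}) layers"
        )
    return labels


def flexibility(labels: np.ndarray) -> np.ndarray:
    """Fraction of the L - 1 layer transitions at which each node changes community."""
    labels = _as_labels(labels, min_layers=2)
    changes = (labels[1:] != labels[:-1]).sum(axis=0)
    return changes / (labels.shape[0] - 1)


def cohesion(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cohesion matrix M and cohesion strength Omega.

    ``M[i, j]`` = (number of steps at which i and j both change label and
    land in the same community) / (L - 1); ``Omega[i]`` = row sum of M
    excluding the diagonal.
    """
    labels = _as_labels(labels, min_layers=2)
    L, N = labels.shape
    M = np.zeros((N, N))
    for t in range(L - 1):
        moved = labels[t + 1] != labels[t]
        if not moved.any():
            continue
        together = labels[t + 1][:, None] == labels[t + 1][None, :]
        joint = moved[:, None] & moved[None, :] & together
        M += joint
    M /= L - 1
    np.fill_diagonal(M, 0.0)
    return M, M.sum(axis=1)


def promiscuity(labels: np.ndarray) -> np.ndarray:
    """Fraction of all realised communities in which each node appears at least once."""
    labels = _as_labels(labels, min_layers=1)
    total = len(np.unique(labels))
    return np.array([len(np.unique(labels[:, i])) for i in range(labels.shape[1])]) / total


def allegiance(labels: np.ndarray, denominator: str = "layers") -> np.ndarray:
    """Pairwise co-assignment probability matrix P.

    denominator='layers' (default): P[i, j] = #{l : g_il == g_jl} / L, so
    P is in [0, 1] with unit diagonal.  denominator='changes' divides by
    L - 1 instead (compatibility variant; values may exceed 1).
    """
    labels = _as_labels(labels, min_layers=1)
    L, N = labels.shape
    co = np.zeros((N, N))
    for t in range(L):
        co += labels[t][:, None] == labels[t][None, :]
    if denominator == "layers":
        P = co / L
        np.fill_diagonal(P, 1.0)
    elif denominator == "changes":
        if L < 2:
            raise UndefinedMetricError("'changes' denominator requires L >= 2")
        P = co / (L - 1)
    else:
        raise ConfigError(f"unknown allegiance denominator {denominator!r}")
    return P


def recruitment_integration(
    P: np.ndarray, ref_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean allegiance of each node to its own / to other reference communities.

    recruitment_i = mean P[i, j] over j != i with ref(j) == ref(i) (NaN for
    singleton reference communities); integration_i = mean P[i, j] over j
    with ref(j) != ref(i).
    """
    P = np.asarray(P, dtype=float)
    ref = np.asarray(ref_labels)
    N = P.shape[0]
    if ref.shape != (N,):
        raise ConfigError("reference structure must label every node exactly once")
    same = ref[:, None] == ref[None, :]
    off = ~np.eye(N, dtype=bool)
    recr = np.full(N, np.nan)
    integ = np.full(N, np.nan)
    for i in range(N):
        own = same[i] & off[i]
        other = ~same[i]
        if own.any():
            recr[i] = P[i, own].mean()
        if other.any():
            integ[i] = P[i, other].mean()
    return recr, integ


# ----------------------------------------------------------------------
# partition similarity
# ----------------------------------------------------------------------

def _pair_counts(labels: np.ndarray) -> tuple[int, np.ndarray]:
    _, sizes = np.unique(labels, return_counts=True)
    return int((sizes * (sizes - 1) // 2).sum()), sizes


def zrand_moments(p1: np.ndarray, p2: np.ndarray) -> tuple[float, float]:
    """Closed-form mean and variance of w — the number of node pairs
    co-assigned in both partitions — under the permutation (hypergeometric)
    model of random relabelings."""
    p1 = np.asarray(p1).ravel()
    p2 = np.asarray(p2).ravel()
    n = p1.size
    if p2.size != n:
        raise ConfigError("partitions must cover the same node set")
    if n < 4:
        raise UndefinedMetricError("closed-form variance requires at least 4 nodes")
    M = n * (n - 1) // 2
    M1, sizes1 = _pair_counts(p1)
    M2, sizes2 = _pair_counts(p2)
    Ew = M1 * M2 / M
    a = 4.0 * M1 - 2.0 * M
    b = 4.0 * M2 - 2.0 * M
    c1 = n * (n**2 - 3 * n - 2) - 8.0 * (n + 1) * M1 + 4.0 * np.sum(sizes1.astype(float) ** 3)
    c2 = n * (n**2 - 3 * n - 2) - 8.0 * (n + 1) * M2 + 4.0 * np.sum(sizes2.astype(float) ** 3)
    var = (
        M / 16.0
        - (a**2) * (b**2) / (256.0 * M**2)
        + c1 * c2 / (16.0 * n * (n - 1) * (n - 2))
        + ((a**2 - 4.0 * c1 - 4.0 * M) * (b**2 - 4.0 * c2 - 4.0 * M))
        / (64.0 * n * (n - 1) * (n - 2) * (n - 3))
    )
    return float(Ew), float(var)


def zrand(p1: np.ndarray, p2: np.ndarray) -> float:
    """z-score of the Rand coefficient of two partitions of the same node set.

    Standardises w (the number of node pairs co-assigned in both
    partitions) by its closed-form mean and variance under the permutation
    (hypergeometric) model.
    """
    p1 = np.asarray(p1).ravel()
    p2 = np.asarray(p2).ravel()
    n = p1.size
    if p2.size != n:
        raise ConfigError("partitions must cover the same node set")
    if n < 2:
        raise UndefinedMetricError("z-Rand undefined for fewer than 2 nodes")
    same1 = p1[:, None] == p1[None, :]
    same2 = p2[:, None] == p2[None, :]
    iu = np.triu_indices(n, k=1)
    w = int(np.count_nonzero(same1[iu] & same2[iu]))
    Ew, var = zrand_moments(p1, p2)
    if var <= 0:
        raise UndefinedMetricError("z-Rand undefined: zero permutation variance")
    return float((w - Ew) / math.sqrt(var))


def zrand_expected_pairs(p1: np.ndarray, p2: np.ndarray) -> float:
    """Closed-form E[w] under the permutation model (exposed for validation)."""
    p1 = np.asarray(p1).ravel()
    p2 = np.asarray(p2).ravel()
    n = p1.size
    M = n * (n - 1) // 2
    M1, _ = _pair_counts(p1)
    M2, _ = _pair_counts(p2)
    return M1 * M2 / M


def rand_similarity(p1: np.ndarray, p2: np.ndarray) -> dict:
    """Plain Rand and adjusted Rand indices (reported side by side, both via
    scikit-learn), for descriptive similarity summaries."""
    from sklearn.metrics import adjusted_rand_score, rand_score

    p1 = np.asarray(p1).ravel()
    p2 = np.asarray(p2).ravel()
    return {"rand": rand_score(p1, p2), "adjusted_rand": adjusted_rand_score(p1, p2)}


def consensus_partition(partitions) -> tuple[np.ndarray, int]:
    """Most representative member of a collection of partitions.

    Returns the member maximising the summed pairwise z-Rand against all
    other members, together with its input index.  Pairs whose z-Rand is
    undefined contribute nothing; if every pair is undefined the input is
    degenerate.  Ties break toward the lowest input index (logged).
    """
    parts = [np.asarray(p).ravel() for p in partitions]
    if len(parts) < 2:
        raise DegenerateInputError("consensus requires at least 2 partitions")
    R = len(parts)
    scores = np.zeros(R)
    any_defined = False
    for i in range(R):
        for j in range(i + 1, R):
            try:
                z = zrand(parts[i], parts[j])
            except UndefinedMetricError:
                continue
            any_defined = True
            scores[i] += z
            scores[j] += z
    if not any_defined:
        raise DegenerateInputError("z-Rand undefined for every pair of partitions")
    best = int(np.argmax(scores))  # argmax returns the first (lowest-index) maximiser
    if np.count_nonzero(scores == scores[best]) > 1:
        logger.info("consensus tie at score %.6g; keeping lowest input index %d",
                    scores[best], best)
    return parts[best].copy(), best


def hierarchical_consensus(collections) -> tuple[np.ndarray, list[np.ndarray]]:
    """Consensus of consensuses: one representative per collection (e.g. per
    participant over layers x iterations), then a consensus across those."""
    reps = [consensus_partition(c)[0] for c in collections]
    group, _ = consensus_partition(reps)
    return group, reps


# ----------------------------------------------------------------------
# static node roles relative to a reference community structure
# ----------------------------------------------------------------------

def within_module_degree(mean_coherence: np.ndarray, ref_labels: np.ndarray) -> np.ndarray:
    """Mean within-community connection strength, z-scored within each
    reference community (population sd; zero-variance communities -> 0;
    singleton communities -> NaN)."""
    C = np.asarray(mean_coherence, dtype=float)
    ref = np.asarray(ref_labels)
    N = C.shape[0]
    if C.shape != (N, N) or not np.allclose(C, C.T):
        raise ConfigError("mean_coherence must be a symmetric N x N matrix")
    raw = np.full(N, np.nan)
    for c in np.unique(ref):
        members = np.flatnonzero(ref == c)
        if members.size < 2:
            continue
        sub = C[np.ix_(members, members)]
        raw[members] = (sub.sum(axis=1) - np.diag(sub)) / (members.size - 1)
    z = np.full(N, np.nan)
    for c in np.unique(ref):
        members = np.flatnonzero(ref == c)
        vals = raw[members]
        if members.size < 2:
            continue
        sd = vals.std()  # population sd
        z[members] = 0.0 if sd == 0 else (vals - vals.mean()) / sd
    return z


def participation_coefficient(mean_coherence: np.ndarray, ref_labels: np.ndarray) -> np.ndarray:
    """Diversity of each node's strength across reference communities:
    1 - sum_s (kappa_is / k_i)^2.  0 = connectivity confined to one
    community; nodes with zero total strength -> NaN."""
    C = np.asarray(mean_coherence, dtype=float)
    ref = np.asarray(ref_labels)
    N = C.shape[0]
    if np.any(C < 0):
        raise ConfigError("participation coefficient requires non-negative weights")
    comms = np.unique(ref)
    kappa = np.zeros((N, comms.size))
    for s, c in enumerate(comms):
        kappa[:, s] = C[:, ref == c].sum(axis=1)
    k = kappa.sum(axis=1)
    pc = np.full(N, np.nan)
    nz = k > 0
    pc[nz] = 1.0 - ((kappa[nz] / k[nz, None]) ** 2).sum(axis=1)
    return pc


def classify_hubs_integrators(
    wmd: np.ndarray, pc: np.ndarray, percentile: float = 95.0
) -> tuple[np.ndarray, np.ndarray]:
    """Soft hub/integrator classification by distribution position.

    hubs = nodes strictly above the given percentile of within-module
    degree; integrators = nodes strictly above that percentile of the
    participation coefficient.  Percentiles use linear interpolation;
    percentile 0 is the unconstrained boundary (every node flagged).
    """

    def _flag(values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if percentile == 0:
            return np.ones(values.size, dtype=bool)
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            return np.zeros(values.size, dtype=bool)
        thr = np.percentile(finite, percentile)
        with np.errstate(invalid="ignore"):
            return values > thr

    return _flag(wmd), _flag(pc)
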