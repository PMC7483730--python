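"""End-to-end validation experiments on synthetic data.

These are the package's reproducibility workloads: each function builds its
inputs with the synthetic generator (or tiny fixed networks), runs the
relevant pipeline stages, and measures a scalar quality of the method —
layer counts, optimizer-vs-enumeration gaps, planted-partition recovery,
false-positive calibration, perturbation sensitivity, and the z-Rand
closed form against a permutation estimate.

Problem sizes are scaled to desk hardware (documented in the methods note):
planted recovery uses 30 regions, the replicate studies 20 regions and a
3-restart Louvain ensemble; all other study constants (3 x 366 volumes at
TR = 2 s, 20-volume windows, 0.06-0.12 Hz band, 7 participants) are the
generator defaults.
"""

from __future__ import annotations

import numpy as np

from . import metrics as _metrics
from .coherence import windowed_band_coherence
from .communities import (
    DynamicCommunityModel,
    exhaustive_best_partition,
    louvain_optimize,
)
from .errors import UndefinedMetricError
from .stats import sliding_metrics, ssd_contrast
from .synthetic import (
    GroundTruthSpec,
    Perturbation,
    generate_regional_bold,
    rotating_schedule,
)

__all__ = [
    "coherence_layer_count",
    "louvain_exhaustive_gap",
    "planted_recovery",
    "ssd_replicates",
    "zrand_permutation_check",
]


def coherence_layer_count(seed: int = 0, n_regions: int = 8) -> dict:
    """Layer count of the default acquisition: 3 x 366 volumes, 20-volume windows."""
    spec = GroundTruthSpec(n_regions=n_regions, seed=seed)
    ts, _ = generate_regional_bold(spec, participant=0, condition="sham")
    stack = windowed_band_coherence(ts, window_length=spec.window_length, band=spec.band)
    return {"n_layers": stack.n_layers, "n_volumes": ts.n_samples}


def _toy_stacks(seed: int):
    """Small weighted stacks for oracle comparison, including the canonical
    two-block toy (3+3 nodes, within-block weight 1, between 0.05, two
    identical layers)."""
    rng = np.random.default_rng(seed)
    block = np.full((6, 6), 0.05)
    block[:3, :3] = 1.0
    block[3:, 3:] = 1.0
    np.fill_diagonal(block, 0.0)
    cases = [(np.stack([block, block]), 1.0, 0.5)]
    for n, n_layers, gamma, omega in [
        (4, 1, 1.0, 0.0),
        (5, 2, 0.8, 0.3),
        (6, 1, 1.3, 0.0),
        (6, 2, 1.0, 1.0),
        (5, 2, 1.0, 0.0),
    ]:
        layers = []
        for _ in range(n_layers):
            w = rng.uniform(0.0, 1.0, size=(n, n))
            w = (w + w.T) / 2.0
            np.fill_diagonal(w, 0.0)
            layers.append(w)
        cases.append((np.stack(layers), gamma, omega))
    return cases


def louvain_exhaustive_gap(seed: int = 0, restarts: int = 100) -> dict:
    """Best-of-``restarts`` Louvain Q vs the exhaustive-enumeration optimum
    on every toy stack; returns the worst absolute gap (0 = optimizer always
    reaches the global optimum)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    gaps = []
    for layers, gamma, omega in _toy_stacks(seed):
        exact = exhaustive_best_partition(layers, gamma, omega)
        best_q = -np.inf
        for _ in range(restarts):
            part = louvain_optimize(layers, gamma, omega,
                                    seed=int(rng.integers(0, 2**31 - 1)))
            best_q = max(best_q, part.q)
        gap = abs(exact.q - best_q)
        gaps.append(gap)
        worst = max(worst, gap)
    return {"max_abs_q_gap": worst, "gaps": gaps, "n_stacks": len(gaps)}


def planted_recovery(
    seed: int = 0,
    n_regions: int = 30,
    n_communities: int = 3,
    snr: float = 3.0,
    gamma: float = 1.0,
    omega: float = 1.0,
    n_restarts: int = 5,
    n_permutations: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Fraction of layers whose recovered partition beats the permutation
    z-Rand null against the planted partition.

    For each layer, the observed z-Rand between recovered and planted labels
    is compared with the (1 - alpha) quantile of z-Rand under ``n_permutations``
    random relabelings of the recovered layer partition.
    """
    spec = GroundTruthSpec(
        n_regions=n_regions, n_communities=n_communities, snr=snr, seed=seed
    )
    ts, planted = generate_regional_bold(spec, participant=0, condition="sham")
    stack = windowed_band_coherence(ts, window_length=spec.window_length, band=spec.band)
    model = DynamicCommunityModel(stack, gamma=gamma, omega=omega)
    ens = model.fit_ensemble(n_runs=n_restarts, seed=seed)
    labels = ens.best().labels

    rng = np.random.default_rng([seed, 1])
    n_sig = 0
    zs = []
    for l_idx in range(stack.n_layers):
        rec = labels[l_idx]
        true = planted[l_idx]
        try:
            z_obs = _metrics.zrand(rec, true)
        except UndefinedMetricError:
            zs.append(np.nan)
            continue
        null = np.empty(n_permutations)
        for k in range(n_permutations):
            null[k] = _metrics.zrand(rec[rng.permutation(rec.size)], true)
        if z_obs > np.quantile(null, 1.0 - alpha):
            n_sig += 1
        zs.append(z_obs)
    frac = n_sig / stack.n_layers
    return {
        "fraction_significant_layers": frac,
        "n_layers": stack.n_layers,
        "mean_zrand": float(np.nanmean(zs)),
    }


def _one_replicate(
    rep_seed: int,
    n_regions: int,
    perturb: bool,
    n_participants: int,
    ensemble_runs: int,
    snr: float,
    factor: float,
    perturb_windows: tuple[int, int],
    gamma: float,
    omega: float,
    epoch_length: int,
    q: float,
):
    n_comm = 3
    block = n_regions // n_comm
    pert = (
        Perturbation(nodes=tuple(range(block)), windows=perturb_windows, factor=factor)
        if perturb
        else None
    )
    spec = GroundTruthSpec(
        n_regions=n_regions,
        n_communities=n_comm,
        snr=snr,
        perturbation=pert,
        n_participants=n_participants,
        seed=rep_seed,
    )
    spec.community_schedule = rotating_schedule(n_regions, n_comm, spec.n_windows)
    per_cond = {"rtms": [], "sham": []}
    for p in range(n_participants):
        for cond in ("sham", "rtms"):
            ts, _ = generate_regional_bold(spec, p, cond)
            stack = windowed_band_coherence(ts, window_length=spec.window_length,
                                            band=spec.band)
            model = DynamicCommunityModel(stack, gamma=gamma, omega=omega)
            ens = model.fit_ensemble(
                n_runs=ensemble_runs,
                seed=np.random.default_rng([rep_seed, p, 0 if cond == "sham" else 1])
                .integers(0, 2**31 - 1),
            )
            series = sliding_metrics(
                [r.labels for r in ens.runs], ("flexibility",),
                epoch_length=epoch_length,
            )
            per_cond[cond].append(series.values["flexibility"])
    times = np.arange(per_cond["sham"][0].shape[0]) * 40.0 / 60.0
    return ssd_contrast(per_cond["rtms"], per_cond["sham"], epoch_times=times, q=q)


def ssd_replicates(
    seed: int = 0,
    n_replicates: int = 100,
    perturb: bool = False,
    n_regions: int = 20,
    n_participants: int = 7,
    ensemble_runs: int = 3,
    snr: float = 3.0,
    factor: float = 2.5,
    perturb_windows: tuple[int, int] = (0, 15),
    gamma: float = 1.0,
    omega: float = 0.5,
    epoch_length: int = 10,
    q: float = 0.05,
) -> dict:
    """Replicate study of the sliding-SSD contrast.

    ``perturb=False``: type-I calibration — fraction of replicates in which
    any epoch survives BH-FDR at q despite no planted perturbation.
    ``perturb=True``: sensitivity — fraction of replicates flagging at least
    one epoch that overlaps the perturbed windows, and fraction flagging any
    epoch entirely after the perturbation ends.
    """
    any_sig = 0
    inside = 0
    late = 0
    w0, w1 = perturb_windows
    for rep in range(n_replicates):
        rep_seed = int(np.random.default_rng([seed, rep]).integers(0, 2**31 - 1))
        cmp_ = _one_replicate(
            rep_seed, n_regions, perturb, n_participants, ensemble_runs,
            snr, factor, perturb_windows, gamma, omega, epoch_length, q,
        )
        sig = np.flatnonzero(cmp_.significant)
        if sig.size:
            any_sig += 1
        # epoch k covers windows [k, k + epoch_length)
        if np.any((sig < w1) & (sig + epoch_length > w0)):
            inside += 1
        if np.any(sig >= w1):
            late += 1
    return {
        "n_replicates": n_replicates,
        "fraction_any_significant": any_sig / n_replicates,
        "fraction_flag_inside_perturbation": inside / n_replicates,
        "fraction_flag_after_perturbation": late / n_replicates,
    }


def zrand_permutation_check(
    seed: int = 0,
    p1=(0, 0, 0, 1, 1, 1),
    p2=(0, 0, 1, 1, 2, 2),
    n_relabelings: int = 10_000,
) -> dict:
    """Closed-form z-Rand moments vs a random-relabeling estimate.

    Returns the closed-form and empirical E[w] and sd(w), the standard
    errors of the empirical estimates, and the z-scores computed both ways.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    rng = np.random.default_rng(seed)
    same1 = p1[:, None] == p1[None, :]
    iu = np.triu_indices(p1.size, k=1)

    def w_of(q):
        same2 = q[:, None] == q[None, :]
        return int(np.count_nonzero(same1[iu] & same2[iu]))

    w_obs = w_of(p2)
    ws = np.empty(n_relabelings)
    for k in range(n_relabelings):
        ws[k] = w_of(p2[rng.permutation(p2.size)])
    ew_emp = float(ws.mean())
    sd_emp = float(ws.std(ddof=1))
    ew_closed, var_closed = _metrics.zrand_moments(p1, p2)
    z_closed = _metrics.zrand(p1, p2)
    z_emp = (w_obs - ew_emp) / sd_emp
    return {
        "w_observed": w_obs,
        "Ew_closed": float(ew_closed),
        "Ew_empirical": ew_emp,
        "Ew_se": sd_emp / np.sqrt(n_relabelings),
        "var_closed": float(var_closed),
        "var_empirical": sd_emp**2,
        "var_empirical_se": sd_emp**2 * np.sqrt(2.0 / (n_relabelings - 1)),
        "z_closed": float(z_closed),
        "z_empirical": float(z_emp),
    }
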