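"""Condition comparison statistics: sliding metric epochs, SSD contrasts,
paired node tests, Monte-Carlo metric nulls, and the behavioral bootstrap.

Conventions:

* SSD epochs are z-scored within participant; the per-epoch group test is
  one-sided by default (elevated SSD), because z-scoring forces epochs away
  from a genuine elevation to be negative by construction, and the
  scientific question is whether the between-condition discrepancy rises
  above its session mean.
* FDR (Benjamini-Hochberg) is applied within the family the contrast
  defines: across nodes for static contrasts, across epochs for sliding
  contrasts.
* "Outside the null" is two-sided by default: beyond the central coverage
  interval of the unlabeled-draw distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import metrics as _metrics
from .errors import ConfigError, DegenerateInputError, InsufficientDataError

__all__ = [
    "SlidingMetricSeries",
    "ConditionComparison",
    "sliding_metrics",
    "ssd_contrast",
    "per_node_condition_test",
    "condition_correlation",
    "metric_null",
    "behavioral_bootstrap",
]

_EPOCH_METRICS = {
    "flexibility": lambda lab: _metrics.flexibility(lab),
    "cohesion_strength": lambda lab: _metrics.cohesion(lab)[1],
    "promiscuity": lambda lab: _metrics.promiscuity(lab),
}


@dataclass
class SlidingMetricSeries:
    """Epoch-resolved node metrics, ensemble-averaged.

    values : dict metric name -> (n_epochs, N) array
    epoch_times : minutes from scan start of each epoch's first window
    """

    values: dict
    epoch_length: int
    step: int
    epoch_times: np.ndarray
    window_seconds: float = 40.0


def sliding_metrics(
    label_runs,
    metric_names=("flexibility",),
    epoch_length: int = 10,
    step: int = 1,
    window_seconds: float = 40.0,
) -> SlidingMetricSeries:
    """Compute node metrics on overlapping label epochs, averaged over the
    Louvain ensemble.

    ``label_runs`` is a single L x N label matrix or a sequence of them
    (one per ensemble run).  Epoch k covers community windows
    [k*step, k*step + epoch_length); with step 1 there are
    L - epoch_length + 1 epochs.
    """
    if isinstance(label_runs, np.ndarray) and label_runs.ndim == 2:
        label_runs = [label_runs]
    label_runs = [np.asarray(lab) for lab in label_runs]
    L = label_runs[0].shape[0]
    if epoch_length > L:
        raise ConfigError(f"epoch_length {epoch_length} exceeds L = {L} windows")
    for name in metric_names:
        if name not in _EPOCH_METRICS:
            raise ConfigError(f"unknown sliding metric {name!r}")
    starts = list(range(0, L - epoch_length + 1, step))
    values = {}
    for name in metric_names:
        fn = _EPOCH_METRICS[name]
        per_run = []
        for lab in label_runs:
            ep = np.stack([fn(lab[s:s + epoch_length]) for s in starts])
            per_run.append(ep)
        values[name] = np.mean(per_run, axis=0)
    epoch_times = np.array(starts) * window_seconds / 60.0
    return SlidingMetricSeries(
        values=values, epoch_length=epoch_length, step=step,
        epoch_times=epoch_times, window_seconds=window_seconds,
    )


@dataclass
class ConditionComparison:
    """Per-epoch group comparison of an SSD contrast."""

    ssd_raw: np.ndarray  # participants x epochs
    ssd_z: np.ndarray  # participants x epochs, z within participant
    t: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray
    epoch_times: np.ndarray
    q: float
    df: int


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateInputError(
            "SSD has zero variance across epochs for at least one participant; "
            "within-participant z-scoring is undefined"
        )
    return (x - x.mean(axis=1, keepdims=True)) / sd


def ssd_contrast(
    metric_tms,
    metric_sham,
    epoch_times: np.ndarray | None = None,
    q: float = 0.05,
    alternative: str = "greater",
) -> ConditionComparison:
    """Sum-of-squared-differences contrast between conditions across time.

    ``metric_tms`` / ``metric_sham``: per participant, an (epochs, N) metric
    array (sequences of equal-shaped arrays).  Per participant and epoch,
    SSD_t = sum_i (m_i^TMS(t) - m_i^sham(t))^2, z-scored across epochs
    within participant; each epoch is then tested against 0 with a
    one-sample t-test over participants and BH-FDR corrected across epochs.
    """
    tms = [np.asarray(a, float) for a in metric_tms]
    sham = [np.asarray(a, float) for a in metric_sham]
    if len(tms) != len(sham) or len(tms) == 0:
        raise InsufficientDataError("need paired metric arrays for every participant")
    shapes = {a.shape for a in tms} | {a.shape for a in sham}
    if len(shapes) != 1:
        raise ConfigError("epoch/node dimensions differ across participants or conditions")
    ssd = np.stack([((a - b) ** 2).sum(axis=1) for a, b in zip(tms, sham)])  # P x E
    if ssd.shape[0] < 2:
        raise InsufficientDataError("group test requires at least 2 participants")
    ssd_z = _zscore_rows(ssd)
    res = sps.ttest_1samp(ssd_z, 0.0, axis=0, alternative=alternative)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    reject, p_fdr, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    if epoch_times is None:
        epoch_times = np.arange(ssd.shape[1], dtype=float)
    return ConditionComparison(
        ssd_raw=ssd, ssd_z=ssd_z, t=t, p_raw=p, p_fdr=p_fdr,
        significant=reject, epoch_times=np.asarray(epoch_times),
        q=q, df=ssd.shape[0] - 1,
    )


def per_node_condition_test(values_tms: np.ndarray, values_sham: np.ndarray,
                            q: float = 0.05) -> pd.DataFrame:
    """Paired t-test per node across participants with BH-FDR across nodes.

    Inputs are (participants, N) arrays of per-participant node metrics.
    """
    a = np.asarray(values_tms, float)
    b = np.asarray(values_sham, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ConfigError("condition arrays must both be (participants, nodes)")
    if a.shape[0] < 2:
        raise InsufficientDataError("paired t-test requires at least 2 participants")
    res = sps.ttest_rel(a, b, axis=0)
    t = np.asarray(res.statistic)
    p = np.asarray(res.pvalue)
    # nodes with exactly zero difference everywhere have undefined t; report 0 / p=1
    zero = ~np.isfinite(t)
    t[zero] = 0.0
    p[zero] = 1.0
    reject, p_fdr, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame(
        {"t": t, "p_raw": p, "p_fdr": p_fdr, "significant": reject}
    )


def condition_correlation(mean_tms: np.ndarray, mean_sham: np.ndarray) -> dict:
    """Pearson correlation of the group-mean node metric across conditions."""
    x = np.asarray(mean_tms, float)
    y = np.asarray(mean_sham, float)
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "r2_percent": float(100.0 * r**2), "p": float(p)}


def metric_null(
    pooled: np.ndarray,
    observed_means: np.ndarray,
    draws: int = 10_000,
    group_size: int = 7,
    coverage: float = 0.95,
    two_sided: bool = True,
    seed=None,
) -> dict:
    """Monte-Carlo null for node metrics from unlabeled pooled values.

    Each draw averages ``group_size`` values sampled with replacement from
    the pooled vector (metrics across subjects, nodes and conditions); a
    node is flagged when its observed group mean falls outside the central
    ``coverage`` interval of the draw distribution (or above the one-sided
    ``coverage`` quantile when ``two_sided=False``).
    """
    pooled = np.asarray(pooled, float).ravel()
    if pooled.size == 0:
        raise InsufficientDataError("empty pooled metric vector")
    if draws < 1000:
        warnings.warn("fewer than 1000 null draws: interval tails are unstable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    null = pooled[rng.integers(0, pooled.size, size=(draws, group_size))].mean(axis=1)
    obs = np.asarray(observed_means, float)
    # tolerance at accumulation precision so a degenerate (constant) pool
    # never flags anything
    tol = 1e-12 * max(1.0, float(np.abs(null).max()))
    if two_sided:
        alpha = (1.0 - coverage) / 2.0
        lo, hi = np.quantile(null, [alpha, 1.0 - alpha])
        flags = (obs < lo - tol) | (obs > hi + tol)
    else:
        lo, hi = -np.inf, np.quantile(null, coverage)
        flags = obs > hi + tol
    return {
        "null_draws": null,
        "interval": (float(lo), float(hi)),
        "flags": flags,
        "coverage": coverage,
        "two_sided": two_sided,
    }


def behavioral_bootstrap(
    behavior: pd.DataFrame,
    draws: int = 10_000,
    seed=None,
) -> dict:
    """Monte-Carlo test of the run-1 contralateral accuracy change.

    Observed statistic: group mean of the run-1 contralateral rTMS - sham
    accuracy difference.  Null distribution: means of ``group_size`` (= the
    number of participants) differences drawn with replacement from the
    pooled other-cell difference vectors — ipsilateral differences from all
    runs and contralateral differences from the remaining runs — ``draws``
    times each.  One-tailed p = proportion of null means strictly below the
    observed mean.
    """
    required = {"participant", "run", "hemifield", "condition", "accuracy"}
    if not required.issubset(behavior.columns):
        raise InsufficientDataError(f"behavior table must have columns {sorted(required)}")
    wide = behavior.pivot_table(
        index=["participant", "run", "hemifield"], columns="condition",
        values="accuracy", aggfunc="mean",
    )
    if wide.isna().any().any() or not {"rtms", "sham"}.issubset(wide.columns):
        raise InsufficientDataError("behavior table is missing rTMS/sham cells")
    diff = (wide["rtms"] - wide["sham"]).reset_index()
    diff.columns = ["participant", "run", "hemifield", "d"]

    target = diff[(diff.run == 1) & (diff.hemifield == "contralateral")]
    if target.empty:
        raise InsufficientDataError("no run-1 contralateral cells present")
    observed = float(target.d.mean())
    n_group = target.d.size

    # pools are sorted so draws depend only on the value multisets, making
    # the test exactly invariant to participant relabeling
    pool_ipsi = np.sort(diff[diff.hemifield == "ipsilateral"].d.to_numpy())
    pool_contra = np.sort(
        diff[(diff.hemifield == "contralateral") & (diff.run != 1)].d.to_numpy()
    )
    if pool_ipsi.size == 0 or pool_contra.size == 0:
        raise InsufficientDataError("null pools are empty")

    rng = np.random.default_rng(seed)
    null_means = []
    for pool in (pool_ipsi, pool_contra):
        idx = rng.integers(0, pool.size, size=(draws, n_group))
        null_means.append(pool[idx].mean(axis=1))
    null_means = np.concatenate(null_means)
    # strict inequality: ties count as non-events
    p = float(np.count_nonzero(null_means < observed) / null_means.size)
    return {
        "observed": observed,
        "p_one_tailed": p,
        "null_means": null_means,
        "n_draws": int(null_means.size),
    }
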