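"""Synthetic regional BOLD generator with planted community structure.

The generator emulates the statistical structure the downstream analysis
assumes: N regional time-series sampled at a fixed repetition time across
several concatenated runs, in which regions belonging to the same (planted)
community share a band-limited Gaussian signal, plus independent broadband
noise.  A transient "stimulation" perturbation can be planted by mixing
other communities' signals into a chosen node set during an early epoch,
which raises cross-community coherence without changing signal power.

Ground truth (the planted window-wise partition) is returned alongside the
series so that community recovery, metric behaviour and condition statistics
can all be tested without any external data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .timeseries import RegionalTimeseriesSet

__all__ = [
    "Perturbation",
    "GroundTruthSpec",
    "SyntheticDataset",
    "static_schedule",
    "rotating_schedule",
    "generate_regional_bold",
    "generate_behavior",
    "generate_dataset",
]


@dataclass(frozen=True)
class Perturbation:
    """A transient elevation of cross-community coupling.

    Parameters
    ----------
    nodes
        Region indices whose signals are perturbed.
    windows
        Half-open window-index interval ``[start, stop)`` during which the
        perturbation is active (coherence windows, not samples).
    factor
        Coupling-increase factor ``f >= 1``.  The perturbed node's community
        component becomes a convex mixture of its own community signal
        (weight ``1 - beta``) and the mean of the other communities' signals
        (weight ``beta``), with ``beta = (f - 1) / f`` and the mixture
        re-normalised to unit variance.  ``f = 1`` is a no-op; ``f = 2``
        mixes own and foreign signals equally.
    """

    nodes: tuple[int, ...]
    windows: tuple[int, int]
    factor: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(int(i) for i in self.nodes))
        if self.factor < 1.0:
            raise InvalidSpecError(f"perturbation factor must be >= 1, got {self.factor}")
        if self.windows[0] < 0 or self.windows[1] <= self.windows[0]:
            raise InvalidSpecError(f"invalid perturbation window range {self.windows}")


def static_schedule(n_regions: int, n_communities: int) -> list[tuple[int, int | None, np.ndarray]]:
    """A single static partition of ``n_regions`` into ``n_communities``
    contiguous, nearly equal blocks, covering all windows.

    Returns a schedule in the form used by :class:`GroundTruthSpec`:
    ``[(start_window, stop_window_or_None, labels)]``.
    """
    if n_communities < 1 or n_communities > n_regions:
        raise InvalidSpecError(
            f"cannot partition {n_regions} regions into {n_communities} non-empty communities"
        )
    labels = np.array_split(np.arange(n_regions), n_communities)
    out = np.empty(n_regions, dtype=np.int64)
    for c, idx in enumerate(labels, start=1):
        if idx.size == 0:
            raise InvalidSpecError("empty community in schedule")
        out[idx] = c
    return [(0, None, out)]


def rotating_schedule(
    n_regions: int,
    n_communities: int,
    n_windows: int,
    period: int = 6,
    n_moving: int = 2,
) -> list[tuple[int, int, np.ndarray]]:
    """A time-varying planted partition with community switches at known windows.

    Starting from the static block partition, every ``period`` windows a
    fresh set of ``n_moving`` nodes (round-robin over regions) is displaced
    into the next community, emulating the modest membership turnover seen
    in task fMRI while keeping the bulk structure stable.
    """
    if period < 1 or n_moving < 0:
        raise InvalidSpecError("period must be >= 1 and n_moving >= 0")
    base = static_schedule(n_regions, n_communities)[0][2]
    schedule = []
    for seg, start in enumerate(range(0, n_windows, period)):
        lab = base.copy()
        for m in range(n_moving):
            node = (seg * n_moving + m) % n_regions
            lab[node] = (lab[node] % n_communities) + 1
        schedule.append((start, min(start + period, n_windows), lab))
    return schedule


@dataclass
class GroundTruthSpec:
    """Study-condition parameters of the synthetic dataset.

    Defaults mirror the acquisition the analysis targets: 148 regions, three
    concatenated runs of 366 volumes at TR = 2 s, task-relevant coherence in
    roughly the 0.06-0.12 Hz band, 20-volume coherence windows.
    """

    n_regions: int = 148
    n_runs: int = 3
    volumes_per_run: int = 366
    sampling_interval: float = 2.0
    band: tuple[float, float] = (0.06, 0.12)
    window_length: int = 20
    community_schedule: list | None = None  # [(start_win, stop_win|None, labels[N])]
    n_communities: int = 6
    snr: float = 2.0
    perturbation: Perturbation | None = None
    n_participants: int = 7
    n_behavior_runs: int = 4
    trials_per_cell: int = 18
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- derived sizes -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.n_runs * self.volumes_per_run

    @property
    def n_windows(self) -> int:
        return self.n_samples // self.window_length

    @property
    def nyquist(self) -> float:
        return 0.5 / self.sampling_interval

    def validate(self) -> None:
        if self.n_regions < 2:
            raise InvalidSpecError("need at least 2 regions")
        if self.n_samples < self.window_length:
            raise InvalidSpecError(
                f"{self.n_samples} total volumes do not fill one {self.window_length}-volume window"
            )
        lo, hi = self.band
        if not (0.0 < lo < hi < self.nyquist):
            raise InvalidSpecError(
                f"band {self.band} must lie strictly inside (0, Nyquist={self.nyquist:g}) Hz"
            )
        if self.snr < 0:
            raise InvalidSpecError("snr must be non-negative")
        if self.community_schedule is None:
            self.community_schedule = static_schedule(self.n_regions, self.n_communities)
        for start, stop, labels in self.community_schedule:
            labels = np.asarray(labels)
            if labels.shape != (self.n_regions,):
                raise InvalidSpecError(
                    "each scheduled partition must assign every region exactly one community"
                )
            if np.any(~np.isfinite(labels.astype(float))):
                raise InvalidSpecError("partition labels must be finite integers")

    # -- schedule expansion --------------------------------------------
    def window_labels(self) -> np.ndarray:
        """Planted partition, one row of region labels per coherence window."""
        L = self.n_windows
        out = np.full((L, self.n_regions), -1, dtype=np.int64)
        for start, stop, labels in self.community_schedule:
            stop_ = L if stop is None else min(int(stop), L)
            out[int(start):stop_] = np.asarray(labels, dtype=np.int64)
        if np.any(out < 0):
            raise InvalidSpecError("community_schedule does not cover all windows")
        return out


@dataclass
class SyntheticDataset:
    """Everything one simulated experiment produces."""

    spec: GroundTruthSpec
    timeseries: dict  # (participant, condition) -> RegionalTimeseriesSet
    true_partition: np.ndarray  # L x N planted labels
    behavior: pd.DataFrame


def _condition_code(condition: str) -> int:
    known = {"sham": 0, "rtms": 1}
    if condition in known:
        return known[condition]
    return 2 + (zlib.crc32(condition.encode()) & 0x0FFFFFFF)


def _bandpassed_noise(rng: np.random.Generator, n: int, dt: float,
                      band: tuple[float, float], size: int) -> np.ndarray:
    """`size` independent unit-variance Gaussian signals band-limited to `band`."""
    freqs = np.fft.rfftfreq(n, d=dt)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    white = rng.standard_normal((size, n))
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~mask] = 0.0
    sig = np.fft.irfft(spec, n=n, axis=1)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def generate_regional_bold(
    spec: GroundTruthSpec,
    participant: int,
    condition: str = "sham",
    perturb: bool | None = None,
) -> tuple[RegionalTimeseriesSet, np.ndarray]:
    """Simulate one participant-condition recording.

    Each region's series is ``snr * s_c(t) + e(t)`` where ``s_c`` is the
    band-limited signal of the region's current planted community and ``e``
    is independent white noise; the result is z-scored per region.  When
    ``perturb`` is true (default: true iff ``condition == 'rtms'``) and the
    spec carries a perturbation, the perturbed nodes' community component is
    mixed with foreign-community signals during the perturbation windows.

    Returns the time-series set and the planted window-wise labels (L x N).
    """
    spec.validate()
    if perturb is None:
        perturb = condition == "rtms"
    rng = np.random.default_rng([spec.seed, int(participant), _condition_code(condition)])

    T, N, dt = spec.n_samples, spec.n_regions, spec.sampling_interval
    win_labels = spec.window_labels()
    comm_ids = np.unique(win_labels)
    K = comm_ids.size
    signals = _bandpassed_noise(rng, T, dt, spec.band, K)  # K x T
    sig_of = {c: signals[k] for k, c in enumerate(comm_ids)}

    # per-sample community of each region (samples past the last full window
    # reuse the last window's labels)
    win_of_sample = np.minimum(np.arange(T) // spec.window_length, spec.n_windows - 1)
    sample_labels = win_labels[win_of_sample]  # T x N

    comm_component = np.empty((T, N))
    for k, c in enumerate(comm_ids):
        m = sample_labels == c
        comm_component[m] = np.broadcast_to(signals[k][:, None], (T, N))[m]

    if perturb and spec.perturbation is not None and K > 1:
        p = spec.perturbation
        beta = (p.factor - 1.0) / p.factor
        w0, w1 = p.windows
        t_mask = (win_of_sample >= w0) & (win_of_sample < min(w1, spec.n_windows))
        for i in p.nodes:
            own = sample_labels[:, i]
            mixed = comm_component[:, i].copy()
            for c in comm_ids:
                sel = t_mask & (own == c)
                if not np.any(sel):
                    continue
                others = [sig_of[o] for o in comm_ids if o != c]
                foreign = np.mean(others, axis=0)
                n_other = len(others)
                mix = (1.0 - beta) * sig_of[c][sel] + beta * foreign[sel]
                # foreign mean of n independent unit-variance signals has
                # variance 1/n; re-normalise the mixture to unit variance
                mix /= np.sqrt((1.0 - beta) ** 2 + beta**2 / n_other)
                mixed[sel] = mix
            comm_component[:, i] = mixed

    noise = rng.standard_normal((T, N))
    data = spec.snr * comm_component + noise
    data = (data - data.mean(axis=0)) / data.std(axis=0)

    region_names = [f"R{i:03d}" for i in range(N)]
    run_boundaries = [r * spec.volumes_per_run for r in range(spec.n_runs)]
    ts = RegionalTimeseriesSet(
        data=data,
        region_names=region_names,
        sampling_interval=dt,
        run_boundaries=run_boundaries,
    )
    return ts, win_labels


def generate_behavior(
    spec: GroundTruthSpec,
    effect: float = 0.08,
    baseline: float = 0.85,
    trials_per_cell: int | None = None,
) -> pd.DataFrame:
    """Simulate the tracking-accuracy table.

    Accuracy in each (participant, run, hemifield, condition) cell is a
    binomial proportion at ``baseline``, reduced by ``effect`` only in the
    (run 1, contralateral, rTMS) cells — the planted behavioral consequence
    of stimulation.
    """
    spec.validate()
    if trials_per_cell is None:
        trials_per_cell = spec.trials_per_cell
    if not 0.0 <= effect <= baseline:
        raise InvalidSpecError(
            f"effect {effect} must lie in [0, baseline={baseline}] (negative accuracy)"
        )
    rng = np.random.default_rng([spec.seed, 970_417])
    rows = []
    for p in range(spec.n_participants):
        for run in range(1, spec.n_behavior_runs + 1):
            for hemi in ("contralateral", "ipsilateral"):
                for cond in ("rtms", "sham"):
                    prob = baseline
                    if run == 1 and hemi == "contralateral" and cond == "rtms":
                        prob = baseline - effect
                    correct = int(rng.binomial(trials_per_cell, prob))
                    rows.append(
                        dict(
                            participant=p,
                            run=run,
                            hemifield=hemi,
                            condition=cond,
                            n_correct=correct,
                            n_trials=trials_per_cell,
                            accuracy=correct / trials_per_cell,
                        )
                    )
    return pd.DataFrame(rows)


def generate_dataset(
    spec: GroundTruthSpec,
    conditions: Sequence[str] = ("sham", "rtms"),
    behavioral_effect: float = 0.08,
) -> SyntheticDataset:
    """Simulate the full experiment: all participants and conditions plus behavior.

    The spec's perturbation, if any, is applied to the 'rtms' condition only.
    """
    timeseries = {}
    true_partition = spec.window_labels()
    for p in range(spec.n_participants):
        for cond in conditions:
            ts, _ = generate_regional_bold(spec, p, cond)
            timeseries[(p, cond)] = ts
    behavior = generate_behavior(spec, effect=behavioral_effect)
    return SyntheticDataset(
        spec=spec, timeseries=timeseries, true_partition=true_partition, behavior=behavior
    )
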