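"""End-to-end pipeline: simulate -> coherence -> communities -> metrics ->
consensus -> condition statistics, driven by a single config.

Every stage writes plain-text artifacts (TSV tables plus JSON manifests)
into the run directory; the run is deterministic given the config,
including its master seed, and the manifest records every derived seed and
per-stage size so a run can be replayed or resumed from any serialized
intermediate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import metrics as _metrics
from . import stats as _stats
from .coherence import windowed_band_coherence
from .communities import DynamicCommunityModel, parameter_sweep
from .errors import DegenerateInputError, StageError
from .synthetic import GroundTruthSpec, Perturbation, generate_behavior, generate_regional_bold
from .timeseries import RegionalTimeseriesSet

__all__ = ["PipelineConfig", "run_pipeline"]

CONDITIONS = ("sham", "rtms")
NODE_METRICS = ("flexibility", "cohesion_strength", "promiscuity")


@dataclass
class PipelineConfig:
    """All knobs of one analysis run.  Defaults are the study conditions."""

    # synthetic data (ignored when input_dir is given)
    n_regions: int = 148
    n_participants: int = 7
    n_runs: int = 3
    volumes_per_run: int = 366
    sampling_interval: float = 2.0
    band: tuple = (0.06, 0.12)
    window_length: int = 20
    n_communities: int = 6
    snr: float = 2.0
    perturbation_nodes: list | None = None
    perturbation_windows: tuple = (0, 15)
    perturbation_factor: float = 2.0
    behavioral_effect: float = 0.08
    input_dir: str | None = None
    # community detection
    gamma: float = 1.0
    omega: float = 1.0
    sweep: bool = False
    sweep_grid_size: int = 4
    sweep_lo: float = 0.25
    sweep_hi: float = 31.62
    runs_per_cell: int = 3
    ensemble_size: int = 100
    # statistics
    epoch_length: int = 10
    step: int = 1
    q: float = 0.05
    coverage: float = 0.95
    draws: int = 10_000
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k in ("band", "perturbation_windows"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("band", "perturbation_windows"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    def ground_truth_spec(self) -> GroundTruthSpec:
        pert = None
        if self.perturbation_nodes:
            pert = Perturbation(
                nodes=tuple(self.perturbation_nodes),
                windows=tuple(self.perturbation_windows),
                factor=self.perturbation_factor,
            )
        return GroundTruthSpec(
            n_regions=self.n_regions,
            n_runs=self.n_runs,
            volumes_per_run=self.volumes_per_run,
            sampling_interval=self.sampling_interval,
            band=tuple(self.band),
            window_length=self.window_length,
            n_communities=self.n_communities,
            snr=self.snr,
            perturbation=pert,
            n_participants=self.n_participants,
            seed=self.seed,
        )


def _stage(manifest: dict, name: str):
    class _Ctx:
        def __enter__(self):
            manifest["stages"].setdefault(name, {})
            return manifest["stages"][name]

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def _derived_seed(master: int, *tags: int) -> int:
    return int(np.random.default_rng([master, *tags]).integers(0, 2**31 - 1))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage; returns (and writes) the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"seed": config.seed, "stages": {}}

    participants = range(config.n_participants)

    # ---------------- simulate (or load) ------------------------------
    timeseries: dict = {}
    behavior = None
    with _stage(manifest, "simulate") as rec:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        if config.input_dir is None:
            spec = config.ground_truth_spec()
            _io.write_partition(spec.window_labels(), ts_dir / "true_partition.tsv")
            for p in participants:
                for cond in CONDITIONS:
                    ts, _ = generate_regional_bold(spec, p, cond)
                    timeseries[(p, cond)] = ts
                    ts.to_tsv(ts_dir / f"ts_p{p}_{cond}.tsv",
                              extra_meta={"participant": p, "condition": cond,
                                          "seed": config.seed})
            behavior = generate_behavior(spec, effect=config.behavioral_effect)
            behavior.to_csv(ts_dir / "behavior.tsv", sep="\t", index=False)
        else:
            src = Path(config.input_dir)
            for p in participants:
                for cond in CONDITIONS:
                    timeseries[(p, cond)] = RegionalTimeseriesSet.from_tsv(
                        src / f"ts_p{p}_{cond}.tsv"
                    )
            beh_path = src / "behavior.tsv"
            if beh_path.exists():
                behavior = pd.read_csv(beh_path, sep="\t")
        rec["n_series"] = len(timeseries)
        rec["n_samples"] = timeseries[(0, "sham")].n_samples
        rec["n_regions"] = timeseries[(0, "sham")].n_regions

    # ---------------- coherence ---------------------------------------
    stacks: dict = {}
    with _stage(manifest, "coherence") as rec:
        coh_dir = out / "coherence"
        for (p, cond), ts in timeseries.items():
            stack = windowed_band_coherence(
                ts, window_length=config.window_length, band=tuple(config.band)
            )
            stacks[(p, cond)] = stack
            stack.to_dir(coh_dir / f"p{p}_{cond}")
        rec["n_layers"] = stacks[(0, "sham")].n_layers
        rec["n_stacks"] = len(stacks)

    # ---------------- community detection -----------------------------
    ensembles: dict = {}
    with _stage(manifest, "communities") as rec:
        comm_dir = out / "communities"
        comm_dir.mkdir(exist_ok=True)
        gamma, omega = config.gamma, config.omega
        if config.sweep:
            grid = np.geomspace(config.sweep_lo, config.sweep_hi, config.sweep_grid_size)
            surface = parameter_sweep(
                [stacks[(p, "sham")] for p in participants],
                gamma_grid=grid, omega_grid=grid,
                runs_per_cell=config.runs_per_cell,
                seed=_derived_seed(config.seed, 11),
            )
            gamma, omega = surface.optimum
            _io.write_matrix(surface.diff, comm_dir / "qsurface_diff.tsv")
            rec["sweep_optimum"] = [gamma, omega]
        rec["gamma"], rec["omega"] = gamma, omega
        seeds = {}
        for (p, cond), stack in stacks.items():
            model = DynamicCommunityModel(stack, gamma=gamma, omega=omega)
            s = _derived_seed(config.seed, 23, p, 0 if cond == "sham" else 1)
            seeds[f"p{p}_{cond}"] = s
            ens = model.fit_ensemble(n_runs=config.ensemble_size, seed=s)
            ensembles[(p, cond)] = ens
            _io.write_partition(ens.best().labels, comm_dir / f"p{p}_{cond}_best.tsv")
        rec["ensemble_size"] = config.ensemble_size
        rec["ensemble_seeds"] = seeds
        rec["mean_q"] = float(np.mean([ens.qs.mean() for ens in ensembles.values()]))

    # ---------------- node metrics ------------------------------------
    tables: dict = {}
    with _stage(manifest, "metrics") as rec:
        met_dir = out / "metrics"
        met_dir.mkdir(exist_ok=True)
        names = stacks[(0, "sham")].region_names
        for (p, cond), ens in ensembles.items():
            df = pd.DataFrame(
                {
                    "flexibility": ens.mean_metric("flexibility"),
                    "cohesion_strength": ens.mean_metric("cohesion"),
                    "promiscuity": ens.mean_metric("promiscuity"),
                },
                index=pd.Index(names, name="region"),
            )
            tables[(p, cond)] = df
            _io.write_matrix(ens.mean_allegiance(), met_dir / f"p{p}_{cond}_allegiance.tsv")
        rec["metrics"] = list(NODE_METRICS)

    # ---------------- consensus + reference-structure metrics ---------
    with _stage(manifest, "consensus") as rec:
        met_dir = out / "metrics"
        per_participant = []
        for p in participants:
            parts = [row for r in ensembles[(p, "sham")].runs for row in r.labels]
            per_participant.append(_metrics.consensus_partition(parts)[0])
        if len(per_participant) == 1:
            group_ref, rep_idx = per_participant[0], 0
        else:
            group_ref, rep_idx = _metrics.consensus_partition(per_participant)
        np.savetxt(out / "metrics" / "consensus.tsv", group_ref[None, :],
                   fmt="%d", delimiter="\t")
        rec["n_consensus_communities"] = int(len(np.unique(group_ref)))
        rec["representative_participant"] = int(rep_idx)
        for (p, cond), ens in ensembles.items():
            P = ens.mean_allegiance()
            recr, integ = _metrics.recruitment_integration(P, group_ref)
            tables[(p, cond)]["recruitment"] = recr
            tables[(p, cond)]["integration"] = integ
            _io.write_metric_table(tables[(p, cond)], met_dir / f"p{p}_{cond}_metrics.tsv")
        mean_sham_coh = np.mean(
            [stacks[(p, "sham")].layers.mean(axis=0) for p in participants], axis=0
        )
        wmd = _metrics.within_module_degree(mean_sham_coh, group_ref)
        pc = _metrics.participation_coefficient(mean_sham_coh, group_ref)
        hubs, integrators = _metrics.classify_hubs_integrators(wmd, pc)
        roles = pd.DataFrame(
            {"within_module_degree": wmd, "participation": pc,
             "hub": hubs, "integrator": integrators},
            index=pd.Index(stacks[(0, "sham")].region_names, name="region"),
        )
        _io.write_metric_table(roles, met_dir / "node_roles.tsv")
        rec["n_hubs"] = int(hubs.sum())
        rec["n_integrators"] = int(integrators.sum())

    # ---------------- condition statistics ----------------------------
    with _stage(manifest, "compare") as rec:
        st_dir = out / "stats"
        st_dir.mkdir(exist_ok=True)
        # static per-node paired tests + cross-condition correlation
        # (group tests need at least 2 participants)
        node_rows = []
        metric_columns = (
            list(tables[(0, "sham")].columns) if config.n_participants >= 2 else []
        )
        if not metric_columns:
            rec["group_tests"] = "skipped (single participant)"
        for metric in metric_columns:
            tms = np.stack([tables[(p, "rtms")][metric].to_numpy() for p in participants])
            sham = np.stack([tables[(p, "sham")][metric].to_numpy() for p in participants])
            if np.isnan(tms).any() or np.isnan(sham).any():
                continue
            df = _stats.per_node_condition_test(tms, sham, q=config.q)
            df.insert(0, "metric", metric)
            df.insert(1, "region", stacks[(0, "sham")].region_names)
            node_rows.append(df)
            try:
                corr = _stats.condition_correlation(tms.mean(axis=0), sham.mean(axis=0))
            except DegenerateInputError:
                corr = None  # constant metric vector: correlation undefined
            rec[f"corr_{metric}"] = corr
            pooled = np.concatenate([tms.ravel(), sham.ravel()])
            null = _stats.metric_null(
                pooled, tms.mean(axis=0), draws=config.draws,
                group_size=config.n_participants, coverage=config.coverage,
                seed=_derived_seed(config.seed, 31, hash(metric) % 1000),
            )
            rec[f"null_flagged_{metric}"] = int(null["flags"].sum())
        if node_rows:
            pd.concat(node_rows).to_csv(st_dir / "per_node_tests.tsv", sep="\t",
                                        index=False)

        # sliding SSD per dynamics metric
        L = stacks[(0, "sham")].n_layers
        if config.epoch_length <= L and config.n_participants >= 2:
            for metric in NODE_METRICS:
                per_cond = {c: [] for c in CONDITIONS}
                for p in participants:
                    for cond in CONDITIONS:
                        series = _stats.sliding_metrics(
                            [r.labels for r in ensembles[(p, cond)].runs],
                            (metric,), epoch_length=config.epoch_length, step=config.step,
                        )
                        per_cond[cond].append(series.values[metric])
                times = np.arange(per_cond["sham"][0].shape[0]) * (
                    config.window_length * config.sampling_interval / 60.0
                )
                try:
                    cmp_ = _stats.ssd_contrast(
                        per_cond["rtms"], per_cond["sham"], epoch_times=times, q=config.q
                    )
                except DegenerateInputError:
                    rec[f"ssd_{metric}"] = "degenerate (zero epoch variance)"
                    continue
                pd.DataFrame(
                    {
                        "epoch_min": cmp_.epoch_times,
                        "t": cmp_.t,
                        "p_raw": cmp_.p_raw,
                        "p_fdr": cmp_.p_fdr,
                        "significant": cmp_.significant,
                    }
                ).to_csv(st_dir / f"ssd_{metric}.tsv", sep="\t", index=False)
                rec[f"ssd_significant_epochs_{metric}"] = int(cmp_.significant.sum())
            rec["n_epochs"] = int(per_cond["sham"][0].shape[0])

        if behavior is not None:
            boot = _stats.behavioral_bootstrap(
                behavior, draws=config.draws, seed=_derived_seed(config.seed, 41)
            )
            rec["behavior_observed_diff"] = boot["observed"]
            rec["behavior_p_one_tailed"] = boot["p_one_tailed"]

    _io.write_json(manifest, out / "manifest.json")
    return manifest
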