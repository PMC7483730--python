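"""Regional time-series container and plain-text round-tripping."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["RegionalTimeseriesSet"]


@dataclass
class RegionalTimeseriesSet:
    """T x N matrix of regional activity with its acquisition metadata.

    data : array, shape (T, N)
        One column per region.  Downstream coherence assumes columns are
        z-scored (mean 0, sd 1); :meth:`zscored` enforces this.
    region_names : list of str
    sampling_interval : float
        Seconds between samples (fMRI TR).
    run_boundaries : list of int
        Sample index at which each concatenated run starts (first entry 0).
    """

    data: np.ndarray
    region_names: list[str]
    sampling_interval: float
    run_boundaries: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("timeseries data must be a T x N matrix")
        if not np.all(np.isfinite(self.data)):
            raise DataError("timeseries contain non-finite values")
        if len(self.region_names) != self.data.shape[1]:
            raise DataError("region_names length does not match the number of columns")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def zscored(self) -> "RegionalTimeseriesSet":
        """Return a copy with each region's series z-scored."""
        sd = self.data.std(axis=0)
        if np.any(sd == 0):
            raise DataError("zero-variance region cannot be z-scored")
        data = (self.data - self.data.mean(axis=0)) / sd
        return RegionalTimeseriesSet(
            data, list(self.region_names), self.sampling_interval, list(self.run_boundaries)
        )

    # ------------------------------------------------------------------
    # plain-text interchange: TSV with a region-name header plus a JSON
    # sidecar carrying the sampling interval and run boundaries
    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path, extra_meta: dict | None = None) -> None:
        path = Path(path)
        pd.DataFrame(self.data, columns=self.region_names).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
        meta = {
            "sampling_interval": self.sampling_interval,
            "run_boundaries": list(map(int, self.run_boundaries)),
        }
        if extra_meta:
            meta.update(extra_meta)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionalTimeseriesSet":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        else:
            raise DataError(f"missing sidecar metadata {sidecar}")
        return cls(
            data=df.to_numpy(dtype=float),
            region_names=list(df.columns),
            sampling_interval=float(meta["sampling_interval"]),
            run_boundaries=list(meta.get("run_boundaries", [0])),
        )
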