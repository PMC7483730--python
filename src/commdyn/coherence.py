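"""Wavelet-coherence functional connectivity.

Pipeline: Morlet continuous wavelet transform of each region's z-scored
series -> smoothed auto/cross spectra -> magnitude-squared coherence ->
average over the scales whose equivalent Fourier frequency falls in the
task band -> average within non-overlapping temporal windows.  The result
is an ordered stack of symmetric N x N coherence matrices in [0, 1], one
per window — the layers of the multilayer network.

The Morlet here is the standard analytic wavelet with centre frequency
omega0 = 6 (pywavelets ``cmor2.0-0.9549...``: Gaussian envelope
exp(-t^2/2), carrier exp(i*omega0*t)).  The coherence estimator smooths
the spectra with a boxcar over time of one wavelet period per scale and a
3-point boxcar across scales; without smoothing the estimator is
identically 1, so the smoother is part of the definition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt
from scipy.ndimage import uniform_filter1d

from .errors import ConfigError, DataError, UndefinedCoherenceError
from .timeseries import RegionalTimeseriesSet

__all__ = [
    "CoherenceStack",
    "frequency_grid",
    "morlet_cwt",
    "wavelet_coherence",
    "windowed_band_coherence",
]

DEFAULT_OMEGA0 = 6.0
DEFAULT_FREQ_RANGE = (0.01, 0.25)
DEFAULT_N_SCALES = 32


def _wavelet_name(omega0: float) -> str:
    # pywt 'cmorB-C': psi(t) ~ exp(-t^2/B) exp(2*pi*i*C*t); B=2, C=omega0/2pi
    # reproduces the standard Morlet with unit-variance Gaussian envelope.
    return f"cmor2.0-{omega0 / (2.0 * np.pi):.12f}"


def frequency_grid(
    fmin: float = DEFAULT_FREQ_RANGE[0],
    fmax: float = DEFAULT_FREQ_RANGE[1],
    n_scales: int = DEFAULT_N_SCALES,
) -> np.ndarray:
    """Logarithmically spaced equivalent Fourier frequencies (Hz), descending in scale."""
    if not (0 < fmin < fmax):
        raise ConfigError(f"invalid frequency range ({fmin}, {fmax})")
    return np.geomspace(fmin, fmax, n_scales)


def scales_for_frequencies(
    frequencies: np.ndarray, sampling_interval: float, omega0: float = DEFAULT_OMEGA0
) -> np.ndarray:
    """Wavelet scales whose equivalent Fourier frequency equals `frequencies`."""
    c = pywt.central_frequency(_wavelet_name(omega0))
    return c / (np.asarray(frequencies) * sampling_interval)


def morlet_cwt(
    series: np.ndarray,
    sampling_interval: float,
    scales: np.ndarray | None = None,
    frequencies: np.ndarray | None = None,
    omega0: float = DEFAULT_OMEGA0,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Morlet CWT of a 1-D series (or T x N matrix, transformed per column).

    Returns ``(coefficients, frequencies)`` where coefficients have shape
    (n_scales, T) for 1-D input and (N, n_scales, T) for matrix input, and
    frequencies are the equivalent Fourier frequencies in Hz.
    """
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise DataError("non-finite values in input series")
    if scales is None:
        if frequencies is None:
            frequencies = frequency_grid()
        scales = scales_for_frequencies(frequencies, sampling_interval, omega0)
    scales = np.asarray(scales, dtype=float)
    wav = _wavelet_name(omega0)
    if series.ndim == 1:
        coef, freqs = pywt.cwt(series, scales, wav, sampling_period=sampling_interval,
                               method="fft")
        return coef, freqs
    if series.ndim != 2:
        raise DataError("series must be 1-D or T x N")
    coef, freqs = pywt.cwt(series.T, scales, wav, sampling_period=sampling_interval,
                           method="fft", axis=-1)
    # pywt returns (n_scales, N, T); reorder to (N, n_scales, T)
    return np.moveaxis(coef, 0, 1), freqs


def _time_smoothing_lengths(frequencies: np.ndarray, sampling_interval: float) -> np.ndarray:
    """Boxcar length per scale: one wavelet period, in samples (>= 1)."""
    return np.maximum(1, np.round(1.0 / (frequencies * sampling_interval)).astype(int))


def _smooth(arr: np.ndarray, lengths: np.ndarray, scale_width: int) -> np.ndarray:
    """Boxcar smoothing over time (per-scale length) then across scales.

    `arr` has the scale axis second-to-last and time last; complex input is
    smoothed component-wise.
    """
    if np.iscomplexobj(arr):
        return _smooth(arr.real, lengths, scale_width) + 1j * _smooth(
            arr.imag, lengths, scale_width
        )
    out = np.empty_like(arr)
    for s, w in enumerate(lengths):
        sl = (..., s, slice(None))
        if w > 1:
            out[sl] = uniform_filter1d(arr[sl], size=int(w), axis=-1, mode="nearest")
        else:
            out[sl] = arr[sl]
    if scale_width > 1 and len(lengths) > 1:
        out = uniform_filter1d(out, size=scale_width, axis=-2, mode="nearest")
    return out


def _coherence(sxy: np.ndarray, sxx: np.ndarray, syy: np.ndarray) -> np.ndarray:
    denom = sxx * syy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(sxy) ** 2 / denom
    coh = np.where(denom > 0, coh, 0.0)
    return np.clip(coh, 0.0, 1.0)


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    sampling_interval: float,
    frequencies: np.ndarray | None = None,
    omega0: float = DEFAULT_OMEGA0,
    smoothing: bool = True,
    scale_smoothing: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared wavelet coherence of two series, (n_scales, T) in [0, 1].

    With ``smoothing=False`` the estimator degenerates to the algebraic
    identity coherence == 1 everywhere; that mode exists only as a guard
    that smoothing is actually applied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D series of equal length")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCoherenceError("coherence undefined for zero-variance input")
    if frequencies is None:
        frequencies = frequency_grid()
    wx, freqs = morlet_cwt(x, sampling_interval, frequencies=frequencies, omega0=omega0)
    wy, _ = morlet_cwt(y, sampling_interval, frequencies=frequencies, omega0=omega0)
    if smoothing:
        lengths = _time_smoothing_lengths(freqs, sampling_interval)
        sw = scale_smoothing
    else:
        lengths = np.ones(len(freqs), dtype=int)
        sw = 1
    sxx = _smooth(np.abs(wx) ** 2, lengths, sw)
    syy = _smooth(np.abs(wy) ** 2, lengths, sw)
    sxy = _smooth(wx * np.conj(wy), lengths, sw)
    return _coherence(sxy, sxx, syy), freqs


@dataclass
class CoherenceStack:
    """Ordered stack of symmetric windowed coherence matrices (multilayer network).

    layers : array, shape (L, N, N)
        Off-diagonal entries in [0, 1]; the diagonal is defined as 0 so
        self-coherence never enters the modularity null model.
    """

    layers: np.ndarray
    window_length: int
    band: tuple[float, float]
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3 or self.layers.shape[1] != self.layers.shape[2]:
            raise DataError("layers must have shape (L, N, N)")
        if not self.region_names:
            self.region_names = [f"R{i:03d}" for i in range(self.layers.shape[1])]

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.layers)):
            raise DataError("non-finite coherence values")
        if not np.allclose(self.layers, np.transpose(self.layers, (0, 2, 1))):
            raise DataError("layers must be symmetric")
        di = self.layers[:, np.arange(self.n_nodes), np.arange(self.n_nodes)]
        if np.any(di != 0):
            raise DataError("layer diagonals must be 0")

    # -- plain-text interchange ----------------------------------------
    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for l_idx in range(self.n_layers):
            np.savetxt(directory / f"layer_{l_idx:03d}.tsv", self.layers[l_idx],
                       delimiter="\t", fmt="%.8g")
        manifest = {
            "n_layers": self.n_layers,
            "n_nodes": self.n_nodes,
            "window_length": self.window_length,
            "band": list(self.band),
            "region_names": self.region_names,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def from_dir(cls, directory: str | Path) -> "CoherenceStack":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        layers = np.stack(
            [
                np.loadtxt(directory / f"layer_{l_idx:03d}.tsv", delimiter="\t")
                for l_idx in range(manifest["n_layers"])
            ]
        )
        return cls(
            layers=layers,
            window_length=manifest["window_length"],
            band=tuple(manifest["band"]),
            region_names=manifest["region_names"],
        )


# ----------------------------------------------------------------------
# fast pair kernel (numba-compiled when available); reproduces the
# scipy.ndimage boxcar semantics (mode='nearest', even sizes shifted left)
# ----------------------------------------------------------------------

def _pairs_window_coherence_py(Wr, Wi, autoS, lengths, scale_width, wlen, L, iu, ju):
    n_pairs = iu.size
    S, T = Wr.shape[1], Wr.shape[2]
    out = np.zeros((n_pairs, L))
    crossR = np.empty((S, T))
    crossI = np.empty((S, T))
    smR = np.empty((S, T))
    smI = np.empty((S, T))
    cum = np.empty(T + 1)
    for p in range(n_pairs):
        i = iu[p]
        j = ju[p]
        for s in range(S):
            for t in range(T):
                ar = Wr[i, s, t]
                ai = Wi[i, s, t]
                br = Wr[j, s, t]
                bi = Wi[j, s, t]
                crossR[s, t] = ar * br + ai * bi
                crossI[s, t] = ai * br - ar * bi
            w = lengths[s]
            if w > 1:
                for comp in range(2):
                    x = crossR[s] if comp == 0 else crossI[s]
                    cum[0] = 0.0
                    for t in range(T):
                        cum[t + 1] = cum[t] + x[t]
                    lo = w // 2
                    hi = w - 1 - lo
                    for t in range(T):
                        a = t - lo
                        b = t + hi
                        acc = 0.0
                        if a < 0:
                            acc += (-a) * x[0]
                            a = 0
                        if b > T - 1:
                            acc += (b - (T - 1)) * x[T - 1]
                            b = T - 1
                        acc += cum[b + 1] - cum[a]
                        if comp == 0:
                            smR[s, t] = acc / w
                        else:
                            smI[s, t] = acc / w
                crossR[s, :] = smR[s, :]
                crossI[s, :] = smI[s, :]
        if scale_width > 1 and S > 1:
            half_lo = scale_width // 2
            half_hi = scale_width - 1 - half_lo
            for s in range(S):
                for t in range(T):
                    accR = 0.0
                    accI = 0.0
                    for d in range(-half_lo, half_hi + 1):
                        s2 = s + d
                        if s2 < 0:
                            s2 = 0
                        elif s2 > S - 1:
                            s2 = S - 1
                        accR += crossR[s2, t]
                        accI += crossI[s2, t]
                    smR[s, t] = accR / scale_width
                    smI[s, t] = accI / scale_width
        else:
            smR[:, :] = crossR
            smI[:, :] = crossI
        for l_idx in range(L):
            acc = 0.0
            for t in range(l_idx * wlen, (l_idx + 1) * wlen):
                bsum = 0.0
                for s in range(S):
                    denom = autoS[i, s, t] * autoS[j, s, t]
                    if denom > 0.0:
                        c = (smR[s, t] ** 2 + smI[s, t] ** 2) / denom
                        if c > 1.0:
                            c = 1.0
                        elif c < 0.0:
                            c = 0.0
                        bsum += c
                acc += bsum / S
            out[p, l_idx] = acc / wlen
    return out


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit as _njit

    _pairs_window_coherence = _njit(cache=False)(_pairs_window_coherence_py)
except Exception:  # pragma: no cover
    _pairs_window_coherence = _pairs_window_coherence_py


def windowed_band_coherence(
    ts: RegionalTimeseriesSet,
    window_length: int = 20,
    band: tuple[float, float] = (0.06, 0.12),
    frequencies: np.ndarray | None = None,
    omega0: float = DEFAULT_OMEGA0,
    scale_smoothing: int = 3,
) -> CoherenceStack:
    """Windowed band-averaged wavelet coherence for every region pair.

    The CWT is computed once on the full concatenated series (windows may
    straddle run seams); coherence is averaged over the scales whose
    equivalent frequency falls in ``band`` and over the samples of each
    non-overlapping ``window_length`` window.  A trailing partial window is
    discarded.
    """
    T, N = ts.data.shape
    if T < window_length:
        raise ConfigError(f"series length {T} shorter than one window ({window_length})")
    if frequencies is None:
        frequencies = frequency_grid()
    in_band = (frequencies >= band[0]) & (frequencies <= band[1])
    if not np.any(in_band):
        raise ConfigError(f"no wavelet scales fall inside band {band}")
    freqs = np.asarray(frequencies)[in_band]

    data = ts.zscored().data
    L = T // window_length

    w, freqs = morlet_cwt(data, ts.sampling_interval, frequencies=freqs, omega0=omega0)
    lengths = _time_smoothing_lengths(freqs, ts.sampling_interval)
    auto = _smooth(np.abs(w) ** 2, lengths, scale_smoothing)  # (N, S, T)

    iu, ju = np.triu_indices(N, k=1)
    win_coh = _pairs_window_coherence(
        np.ascontiguousarray(w.real),
        np.ascontiguousarray(w.imag),
        np.ascontiguousarray(auto),
        lengths.astype(np.int64),
        int(scale_smoothing),
        int(window_length),
        int(L),
        iu.astype(np.int64),
        ju.astype(np.int64),
    )
    layers = np.zeros((L, N, N))
    layers[:, iu, ju] = win_coh.T
    layers[:, ju, iu] = win_coh.T

    return CoherenceStack(
        layers=layers,
        window_length=window_length,
        band=band,
        region_names=list(ts.region_names),
    )
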