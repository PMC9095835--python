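"""Spectral estimation: per-epoch periodograms, Welch PSD, seven-band
absolute/relative power, cortical smoothing, and peak alpha frequency.

Band power follows the analysis convention of resting-state EEG studies of
thalamocortical dysrhythmia: spectra on a 0.5 Hz grid (2-s windows), power
summed over half-open bands [low, high), relative power as the band share of
the summed power of all defined bands, computed per epoch and then averaged
over epochs.  The inter-band gaps (7.5-8, 12.5-13, the 55-65 Hz notch region,
and everything above 90 Hz) contribute to no band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

from .geometry import CorticalMesh

__all__ = [
    "Band",
    "FrequencyBands",
    "DEFAULT_BANDS",
    "Spectrum",
    "BandPowerTable",
    "epoch_fft_power",
    "welch_psd",
    "band_power",
    "relative_power",
    "smoothing_weights",
    "smooth_on_cortex",
    "compute_paf",
]

GRID_STEP_HZ = 0.5


@dataclass(frozen=True)
class Band:
    name: str
    low: float   # Hz, inclusive
    high: float  # Hz, exclusive

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


@dataclass(frozen=True)
class FrequencyBands:
    """Ordered, non-overlapping half-open bands on the 0.5 Hz grid."""

    bands: tuple

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(self.bands))
        lows = [b.low for b in self.bands]
        if sorted(lows) != lows:
            raise ValueError("bands must be ordered by frequency")
        for a, b in zip(self.bands, self.bands[1:]):
            if b.low < a.high:
                raise ValueError(f"bands {a.name} and {b.name} overlap")
        for b in self.bands:
            if b.high - b.low < GRID_STEP_HZ:
                raise ValueError(f"band {b.name} contains no 0.5 Hz grid point")

    def __iter__(self):
        return iter(self.bands)

    def __len__(self):
        return len(self.bands)

    @property
    def names(self) -> tuple:
        return tuple(b.name for b in self.bands)

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)


DEFAULT_BANDS = FrequencyBands((
    Band("delta", 2.0, 3.5),
    Band("theta", 3.5, 7.5),
    Band("alpha1", 8.0, 10.0),
    Band("alpha2", 10.0, 12.5),
    Band("beta", 13.0, 30.0),
    Band("gamma1", 30.0, 55.0),
    Band("gamma2", 65.0, 90.0),
))


@dataclass
class Spectrum:
    """Power spectral density on the 0.5 Hz grid.

    ``power`` has shape (n_locations, n_freqs) for averaged spectra or
    (n_epochs, n_locations, n_freqs) for per-epoch spectra.
    """

    frequencies: np.ndarray
    power: np.ndarray
    per_epoch: bool = False
    level: str = "scalp"   # scalp channel | vertex | node

    def __post_init__(self):
        df = np.diff(self.frequencies)
        if len(df) and not np.allclose(df, GRID_STEP_HZ, atol=1e-9):
            raise ValueError("frequency grid step must be exactly 0.5 Hz")
        if np.any(self.power < -1e-12):
            raise ValueError("spectral power must be non-negative")


@dataclass
class BandPowerTable:
    """Absolute and relative band power per location, averaged over epochs.

    ``abs_epoch``/``rel_epoch`` (n_epochs, n_locations, n_bands) retain the
    per-epoch tables that CFC consumes; ``abs_power``/``rel_power`` are the
    epoch means (or the single table for already-averaged spectra).
    """

    band_names: tuple
    abs_power: np.ndarray
    rel_power: np.ndarray
    n_epochs: int
    level: str = "scalp"
    abs_epoch: np.ndarray | None = None
    rel_epoch: np.ndarray | None = None

    def __post_init__(self):
        sums = self.rel_power.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-10):
            raise ValueError("relative powers must sum to 1 per location")


def _check_epoch_grid(n_samples: int, fs: float) -> None:
    if abs(n_samples / fs - 2.0) > 1e-9:
        raise ValueError(
            f"epoch length must be 2 s for the 0.5 Hz grid (got {n_samples / fs:g} s)")


def _linear_detrend(x: np.ndarray) -> np.ndarray:
    """Least-squares line removal along the last axis (closed form)."""
    n = x.shape[-1]
    t = np.arange(n) - (n - 1) / 2.0
    denom = (t**2).sum()
    mean = x.mean(axis=-1, keepdims=True)
    slope = (x @ t)[..., None] / denom
    return x - mean - slope * t


def _hann_density_psd(segments: np.ndarray, fs: float) -> np.ndarray:
    """One-sided PSD (unit^2/Hz) of linearly detrended, Hann-tapered
    segments along the last axis; matches scipy's periodogram scaling.

    Processed in row blocks to bound temporary memory on large inputs.
    """
    n = segments.shape[-1]
    win = sps.get_window("hann", n)
    scale = 1.0 / (fs * (win**2).sum())
    lead = segments.shape[:-1]
    flat = segments.reshape(-1, n)
    out = np.empty((flat.shape[0], n // 2 + 1))
    block = max(1, 4_000_000 // n)
    for i in range(0, flat.shape[0], block):
        spec = np.fft.rfft(_linear_detrend(flat[i:i + block]) * win, axis=-1)
        out[i:i + block] = (spec.real**2 + spec.imag**2) * scale
    out[..., 1:] *= 2.0
    if n % 2 == 0:
        out[..., -1] /= 2.0
    return out.reshape(lead + (n // 2 + 1,))


def epoch_fft_power(epochs: np.ndarray, fs: float, level: str = "scalp") -> Spectrum:
    """Per-epoch periodogram: linear detrend, Hann taper, squared FFT.

    ``epochs`` is (n_epochs, n_locations, n_samples) with 2-s epochs, giving
    Fourier coefficients at 0.5 Hz steps.  Power is a density (unit^2/Hz) with
    the usual taper-power normalization.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_epochs, n_locations, n_samples)")
    _check_epoch_grid(epochs.shape[-1], fs)
    freqs = np.fft.rfftfreq(epochs.shape[-1], 1.0 / fs)
    power = _hann_density_psd(epochs, fs)
    return Spectrum(freqs, power, per_epoch=True, level=level)


def welch_psd(data: np.ndarray, fs: float, window_s: float = 2.0,
              overlap: float = 0.5, level: str = "vertex") -> Spectrum:
    """Welch PSD: mean of Hann-tapered 50%-overlapping segment periodograms.

    ``data`` is (n_locations, n_samples); epoched input may be concatenated
    along time beforehand.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    nperseg = int(round(window_s * fs))
    _check_epoch_grid(nperseg, fs)
    step = nperseg - int(round(overlap * nperseg))
    if data.shape[-1] < nperseg + step:
        raise ValueError("input too short for at least two Welch windows")
    n_seg = (data.shape[-1] - nperseg) // step + 1
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    n_loc = data.shape[0]
    power = np.empty((n_loc, nperseg // 2 + 1))
    block = max(1, 4_000_000 // (n_seg * nperseg))
    for i in range(0, n_loc, block):
        segments = data[i:i + block][:, idx]        # (block, n_seg, nperseg)
        power[i:i + block] = _hann_density_psd(segments, fs).mean(axis=-2)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return Spectrum(freqs, power, per_epoch=False, level=level)


def band_power(spec: Spectrum, bands: FrequencyBands = DEFAULT_BANDS) -> np.ndarray:
    """Sum of spectral power over each half-open band [low, high).

    Returns (..., n_locations, n_bands) matching the spectrum's epoch layout.
    """
    f = spec.frequencies
    out = []
    for b in bands:
        mask = (f >= b.low - 1e-9) & (f < b.high - 1e-9)
        if not mask.any():
            raise ValueError(f"frequency grid does not cover band {b.name}")
        if f[0] > b.low + 1e-9 or f[-1] < b.high - GRID_STEP_HZ - 1e-9:
            raise ValueError(f"frequency grid does not fully cover band {b.name}")
        out.append(spec.power[..., mask].sum(axis=-1))
    return np.stack(out, axis=-1)


def relative_power(abs_power: np.ndarray, bands: FrequencyBands = DEFAULT_BANDS,
                   level: str = "scalp") -> BandPowerTable:
    """Band share of total defined-band power, per epoch, then epoch-averaged.

    ``abs_power`` is (n_epochs, n_locations, n_bands) or (n_locations,
    n_bands) from :func:`band_power`.
    """
    abs_power = np.asarray(abs_power, dtype=float)
    total = abs_power.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero total band power in at least one epoch/location")
    rel = abs_power / total
    if abs_power.ndim == 3:
        return BandPowerTable(bands.names, abs_power.mean(axis=0),
                              rel.mean(axis=0), abs_power.shape[0], level,
                              abs_epoch=abs_power, rel_epoch=rel)
    return BandPowerTable(bands.names, abs_power, rel, 1, level)


def smoothing_weights(mesh: CorticalMesh, fwhm_mm: float = 3.0) -> np.ndarray:
    """Row-normalized geodesic Gaussian kernel over the mesh graph.

    Distances are graph-shortest-path lengths over mesh edges (truncated at
    4 sigma); row ``i`` holds the weights averaging into vertex ``i``.
    """
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    edges = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]],
                       mesh.faces[:, [2, 0]]])
    lengths = np.linalg.norm(mesh.vertex_positions[edges[:, 0]] -
                             mesh.vertex_positions[edges[:, 1]], axis=1)
    n = mesh.n_vertices
    graph = sparse.csr_matrix((lengths, (edges[:, 0], edges[:, 1])), shape=(n, n))
    graph = graph.maximum(graph.T)
    if connected_components(graph, directed=False)[0] != 1:
        raise ValueError("mesh graph is disconnected")
    dist = dijkstra(graph, directed=False, limit=4.0 * sigma)
    with np.errstate(over="ignore"):
        w = np.exp(-0.5 * (dist / sigma) ** 2)
    w[np.isinf(dist)] = 0.0
    # symmetric Sinkhorn scaling -> doubly stochastic weights, so constant
    # maps are fixed points AND total mass is conserved
    d = np.ones(n)
    for _ in range(200):
        d = np.sqrt(d / (w @ d))
        if abs((d[:, None] * w * d[None, :]).sum(axis=1) - 1.0).max() < 1e-13:
            break
    w = d[:, None] * w * d[None, :]
    w /= w.sum(axis=1, keepdims=True)
    return w


def smooth_on_cortex(values: np.ndarray, mesh: CorticalMesh,
                     fwhm_mm: float = 3.0,
                     weights: np.ndarray | None = None) -> np.ndarray:
    """Geodesic Gaussian smoothing of a vertex map with normalized weights.

    Weight renormalization leaves a constant map unchanged and conserves
    total mass on the symmetric graph.  Pass a precomputed ``weights`` matrix
    (from :func:`smoothing_weights`) to amortize the distance computation.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != mesh.n_vertices:
        raise ValueError("map length must equal n_vertices")
    if not np.all(np.isfinite(values)):
        raise ValueError("vertex map must be finite")
    if fwhm_mm <= 0:
        return values.copy()
    if weights is None:
        weights = smoothing_weights(mesh, fwhm_mm)
    return values @ weights.T


def compute_paf(spec: Spectrum, window: tuple = (6.0, 14.0)) -> np.ndarray:
    """Peak alpha frequency per location: the frequency of the largest local
    maximum of the log power spectrum inside the search window (default
    6-14 Hz).  NaN flags locations with no interior spectral peak.
    """
    if spec.per_epoch:
        raise ValueError("compute_paf expects an epoch-averaged spectrum")
    f = spec.frequencies
    lo, hi = window
    if f[0] > lo + 1e-9 or f[-1] < hi - 1e-9:
        raise ValueError("frequency grid does not cover the PAF window")
    with np.errstate(divide="ignore"):
        logp = np.log(spec.power)
    n_loc = logp.shape[0]
    paf = np.full(n_loc, np.nan)
    in_win = (f >= lo - 1e-9) & (f <= hi + 1e-9)
    idx = np.where(in_win)[0]
    for loc in range(n_loc):
        lp = logp[loc]
        best, best_val = None, -np.inf
        for i in idx:
            if 0 < i < len(f) - 1 and lp[i] > lp[i - 1] and lp[i] > lp[i + 1]:
                if lp[i] > best_val:
                    best, best_val = i, lp[i]
        if best is not None:
            paf[loc] = f[best]
    return paf
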