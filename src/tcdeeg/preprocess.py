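"""Deterministic signal conditioning: zero-phase high-pass + line-noise
notch, average reference, 2-s epoching with amplitude rejection, and
selection of the first 80 s of clean data.

All filters are 4th-order Butterworth sections applied forward-backward
(zero phase).  The notch is a 55-65 Hz band-stop; at sampling rates that
resolve them, the line-frequency harmonics (115-125 Hz, ...) are stopped as
well.  Every step appends a provenance entry so a run can be reproduced from
its log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import SubjectRecording

__all__ = ["EpochedRecording", "InsufficientDataError",
           "highpass_notch", "average_reference", "epoch_and_select"]


class InsufficientDataError(RuntimeError):
    pass


@dataclass
class EpochedRecording:
    """Clean 2-s epochs (epoch x channel x sample, microvolts)."""

    epochs: np.ndarray
    fs: float
    kept_epoch_ids: np.ndarray
    labels: tuple
    epoch_length: float = 2.0
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.kept_epoch_ids = np.asarray(self.kept_epoch_ids, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be epoch x channel x sample")
        if self.epochs.shape[-1] != int(round(self.fs * self.epoch_length)):
            raise ValueError("every epoch must span exactly epoch_length")
        if np.any(np.diff(self.kept_epoch_ids) <= 0):
            raise ValueError("kept_epoch_ids must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def highpass_notch(rec: SubjectRecording, hp_hz: float = 2.0,
                   notch: tuple = (55.0, 65.0), order: int = 4
                   ) -> SubjectRecording:
    """Zero-phase Butterworth high-pass plus 55-65 Hz band-stop (and its
    harmonics up to Nyquist where the sampling rate permits)."""
    nyq = rec.fs / 2.0
    if nyq <= notch[1]:
        raise ValueError("sampling rate too low for the notch band")
    sos = sps.butter(order, hp_hz, btype="highpass", fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=-1)
    stops = []
    line = 0.5 * (notch[0] + notch[1])
    half = 0.5 * (notch[1] - notch[0])
    k = 1
    while k * line + half < nyq:
        stops.append((k * line - half, k * line + half))
        k += 1
    for lo, hi in stops:
        sos = sps.butter(order, (lo, hi), btype="bandstop", fs=rec.fs,
                         output="sos")
        data = sps.sosfiltfilt(sos, data, axis=-1)
    return rec.with_data(data, {"step": "highpass_notch", "hp_hz": hp_hz,
                                "notch_bands": stops, "order": order})


def average_reference(rec: SubjectRecording) -> SubjectRecording:
    """Re-reference so the instantaneous channel mean is zero."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.with_data(data, {"step": "average_reference"})


def epoch_and_select(rec: SubjectRecording, epoch_s: float = 2.0,
                     reject_abs_uV: float = 100.0, budget_s: float = 80.0
                     ) -> EpochedRecording:
    """Cut consecutive non-overlapping epochs, drop any containing a sample
    beyond the absolute-amplitude threshold, and keep the earliest surviving
    epochs totalling ``budget_s`` (default 40 x 2 s) in temporal order."""
    ep_len = int(round(epoch_s * rec.fs))
    n_total = rec.data.shape[1] // ep_len
    needed = int(round(budget_s / epoch_s))
    cut = rec.data[:, : n_total * ep_len].reshape(rec.n_channels, n_total, ep_len)
    cut = np.moveaxis(cut, 0, 1)                       # (epoch, channel, sample)
    clean = np.where(np.abs(cut).max(axis=(1, 2)) <= reject_abs_uV)[0]
    if len(clean) < needed:
        raise InsufficientDataError(
            f"only {len(clean)} clean epochs available, need {needed} "
            f"({needed - len(clean)} short)")
    kept = clean[:needed]
    return EpochedRecording(
        epochs=cut[kept], fs=rec.fs, kept_epoch_ids=kept, labels=rec.labels,
        epoch_length=epoch_s,
        provenance=rec.provenance + [{"step": "epoch_and_select",
                                      "epoch_s": epoch_s,
                                      "reject_abs_uV": reject_abs_uV,
                                      "budget_s": budget_s}])
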