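"""Continuous multichannel recordings and their HDF5 container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = ["SubjectRecording", "save_recording", "load_recording"]


@dataclass
class SubjectRecording:
    """Continuous EEG, channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    labels: tuple
    subject_id: str = "S000"
    group: str = ""
    sex: str = ""
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count must match channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def with_data(self, data: np.ndarray, step: dict) -> "SubjectRecording":
        """Copy with new sample data and one provenance entry appended."""
        return replace(self, data=data, provenance=self.provenance + [step])


def save_recording(rec: SubjectRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("data", data=rec.data)
        ds.attrs["units"] = "uV"
        fh.attrs["fs"] = rec.fs
        fh.attrs["subject_id"] = rec.subject_id
        fh.attrs["group"] = rec.group
        fh.attrs["sex"] = rec.sex
        fh.create_dataset("labels",
                          data=np.array(rec.labels, dtype=h5py.string_dtype()))


def load_recording(path: str | Path) -> SubjectRecording:
    with h5py.File(path, "r") as fh:
        return SubjectRecording(
            data=fh["data"][()],
            fs=float(fh.attrs["fs"]),
            labels=[s.decode() if isinstance(s, bytes) else s
                    for s in fh["labels"][()]],
            subject_id=str(fh.attrs["subject_id"]),
            group=str(fh.attrs["group"]),
            sex=str(fh.attrs["sex"]),
        )
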