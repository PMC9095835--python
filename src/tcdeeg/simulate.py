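"""Synthetic two-group EEG cohorts with thalamocortical-dysrhythmia-like
ground truth.

Each subject's cortical activity is built per atlas node as a sum of seven
band-limited noise components: spectrally shaped Gaussian noise whose
amplitude carries a 1/f profile (component amplitude proportional to the
inverse band-centre frequency) scaled by group-level band gains.  The alpha1
component is the dominant rhythm: a Gaussian spectral bump centred on the
subject's drawn peak alpha frequency (PAF), so that a group with a lowered
PAF (e.g. 7.8 Hz vs 9.2 Hz) spills oscillatory power into the theta band —
the classic dysrhythmia signature.  Gamma gains act only on a designated
focus-node set, giving spatially localized gamma elevation.

Epoch-wise power-power coupling uses a Gaussian copula: a shared latent
normal per 2-s epoch drives log-normal amplitude modulation of the low bands
and gamma1.  Because Spearman's rho is invariant under the monotone exp map,
the latent correlation needed for a target rank correlation rho_s is exact:
rho_latent = 2 sin(pi rho_s / 6).  Negative targets drive the amplitudes in
opposition (inverse theta-gamma coupling).

Node signals are copied to member vertices (fixed normal orientation),
projected to the scalp through the lead field, and white sensor noise is
added.  All ground-truth values (PAF, node x band source amplitude, realized
epoch-amplitude rank correlations, seed) are recorded per subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as ss

from .geometry import LeadField
from .parcellation import Atlas
from .recording import SubjectRecording, save_recording
from .spectral import DEFAULT_BANDS, FrequencyBands

__all__ = [
    "GroupSpec",
    "GroundTruth",
    "simulate_subject",
    "simulate_cohort",
    "control_spec",
    "affected_spec",
    "preset_specs",
    "spearman_to_latent",
    "EPOCH_S",
]

EPOCH_S = 2.0
SOURCE_SCALE_PAM = 1000.0         # base per-vertex dipole amplitude, pA.m
ALPHA_BUMP_SIGMA_HZ = 0.7         # dominant-rhythm spectral width (~1.6 Hz FWHM)
AMP_MODULATION_S = 0.4            # log-normal epoch amplitude modulation depth
MODULATED_BANDS = ("theta", "alpha1", "alpha2", "gamma1")

_DEFAULT_GAIN = {"delta": 1.0, "theta": 1.0, "alpha1": 3.0, "alpha2": 1.0,
                 "beta": 0.8, "gamma1": 1.0, "gamma2": 1.0}


def spearman_to_latent(rho_s: float) -> float:
    """Gaussian-copula latent (Pearson) correlation giving Spearman ``rho_s``.

    For bivariate normal latents, rho_s = (6/pi) asin(rho_latent / 2); this is
    the exact inverse.  Rank correlations survive any monotone amplitude map.
    """
    if abs(rho_s) > 1:
        raise ValueError("|rho| must be <= 1")
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one synthetic group."""

    label: str
    n_subjects: int = 10
    paf_mean: float = 9.5          # Hz
    paf_sd: float = 0.9            # Hz
    band_gain: dict = field(default_factory=lambda: dict(_DEFAULT_GAIN))
    gamma_focus_nodes: frozenset = frozenset()
    cfc_rho: dict = field(default_factory=dict)   # low band -> target Spearman
    noise_sd: float = 1.0          # sensor white noise, uV

    def __post_init__(self):
        object.__setattr__(self, "gamma_focus_nodes",
                           frozenset(self.gamma_focus_nodes))
        object.__setattr__(self, "band_gain", dict(self.band_gain))
        object.__setattr__(self, "cfc_rho", dict(self.cfc_rho))
        if not 6.0 <= self.paf_mean <= 14.0:
            raise ValueError("paf_mean must lie in [6, 14] Hz")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(g <= 0 for g in self.band_gain.values()):
            raise ValueError("band gains must be positive")
        for band, rho in self.cfc_rho.items():
            if band not in ("theta", "alpha1", "alpha2"):
                raise ValueError(f"cfc_rho band must be a low band, got {band}")
            if abs(rho) > 0.95:
                raise ValueError("|cfc_rho| must be <= 0.95")
        if self.paf_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class GroundTruth:
    """Per-subject generative ground truth (acceptance surface)."""

    subject_id: str
    paf: float                                    # Hz
    band_amplitude: np.ndarray                    # (n_nodes, n_bands) pA.m
    epoch_amplitudes: dict                        # band -> (n_epochs,) modulation
    realized_rho: dict                            # low band -> Spearman vs gamma1
    seed: int
    node_signals: np.ndarray | None = None        # (n_nodes, n_samples) pA.m

    def to_json(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "paf": float(self.paf),
            "band_amplitude": self.band_amplitude.tolist(),
            "epoch_amplitudes": {b: a.tolist()
                                 for b, a in self.epoch_amplitudes.items()},
            "realized_rho": {b: float(r) for b, r in self.realized_rho.items()},
            "seed": int(self.seed),
        }


def _shaped_noise(rng: np.random.Generator, n_samples: int, fs: float,
                  shape: np.ndarray) -> np.ndarray:
    """Unit-variance real noise whose amplitude spectrum follows ``shape``."""
    n_f = n_samples // 2 + 1
    w = rng.standard_normal(n_f) + 1j * rng.standard_normal(n_f)
    x = np.fft.irfft(w * shape, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_shapes(freqs: np.ndarray, paf: float,
                 bands: FrequencyBands) -> dict[str, np.ndarray]:
    shapes = {}
    for b in bands:
        if b.name == "alpha1":
            shapes[b.name] = np.exp(-0.5 * ((freqs - paf) / ALPHA_BUMP_SIGMA_HZ) ** 2)
        else:
            shapes[b.name] = ((freqs >= b.low) & (freqs < b.high)).astype(float)
    return shapes


def simulate_subject(spec: GroupSpec, leadfield: LeadField, atlas: Atlas,
                     duration: float = 120.0, fs: float = 500.0,
                     seed: int = 0, subject_id: str | None = None,
                     sex: str = "M", bands: FrequencyBands = DEFAULT_BANDS,
                     keep_sources: bool = False,
                     ) -> tuple[SubjectRecording, GroundTruth]:
    """Generate one subject's sensor recording plus its ground truth.

    Deterministic for a fixed seed.  ``duration`` must be at least 100 s so
    the preprocessing chain can retain 80 s of clean epochs; ``fs`` must
    resolve the gamma2 band (Nyquist above 90 Hz).
    """
    if duration < 100.0:
        raise ValueError("duration must be >= 100 s")
    if fs / 2.0 <= max(b.high for b in bands):
        raise ValueError("fs too low: Nyquist must exceed the highest band edge")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * fs))
    n_epochs = int(n_samples // (EPOCH_S * fs))
    ep_len = int(EPOCH_S * fs)
    n_nodes = atlas.n_nodes

    paf = float(np.clip(rng.normal(spec.paf_mean, spec.paf_sd), 6.1, 13.9))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shapes = _band_shapes(freqs, paf, bands)

    # --- epoch-wise amplitude modulation via the Gaussian copula -----------
    v_gamma = rng.standard_normal(n_epochs)           # shared gamma1 latent
    latents = {"gamma1": v_gamma}
    for name in MODULATED_BANDS:
        if name == "gamma1":
            continue
        rho_l = spearman_to_latent(spec.cfc_rho.get(name, 0.0))
        eps = rng.standard_normal(n_epochs)
        latents[name] = rho_l * v_gamma + np.sqrt(1.0 - rho_l**2) * eps
    s = AMP_MODULATION_S
    epoch_amp = {name: np.exp(s * z - 0.5 * s**2) for name, z in latents.items()}
    realized = {}
    for name in ("theta", "alpha1", "alpha2"):
        realized[name] = float(ss.spearmanr(epoch_amp[name],
                                            epoch_amp["gamma1"]).statistic)

    # --- node source signals ----------------------------------------------
    centers = {b.name: (paf if b.name == "alpha1" else b.center) for b in bands}
    amp_table = np.zeros((n_nodes, len(bands)))
    node_signals = np.zeros((n_nodes, n_samples))
    for node in range(n_nodes):
        for j, b in enumerate(bands):
            gain = spec.band_gain.get(b.name, 1.0)
            if b.name in ("gamma1", "gamma2") and node not in spec.gamma_focus_nodes:
                gain = 1.0
            amp = SOURCE_SCALE_PAM * gain / centers[b.name]
            amp_table[node, j] = amp
            x = amp * _shaped_noise(rng, n_samples, fs, shapes[b.name])
            if b.name in MODULATED_BANDS:
                mod = np.repeat(epoch_amp[b.name], ep_len)
                x[: len(mod)] *= mod
            node_signals[node] += x

    # --- project to sensors -------------------------------------------------
    node_gain = np.zeros((leadfield.n_channels, n_nodes))
    for node in range(n_nodes):
        node_gain[:, node] = leadfield.gain[:, atlas.node_members(node)].sum(axis=1)
    data = node_gain @ node_signals
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)

    sid = subject_id or f"{spec.label}-{seed:06d}"
    rec = SubjectRecording(data=data, fs=fs, labels=leadfield.montage.labels,
                           subject_id=sid, group=spec.label, sex=sex)
    truth = GroundTruth(subject_id=sid, paf=paf, band_amplitude=amp_table,
                        epoch_amplitudes=epoch_amp, realized_rho=realized,
                        seed=seed,
                        node_signals=node_signals if keep_sources else None)
    return rec, truth


def simulate_cohort(specs: list[GroupSpec], leadfield: LeadField, atlas: Atlas,
                    duration: float = 120.0, fs: float = 500.0,
                    master_seed: int = 0, out_dir: str | Path | None = None,
                    bands: FrequencyBands = DEFAULT_BANDS,
                    ) -> tuple[list[tuple[SubjectRecording, GroundTruth]], list[dict]]:
    """Simulate every subject of every group with deterministic per-subject
    seeds derived from ``master_seed``; optionally persist recordings, ground
    truth, and a JSON manifest under ``out_dir``.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    out = []
    manifest = []
    seen_ids = set()
    for gi, spec in enumerate(specs):
        for si in range(spec.n_subjects):
            sub_seed = int(np.random.SeedSequence(
                entropy=master_seed, spawn_key=(gi, si)).generate_state(1)[0]
                % (2**31 - 1))
            sid = f"{spec.label}-{si:03d}"
            if sid in seen_ids:
                raise ValueError(f"duplicate subject id {sid}")
            seen_ids.add(sid)
            sex = "M" if si % 2 == 0 else "F"
            rec, truth = simulate_subject(spec, leadfield, atlas, duration, fs,
                                          seed=sub_seed, subject_id=sid,
                                          sex=sex, bands=bands)
            entry = {"subject_id": sid, "group": spec.label, "sex": sex,
                     "seed": sub_seed, "file": None}
            if out_dir is not None:
                root_dir = Path(out_dir)
                root_dir.mkdir(parents=True, exist_ok=True)
                rec_path = root_dir / f"{sid}.h5"
                save_recording(rec, rec_path)
                with open(root_dir / f"{sid}.truth.json", "w") as fh:
                    json.dump(truth.to_json(), fh, indent=1)
                entry["file"] = rec_path.name
            manifest.append(entry)
            out.append((rec, truth))
    if out_dir is not None:
        with open(Path(out_dir) / "manifest.json", "w") as fh:
            json.dump({"master_seed": master_seed, "subjects": manifest}, fh,
                      indent=1)
    return out, manifest


# ---------------------------------------------------------------------------
# shipped presets mirroring the reported group signatures

def _focus_nodes(atlas: Atlas) -> frozenset:
    """Temporal/parietal/occipital nodes of the atlas (gamma elevation sites)."""
    return frozenset(i for i, reg in enumerate(atlas.node_region)
                     if reg.split("-")[0] in ("T", "P", "O"))


def control_spec(atlas: Atlas, n_subjects: int = 10) -> GroupSpec:
    """Control-like group: PAF 9.2 Hz, canonical band profile, weak positive
    theta-gamma1 coupling."""
    return GroupSpec(
        label="control", n_subjects=n_subjects, paf_mean=9.2, paf_sd=0.9,
        band_gain={"delta": 1.0, "theta": 1.0, "alpha1": 3.0, "alpha2": 1.0,
                   "beta": 0.8, "gamma1": 1.0, "gamma2": 1.0},
        gamma_focus_nodes=_focus_nodes(atlas),
        cfc_rho={"theta": 0.2}, noise_sd=1.0)


def affected_spec(atlas: Atlas, n_subjects: int = 10) -> GroupSpec:
    """FXS-like group: PAF slowed to 7.8 Hz, elevated theta, reduced alpha2,
    gamma elevated on temporal/parietal/occipital nodes, inverse theta-gamma1
    coupling."""
    return GroupSpec(
        label="affected", n_subjects=n_subjects, paf_mean=7.8, paf_sd=0.9,
        band_gain={"delta": 1.0, "theta": 1.25, "alpha1": 2.2, "alpha2": 0.7,
                   "beta": 0.8, "gamma1": 1.8, "gamma2": 1.4},
        gamma_focus_nodes=_focus_nodes(atlas),
        cfc_rho={"theta": -0.4}, noise_sd=1.0)


def preset_specs(atlas: Atlas, n_subjects: int = 10) -> tuple[GroupSpec, GroupSpec]:
    return control_spec(atlas, n_subjects), affected_spec(atlas, n_subjects)
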