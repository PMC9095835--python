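"""Power-power cross-frequency coupling.

Couples each low band's whole-brain mean relative power (theta, alpha1,
alpha2) with gamma1 relative power inside every cortical node, as a Spearman
rank correlation across the 2-s epoch series, Fisher Z-transformed for group
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = ["EpochPowerSeries", "LOW_BANDS", "whole_brain_low_power",
           "cfc_spearman", "fisher_z", "cfc_table"]

LOW_BANDS = ("theta", "alpha1", "alpha2")
_RHO_CLIP = 1.0 - 1e-7


@dataclass
class EpochPowerSeries:
    """Source-level relative power, epoch x band x node."""

    rel_power: np.ndarray
    band_names: tuple
    node_ids: np.ndarray

    def __post_init__(self):
        self.rel_power = np.asarray(self.rel_power, dtype=float)
        self.band_names = tuple(self.band_names)
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        if self.rel_power.ndim != 3:
            raise ValueError("rel_power must be epoch x band x node")
        sums = self.rel_power.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-10):
            raise ValueError("band shares must sum to 1 per epoch and node")

    @property
    def n_epochs(self) -> int:
        return self.rel_power.shape[0]

    def band(self, name: str) -> np.ndarray:
        """(n_epochs, n_nodes) series of one band's relative power."""
        return self.rel_power[:, self.band_names.index(name), :]


def whole_brain_low_power(series: EpochPowerSeries, band: str) -> np.ndarray:
    """Per-epoch mean of a low band's relative power across all nodes."""
    if band not in LOW_BANDS:
        raise ValueError(f"band must be one of {LOW_BANDS}, got {band!r}")
    return series.band(band).mean(axis=1)


def cfc_spearman(low_series: np.ndarray, gamma_series: np.ndarray
                 ) -> np.ndarray:
    """Spearman rho between a scalar epoch series and each node's gamma1
    series (average ranks for ties).  Nodes with a constant series are
    flagged NaN with a warning."""
    low_series = np.asarray(low_series, dtype=float)
    gamma_series = np.asarray(gamma_series, dtype=float)
    if gamma_series.ndim == 1:
        gamma_series = gamma_series[:, None]
    if len(low_series) != gamma_series.shape[0]:
        raise ValueError("epoch counts differ")
    if len(low_series) < 10:
        raise ValueError("need at least 10 epochs for CFC")
    if not (np.all(np.isfinite(low_series)) and np.all(np.isfinite(gamma_series))):
        raise ValueError("missing values in power series")
    n_nodes = gamma_series.shape[1]
    rho = np.full(n_nodes, np.nan)
    low_const = np.ptp(low_series) == 0
    for k in range(n_nodes):
        if low_const or np.ptp(gamma_series[:, k]) == 0:
            warnings.warn(f"constant power series at node {k}; rho flagged NaN")
            continue
        rho[k] = ss.spearmanr(low_series, gamma_series[:, k]).statistic
    return rho


def fisher_z(rho: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing z = atanh(rho), with |rho| clipped just below 1
    so degenerate perfect correlations stay finite."""
    r = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(np.abs(r[np.isfinite(r)]) > 1.0):
        raise ValueError("|rho| must be <= 1")
    z = np.arctanh(np.clip(np.abs(r), None, _RHO_CLIP) * np.sign(r))
    return float(z[0]) if np.isscalar(rho) or np.ndim(rho) == 0 else z


def cfc_table(series: EpochPowerSeries,
              low_bands: tuple = LOW_BANDS) -> pd.DataFrame:
    """Tidy CFC table: one row per (low band, node) with rho and Fisher z."""
    gamma = series.band("gamma1")
    rows = []
    for band in low_bands:
        low = whole_brain_low_power(series, band)
        rho = cfc_spearman(low, gamma)
        z = fisher_z(rho)
        for k, node in enumerate(series.node_ids):
            rows.append({"low_band": band, "node_id": int(node),
                         "spearman_rho": rho[k], "fisher_z": z[k],
                         "n_epochs": series.n_epochs})
    return pd.DataFrame(rows)
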