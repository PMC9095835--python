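"""Group-difference inference.

Vertex/channel two-sample t-maps, cluster-based Monte-Carlo permutation
testing (clusters formed at the 0.025 per-tail critical value, cluster mass
= sum of member t values, max-|mass| permutation null), Benjamini-Hochberg
FDR across the signal x band grid, a scalp-level Bonferroni rule (0.05 over
the 7 bands), and age-controlled partial Spearman correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import sparse
from scipy import stats as ss
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AdjacencyGraph", "Cluster", "ClusterStatResult", "FDRResult",
    "two_sample_tmap", "cluster_permutation", "bh_fdr",
    "scalp_band_bonferroni", "partial_spearman",
    "channel_adjacency", "mesh_adjacency_graph",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric neighbourhood structure over analysis locations."""

    n_locations: int
    neighbors: tuple      # tuple of frozensets

    def __post_init__(self):
        nbrs = tuple(frozenset(s) for s in self.neighbors)
        object.__setattr__(self, "neighbors", nbrs)
        if len(nbrs) != self.n_locations:
            raise ValueError("neighbor list length must equal n_locations")
        for i, s in enumerate(nbrs):
            if i in s:
                raise ValueError("self-loops are not allowed")
            for j in s:
                if i not in nbrs[j]:
                    raise ValueError("adjacency must be symmetric")

    def to_sparse(self) -> sparse.csr_matrix:
        rows, cols = [], []
        for i, s in enumerate(self.neighbors):
            for j in s:
                rows.append(i)
                cols.append(j)
        data = np.ones(len(rows), dtype=np.int8)
        return sparse.csr_matrix((data, (rows, cols)),
                                 shape=(self.n_locations, self.n_locations))

    @property
    def n_components(self) -> int:
        return connected_components(self.to_sparse(), directed=False)[0]


def mesh_adjacency_graph(mesh) -> AdjacencyGraph:
    from .geometry import mesh_adjacency
    return AdjacencyGraph(mesh.n_vertices, tuple(mesh_adjacency(mesh)))


def channel_adjacency(positions: np.ndarray, factor: float = 1.3
                      ) -> AdjacencyGraph:
    """Channels are neighbours when closer than ``factor`` times the median
    nearest-neighbour inter-electrode distance."""
    pos = np.asarray(positions, dtype=float)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    thresh = factor * np.median(d.min(axis=1))
    nbrs = [frozenset(np.where(d[i] <= thresh)[0].tolist())
            for i in range(len(pos))]
    return AdjacencyGraph(len(pos), tuple(nbrs))


# ---------------------------------------------------------------------------
# t maps

def two_sample_tmap(group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Pooled-variance (Student) two-sample t per location, A minus B.

    Locations with zero pooled variance get t = 0 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the location set")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    t = np.zeros_like(diff)
    ok = se > 0
    if not ok.all():
        warnings.warn("zero pooled variance at some locations; t set to 0")
    t[ok] = diff[ok] / se[ok]
    return t


# ---------------------------------------------------------------------------
# cluster permutation

@dataclass
class Cluster:
    members: tuple
    mass: float          # sum of member t values
    p_value: float
    tail: str            # "pos" | "neg"


@dataclass
class ClusterStatResult:
    t_map: np.ndarray
    clusters: list
    location_p: np.ndarray      # per-location permutation p of |t|
    n_permutations: int
    alpha_per_tail: float
    seed: int | None
    exact: bool = False

    @property
    def min_cluster_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def _clusters_from_tmap(t: np.ndarray, thresh: float, adj: sparse.csr_matrix
                        ) -> list[tuple[np.ndarray, float, str]]:
    out = []
    for tail, mask in (("pos", t > thresh), ("neg", t < -thresh)):
        idx = np.where(mask)[0]
        if len(idx) == 0:
            continue
        sub = adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            out.append((members, float(t[members].sum()), tail))
    return out


def _max_cluster_mass(t: np.ndarray, thresh: float, adj: sparse.csr_matrix
                      ) -> float:
    best = 0.0
    for members, mass, _ in _clusters_from_tmap(t, thresh, adj):
        best = max(best, abs(mass))
    return best


def cluster_permutation(group_a: np.ndarray, group_b: np.ndarray,
                        adjacency: AdjacencyGraph, n_perm: int = 2000,
                        alpha_per_tail: float = 0.025,
                        seed: int | None = 0) -> ClusterStatResult:
    """Cluster-based Monte-Carlo permutation test of a group difference.

    Observed positive/negative clusters are formed at the per-tail t critical
    value; each cluster's mass is referenced to the permutation distribution
    of the maximum absolute cluster mass under full label exchange, giving
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.  When the total number
    of distinct relabellings is at most ``n_perm``, the exact enumeration is
    used instead.  Per-location permutation p values of |t| are returned for
    downstream FDR.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n_loc = a.shape[1]
    if adjacency.n_locations != n_loc:
        raise ValueError("adjacency must cover all locations")
    na, nb = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])
    df = na + nb - 2
    thresh = ss.t.ppf(1.0 - alpha_per_tail, df)
    adj = adjacency.to_sparse()

    t_obs = two_sample_tmap(a, b)
    obs_clusters = _clusters_from_tmap(t_obs, thresh, adj)

    total = comb(na + nb, na)
    exact = total <= n_perm
    if exact:
        assignments = combinations(range(na + nb), na)
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        assignments = (rng.permutation(na + nb)[:na] for _ in range(n_perm))
        n_used = n_perm

    null_max = np.empty(n_used)
    abs_t_obs = np.abs(t_obs)
    loc_exceed = np.zeros(n_loc)
    for i, pick in enumerate(assignments):
        sel = np.zeros(na + nb, dtype=bool)
        sel[list(pick)] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_perm = two_sample_tmap(pooled[sel], pooled[~sel])
        null_max[i] = _max_cluster_mass(t_perm, thresh, adj)
        loc_exceed += np.abs(t_perm) >= abs_t_obs - 1e-12

    if exact:
        location_p = loc_exceed / n_used
    else:
        location_p = (1.0 + loc_exceed) / (n_used + 1.0)
    clusters = []
    for members, mass, tail in obs_clusters:
        n_ge = int(np.sum(null_max >= abs(mass) - 1e-12))
        p = n_ge / n_used if exact else (1.0 + n_ge) / (n_used + 1.0)
        clusters.append(Cluster(tuple(int(m) for m in members), mass,
                                max(p, 1.0 / (n_used + 1.0)), tail))
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterStatResult(t_map=t_obs, clusters=clusters,
                             location_p=location_p, n_permutations=n_used,
                             alpha_per_tail=alpha_per_tail, seed=seed,
                             exact=exact)


# ---------------------------------------------------------------------------
# FDR and Bonferroni

@dataclass
class FDRResult:
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    rejected: np.ndarray
    q: float


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up adjusted p values and rejections at ``q``,
    applied to the flattened p-value collection (signals x bands)."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return FDRResult(p, p.copy(), np.zeros(0, dtype=bool), q)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    rejected, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FDRResult(p, p_adj, rejected, q)


def scalp_band_bonferroni(band_results: dict, alpha: float = 0.05,
                          n_bands: int = 7) -> dict:
    """Scalp-level significance: each band's minimum cluster p compared to
    ``alpha / 7`` (Bonferroni over the seven bands)."""
    if len(band_results) != n_bands:
        raise ValueError(f"expected {n_bands} bands, got {len(band_results)}")
    cut = alpha / n_bands
    report = {}
    for band, res in band_results.items():
        p = res.min_cluster_p if isinstance(res, ClusterStatResult) else float(res)
        report[band] = {"min_cluster_p": p, "threshold": cut,
                        "significant": bool(p < cut)}
    return report


# ---------------------------------------------------------------------------
# partial rank correlation

def partial_spearman(x: np.ndarray, y: np.ndarray, covariate: np.ndarray
                     ) -> tuple[float, float]:
    """Spearman correlation of x and y controlling for one covariate.

    All three series are rank-transformed (average ranks); the partial
    Pearson correlation of the rank vectors is
    ``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`` and the p value
    comes from the t approximation with n - 3 degrees of freedom.  A constant
    covariate degrades gracefully to the plain Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (len(x) == len(y) == len(z)):
        raise ValueError("inputs must share length")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    if not np.all(np.isfinite(z)):
        raise ValueError("covariate must be finite")
    rx, ry, rz = ss.rankdata(x), ss.rankdata(y), ss.rankdata(z)
    if np.ptp(rz) == 0:
        warnings.warn("constant covariate; falling back to plain Spearman")
        rho = ss.spearmanr(x, y).statistic
        dof = n - 2
    else:
        r_xy = np.corrcoef(rx, ry)[0, 1]
        r_xz = np.corrcoef(rx, rz)[0, 1]
        r_yz = np.corrcoef(ry, rz)[0, 1]
        denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
        if denom < 1e-7:
            # x or y is (rank-)identical to the covariate: nothing is left
            # to correlate once the covariate is removed
            warnings.warn("variable coincides with the covariate; "
                          "partial correlation set to 0")
            return 0.0, 1.0
        rho = (r_xy - r_xz * r_yz) / denom
        dof = n - 3
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) >= 1.0 - 1e-12:
        warnings.warn("degenerate perfect partial correlation; p clipped")
        return rho, 0.0
    t = rho * np.sqrt(dof / (1.0 - rho**2))
    p = 2.0 * ss.t.sf(abs(t), dof)
    return rho, float(p)
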