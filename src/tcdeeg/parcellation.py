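"""Vertex -> node -> region / resting-state-network aggregation.

Two atlases are supported: the shipped Desikan-Killiany (DK) classification
table (68 cortical nodes, 14 anatomical regions = 7 lobes x 2 hemispheres,
and 6 resting-state-network classes with 44 nodes assigned to DMN / DAN /
SAN / AUD / VIS and the rest labelled Other), and an auto-generated toy atlas
that clusters the toy mesh's vertices into a configurable node count so that
every downstream code path runs at desk scale.  Both are plain CSV and can be
replaced by the user without code changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CorticalMesh

__all__ = [
    "Atlas",
    "AtlasError",
    "make_toy_atlas",
    "dk_node_table",
    "aggregate_vertices",
    "group_nodes",
    "REGION_LABELS",
    "RSN_LABELS",
]

REGION_LABELS = tuple(f"{lobe}-{h}" for lobe in ("O", "L", "P", "T", "C", "F", "PF")
                      for h in ("R", "L"))
RSN_LABELS = ("DMN", "DAN", "SAN", "AUD", "VIS", "Other")


class AtlasError(ValueError):
    pass


@dataclass(frozen=True)
class Atlas:
    """vertex->node assignment plus node->region and node->RSN lookups."""

    vertex_to_node: np.ndarray      # (n_vertices,) int, every vertex assigned
    node_region: tuple              # region label per node id
    node_rsn: tuple                 # RSN label per node id

    def __post_init__(self):
        v2n = np.asarray(self.vertex_to_node, dtype=np.int64)
        object.__setattr__(self, "vertex_to_node", v2n)
        object.__setattr__(self, "node_region", tuple(self.node_region))
        object.__setattr__(self, "node_rsn", tuple(self.node_rsn))
        if v2n.min() < 0:
            raise AtlasError("unassigned vertex (negative node id)")
        k = len(self.node_region)
        if len(self.node_rsn) != k:
            raise AtlasError("region and RSN lookups disagree on node count")
        present = np.unique(v2n)
        if v2n.size and (v2n.max() >= k or len(present) != k):
            raise AtlasError("node ids must be contiguous and every node non-empty")
        bad = set(self.node_rsn) - set(RSN_LABELS)
        if bad:
            raise AtlasError(f"unknown RSN labels: {sorted(bad)}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_region)

    def node_members(self, node_id: int) -> np.ndarray:
        return np.where(self.vertex_to_node == node_id)[0]


def dk_node_table() -> pd.DataFrame:
    """The shipped DK 68-node classification (node, hemisphere, region, RSN)."""
    with resources.files("tcdeeg").joinpath("data/dk_nodes.csv").open() as fh:
        return pd.read_csv(fh)


def make_toy_atlas(mesh: CorticalMesh, n_nodes: int = 24, seed: int = 0) -> Atlas:
    """Cluster toy-mesh vertices into nodes; regions/RSNs assigned round-robin.

    Deterministic for fixed inputs: k-means on vertex positions with a seeded
    init, nodes relabelled by lexicographic order of their centroids.
    """
    if n_nodes < 2 or n_nodes > mesh.n_vertices:
        raise AtlasError("n_nodes must be in [2, n_vertices]")
    from scipy.cluster.vq import kmeans2
    rng = np.random.default_rng(seed)
    pts = mesh.vertex_positions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, labels = kmeans2(pts, n_nodes, minit="++", seed=rng, iter=50)
    # repair empty clusters by splitting the largest
    for k in range(n_nodes):
        if not np.any(labels == k):
            big = np.bincount(labels, minlength=n_nodes).argmax()
            members = np.where(labels == big)[0]
            labels[members[: len(members) // 2]] = k
    cent = np.array([pts[labels == k].mean(axis=0) for k in range(n_nodes)])
    order = np.lexsort((cent[:, 2], cent[:, 1], cent[:, 0]))
    remap = np.empty(n_nodes, dtype=np.int64)
    remap[order] = np.arange(n_nodes)
    labels = remap[labels]
    regions = tuple(REGION_LABELS[k % len(REGION_LABELS)] for k in range(n_nodes))
    rsns = tuple(RSN_LABELS[k % len(RSN_LABELS)] for k in range(n_nodes))
    return Atlas(labels, regions, rsns)


def aggregate_vertices(values: np.ndarray, atlas: Atlas) -> np.ndarray:
    """Arithmetic mean of vertex values over each node's member vertices.

    ``values`` is (..., n_vertices); returns (..., n_nodes).
    """
    values = np.asarray(values, dtype=float)
    v2n = atlas.vertex_to_node
    if values.shape[-1] != len(v2n):
        raise AtlasError("vertex map length must equal the atlas vertex count")
    counts = np.bincount(v2n, minlength=atlas.n_nodes)
    flat = values.reshape(-1, values.shape[-1])
    sums = np.zeros((flat.shape[0], atlas.n_nodes))
    for k in range(atlas.n_nodes):
        sums[:, k] = flat[:, v2n == k].sum(axis=1)
    return (sums / counts).reshape(values.shape[:-1] + (atlas.n_nodes,))


def group_nodes(table: pd.DataFrame, atlas: Atlas, level: str
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label node rows by region or RSN, keeping nodes as replicates.

    ``table`` must carry a ``node_id`` column; value columns are every other
    numeric column.  Returns ``(long, means)``: the input rows with a
    ``group_label`` column appended (no premature averaging), and a
    convenience per-group mean table.  Groups with no member nodes in the
    table are omitted with a warning.
    """
    if level not in ("region", "rsn"):
        raise ValueError("level must be 'region' or 'rsn'")
    lookup = atlas.node_region if level == "region" else atlas.node_rsn
    if table["node_id"].max() >= atlas.n_nodes or table["node_id"].min() < 0:
        raise AtlasError("unknown node id in table")
    long = table.copy()
    long["group_label"] = [lookup[i] for i in table["node_id"]]
    expected = set(lookup)
    missing = expected - set(long["group_label"])
    if missing:
        warnings.warn(f"groups with no nodes omitted: {sorted(missing)}")
    value_cols = [c for c in long.columns
                  if c not in ("node_id", "group_label")
                  and np.issubdtype(long[c].dtype, np.number)]
    means = long.groupby("group_label")[value_cols].mean().reset_index()
    return long, means
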