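"""Toy head geometry and the analytic single-sphere EEG forward model.

The forward problem is solved in closed form for a current dipole inside a
homogeneous conducting sphere with an insulating exterior.  Writing the
infinite-medium dipole potential as a Legendre series about the sphere centre
and enforcing zero normal current at the scalp radius ``R`` multiplies each
degree-``n`` harmonic by ``(2n + 1)/n``; the resulting series sums in closed
form.  With the dipole at radius ``b`` (``f = b/R``), ``x`` the cosine of the
angle between dipole position and electrode, ``g = sqrt(1 - 2 f x + f^2)`` and
``h = 1 - f x + g``:

    4 pi sigma R^2 V  =  2 m_r (x - f) / g^3  +  m_r (1/g - 1) / f
                      +  2 c / g^3            +  c (g + 1) / (g h)

where ``m_r`` is the radial dipole component and ``c = m.e_hat - x m_r`` its
component toward the electrode azimuth.  Gains are expressed in microvolts per
picoampere-meter and average-referenced across electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CorticalMesh",
    "ElectrodeMontage",
    "SphereModel",
    "LeadField",
    "build_toy_mesh",
    "place_electrodes",
    "compute_lead_field",
    "mesh_adjacency",
    "save_mesh_obj",
    "load_mesh_obj",
    "save_montage_sfp",
    "load_montage_sfp",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class GeometryError(ValueError):
    """Raised when geometry inputs violate the forward-model preconditions."""


@dataclass(frozen=True)
class CorticalMesh:
    """Closed triangulated cortical surface with fixed dipole orientations.

    Positions are in millimetres; ``vertex_normals`` are the unit dipole
    orientations (one fixed source per vertex, oriented along the normal).
    """

    vertex_positions: np.ndarray  # (n_vertices, 3) mm
    faces: np.ndarray             # (n_faces, 3) int
    vertex_normals: np.ndarray    # (n_vertices, 3) unit

    def __post_init__(self):
        v = np.asarray(self.vertex_positions, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        n = np.asarray(self.vertex_normals, dtype=float)
        object.__setattr__(self, "vertex_positions", v)
        object.__setattr__(self, "faces", f)
        object.__setattr__(self, "vertex_normals", n)
        if f.max() >= len(v) or f.min() < 0:
            raise GeometryError("face index out of range")
        norms = np.linalg.norm(n, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise GeometryError("vertex normals must have unit norm")
        edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise GeometryError("mesh is not a closed orientable surface "
                                "(every edge must be shared by exactly 2 faces)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_positions)

    @property
    def eccentricity(self) -> np.ndarray:
        """Distance of each vertex from the origin (mm)."""
        return np.linalg.norm(self.vertex_positions, axis=1)


@dataclass(frozen=True)
class ElectrodeMontage:
    """Scalp electrode set; positions (mm) lie on the scalp sphere surface."""

    labels: tuple
    positions: np.ndarray  # (n_channels, 3) mm

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "positions",
                           np.asarray(self.positions, dtype=float))
        if len(self.labels) < 8:
            raise GeometryError("montage needs at least 8 electrodes")
        if len(set(self.labels)) != len(self.labels):
            raise GeometryError("electrode labels must be unique")
        if len(self.labels) != len(self.positions):
            raise GeometryError("labels and positions disagree in length")

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SphereModel:
    """Homogeneous conducting sphere standing in for the head."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scalp_radius: float = 90.0     # mm
    conductivity: float = 0.33     # S/m

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.scalp_radius <= 0:
            raise GeometryError("scalp_radius must be positive")
        if self.conductivity <= 0:
            raise GeometryError("conductivity must be positive")


@dataclass(frozen=True)
class LeadField:
    """Average-referenced gain matrix, microvolt per picoampere-meter.

    ``gain[i, j]`` is the potential at electrode ``i`` produced by a unit
    dipole (1 pA.m) at mesh vertex ``j`` oriented along its normal.
    """

    gain: np.ndarray  # (n_channels, n_sources)
    mesh: CorticalMesh
    montage: ElectrodeMontage
    sphere: SphereModel

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


# ---------------------------------------------------------------------------
# mesh construction

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One 4-to-1 triangle split with midpoints re-projected to the unit sphere."""
    verts = list(verts)
    cache: dict[tuple[int, int], int] = {}

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key not in cache:
            m = verts[a] + verts[b]
            m /= np.linalg.norm(m)
            cache[key] = len(verts)
            verts.append(m)
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
    return np.array(verts), np.array(new_faces, dtype=np.int64)


def _vertex_normals(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted average of adjacent face normals, normalised."""
    fn = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                  verts[faces[:, 2]] - verts[faces[:, 0]])
    normals = np.zeros_like(verts)
    for k in range(3):
        np.add.at(normals, faces[:, k], fn)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return normals


def build_toy_mesh(subdivision_level: int = 3, cortical_radius: float = 70.0,
                   radial_modulation: float = 0.0) -> CorticalMesh:
    """Icosphere cortical shell with ``10 * 4**level + 2`` vertices.

    ``radial_modulation`` (fraction, default 0) wrinkles the shell radially so
    that vertex eccentricity varies — used to exercise depth-dependent
    behaviour of the inverse; 0 yields an exact sphere of ``cortical_radius``.
    """
    if not (0 <= int(subdivision_level) <= 5) or subdivision_level != int(subdivision_level):
        raise GeometryError("subdivision_level must be an integer in 0..5")
    if cortical_radius <= 0:
        raise GeometryError("cortical_radius must be positive")
    verts, faces = _icosahedron()
    for _ in range(int(subdivision_level)):
        verts, faces = _subdivide(verts, faces)
    if radial_modulation:
        if not 0 < radial_modulation < 0.5:
            raise GeometryError("radial_modulation must lie in (0, 0.5)")
        # smooth low-order angular pattern -> reproducible depth variation
        x, y, z = verts.T
        bump = 1.0 - radial_modulation * (0.5 + 0.5 * np.sin(3 * np.arctan2(y, x)) * z**2)
        verts = verts * bump[:, None]
    verts = verts * cortical_radius
    return CorticalMesh(verts, faces, _vertex_normals(verts, faces))


def place_electrodes(n_channels: int = 32, scalp_radius: float = 90.0) -> ElectrodeMontage:
    """Quasi-uniform Fibonacci-lattice montage on the scalp sphere.

    Deterministic for fixed ``n_channels``; labels are ``E001``, ``E002``, ...
    """
    if n_channels < 8:
        raise GeometryError("need at least 8 electrodes")
    i = np.arange(n_channels)
    z = 1.0 - (2.0 * i + 1.0) / n_channels
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    theta = _GOLDEN_ANGLE * i
    pos = scalp_radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    labels = [f"E{k + 1:03d}" for k in range(n_channels)]
    return ElectrodeMontage(labels, pos)


def mesh_adjacency(mesh: CorticalMesh) -> list[set]:
    """Neighbour sets (1-ring) per vertex from the mesh edges."""
    nbrs: list[set] = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.faces:
        nbrs[a] |= {b, c}
        nbrs[b] |= {a, c}
        nbrs[c] |= {a, b}
    return nbrs


# ---------------------------------------------------------------------------
# analytic forward model

def _sphere_dipole_potential(dip_pos: np.ndarray, dip_mom: np.ndarray,
                             elec_pos: np.ndarray, radius: float,
                             conductivity: float) -> np.ndarray:
    """Surface potential (V) of dipoles in a homogeneous sphere centred at 0.

    ``dip_pos`` (S, 3) m, ``dip_mom`` (S, 3) A.m, ``elec_pos`` (E, 3) m on the
    sphere of ``radius`` m.  Returns (E, S).
    """
    b = np.linalg.norm(dip_pos, axis=1)                      # (S,)
    if np.any(b >= radius):
        raise GeometryError("dipole on or outside the sphere surface")
    safe_b = np.where(b > 0, b, 1.0)
    r0_hat = np.where((b > 0)[:, None], dip_pos / safe_b[:, None], 0.0)
    e_hat = elec_pos / radius                                # (E, 3)

    f = (b / radius)[None, :]                                # (1, S)
    x = e_hat @ r0_hat.T                                     # (E, S)
    m_r = np.sum(dip_mom * r0_hat, axis=1)[None, :]          # (1, S)
    m_e = e_hat @ dip_mom.T                                  # (E, S)
    c = m_e - x * m_r

    g = np.sqrt(1.0 - 2.0 * f * x + f**2)
    h = 1.0 - f * x + g
    with np.errstate(divide="ignore", invalid="ignore"):
        t_radial = 2.0 * m_r * (x - f) / g**3 + \
            np.where(f > 1e-12, m_r * (1.0 / g - 1.0) / np.where(f > 0, f, 1.0),
                     m_r * x)
    t_tang = 2.0 * c / g**3 + c * (g + 1.0) / (g * h)
    return (t_radial + t_tang) / (4.0 * np.pi * conductivity * radius**2)


def compute_lead_field(mesh: CorticalMesh, montage: ElectrodeMontage,
                       sphere: SphereModel | None = None) -> LeadField:
    """Average-referenced analytic lead field (µV per pA·m).

    Each gain column is the closed-form potential of a unit current dipole at
    a mesh vertex, oriented along its normal, inside the homogeneous sphere.
    """
    sphere = sphere or SphereModel()
    dip_pos_mm = mesh.vertex_positions - sphere.center
    ecc = np.linalg.norm(dip_pos_mm, axis=1)
    if np.any(ecc >= sphere.scalp_radius):
        bad = int(np.argmax(ecc))
        raise GeometryError(f"vertex {bad} lies on/outside the scalp sphere")
    elec_mm = montage.positions - sphere.center
    if not np.allclose(np.linalg.norm(elec_mm, axis=1), sphere.scalp_radius,
                       atol=1e-6):
        raise GeometryError("electrodes must lie on the scalp sphere surface")

    # SI units inside: mm -> m, dipole 1 pA.m = 1e-12 A.m, V -> µV
    v = _sphere_dipole_potential(dip_pos_mm * 1e-3,
                                 mesh.vertex_normals * 1e-12,
                                 elec_mm * 1e-3,
                                 sphere.scalp_radius * 1e-3,
                                 sphere.conductivity) * 1e6
    v -= v.mean(axis=0, keepdims=True)   # average reference
    return LeadField(v, mesh, montage, sphere)


# ---------------------------------------------------------------------------
# plain-text IO

def save_mesh_obj(mesh: CorticalMesh, path: str | Path) -> None:
    """Write vertices and faces as Wavefront OBJ (normals are recomputed on load)."""
    with open(path, "w") as fh:
        for v in mesh.vertex_positions:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def load_mesh_obj(path: str | Path) -> CorticalMesh:
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(p) for p in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    v = np.array(verts)
    f = np.array(faces, dtype=np.int64)
    return CorticalMesh(v, f, _vertex_normals(v, f))


def save_montage_sfp(montage: ElectrodeMontage, path: str | Path) -> None:
    """sfp-style whitespace-delimited ``label x y z`` electrode file."""
    with open(path, "w") as fh:
        for lab, p in zip(montage.labels, montage.positions):
            fh.write(f"{lab} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def load_montage_sfp(path: str | Path) -> ElectrodeMontage:
    labels, pos = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 4:
                labels.append(parts[0])
                pos.append([float(p) for p in parts[1:4]])
    return ElectrodeMontage(labels, np.array(pos))
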