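"""Triangulated surface geometry for the heart-torso volume conductor.

Provides the closed-surface mesh container used throughout the package, a
synthetic heart-torso phantom (ellipsoidal "ventricle" inside an ellipsoidal
torso), grid-like electrode layouts on the torso, two-zone ischemic lesion
membership on the heart surface, and the discrete surface operators (gradient
and cotangent Laplacian) shared by the interpolation and regularisation
stages.

All coordinates are in millimetres.  Meshes are closed, orientable and wound
so that face normals point outward (positive signed volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import trimesh
from scipy.spatial import cKDTree


class GeometryError(ValueError):
    """Raised when a mesh or layout violates a geometric precondition."""


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """A closed triangulated surface (heart or torso).

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Outward-wound vertex index triples.
    role : str
        Either ``"heart"`` or ``"torso"`` (or ``""`` for generic surfaces).
    """

    vertices: np.ndarray
    faces: np.ndarray
    role: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be an (m, 3) array")

    # -- basic quantities ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_corners(self) -> np.ndarray:
        """Return an (m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        c = self.face_corners()
        cross = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        c = self.face_corners()
        cross = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
        norm = np.linalg.norm(cross, axis=1, keepdims=True)
        return cross / np.where(norm == 0.0, 1.0, norm)

    def face_centroids(self) -> np.ndarray:
        return self.face_corners().mean(axis=1)

    def signed_volume(self) -> float:
        """Signed enclosed volume; positive for outward-wound closed meshes."""
        c = self.face_corners()
        return float(np.einsum("ij,ij->", c[:, 0], np.cross(c[:, 1], c[:, 2])) / 6.0)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) sorted index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def validate(self) -> None:
        """Check the closed outward-oriented mesh contract, raising on failure."""
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= self.n_vertices:
            raise GeometryError("face indices out of range")
        directed = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        und = np.sort(directed, axis=1)
        _, counts = np.unique(und, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise GeometryError("mesh is not closed: an edge is not shared by exactly 2 faces")
        # consistent winding: every directed edge must appear exactly once
        _, dcounts = np.unique(directed, axis=0, return_counts=True)
        if not np.all(dcounts == 1):
            raise GeometryError("inconsistent face winding")
        if np.any(self.face_areas() <= 0.0):
            raise GeometryError("zero-area face present")
        if self.signed_volume() <= 0.0:
            raise GeometryError("face normals do not point outward (signed volume <= 0)")

    # -- file I/O -----------------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def save(self, path: str | Path) -> None:
        """Write the mesh as ASCII PLY or OBJ, chosen by file extension."""
        path = Path(path)
        tm = self.to_trimesh()
        ext = path.suffix.lower()
        if ext == ".ply":
            data = trimesh.exchange.export.export_mesh(tm, None, "ply", encoding="ascii")
        elif ext == ".obj":
            data = trimesh.exchange.export.export_mesh(tm, None, "obj")
        else:
            raise GeometryError(f"unsupported mesh format: {ext}")
        if isinstance(data, str):
            data = data.encode()
        path.write_bytes(data)

    @classmethod
    def load(cls, path: str | Path, role: str = "") -> "TriangleMesh":
        tm = trimesh.load(str(path), process=False, force="mesh")
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces), role=role)


@dataclass
class ElectrodeLayout:
    """An ordered set of torso-mesh node indices acting as recording leads."""

    node_indices: np.ndarray

    def __post_init__(self) -> None:
        self.node_indices = np.ascontiguousarray(self.node_indices, dtype=np.int64)
        if len(np.unique(self.node_indices)) != len(self.node_indices):
            raise GeometryError("electrode indices must be unique")

    @property
    def count(self) -> int:
        return len(self.node_indices)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(str(i) for i in self.node_indices) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ElectrodeLayout":
        idx = [int(line) for line in Path(path).read_text().split()]
        return cls(np.asarray(idx))


@dataclass
class LesionSpec:
    """A circular transmural ischemic lesion.

    The lesion is a ball of ``radius`` mm around ``centre``; the inner
    ``central_fraction`` of the radius is the fully remodelled central zone and
    the remainder a boundary zone in which remodelling tapers linearly to zero.
    """

    centre: np.ndarray
    radius: float
    central_fraction: float = 0.8

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)
        if self.radius <= 0:
            raise GeometryError("lesion radius must be positive")
        if not (0.0 < self.central_fraction < 1.0):
            raise GeometryError("central_fraction must lie strictly in (0, 1)")


@dataclass
class SurfaceOperators:
    """Discrete first- and second-order roughness operators on a mesh.

    ``gradient_operator`` is the (edges x nodes) incidence matrix with entries
    +-1/edge_length, so it annihilates constants and its squared norm is a
    first-difference Dirichlet energy.  ``laplacian_operator`` is the symmetric
    cotangent-weighted Laplacian with zero row sums.
    """

    gradient_operator: sp.csr_matrix
    laplacian_operator: sp.csr_matrix


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------


def icosphere(radius: float, subdivisions: int) -> TriangleMesh:
    """A subdivided icosahedron with all vertices at distance ``radius``."""
    if radius <= 0:
        raise GeometryError("radius must be positive")
    if subdivisions < 0:
        raise GeometryError("subdivisions must be non-negative")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def ellipsoid_mesh(semiaxes, subdivisions: int, centre=(0.0, 0.0, 0.0), role: str = "") -> TriangleMesh:
    """An ellipsoid mesh built by anisotropic scaling of an icosphere."""
    a = np.asarray(semiaxes, dtype=float)
    if np.any(a <= 0):
        raise GeometryError("semiaxes must be positive")
    base = icosphere(1.0, subdivisions)
    verts = base.vertices * a + np.asarray(centre, dtype=float)
    return TriangleMesh(verts, base.faces, role=role)


#: Default phantom scale mimicking adult anatomy: ellipsoidal torso and an
#: ellipsoidal single-surface "ventricle" offset to the left-anterior chest.
DEFAULT_TORSO_SEMIAXES = (170.0, 120.0, 300.0)
DEFAULT_HEART_SEMIAXES = (45.0, 40.0, 70.0)
DEFAULT_HEART_OFFSET = (55.0, 35.0, 80.0)


def torso_ventricle_phantom(
    torso_semiaxes=DEFAULT_TORSO_SEMIAXES,
    heart_semiaxes=DEFAULT_HEART_SEMIAXES,
    heart_offset=DEFAULT_HEART_OFFSET,
    resolution: int = 3,
) -> tuple[TriangleMesh, TriangleMesh]:
    """Build the synthetic heart-torso phantom.

    Returns ``(heart, torso)``.  ``resolution`` is the icosphere subdivision
    level of the heart mesh; the torso uses one extra level so the two
    surfaces keep roughly an anatomical-scale node-count ratio (642/2562 nodes at
    the default ``resolution=3``).

    Raises
    ------
    GeometryError
        If the offset heart surface is not strictly inside the torso.
    """
    torso_semiaxes = np.asarray(torso_semiaxes, dtype=float)
    heart = ellipsoid_mesh(heart_semiaxes, resolution, centre=heart_offset, role="heart")
    torso = ellipsoid_mesh(torso_semiaxes, resolution + 1, role="torso")
    # strict containment test against the torso implicit surface
    level = np.sum((heart.vertices / torso_semiaxes) ** 2, axis=1)
    if np.any(level >= 1.0):
        raise GeometryError("heart surface intersects or leaves the torso")
    min_dist = min_surface_distance(heart, torso)
    if min_dist <= 0.0:
        raise GeometryError("heart and torso surfaces touch")
    return heart, torso


def min_surface_distance(a: TriangleMesh, b: TriangleMesh) -> float:
    """Approximate minimum distance between two surfaces (vertex-to-vertex)."""
    tree = cKDTree(b.vertices)
    d, _ = tree.query(a.vertices)
    return float(d.min())


# ---------------------------------------------------------------------------
# Electrode layout
# ---------------------------------------------------------------------------


def electrode_grid(torso: TriangleMesh, n: int) -> ElectrodeLayout:
    """Place ``n`` electrodes on the torso as a snapped (azimuth, height) grid.

    A regular grid in cylindrical coordinates (azimuth around the torso long
    axis, height along it) is laid over the surface and each grid point is
    snapped to the nearest torso node.  Duplicate snaps are dropped; if fewer
    than ``n`` unique nodes result, the layout is topped up by deterministic
    farthest-point additions.  The construction is deterministic for a fixed
    mesh and ``n``.
    """
    if not (4 <= n <= torso.n_vertices):
        raise GeometryError(f"electrode count {n} must lie in [4, {torso.n_vertices}]")
    v = torso.vertices
    centre = v.mean(axis=0)
    rel = v - centre
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    z = rel[:, 2]
    r_mean = float(np.hypot(rel[:, 0], rel[:, 1]).mean())
    z_lo, z_hi = float(z.min()), float(z.max())
    height = z_hi - z_lo
    circumference = 2.0 * math.pi * r_mean

    # grid aspect follows the surface aspect so cells are roughly square
    n_z = max(2, int(round(math.sqrt(n * height / circumference))))
    n_az = max(4, int(math.ceil(n / n_z)))
    while n_z * n_az < n:
        n_az += 1

    # embed nodes in a flattened (arc-length azimuth, height) chart
    chart = np.column_stack([theta * r_mean, z])
    tree = cKDTree(chart)

    dz = height / (n_z + 1)
    z_levels = z_lo + dz * np.arange(1, n_z + 1)
    az_levels = -math.pi + 2.0 * math.pi * (np.arange(n_az) + 0.5) / n_az

    picked: list[int] = []
    seen: set[int] = set()
    for zi in z_levels:
        for az in az_levels:
            # nearest node in the chart metric; azimuth wrap handled by
            # querying the +-2*pi*r images as well
            best_idx, best_d = -1, np.inf
            for shift in (-2.0 * math.pi * r_mean, 0.0, 2.0 * math.pi * r_mean):
                d, idx = tree.query([az * r_mean + shift, zi])
                if d < best_d:
                    best_d, best_idx = d, int(idx)
            if best_idx not in seen:
                seen.add(best_idx)
                picked.append(best_idx)

    if len(picked) < n:
        picked = _farthest_point_top_up(v, picked, n)
    return ElectrodeLayout(np.asarray(picked[:n]))


def _farthest_point_top_up(points: np.ndarray, picked: list[int], n: int) -> list[int]:
    """Extend ``picked`` to ``n`` indices by maximin farthest-point additions."""
    picked = list(picked)
    chosen = points[picked]
    d = np.linalg.norm(points[:, None, :] - chosen[None, :, :], axis=2).min(axis=1)
    d[picked] = -np.inf
    while len(picked) < n:
        i = int(np.argmax(d))
        picked.append(i)
        d = np.minimum(d, np.linalg.norm(points - points[i], axis=1))
        d[i] = -np.inf
    return picked


def farthest_point_sample(points: np.ndarray, n: int, start: int = 0) -> np.ndarray:
    """Deterministic farthest-point sampling; used as a uniformity reference."""
    return np.asarray(_farthest_point_top_up(points, [start], n))


# ---------------------------------------------------------------------------
# Lesion membership
# ---------------------------------------------------------------------------


def lesion_zones(heart: TriangleMesh, lesion: LesionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Classify heart nodes into healthy/boundary/central zones with ramp weights.

    Distance is Euclidean from the lesion centre (a transmural ball).  Nodes
    within ``central_fraction * radius`` are central (weight 1); nodes in the
    remaining annulus are boundary with weight falling linearly 1 -> 0; nodes
    beyond the radius are healthy (weight 0).

    Returns
    -------
    labels : (n,) array of str
        One of ``"healthy"``, ``"boundary"``, ``"central"`` per node.
    weights : (n,) float array
        Remodelling ramp weight in [0, 1].
    """
    d = np.linalg.norm(heart.vertices - lesion.centre, axis=1)
    r, f = lesion.radius, lesion.central_fraction
    central = d <= f * r
    boundary = (d > f * r) & (d <= r)
    labels = np.full(len(d), "healthy", dtype=object)
    labels[boundary] = "boundary"
    labels[central] = "central"
    weights = np.zeros(len(d))
    weights[central] = 1.0
    weights[boundary] = (r - d[boundary]) / ((1.0 - f) * r)
    return labels, weights


# ---------------------------------------------------------------------------
# Discrete surface operators
# ---------------------------------------------------------------------------


def surface_operators(mesh: TriangleMesh) -> SurfaceOperators:
    """Build the edge-difference gradient and cotangent Laplacian operators."""
    return SurfaceOperators(
        gradient_operator=gradient_operator(mesh),
        laplacian_operator=cotangent_laplacian(mesh),
    )


def gradient_operator(mesh: TriangleMesh) -> sp.csr_matrix:
    """(edges x nodes) incidence matrix with entries +-1/edge_length."""
    e = mesh.edges()
    lengths = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    ne = len(e)
    rows = np.repeat(np.arange(ne), 2)
    cols = e.ravel()
    vals = np.column_stack([1.0 / lengths, -1.0 / lengths]).ravel()
    return sp.csr_matrix((vals, (rows, cols)), shape=(ne, mesh.n_vertices))


def cotangent_laplacian(mesh: TriangleMesh) -> sp.csr_matrix:
    """Symmetric cotangent-weighted Laplacian, positive semi-definite.

    ``L[i, j] = -(cot a + cot b) / 2`` for the two angles opposite edge (i, j)
    and the diagonal makes every row sum to zero, so constants are in the null
    space and on flat triangulations interior rows annihilate linear fields.
    """
    f = mesh.faces
    v = mesh.vertices
    rows, cols, vals = [], [], []
    for k in range(3):
        i = f[:, k]
        j = f[:, (k + 1) % 3]
        o = f[:, (k + 2) % 3]
        a = v[i] - v[o]
        b = v[j] - v[o]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cot = np.einsum("ij,ij->i", a, b) / np.where(cross == 0.0, 1.0, cross)
        w = 0.5 * cot
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([-w, -w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n = mesh.n_vertices
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    L = L + sp.diags(np.asarray(-L.sum(axis=1)).ravel())
    return L.tocsr()
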