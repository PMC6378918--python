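"""Boundary-element forward model: epicardial to body-surface potentials.

The torso is treated as a homogeneous isotropic volume conductor bounded
externally by the insulated torso surface and internally by the epicardial
surface.  Green's representation of the Laplace solution in the inter-surface
volume is collocated at mesh vertices with lumped linear shape functions
(each triangle's double-layer solid angle and single-layer potential split
equally over its three vertices).  Eliminating the unknown epicardial normal
gradient yields the dense transfer matrix ``A`` with ``y = A x`` mapping
epicardial node potentials ``x`` to torso node potentials ``y``.

Self (auto) solid-angle diagonals are fixed by requiring that a constant
potential is transferred exactly, which also makes every row of ``A`` sum to
one by construction.  Conductivity cancels in the potential-to-potential map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .geometry import GeometryError, TriangleMesh
from .sources import PotentialField

FOUR_PI = 4.0 * np.pi


@dataclass
class TransferMatrix:
    """Dense torso-node x heart-node transfer matrix for one mesh pair."""

    entries: np.ndarray
    heart_id: str = "heart"
    torso_id: str = "torso"

    def __post_init__(self) -> None:
        self.entries = np.ascontiguousarray(self.entries, dtype=float)
        if self.entries.ndim != 2:
            raise ValueError("transfer matrix must be 2-D")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("transfer matrix entries must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def save(self, path: str | Path) -> None:
        header = (
            f"heart={self.heart_id} n_heart={self.shape[1]} "
            f"torso={self.torso_id} n_torso={self.shape[0]}"
        )
        np.savetxt(path, self.entries, delimiter="\t", header=header)

    @classmethod
    def load(cls, path: str | Path) -> "TransferMatrix":
        with open(path) as fh:
            first = fh.readline()
        meta = dict(
            kv.split("=") for kv in first.lstrip("# ").split() if "=" in kv
        )
        entries = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
        return cls(entries, heart_id=meta.get("heart", "heart"), torso_id=meta.get("torso", "torso"))


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------


def solid_angle(triangle: np.ndarray, observation: np.ndarray) -> float:
    """Signed solid angle (sr) subtended by one triangle at one point.

    Uses the van Oosterom-Strackee closed form.  The sign follows the
    triangle winding: positive when the outward normal faces away from the
    observer, so that summing over a closed outward-wound mesh gives 4*pi
    from an interior point and 0 from an exterior point.
    """
    tri = np.asarray(triangle, dtype=float).reshape(1, 3, 3)
    obs = np.asarray(observation, dtype=float).reshape(1, 3)
    return float(solid_angles(obs, tri)[0, 0])


def solid_angles(obs: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Vectorised signed solid angles: (n_obs, n_tris)."""
    # R_k: (n_obs, n_tris, 3) vertex vectors relative to each observer
    r = tris[None, :, :, :] - obs[:, None, None, :]
    n = np.linalg.norm(r, axis=3)  # (K, F, 3)
    r1, r2, r3 = r[:, :, 0], r[:, :, 1], r[:, :, 2]
    n1, n2, n3 = n[:, :, 0], n[:, :, 1], n[:, :, 2]
    num = np.einsum("kfi,kfi->kf", r1, np.cross(r2, r3))
    den = (
        n1 * n2 * n3
        + np.einsum("kfi,kfi->kf", r1, r2) * n3
        + np.einsum("kfi,kfi->kf", r1, r3) * n2
        + np.einsum("kfi,kfi->kf", r2, r3) * n1
    )
    return 2.0 * np.arctan2(num, den)


def triangle_potentials(obs: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Vectorised single-layer integrals ``int_T dS / |r - r'|``: (n_obs, n_tris).

    Analytic edge formula (Wilton et al. / Graglia); finite for observation
    points on the triangle, including at its vertices.
    """
    obs = np.asarray(obs, dtype=float)
    tris = np.asarray(tris, dtype=float)
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    nrm = np.cross(e1, e2)
    nhat = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)  # (F, 3)

    rel0 = obs[:, None, :] - tris[None, :, 0, :]  # (K, F, 3)
    d = np.einsum("kfi,fi->kf", rel0, nhat)  # signed height
    rho = obs[:, None, :] - d[:, :, None] * nhat[None, :, :]  # foot point (K, F, 3)

    total = np.zeros(d.shape)
    for a_idx, b_idx in ((0, 1), (1, 2), (2, 0)):
        a = tris[:, a_idx]  # (F, 3)
        b = tris[:, b_idx]
        edge = b - a
        elen = np.linalg.norm(edge, axis=1, keepdims=True)
        shat = edge / elen  # (F, 3)
        mhat = np.cross(shat, nhat)  # outward in-plane edge normal
        arel = a[None, :, :] - rho  # (K, F, 3)
        brel = b[None, :, :] - rho
        p0 = np.einsum("kfi,fi->kf", arel, mhat)
        lm = np.einsum("kfi,fi->kf", arel, shat)
        lp = np.einsum("kfi,fi->kf", brel, shat)
        rm = np.linalg.norm(obs[:, None, :] - a[None, :, :], axis=2)
        rp = np.linalg.norm(obs[:, None, :] - b[None, :, :], axis=2)
        num = rp + lp
        den = rm + lm
        safe = (np.abs(p0) > 1e-12) & (num > 1e-300) & (den > 1e-300)
        term = np.zeros_like(p0)
        term[safe] = p0[safe] * np.log(num[safe] / den[safe])
        total += term
    omega = np.abs(solid_angles(obs, tris))
    return total - np.abs(d) * omega


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _vertex_lumping(mesh: TriangleMesh) -> sp.csr_matrix:
    """(faces x nodes) matrix distributing a per-face value 1/3 per vertex."""
    f = mesh.faces
    nf = len(f)
    rows = np.repeat(np.arange(nf), 3)
    return sp.csr_matrix(
        (np.full(3 * nf, 1.0 / 3.0), (rows, f.ravel())),
        shape=(nf, mesh.n_vertices),
    )


def _assemble_blocks(obs_mesh: TriangleMesh, src_mesh: TriangleMesh, chunk: int = 64):
    """Node-lumped double-layer (D) and single-layer (S) collocation blocks."""
    obs = obs_mesh.vertices
    tris = src_mesh.face_corners()
    lump = _vertex_lumping(src_mesh)
    n_obs = len(obs)
    D = np.empty((n_obs, src_mesh.n_vertices))
    S = np.empty((n_obs, src_mesh.n_vertices))
    for start in range(0, n_obs, chunk):
        sl = slice(start, min(start + chunk, n_obs))
        D[sl] = solid_angles(obs[sl], tris) @ lump
        S[sl] = triangle_potentials(obs[sl], tris) @ lump
    return D, S


def assemble_transfer(torso: TriangleMesh, heart: TriangleMesh) -> TransferMatrix:
    """Assemble the epicardial-to-torso transfer matrix.

    Both meshes must be closed and outward-oriented with the heart strictly
    inside the torso.  The assembly is purely geometric and deterministic.
    """
    torso.validate()
    heart.validate()

    D_TT, _ = _assemble_blocks(torso, torso)
    D_TH, S_TH = _assemble_blocks(torso, heart)
    D_HT, _ = _assemble_blocks(heart, torso)
    D_HH, S_HH = _assemble_blocks(heart, heart)

    # containment check: the torso surface must subtend 4*pi at heart vertices
    rowsum_HT = D_HT.sum(axis=1)
    if np.any(np.abs(rowsum_HT - FOUR_PI) > 0.2):
        raise GeometryError("heart surface is not strictly inside the torso")
    # and the heart surface 0 (or near it) at torso vertices
    if np.any(np.abs(D_TH.sum(axis=1)) > 0.2):
        raise GeometryError("torso vertices lie inside or on the heart surface")

    n_t = torso.n_vertices
    # auto solid angles fixed by the constant-potential condition
    P_TT = D_TT + np.diag(FOUR_PI - D_TT.sum(axis=1))
    B_HH = FOUR_PI * np.eye(heart.n_vertices) + D_HH - np.diag(D_HH.sum(axis=1))

    try:
        X = sla.solve(S_HH, np.hstack([D_HT, B_HH]))
    except sla.LinAlgError as exc:  # pragma: no cover - defensive
        raise GeometryError("singular epicardial single-layer block") from exc
    S_inv_D_HT = X[:, : torso.n_vertices]
    S_inv_B_HH = X[:, torso.n_vertices :]

    M_TT = FOUR_PI * np.eye(n_t) - P_TT + S_TH @ S_inv_D_HT
    M_TH = -D_TH + S_TH @ S_inv_B_HH
    try:
        A = sla.solve(M_TT, M_TH)
    except sla.LinAlgError as exc:
        cond = np.linalg.cond(M_TT)
        raise GeometryError(
            f"singular torso collocation system (cond ~ {cond:.3e})"
        ) from exc
    return TransferMatrix(A, heart_id=heart.role or "heart", torso_id=torso.role or "torso")


def forward_bsp(A: TransferMatrix, x: PotentialField) -> PotentialField:
    """Map an epicardial potential field to the torso surface (column-wise)."""
    if A.shape[1] != x.n_nodes:
        raise ValueError(
            f"transfer matrix expects {A.shape[1]} heart nodes, field has {x.n_nodes}"
        )
    return replace(x, values=A.entries @ x.values)
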