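"""Lead sampling and body-surface potential map reconstruction.

A limited electrode layout samples the torso potential field at its node
indices (the multi-lead ECG).  The full map is then recovered by discrete
harmonic extension on the torso surface graph: electrode nodes are held at
their measured values and every free node minimises the cotangent-Laplacian
Dirichlet energy, i.e. one sparse linear solve per timestep sharing a single
factorisation.  This is the surface-Laplacian ("linear") interpolation
classically used for body-surface potential mapping.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .geometry import ElectrodeLayout, TriangleMesh, cotangent_laplacian
from .sources import PotentialField


def sample_leads(bsp: PotentialField, layout: ElectrodeLayout) -> np.ndarray:
    """Extract the (electrodes x time) lead matrix at the layout nodes."""
    idx = layout.node_indices
    if idx.min() < 0 or idx.max() >= bsp.n_nodes:
        raise IndexError("electrode index out of range for this torso field")
    return bsp.values[idx].copy()


def interpolate_full_bsp(
    leads: np.ndarray,
    layout: ElectrodeLayout,
    torso: TriangleMesh,
    dt: float = 1.0,
    t0: float = 0.0,
) -> PotentialField:
    """Harmonic extension of electrode measurements to every torso node.

    Electrode nodes keep their measured values exactly; free nodes solve the
    constrained cotangent-Laplacian system ``L_ff v_f = -L_fe v_e``.
    """
    leads = np.atleast_2d(np.asarray(leads, dtype=float))
    if leads.shape[0] != layout.count:
        raise ValueError("lead matrix rows must match the electrode count")
    if layout.count < 4:
        raise ValueError("at least 4 electrodes are required")

    n = torso.n_vertices
    fixed = np.zeros(n, dtype=bool)
    fixed[layout.node_indices] = True
    free = ~fixed

    L = cotangent_laplacian(torso)
    _check_free_connectivity(L, free)

    L_ff = L[free][:, free].tocsc()
    L_fe = L[free][:, fixed].tocsc()

    values = np.empty((n, leads.shape[1]))
    # layout order -> mesh-node order for the constrained block
    order = np.argsort(layout.node_indices)
    v_e = leads[order]
    values[layout.node_indices] = leads
    solver = splu(L_ff)
    values[free] = solver.solve(-(L_fe @ v_e))
    return PotentialField(values, dt=dt, t0=t0)


def _check_free_connectivity(L: sp.spmatrix, free: np.ndarray) -> None:
    """Every free connected component must touch at least one electrode."""
    if not np.any(free):
        return
    sub = L[free][:, free]
    n_comp, labels = connected_components(sub != 0, directed=False)
    if n_comp <= 1:
        coupling = np.abs(L[free][:, ~free]).sum()
        if coupling == 0:
            raise ValueError("free nodes are disconnected from every electrode")
        return
    coupling = np.asarray(np.abs(L[free][:, ~free]).sum(axis=1)).ravel()
    for c in range(n_comp):
        if coupling[labels == c].sum() == 0:
            raise ValueError(
                f"free-node component {c} has no constrained neighbour"
            )


# ---------------------------------------------------------------------------
# Lead-matrix text format: header row of electrode node indices, then one
# row per electrode of tab-separated samples.
# ---------------------------------------------------------------------------


def save_leads(path: str | Path, leads: np.ndarray, layout: ElectrodeLayout) -> None:
    header = "\t".join(str(i) for i in layout.node_indices)
    np.savetxt(path, np.atleast_2d(leads), delimiter="\t", header=header, comments="")


def load_leads(path: str | Path) -> tuple[np.ndarray, ElectrodeLayout]:
    with open(path) as fh:
        header = fh.readline().split()
    layout = ElectrodeLayout(np.asarray([int(h) for h in header]))
    leads = np.atleast_2d(np.loadtxt(path, delimiter="\t", skiprows=1))
    return leads, layout
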