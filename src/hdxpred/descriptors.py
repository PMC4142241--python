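"""Structural descriptors: solvent accessibility and positional fluctuation.

SASA is computed with the Shrake-Rupley method: a deterministic
golden-spiral point set on each atom's solvent-expanded sphere
(radius + probe), points occluded by any neighbouring expanded sphere
removed, exposed fraction times sphere area summed per residue.  The
buried surface of a subunit is SASA(chain alone) - SASA(chain in the
oligomer), which highlights subunit interfaces.  RMSF superposes every
frame onto the ensemble-mean structure (Kabsch, one refinement pass) and
reports per-residue RMS deviation from the mean positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_model import Ensemble, StructureFrame

__all__ = ["VDW_RADII", "sasa", "buried_surface", "rmsf", "kabsch_rotation"]

#: van der Waals radii (A), Bondi (1964) set; 1.8 A fallback for others
VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "SE": 1.90,
}
_DEFAULT_RADIUS = 1.80


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _atom_arrays(frame: StructureFrame, include_hydrogens: bool,
                 radii: Optional[dict] = None):
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    coords, rad, owners = [], [], []
    for r, a in frame.iter_atoms():
        if not include_hydrogens and not a.is_heavy:
            continue
        coords.append(a.coords)
        rad.append(table.get(a.element.upper(), _DEFAULT_RADIUS))
        owners.append(r.key())
    return np.asarray(coords), np.asarray(rad), owners


def sasa(
    frame: StructureFrame,
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_hydrogens: bool = False,
    radii: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-residue solvent-accessible surface area (A^2).

    Heavy atoms only by default (the convention of standard SASA tools on
    crystal structures).  Deterministic for a fixed ``n_points``.
    """
    coords, rad, owners = _atom_arrays(frame, include_hydrogens, radii)
    expanded = rad + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    per_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 >= expanded[j] ** 2
            if not exposed.any():
                break
        per_atom[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed.sum() / n_points
    rows: dict[tuple, float] = {}
    for owner, area in zip(owners, per_atom):
        rows[owner] = rows.get(owner, 0.0) + area
    return pd.DataFrame(
        [(c, r, a) for (c, r), a in rows.items()],
        columns=["chain", "resseq", "sasa"],
    )


def buried_surface(
    frame: StructureFrame,
    chain_id: str,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> pd.DataFrame:
    """Per-residue surface buried upon oligomerization for one chain:
    SASA of the chain extracted alone minus its SASA within the oligomer
    (non-negative up to quadrature noise)."""
    chain_res = frame.chain(chain_id)
    if not chain_res:
        raise ValueError(f"no chain {chain_id!r}")
    alone = StructureFrame([r for r in frame.residues if r.chain_id == chain_id])
    s_alone = sasa(alone, probe_radius, n_points).set_index("resseq").sasa
    s_olig = (
        sasa(frame, probe_radius, n_points)
        .query("chain == @chain_id")
        .set_index("resseq")
        .sasa
    )
    delta = (s_alone - s_olig).rename("delta_sasa")
    out = delta.reset_index()
    out.insert(0, "chain", chain_id)
    return out


def kabsch_rotation(moving: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centred ``moving`` onto centred
    ``reference`` (proper rotation, reflections excluded)."""
    h = moving.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, 1.0, d])
    return u @ s @ vt


_BACKBONE = ("N", "CA", "C", "O")


def rmsf(
    ensemble: Ensemble,
    selection: str = "backbone",
    superpose: bool = True,
) -> pd.DataFrame:
    """Per-residue RMSF (A) about the ensemble-mean structure.

    ``selection``: "backbone" (N, CA, C, O), "CA", or "heavy".  With
    ``superpose``, frames are rigid-body aligned onto the mean structure
    and the mean is refined once.
    """
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least two frames")

    def _select(frame: StructureFrame):
        coords, owners = [], []
        for r, a in frame.iter_atoms():
            if selection == "CA" and a.name != "CA":
                continue
            if selection == "backbone" and a.name not in _BACKBONE:
                continue
            if selection == "heavy" and not a.is_heavy:
                continue
            coords.append(a.coords)
            owners.append(r.key())
        return np.asarray(coords), owners

    stacks, owners = [], None
    for frame in ensemble.frames:
        c, o = _select(frame)
        stacks.append(c)
        owners = o
    X = np.stack(stacks)  # (n_frames, n_atoms, 3)

    if superpose:
        for _ in range(2):  # align, refine mean, align again
            mean = X.mean(axis=0)
            mean_c = mean - mean.mean(axis=0)
            for k in range(X.shape[0]):
                frame_c = X[k] - X[k].mean(axis=0)
                R = kabsch_rotation(frame_c, mean_c)
                X[k] = frame_c @ R
    mean = X.mean(axis=0)
    dev2 = ((X - mean) ** 2).sum(axis=2).mean(axis=0)  # per-atom MSF

    per_res: dict[tuple, list] = {}
    for owner, v in zip(owners, dev2):
        per_res.setdefault(owner, []).append(v)
    rows = [(c, r, float(np.sqrt(np.mean(v)))) for (c, r), v in per_res.items()]
    return pd.DataFrame(rows, columns=["chain", "resseq", "rmsf"])
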