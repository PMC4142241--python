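"""Phenomenological per-residue protection factors.

The protection factor P of an amide quantifies how much slower it exchanges
than a fully exposed amide.  For a conformation X it is estimated from two
local-environment counts,

    ln P_i(X) = beta_c * Nc_i(X) + beta_h * Nh_i(X),

where Nc is the number of heavy (non-hydrogen) atoms within a cutoff of the
amide nitrogen and Nh the number of acceptor oxygens within a (shorter)
cutoff of the amide hydrogen.  Burial in the core or a subunit interface
drives Nc; participation in secondary structure drives Nh.  Over an
ensemble the counts (hence lnP) are averaged with the frame weights.

Counts run across ALL chains, so inter-subunit contacts in an oligomer
protect interface amides; residues in a configurable sequence-neighbour
window on the same chain are excluded from Nc to avoid a constant offset
from covalently bonded atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_model import Ensemble, Residue, StructureFrame

__all__ = [
    "ProtectionParams",
    "ProtectionProfile",
    "count_contacts",
    "count_hbonds",
    "lnP_frame",
    "average_protection",
]


@dataclass(frozen=True)
class ProtectionParams:
    """Parameters of the phenomenological protection model.

    Defaults are the published best-prediction weights (beta_c = 0.35,
    beta_h = 2) with a 6.5 A heavy-atom contact cutoff around the amide
    nitrogen and a 2.4 A amide-H ... acceptor-O hydrogen-bond cutoff; both
    cutoffs are strict (<).
    """

    beta_c: float = 0.35
    beta_h: float = 2.0
    contact_cutoff: float = 6.5      # A, around amide N
    hbond_cutoff: float = 2.4        # A, around amide H
    contact_exclusion: tuple[int, ...] = (-1, 0, 1)  # same-chain resseq offsets
    acceptor_policy: str = "protein_oxygen_only"     # or "all_oxygen"

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.hbond_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.beta_c < 0 or self.beta_h < 0:
            raise ValueError("beta weights must be non-negative")
        if self.acceptor_policy not in ("protein_oxygen_only", "all_oxygen"):
            raise ValueError("unknown acceptor_policy")


@dataclass
class ProtectionProfile:
    """Per-(frame, chain, residue) counts and lnP plus residue aggregates.

    ``per_frame`` columns: frame, chain, resseq, aa, Nc, Nh, lnP, weight
    (rows only for residues carrying an amide hydrogen).
    ``per_residue`` columns: resseq, aa, mean_Nc, mean_Nh, mean_lnP,
    n_frames, n_chains (chain- and frame-averaged with ensemble weights).
    """

    per_frame: pd.DataFrame
    per_residue: pd.DataFrame
    params: ProtectionParams
    mode: str = "mean_lnP"

    def lnP_by_residue(self) -> dict[int, float]:
        return dict(zip(self.per_residue.resseq, self.per_residue.mean_lnP))

    def to_csv(self, path: str | Path) -> None:
        self.per_residue.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Per-frame machinery
# ---------------------------------------------------------------------------

class _FrameGrids:
    """KD-trees over a frame's heavy atoms and acceptor oxygens.

    Uses periodic (minimum-image) distances when the frame has an
    orthorhombic box.
    """

    def __init__(self, frame: StructureFrame, params: ProtectionParams):
        boxsize = None
        if frame.box is not None:
            boxsize = np.asarray(frame.box, dtype=float)
        heavy, owners = frame.heavy_coords()
        self.heavy = heavy
        self.owners = owners
        self.heavy_tree = cKDTree(np.mod(heavy, boxsize) if boxsize is not None else heavy,
                                  boxsize=boxsize)
        ox, ox_owner = [], []
        for r, a in frame.iter_atoms():
            if a.element == "O":
                ox.append(a.coords)
                ox_owner.append(r.key())
        if params.acceptor_policy == "all_oxygen" and len(frame.solvent_oxygens):
            for c in frame.solvent_oxygens:
                ox.append(c)
                ox_owner.append(("<solvent>", 0))
        self.oxygens = np.asarray(ox).reshape(-1, 3)
        self.ox_owner = ox_owner
        self.ox_tree = cKDTree(
            np.mod(self.oxygens, boxsize) if boxsize is not None else self.oxygens,
            boxsize=boxsize,
        ) if len(self.oxygens) else None
        self.boxsize = boxsize

    def _query(self, tree: cKDTree, point: np.ndarray, cutoff: float) -> list[int]:
        q = np.mod(point, self.boxsize) if self.boxsize is not None else point
        idx = tree.query_ball_point(q, cutoff)
        # strict inequality: drop hits exactly at the cutoff
        if self.boxsize is None:
            coords = self.heavy if tree is self.heavy_tree else self.oxygens
            return [i for i in idx if np.linalg.norm(coords[i] - point) < cutoff]
        return [
            i for i in idx
            if _min_image_dist(
                (self.heavy if tree is self.heavy_tree else self.oxygens)[i],
                point, self.boxsize) < cutoff
        ]


def _min_image_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    d = a - b
    d -= box * np.round(d / box)
    return float(np.linalg.norm(d))


def count_contacts(
    frame: StructureFrame,
    residue: Residue,
    params: ProtectionParams = ProtectionParams(),
    _grids: Optional[_FrameGrids] = None,
) -> int:
    """Number of heavy atoms strictly within the contact cutoff of the
    residue's amide nitrogen, across all chains, excluding atoms of
    same-chain residues in the ``contact_exclusion`` window."""
    n = residue.amide_n
    if n is None:
        raise ValueError(f"residue {residue.key()} has no backbone N")
    grids = _grids or _FrameGrids(frame, params)
    excluded = {
        (residue.chain_id, residue.resseq + off) for off in params.contact_exclusion
    }
    idx = grids._query(grids.heavy_tree, n.coords, params.contact_cutoff)
    return sum(1 for i in idx if grids.owners[i] not in excluded)


def count_hbonds(
    frame: StructureFrame,
    residue: Residue,
    params: ProtectionParams = ProtectionParams(),
    _grids: Optional[_FrameGrids] = None,
) -> int:
    """Number of acceptor oxygens strictly within the H-bond cutoff of the
    residue's amide hydrogen; 0 for residues without an amide hydrogen."""
    h = residue.amide_h
    if h is None:
        return 0
    grids = _grids or _FrameGrids(frame, params)
    if grids.ox_tree is None:
        return 0
    idx = grids._query(grids.ox_tree, h.coords, params.hbond_cutoff)
    return len(idx)


def lnP_frame(
    frame: StructureFrame,
    params: ProtectionParams = ProtectionParams(),
) -> pd.DataFrame:
    """Per-residue Nc, Nh and lnP for one conformation.

    Returns a DataFrame (chain, resseq, aa, Nc, Nh, lnP) with one row per
    residue that carries an amide hydrogen; lnP = beta_c*Nc + beta_h*Nh.
    """
    grids = _FrameGrids(frame, params)
    rows = []
    for res in frame.residues:
        if res.amide_h is None or res.amide_n is None:
            continue
        nc = count_contacts(frame, res, params, _grids=grids)
        nh = count_hbonds(frame, res, params, _grids=grids)
        rows.append(
            (res.chain_id, res.resseq, res.one_letter, nc, nh,
             params.beta_c * nc + params.beta_h * nh)
        )
    return pd.DataFrame(rows, columns=["chain", "resseq", "aa", "Nc", "Nh", "lnP"])


def average_protection(
    ensemble: Ensemble,
    params: ProtectionParams = ProtectionParams(),
    mode: str = "mean_lnP",
) -> ProtectionProfile:
    """Ensemble/chain-averaged protection profile.

    ``mode="mean_lnP"`` aggregates lnP (equivalently the beta-weighted mean
    counts, by linearity) over frames and chains with the ensemble weights;
    ``mode="mean_D"`` keeps the same aggregates for inspection but signals
    the uptake layer to average per-frame deuterium fractions instead of
    lnP.  Per-(frame, chain) values are always retained in ``per_frame``.
    """
    if mode not in ("mean_lnP", "mean_D"):
        raise ValueError("mode must be 'mean_lnP' or 'mean_D'")
    parts = []
    for frame, w in zip(ensemble.frames, ensemble.weights):
        df = lnP_frame(frame, params)
        df.insert(0, "frame", frame.frame_index)
        df["weight"] = w
        parts.append(df)
    per_frame = pd.concat(parts, ignore_index=True)

    def _agg(g: pd.DataFrame) -> pd.Series:
        w = g.weight / g.weight.sum()
        return pd.Series(
            {
                "aa": g.aa.iloc[0],
                "mean_Nc": float((g.Nc * w).sum()),
                "mean_Nh": float((g.Nh * w).sum()),
                "mean_lnP": float((g.lnP * w).sum()),
                "n_frames": g.frame.nunique(),
                "n_chains": g.chain.nunique(),
            }
        )

    per_residue = (
        per_frame.groupby("resseq", sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return ProtectionProfile(per_frame, per_residue, params, mode)
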