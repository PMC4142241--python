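"""Deterministic synthetic inputs with known ground truth.

Generates idealized backbone structures (extended chains, alpha-helices,
Cn-symmetric ring oligomers), pseudo-trajectories (Gaussian coordinate
jitter around a base structure, optionally mixing a "closed" ring with an
"open" ring of larger radius to emulate interface-exposing conformational
equilibria), and synthetic experimental uptake tables produced from
planted per-residue lnP and k_int.  Everything is reproducible bit-for-bit
from the seed, so the whole prediction pipeline is testable without any
external structure or dataset.

Structures are backbone-only (N, CA, C, O, plus constructed amide H);
optional CB dummies exercise the contact counts.  The helix uses canonical
alpha dihedrals, so interior residues receive exactly one i -> i-4
hydrogen bond under the 2.4 A criterion; the fully extended chain has
none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .structure_model import (
    Atom,
    Ensemble,
    Residue,
    StructureFrame,
    build_amide_hydrogens,
)
from .uptake import Fragment

__all__ = ["FixtureSpec", "make_structure", "make_ensemble", "make_uptake_table"]

# backbone geometry (lengths A, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_OMEGA = 180.0

# canonical dihedrals
HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -139.0, 135.0  # antiparallel beta strand

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic fixture; fixed seed -> identical bytes."""

    kind: str = "ideal_helix"   # extended_chain | ideal_helix | ring_oligomer
    n_residues: int = 20
    sequence: str = ""          # default poly-Ala of n_residues
    n_chains: int = 6
    radius: float = 8.0         # ring radius (A) for ring_oligomer
    n_frames: int = 25
    jitter_sigma: float = 0.3   # A per coordinate
    open_fraction: float = 0.0  # fraction of frames in the "open" ring state
    open_radius_shift: float = 6.0  # extra ring radius of the open state (A)
    seed: int = 0
    with_side_chain_dummies: bool = False

    def resolved_sequence(self) -> str:
        seq = self.sequence or "A" * self.n_residues
        if len(seq) < 2:
            raise ValueError("need at least 2 residues")
        return seq


# ---------------------------------------------------------------------------
# Internal-coordinate chain builder
# ---------------------------------------------------------------------------

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           r: float, theta_deg: float, chi_deg: float) -> np.ndarray:
    """Position a fourth atom from bond length, bond angle and dihedral."""
    theta, chi = np.radians(theta_deg), np.radians(chi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(chi), r * np.sin(theta) * np.sin(chi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(sequence: str, phi: float, psi: float,
                    with_cb: bool = False) -> list[dict]:
    """Backbone atoms for each residue of a chain with uniform dihedrals."""
    n_res = len(sequence)
    atoms: list[dict] = [dict() for _ in range(n_res)]
    atoms[0]["N"] = np.zeros(3)
    atoms[0]["CA"] = np.array([_B_N_CA, 0.0, 0.0])
    th = np.radians(_A_N_CA_C)
    atoms[0]["C"] = atoms[0]["CA"] + _B_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(1, n_res):
        p = atoms[i - 1]
        atoms[i]["N"] = _place(p["N"], p["CA"], p["C"], _B_C_N, _A_CA_C_N, psi)
        atoms[i]["CA"] = _place(p["CA"], p["C"], atoms[i]["N"], _B_N_CA, _A_C_N_CA, _OMEGA)
        atoms[i]["C"] = _place(p["C"], atoms[i]["N"], atoms[i]["CA"], _B_CA_C, _A_N_CA_C, phi)
    for i in range(n_res):
        nxt_psi = psi  # last residue: keep the chain's psi for O placement
        atoms[i]["O"] = _place(atoms[i]["N"], atoms[i]["CA"], atoms[i]["C"],
                               _B_C_O, _A_CA_C_O, nxt_psi + 180.0)
        if with_cb and sequence[i] != "G":
            atoms[i]["CB"] = _place(atoms[i]["C"], atoms[i]["N"], atoms[i]["CA"],
                                    1.53, 110.5, 122.5)
    return atoms


def _chain_frame(sequence: str, chain_id: str, phi: float, psi: float,
                 with_cb: bool) -> list[Residue]:
    coords = _build_backbone(sequence, phi, psi, with_cb)
    residues = []
    for i, aa in enumerate(sequence):
        rname = _ONE_TO_THREE.get(aa, "ALA")
        res = Residue(chain_id, i + 1, rname)
        for name, xyz in coords[i].items():
            element = name[0]
            res.atoms.append(Atom(name, element, xyz.copy()))
        residues.append(res)
    return residues


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_structure(spec: FixtureSpec, radius: Optional[float] = None) -> StructureFrame:
    """Build one synthetic conformation (amide hydrogens included)."""
    seq = spec.resolved_sequence()
    if spec.kind == "extended_chain":
        residues = _chain_frame(seq, "A", EXTENDED_PHI, EXTENDED_PSI,
                                spec.with_side_chain_dummies)
    elif spec.kind == "ideal_helix":
        residues = _chain_frame(seq, "A", HELIX_PHI, HELIX_PSI,
                                spec.with_side_chain_dummies)
    elif spec.kind == "ring_oligomer":
        r = spec.radius if radius is None else radius
        base = _chain_frame(seq, "A", HELIX_PHI, HELIX_PSI,
                            spec.with_side_chain_dummies)
        # orient the helix axis along z, then place copies on a ring
        coords = np.array([a.coords for res in base for a in res.atoms])
        axis = coords[-1] - coords[0]
        axis /= np.linalg.norm(axis)
        # rotation taking the helix axis to +z
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(axis, z)
        s, c = np.linalg.norm(v), float(axis @ z)
        if s < 1e-12:
            R_axis = np.eye(3)
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            R_axis = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        center = coords.mean(axis=0)
        residues = []
        chain_ids = "ABCDEFGHIJKLMNOP"
        for k in range(spec.n_chains):
            Rk = _rot_z(2.0 * np.pi * k / spec.n_chains)
            for res in base:
                new = Residue(chain_ids[k], res.resseq, res.name)
                for a in res.atoms:
                    xyz = R_axis @ (a.coords - center) + np.array([r, 0.0, 0.0])
                    new.atoms.append(Atom(a.name, a.element, Rk @ xyz))
                residues.append(new)
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    frame = StructureFrame(residues)
    return build_amide_hydrogens(frame)


def make_ensemble(spec: FixtureSpec) -> Ensemble:
    """Pseudo-trajectory: seeded Gaussian jitter around the base structure.

    With ``open_fraction > 0`` (ring_oligomer only) a deterministic subset
    of frames is generated from an "open" ring whose radius is larger by
    ``open_radius_shift``, emulating a closed/open conformational mixture
    that exposes the subunit interfaces part of the time.
    """
    rng = np.random.default_rng(spec.seed)
    closed = make_structure(spec)
    open_frame = None
    if spec.open_fraction > 0:
        if spec.kind != "ring_oligomer":
            raise ValueError("open/closed mixing requires a ring_oligomer")
        open_frame = make_structure(spec, radius=spec.radius + spec.open_radius_shift)
    n_open = int(round(spec.open_fraction * spec.n_frames))
    is_open = np.zeros(spec.n_frames, dtype=bool)
    if open_frame is not None and n_open:
        is_open[rng.permutation(spec.n_frames)[:n_open]] = True
    frames = []
    for i in range(spec.n_frames):
        base = open_frame if is_open[i] else closed
        f = base.copy()
        f.frame_index = i
        if spec.jitter_sigma > 0:
            for res in f.residues:
                for a in res.atoms:
                    a.coords = a.coords + rng.normal(0.0, spec.jitter_sigma, 3)
        frames.append(f)
    return Ensemble(frames)


def make_uptake_table(
    lnP: Mapping[int, float],
    k_int_s: Mapping[int, float],
    fragments: Sequence[Fragment],
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic experimental table from planted per-residue parameters.

    D values follow the EX2 uptake law averaged over each fragment's
    amides, plus Gaussian noise truncated to [0, 1].  Returns the table
    (fragment_id, time_s, D) and a ground-truth record (planted
    parameters and noise-free values) for parameter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    rows, truth_values = [], {}
    for frag in fragments:
        resseqs = [r for r in frag.resseqs if r in lnP and r in k_int_s]
        if not resseqs:
            raise ValueError(f"fragment {frag.id}: no planted residues")
        keff = np.array([k_int_s[r] * np.exp(-lnP[r]) for r in resseqs])
        D = (1.0 - np.exp(-np.outer(keff, t))).mean(axis=0)
        truth_values[frag.id] = D.tolist()
        noisy = np.clip(D + rng.normal(0.0, noise_sd, D.shape) if noise_sd > 0 else D,
                        0.0, 1.0)
        for ti, di in zip(t, noisy):
            rows.append((frag.id, float(ti), float(di)))
    table = pd.DataFrame(rows, columns=["fragment_id", "time_s", "D"])
    truth = {
        "lnP": {str(k): float(v) for k, v in lnP.items()},
        "k_int_s": {str(k): float(v) for k, v in k_int_s.items()},
        "times_s": t.tolist(),
        "noise_sd": noise_sd,
        "seed": seed,
        "noise_free_D": truth_values,
    }
    return table, truth
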