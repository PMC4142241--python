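"""Uniform topology + coordinates model for structures and trajectory frames.

Parses PDB files (single- or multi-MODEL) into lightweight frame objects,
locates or constructs backbone amide hydrogens, and reports per-chain
topology.  Only the twenty standard amino acids are retained as protein;
amino-acid-like HETATM records (e.g. MSE) are dropped with a warning.

Backbone amide hydrogens are the exchanging sites in HDX: every residue
except proline and the chain-initial residue carries exactly one.  Crystal
structures usually lack hydrogens, so :func:`build_amide_hydrogens` places
them with standard sp2 peptide geometry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("hdxpred")

#: three-letter -> one-letter codes for the standard amino acids
STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: default N-H bond length used when constructing amide hydrogens (Angstrom)
NH_BOND_LENGTH = 1.01

#: atom names accepted as the backbone amide hydrogen
_AMIDE_H_NAMES = ("H", "HN", "D", "DN")


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be interpreted."""


class EmptyStructureError(ValueError):
    """Raised when a file contains no standard protein residues."""


@dataclass
class Atom:
    """A single atom: label, element and Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    residue_index: int = -1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class Residue:
    """One amino-acid residue with author (PDB) numbering.

    ``amide_h`` is the backbone N-H hydrogen when present; proline and
    chain-initial residues never carry one.
    """

    chain_id: str
    resseq: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def amide_n(self) -> Optional[Atom]:
        return self.atom("N")

    @property
    def amide_h(self) -> Optional[Atom]:
        if self.name == "PRO":
            return None
        for name in _AMIDE_H_NAMES:
            a = self.atom(name)
            if a is not None:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return STANDARD_AA.get(self.name, "X")

    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.resseq)


@dataclass
class StructureFrame:
    """One conformation: residues grouped by chain, optional periodic box."""

    residues: list[Residue]
    frame_index: int = 0
    box: Optional[np.ndarray] = None  # orthorhombic box lengths (3,) in A
    solvent_oxygens: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3))
    )

    def __post_init__(self) -> None:
        keys = [r.key() for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, resseq) pairs in frame")

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    def heavy_coords(self) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """All heavy-atom coordinates and their (chain, resseq) owners."""
        coords, owners = [], []
        for r, a in self.iter_atoms():
            if a.is_heavy:
                coords.append(a.coords)
                owners.append(r.key())
        return np.asarray(coords).reshape(-1, 3), owners

    def topology_key(self) -> tuple:
        return tuple((r.chain_id, r.resseq, r.name) for r in self.residues)

    def copy(self) -> "StructureFrame":
        residues = [
            Residue(
                r.chain_id, r.resseq, r.name,
                [Atom(a.name, a.element, a.coords.copy()) for a in r.atoms],
            )
            for r in self.residues
        ]
        return StructureFrame(
            residues, self.frame_index,
            None if self.box is None else self.box.copy(),
            self.solvent_oxygens.copy(),
        )


@dataclass
class Ensemble:
    """Ordered frames sharing one topology, with normalized weights."""

    frames: list[StructureFrame]
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("ensemble needs at least one frame")
        key0 = self.frames[0].topology_key()
        for f in self.frames[1:]:
            if f.topology_key() != key0:
                raise ValueError("frames do not share a topology")
        n = len(self.frames)
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,) or np.any(self.weights < 0):
                raise ValueError("weights must be non-negative, one per frame")
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def first(self) -> StructureFrame:
        return self.frames[0]


@dataclass
class ChainDescriptor:
    chain_id: str
    first_resseq: int
    last_resseq: int
    sequence: str
    gaps: list[tuple[int, int]]


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _pick_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate conformers: highest occupancy wins, ties -> first."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def read_structure(
    path: str | Path,
    model_policy: str = "first",
    keep_solvent: bool = False,
) -> Ensemble:
    """Read a PDB file into an :class:`Ensemble`.

    Parameters
    ----------
    path:
        PDB file (ATOM/HETATM/MODEL/ENDMDL/CRYST1 records honoured).
    model_policy:
        ``"first"`` keeps only the first MODEL; ``"all"`` yields one frame
        per MODEL (a multi-model file is treated as a trajectory).
    keep_solvent:
        Retain water oxygens as potential H-bond acceptors (off by default;
        the contact/H-bond counts use protein atoms only unless asked).
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    box = None
    cell = st.cell
    if cell.a > 1.5 and cell.alpha == 90 and cell.beta == 90 and cell.gamma == 90:
        box = np.array([cell.a, cell.b, cell.c])

    models = list(st) if model_policy == "all" else [st[0]]
    frames = []
    warned: set[str] = set()
    for idx, model in enumerate(models):
        residues: list[Residue] = []
        solvent: list[np.ndarray] = []
        for chain in model:
            for gres in chain:
                rname = gres.name.strip()
                if rname in ("HOH", "DOD", "WAT"):
                    for atom in gres:
                        if atom.element.name == "O":
                            solvent.append(np.array(atom.pos.tolist()))
                    continue
                if rname not in STANDARD_AA:
                    info = gemmi.find_tabulated_residue(rname)
                    if info is not None and info.is_amino_acid() and rname not in warned:
                        warnings.warn(
                            f"non-standard residue {rname} {chain.name}{gres.seqid.num} excluded"
                        )
                        warned.add(rname)
                    continue
                atoms = [
                    Atom(a.name, a.element.name, np.array(a.pos.tolist()))
                    for a in _pick_altloc(gres)
                ]
                residues.append(Residue(chain.name, gres.seqid.num, rname, atoms))
        if not residues:
            raise EmptyStructureError(f"{path}: no standard protein residues")
        frames.append(
            StructureFrame(
                residues, frame_index=idx, box=box,
                solvent_oxygens=np.asarray(solvent).reshape(-1, 3)
                if keep_solvent else np.empty((0, 3)),
            )
        )
    return Ensemble(frames)


_ELEMENT_WIDTH = {"H": " H", "D": " D", "C": " C", "N": " N", "O": " O", "S": " S", "P": " P"}


def write_pdb(target: StructureFrame | Ensemble, path: str | Path) -> None:
    """Write frame(s) as a (multi-MODEL) PDB file with 3-decimal coordinates."""
    frames = target.frames if isinstance(target, Ensemble) else [target]
    lines: list[str] = []
    box = frames[0].box
    if box is not None:
        lines.append(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    multi = len(frames) > 1
    for i, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        serial = 1
        for res in frame.residues:
            for a in res.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                elem = _ELEMENT_WIDTH.get(a.element, f"{a.element:>2s}")
                lines.append(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.name:>3s} "
                    f"{res.chain_id:1s}{res.resseq:4d}    "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {elem}"
                )
                serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Amide hydrogen construction
# ---------------------------------------------------------------------------

def _place_amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Place H on the sp2 nitrogen: along the external bisector of the
    C(i-1)-N-CA angle, i.e. in the peptide plane and trans to the preceding
    carbonyl oxygen, at the standard N-H bond length."""
    u = n - c_prev
    v = n - ca
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    d = u + v
    d /= np.linalg.norm(d)
    return n + NH_BOND_LENGTH * d


def build_amide_hydrogens(frame: StructureFrame) -> StructureFrame:
    """Return a copy of *frame* in which every residue that should carry a
    backbone amide hydrogen has one.

    Existing hydrogens are never moved (the call is idempotent); proline and
    chain-initial residues are left without.  Residues whose own N/CA or
    whose predecessor's C is missing (including after a numbering gap) are
    skipped with a warning and later excluded from exchange sums.
    """
    out = frame.copy()
    by_key = {r.key(): r for r in out.residues}
    for chain_id in out.chain_ids:
        chain = sorted(out.chain(chain_id), key=lambda r: r.resseq)
        first_resseq = chain[0].resseq
        for res in chain:
            if res.name == "PRO" or res.resseq == first_resseq:
                continue
            if res.amide_h is not None:
                continue
            prev = by_key.get((chain_id, res.resseq - 1))
            n, ca = res.atom("N"), res.atom("CA")
            c_prev = prev.atom("C") if prev is not None else None
            if n is None or ca is None or c_prev is None:
                logger.warning(
                    "cannot build amide H for %s%d (missing backbone atoms)",
                    chain_id, res.resseq,
                )
                continue
            h = _place_amide_h(n.coords, ca.coords, c_prev.coords)
            res.atoms.append(Atom("H", "H", h))
    return out


def chain_map(ensemble: Ensemble) -> list[ChainDescriptor]:
    """Describe each chain of the (shared) topology: range, sequence, gaps."""
    frame = ensemble.first
    out = []
    for chain_id in frame.chain_ids:
        chain = sorted(frame.chain(chain_id), key=lambda r: r.resseq)
        seq = "".join(r.one_letter for r in chain)
        gaps = []
        for a, b in zip(chain, chain[1:]):
            if b.resseq > a.resseq + 1:
                gaps.append((a.resseq + 1, b.resseq - 1))
        out.append(
            ChainDescriptor(chain_id, chain[0].resseq, chain[-1].resseq, seq, gaps)
        )
    return out
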