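"""Peptide-fragment assignment checks by monoisotopic mass.

HDX-MS fragments are identified from proteolytic digests; a misassigned
fragment produces a spurious mismatch between predicted and measured
uptake.  Given an observed monoisotopic mass, every contiguous subsequence
of the protein within length bounds is scanned and candidates inside a ppm
tolerance are ranked by absolute mass error.  Masses are neutral peptide
monoisotopic masses (no adducts, no modifications by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

__all__ = [
    "PeptideCandidate",
    "monoisotopic_mass",
    "reassign",
    "validate_fragment_table",
    "read_fasta_sequence",
]

#: monoisotopic residue masses (Da), from the standard proteomics tables
RESIDUE_MASS: Mapping[str, float] = dict(_ptmass.std_aa_mass)
WATER_MASS: float = _ptmass.calculate_mass(formula="H2O")


@dataclass
class PeptideCandidate:
    """One candidate peptide for an observed mass, with signed errors."""

    start: int                 # residue numbers, inclusive
    end: int
    sequence: str
    monoisotopic_mass: float   # Da
    mass_error_da: float       # computed - observed, signed
    mass_error_ppm: float


def monoisotopic_mass(sequence: str, modifications: Optional[Mapping[str, float]] = None) -> float:
    """Neutral monoisotopic mass (Da) of a peptide: residue masses + water.

    ``modifications`` maps residue codes to fixed mass shifts (empty by
    default; e.g. carbamidomethyl-Cys would be ``{"C": 57.02146}``).
    """
    if not sequence:
        raise ValueError("empty sequence")
    mods = modifications or {}
    total = WATER_MASS
    for aa in sequence:
        if aa not in RESIDUE_MASS:
            raise ValueError(f"unknown residue code {aa!r}")
        total += RESIDUE_MASS[aa] + mods.get(aa, 0.0)
    return total


def reassign(
    observed_mass: float,
    protein_sequence: str,
    tolerance_ppm: float = 50.0,
    length_bounds: tuple[int, int] = (4, 40),
    first_resseq: int = 1,
    modifications: Optional[Mapping[str, float]] = None,
) -> list[PeptideCandidate]:
    """Exhaustively search contiguous subsequences matching an observed mass.

    Candidates within ``tolerance_ppm`` are ranked by absolute ppm error,
    ties broken by shorter length then smaller start.  ``first_resseq``
    offsets reported residue numbers to author numbering.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    lo, hi = length_bounds
    lo = max(1, lo)
    n = len(protein_sequence)
    mods = modifications or {}
    # prefix sums of residue masses -> O(1) mass per candidate
    res_mass = np.array(
        [RESIDUE_MASS[aa] + mods.get(aa, 0.0) for aa in protein_sequence]
    )
    prefix = np.concatenate([[0.0], np.cumsum(res_mass)])
    out: list[PeptideCandidate] = []
    for length in range(lo, min(hi, n) + 1):
        masses = prefix[length:] - prefix[:-length] + WATER_MASS
        errors = masses - observed_mass
        ppm = errors / observed_mass * 1e6
        for start0 in np.nonzero(np.abs(ppm) <= tolerance_ppm)[0]:
            out.append(
                PeptideCandidate(
                    start=first_resseq + int(start0),
                    end=first_resseq + int(start0) + length - 1,
                    sequence=protein_sequence[start0 : start0 + length],
                    monoisotopic_mass=float(masses[start0]),
                    mass_error_da=float(errors[start0]),
                    mass_error_ppm=float(ppm[start0]),
                )
            )
    out.sort(key=lambda c: (abs(c.mass_error_ppm), c.end - c.start, c.start))
    return out


def validate_fragment_table(
    fragments: Sequence,
    protein_sequence: str,
    tolerance_ppm: float = 50.0,
    first_resseq: int = 1,
    n_alternatives: int = 3,
) -> pd.DataFrame:
    """Check each fragment's observed mass against its assigned range.

    Fragments (objects with id, start_resseq, end_resseq, observed_mass)
    lacking an observed mass get status ``skipped``; otherwise ``match``
    when the assigned range lies within tolerance, else ``mismatch`` with
    the top alternatives from :func:`reassign`.
    """
    rows = []
    for frag in fragments:
        obs = getattr(frag, "observed_mass", None)
        if obs is None:
            rows.append((frag.id, "skipped", np.nan, np.nan, ""))
            continue
        i0 = frag.start_resseq - first_resseq
        i1 = frag.end_resseq - first_resseq + 1
        if i0 < 0 or i1 > len(protein_sequence):
            rows.append((frag.id, "out_of_range", np.nan, np.nan, ""))
            continue
        calc = monoisotopic_mass(protein_sequence[i0:i1])
        ppm = (calc - obs) / obs * 1e6
        if abs(ppm) <= tolerance_ppm:
            rows.append((frag.id, "match", calc, ppm, ""))
        else:
            alts = reassign(obs, protein_sequence, tolerance_ppm,
                            first_resseq=first_resseq)[:n_alternatives]
            alt_str = ";".join(f"{a.start}-{a.end}({a.mass_error_ppm:+.1f}ppm)" for a in alts)
            rows.append((frag.id, "mismatch", calc, ppm, alt_str))
    return pd.DataFrame(
        rows,
        columns=["fragment_id", "status", "calc_mass", "error_ppm", "alternatives"],
    )


def read_fasta_sequence(path: str | Path) -> str:
    """First sequence of a FASTA file as a plain 1-letter string."""
    seq: list[str] = []
    started = False
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if started:
                break
            started = True
            continue
        seq.append(line.strip())
    if not seq:
        raise ValueError(f"{path}: no sequence found")
    return "".join(seq)
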