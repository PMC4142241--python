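"""Shared synthetic fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hdxpred.fixtures import FixtureSpec, make_ensemble, make_structure
from hdxpred.structure_model import Atom, Residue, StructureFrame


@pytest.fixture(scope="session")
def helix20():
    """Ideal 20-residue poly-Ala alpha-helix with built amide hydrogens."""
    return make_structure(FixtureSpec(kind="ideal_helix", n_residues=20))


@pytest.fixture(scope="session")
def extended20():
    return make_structure(FixtureSpec(kind="extended_chain", n_residues=20))


@pytest.fixture(scope="session")
def hexamer():
    """C6-symmetric ring of 12-residue helices with interface contacts."""
    return make_structure(
        FixtureSpec(kind="ring_oligomer", n_residues=12, n_chains=6, radius=8.0)
    )


@pytest.fixture(scope="session")
def jittered_helix_ensemble():
    return make_ensemble(
        FixtureSpec(kind="ideal_helix", n_residues=14, n_frames=20,
                    jitter_sigma=0.3, seed=7)
    )


def random_frame(rng: np.random.Generator, n_residues: int = 8,
                 n_extra: int = 150, box_size: float = 25.0) -> StructureFrame:
    """A random-coordinate frame for brute-force count checks.

    Each residue gets backbone N, CA and an amide H near N; ``n_extra``
    atoms of random element (C/N/O/S) are sprinkled in the box and parked
    on extra residues so exclusion windows stay meaningful.
    """
    residues = []
    for i in range(n_residues):
        n_pos = rng.uniform(0, box_size, 3)
        res = Residue("A", i + 1, "ALA")
        res.atoms.append(Atom("N", "N", n_pos))
        res.atoms.append(Atom("CA", "C", n_pos + rng.normal(0, 0.5, 3)))
        res.atoms.append(Atom("H", "H", n_pos + rng.normal(0, 0.4, 3)))
        residues.append(res)
    extra_per_res = rng.multinomial(n_extra, np.ones(n_residues) / n_residues)
    elements = np.array(["C", "N", "O", "S"])
    for res, k in zip(residues, extra_per_res):
        for j in range(k):
            el = str(rng.choice(elements))
            res.atoms.append(
                Atom(f"X{j}", el, rng.uniform(0, box_size, 3))
            )
    return StructureFrame(residues)


def brute_force_contacts(frame: StructureFrame, residue, cutoff: float,
                         exclusion=(-1, 0, 1)) -> int:
    """O(N^2) reference count of heavy atoms near the amide nitrogen."""
    n = residue.amide_n.coords
    excluded = {(residue.chain_id, residue.resseq + off) for off in exclusion}
    count = 0
    for r in frame.residues:
        for a in r.atoms:
            if not a.is_heavy or r.key() in excluded:
                continue
            if np.linalg.norm(a.coords - n) < cutoff:
                count += 1
    return count


def brute_force_hbonds(frame: StructureFrame, residue, cutoff: float) -> int:
    """O(N^2) reference count of acceptor oxygens near the amide hydrogen."""
    h = residue.amide_h
    if h is None:
        return 0
    count = 0
    for r in frame.residues:
        for a in r.atoms:
            if a.element == "O" and np.linalg.norm(a.coords - h.coords) < cutoff:
                count += 1
    return count
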