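"""Deuterium uptake curves for residues and peptide fragments.

In the EX2 regime an amide with protection factor P = exp(lnP) exchanges
with observed rate k_int/P, so its deuterium fraction follows

    D_i(t) = 1 - exp(-(k_int_i / P_i) * t),

and a proteolytic fragment's deuterium fraction is the unweighted mean of
D_i(t) over the fragment's exchangeable amides (prolines and the
protein-initial residue carry none and are excluded from both numerator
and denominator).

Two ensemble-averaging conventions are supported:

* ``mean_lnP`` — average lnP over frames/chains first, then evaluate D(t)
  from the averaged profile (one curve per fragment);
* ``mean_D`` — evaluate D(t) per (frame, chain) from instantaneous lnP and
  average the curves with the ensemble weights.

They agree exactly for a single frame and chain, and differ on
heterogeneous ensembles (averaging the nonlinear D is not the same as
averaging lnP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intrinsic_rates import (
    ExchangeConditions,
    IntrinsicRateTable,
    PER_MINUTE_TO_PER_SECOND,
    k_int_profile,
)
from .protection import ProtectionParams, ProtectionProfile, average_protection, lnP_frame
from .structure_model import Ensemble, StructureFrame, build_amide_hydrogens, chain_map

__all__ = [
    "DEFAULT_TIME_GRID_S",
    "Fragment",
    "UptakeCurve",
    "residue_uptake",
    "fragment_uptake",
    "perframe_uptake_series",
    "uptake_table",
    "k_int_map",
    "read_fragment_csv",
    "predict_uptake",
]

#: the standard manual-mixing time grid: 30 s, 1, 2, 4, 8, 15, 30 min, 1, 2, 4 h
DEFAULT_TIME_GRID_S = np.array(
    [30.0, 60.0, 120.0, 240.0, 480.0, 900.0, 1800.0, 3600.0, 7200.0, 14400.0]
)


@dataclass
class Fragment:
    """A proteolytic peptide: inclusive author-numbered range on a chain.

    ``chain_scope`` is either a chain id or ``"averaged"`` (predicted curve
    averaged over all chains carrying the range, the convention for
    symmetric oligomers).  ``observed_mass`` (monoisotopic, Da) is optional
    and only used by the assignment checker.
    """

    id: str
    start_resseq: int
    end_resseq: int
    sequence: str = ""
    chain_scope: str = "averaged"
    observed_mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start_resseq > self.end_resseq:
            raise ValueError(f"fragment {self.id}: start > end")
        if self.sequence and len(self.sequence) != self.end_resseq - self.start_resseq + 1:
            raise ValueError(f"fragment {self.id}: sequence length mismatch")

    @property
    def resseqs(self) -> range:
        return range(self.start_resseq, self.end_resseq + 1)


@dataclass
class UptakeCurve:
    """Deuterium fraction on a time grid, predicted or experimental."""

    times: np.ndarray          # seconds, strictly increasing
    values: np.ndarray         # fraction in [0, 1]
    provenance: str = "predicted_ensemble"
    uncertainty: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("deuterium fractions must lie in [0, 1]")


def residue_uptake(lnP: float, k_int: float, times: Sequence[float]) -> UptakeCurve:
    """Single-residue uptake D(t) = 1 - exp(-(k_int/P) t), P = exp(lnP).

    ``k_int`` in 1/s, ``times`` in seconds (non-negative).
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if k_int < 0:
        raise ValueError("k_int must be non-negative")
    values = 1.0 - np.exp(-(k_int * np.exp(-lnP)) * t)
    return UptakeCurve(t, values, provenance="predicted_crystal")


def _residue_D(lnP: np.ndarray, k_s: np.ndarray, times: np.ndarray) -> np.ndarray:
    """(n_residues, n_times) matrix of D_i(t)."""
    keff = k_s * np.exp(-np.asarray(lnP))
    return 1.0 - np.exp(-np.outer(keff, times))


def _rate_lookup(rates: Mapping, chain: Optional[str], resseq: int) -> Optional[float]:
    if chain is not None and (chain, resseq) in rates:
        return rates[(chain, resseq)]
    return rates.get(resseq)


def fragment_uptake(
    fragment: Fragment,
    profile: ProtectionProfile,
    rates: Mapping,
    times: Sequence[float] = DEFAULT_TIME_GRID_S,
    mode: Optional[str] = None,
    exclude_n_terminal_residues_per_fragment: int = 0,
) -> UptakeCurve:
    """Fragment uptake curve from a protection profile and intrinsic rates.

    ``rates`` maps resseq (or ``(chain, resseq)``) to k_int in 1/s.  Only
    residues present in the profile (i.e. carrying an amide hydrogen) and
    in ``rates`` enter the unweighted mean; an option to drop the first
    1-2 fragment residues (rapid back-exchange convention) exists but is
    off by default.
    """
    mode = mode or profile.mode
    t = np.asarray(times, dtype=float)
    skip = set(
        list(fragment.resseqs)[: exclude_n_terminal_residues_per_fragment]
    )
    span = fragment.resseqs

    all_resseqs = profile.per_frame.resseq
    if len(all_resseqs) and (
        fragment.end_resseq < all_resseqs.min() or fragment.start_resseq > all_resseqs.max()
    ):
        raise ValueError(f"fragment {fragment.id}: range outside the profiled chain")

    if mode == "mean_lnP":
        sub = profile.per_residue[
            profile.per_residue.resseq.isin(span)
            & ~profile.per_residue.resseq.isin(skip)
        ]
        lnps, ks = [], []
        for _, row in sub.iterrows():
            k = _rate_lookup(rates, None, int(row.resseq))
            if k is None or not np.isfinite(k):
                continue
            lnps.append(row.mean_lnP)
            ks.append(k)
        if not lnps:
            raise ValueError(f"fragment {fragment.id}: no exchangeable amides")
        D = _residue_D(np.array(lnps), np.array(ks), t)
        return UptakeCurve(t, D.mean(axis=0), provenance="predicted_ensemble")

    if mode == "mean_D":
        pf = profile.per_frame
        sel = pf.resseq.isin(span) & ~pf.resseq.isin(skip)
        if fragment.chain_scope != "averaged":
            sel &= pf.chain == fragment.chain_scope
        sub = pf[sel]
        if sub.empty:
            raise ValueError(f"fragment {fragment.id}: no exchangeable amides")
        curves, weights = [], []
        for (_, chain), g in sub.groupby(["frame", "chain"], sort=True):
            ks, lnps = [], []
            for _, row in g.iterrows():
                k = _rate_lookup(rates, chain, int(row.resseq))
                if k is None or not np.isfinite(k):
                    continue
                ks.append(k)
                lnps.append(row.lnP)
            if not ks:
                continue
            curves.append(_residue_D(np.array(lnps), np.array(ks), t).mean(axis=0))
            weights.append(g.weight.iloc[0])
        if not curves:
            raise ValueError(f"fragment {fragment.id}: no exchangeable amides")
        w = np.asarray(weights)
        w = w / w.sum()
        values = np.average(np.vstack(curves), axis=0, weights=w)
        return UptakeCurve(t, values, provenance="predicted_perframe")

    raise ValueError("mode must be 'mean_lnP' or 'mean_D'")


def perframe_uptake_series(
    ensemble: Ensemble,
    fragment: Fragment,
    params: ProtectionParams = ProtectionParams(),
    cond: ExchangeConditions = ExchangeConditions(),
    t_star: float = 480.0,
    chain_id: Optional[str] = None,
    table: Optional[IntrinsicRateTable] = None,
) -> dict:
    """D(t*) along the ensemble from each frame's instantaneous lnP.

    With ``chain_id`` set, a single subunit is followed (no chain
    averaging).  Returns the per-frame series plus its weighted mean and
    min/max.
    """
    rates = k_int_map(ensemble.first, cond, table)
    series = []
    for frame in ensemble.frames:
        frame_h = build_amide_hydrogens(frame)
        df = lnP_frame(frame_h, params)
        sel = df.resseq.isin(fragment.resseqs)
        if chain_id is not None:
            sel &= df.chain == chain_id
        sub = df[sel]
        ks, lnps = [], []
        for _, row in sub.iterrows():
            k = _rate_lookup(rates, row.chain, int(row.resseq))
            if k is None:
                continue
            ks.append(k)
            lnps.append(row.lnP)
        if not ks:
            raise ValueError(f"fragment {fragment.id}: no exchangeable amides")
        D = _residue_D(np.array(lnps), np.array(ks), np.array([t_star]))
        series.append(float(D.mean(axis=0)[0]))
    series_arr = np.asarray(series)
    return {
        "t_star": t_star,
        "series": series_arr,
        "mean": float(np.average(series_arr, weights=ensemble.weights)),
        "min": float(series_arr.min()),
        "max": float(series_arr.max()),
    }


def uptake_table(
    fragments: Sequence[Fragment],
    profile: ProtectionProfile,
    rates: Mapping,
    times: Sequence[float] = DEFAULT_TIME_GRID_S,
    mode: Optional[str] = None,
) -> pd.DataFrame:
    """Long-format prediction table: fragment_id, time_s, D_pred, mode."""
    mode = mode or profile.mode
    rows = []
    for frag in fragments:
        curve = fragment_uptake(frag, profile, rates, times, mode)
        for t, d in zip(curve.times, curve.values):
            rows.append((frag.id, float(t), float(d), mode))
    return pd.DataFrame(rows, columns=["fragment_id", "time_s", "D_pred", "mode"])


# ---------------------------------------------------------------------------
# Plumbing between structure, rates and fragments
# ---------------------------------------------------------------------------

def k_int_map(
    frame: StructureFrame,
    cond: ExchangeConditions = ExchangeConditions(),
    table: Optional[IntrinsicRateTable] = None,
) -> dict:
    """Intrinsic rates (1/s) for every exchangeable amide of a frame.

    Keys: both ``(chain_id, resseq)`` and plain ``resseq`` (first chain
    encountered wins for the collapsed key; chains of a homo-oligomer give
    identical rates).  Residues directly after a numbering gap have an
    unknown predecessor and are left out, matching the amide-H builder.
    """
    out: dict = {}
    for chain_id in frame.chain_ids:
        chain = sorted(frame.chain(chain_id), key=lambda r: r.resseq)
        # split into contiguous segments at resseq gaps
        segments: list[list] = [[chain[0]]]
        for res in chain[1:]:
            if res.resseq == segments[-1][-1].resseq + 1:
                segments[-1].append(res)
            else:
                segments.append([res])
        for seg in segments:
            seq = "".join(r.one_letter for r in seg)
            rates = k_int_profile(seq, cond, table)
            for res, k in zip(seg, rates):
                if np.isnan(k):
                    continue
                k_s = k * PER_MINUTE_TO_PER_SECOND
                out[(chain_id, res.resseq)] = k_s
                out.setdefault(res.resseq, k_s)
    return out


def read_fragment_csv(path: str | Path) -> list[Fragment]:
    """Read a fragment table: id, chain, start, end[, sequence, observed_mass]."""
    df = pd.read_csv(path, dtype={"id": str})
    frags = []
    for _, row in df.iterrows():
        frags.append(
            Fragment(
                id=str(row["id"]),
                start_resseq=int(row["start"]),
                end_resseq=int(row["end"]),
                sequence=str(row["sequence"]) if "sequence" in df.columns and pd.notna(row.get("sequence")) else "",
                chain_scope=str(row["chain"]) if "chain" in df.columns and pd.notna(row.get("chain")) else "averaged",
                observed_mass=float(row["observed_mass"])
                if "observed_mass" in df.columns and pd.notna(row.get("observed_mass"))
                else None,
            )
        )
    return frags


def predict_uptake(
    ensemble: Ensemble,
    fragments: Sequence[Fragment],
    params: ProtectionParams = ProtectionParams(),
    cond: ExchangeConditions = ExchangeConditions(),
    times: Sequence[float] = DEFAULT_TIME_GRID_S,
    mode: str = "mean_lnP",
    table: Optional[IntrinsicRateTable] = None,
) -> tuple[pd.DataFrame, ProtectionProfile, dict]:
    """End-to-end prediction: build amide hydrogens, average protection over
    the ensemble, compute intrinsic rates, and evaluate fragment curves.

    Returns (uptake table, protection profile, intrinsic-rate map)."""
    frames_h = [build_amide_hydrogens(f) for f in ensemble.frames]
    ens_h = Ensemble(frames_h, ensemble.weights)
    profile = average_protection(ens_h, params, mode=mode)
    rates = k_int_map(ens_h.first, cond, table)
    table_df = uptake_table(fragments, profile, rates, times, mode)
    return table_df, profile, rates
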