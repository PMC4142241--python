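"""Comparison of predicted uptake with experimental HDX-MS tables.

Experimental tables are long-format (fragment_id, time_s, D, [sd],
[condition]).  Predictions and experiment are paired on shared fragment
ids and time points (times matched to a relative tolerance), residuals and
per-fragment / global RMSDs computed, and fragment kinetics summarized by
an apparent exchange rate from a single-exponential fit

    D(t) = A * (1 - exp(-k_app * t)),   0 < A <= 1,

the simplest apparent-rate convention; strongly biphasic kinetics shows up
as a poor fit (large residual norm) rather than being modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .uptake import UptakeCurve

__all__ = [
    "read_experiment_csv",
    "pair_predictions",
    "fragment_rmsd",
    "ApparentRateFit",
    "apparent_rate",
    "residue_rate_map",
    "scatter_plot",
]


def read_experiment_csv(path: str | Path, condition: Optional[str] = None) -> pd.DataFrame:
    """Load and validate an experimental uptake table.

    Requires columns fragment_id, time_s, D; rows with D outside [0, 1] or
    non-positive times are rejected with a message.
    """
    df = pd.read_csv(path, dtype={"fragment_id": str})
    missing = {"fragment_id", "time_s", "D"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = (df.D < 0) | (df.D > 1) | (df.time_s <= 0)
    if bad.any():
        raise ValueError(
            f"{path}: {int(bad.sum())} rows rejected (D outside [0,1] or time <= 0)"
        )
    if condition is not None and "condition" in df.columns:
        df = df[df.condition == condition]
    return df.reset_index(drop=True)


def pair_predictions(
    pred: pd.DataFrame,
    exp: pd.DataFrame,
    time_rtol: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair predicted and experimental rows on (fragment, time).

    Returns (paired, unmatched); paired has columns fragment_id, time_s,
    D_pred, D_exp.  Time points match when within ``time_rtol`` relative.
    """
    paired_rows, unmatched_rows = [], []
    exp_by_frag = {fid: g for fid, g in exp.groupby("fragment_id")}
    for fid, g in pred.groupby("fragment_id"):
        eg = exp_by_frag.get(fid)
        if eg is None:
            for _, row in g.iterrows():
                unmatched_rows.append((fid, row.time_s, "no_experimental_fragment"))
            continue
        for _, row in g.iterrows():
            rel = np.abs(eg.time_s - row.time_s) / row.time_s
            hit = rel.idxmin() if len(eg) else None
            if hit is not None and rel[hit] <= time_rtol:
                paired_rows.append((fid, row.time_s, row.D_pred, exp.loc[hit, "D"]))
            else:
                unmatched_rows.append((fid, row.time_s, "no_matching_time"))
    paired = pd.DataFrame(paired_rows, columns=["fragment_id", "time_s", "D_pred", "D_exp"])
    unmatched = pd.DataFrame(unmatched_rows, columns=["fragment_id", "time_s", "reason"])
    if paired.empty:
        raise ValueError("no overlap between prediction and experiment")
    return paired, unmatched


def fragment_rmsd(paired: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-fragment and global root-mean-square D_pred - D_exp."""
    resid = paired.D_pred - paired.D_exp
    per_fragment = (
        (resid**2).groupby(paired.fragment_id).mean().pow(0.5).rename("rmsd")
    )
    return per_fragment, float(np.sqrt((resid**2).mean()))


@dataclass
class ApparentRateFit:
    k_app: Optional[float]     # 1/s
    amplitude: Optional[float]
    residual_norm: float
    converged: bool


def apparent_rate(
    curve: UptakeCurve,
    residual_threshold: float = 0.05,
) -> ApparentRateFit:
    """Least-squares single-exponential apparent rate of an uptake curve.

    Initialized deterministically from the half-rise time; a fit whose
    root-mean-square residual exceeds ``residual_threshold`` (or that does
    not converge) is flagged ``converged=False`` (biphasic or flat data).
    """
    t, d = curve.times, curve.values
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    a0 = max(float(d.max()), 1e-3)
    half = 0.5 * a0
    above = np.nonzero(d >= half)[0]
    t_half = t[above[0]] if len(above) else t[-1]
    k0 = np.log(2.0) / max(t_half, 1e-12)

    def _resid(p):
        k, a = p
        return a * (1.0 - np.exp(-k * t)) - d

    try:
        sol = least_squares(
            _resid, x0=[k0, min(a0, 1.0)],
            bounds=([1e-15, 1e-6], [np.inf, 1.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except ValueError:
        return ApparentRateFit(None, None, np.inf, False)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    if not sol.success or rms > residual_threshold or d.max() < 1e-6:
        return ApparentRateFit(None, None, rms, False)
    return ApparentRateFit(float(sol.x[0]), float(sol.x[1]), rms, True)


def residue_rate_map(
    profile,
    rates: Mapping,
    sequence_resseqs: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per-residue predicted observed rate k_int * exp(-lnP) (1/s).

    Residues without an amide hydrogen (prolines, chain-initial) appear
    with NaN rate and has_amide=False so plots can black them out.
    """
    lnp = profile.lnP_by_residue()
    resseqs = sequence_resseqs if sequence_resseqs is not None else sorted(lnp)
    rows = []
    for resseq in resseqs:
        k = rates.get(resseq)
        if resseq in lnp and k is not None:
            rows.append((resseq, True, k * np.exp(-lnp[resseq]), lnp[resseq]))
        else:
            rows.append((resseq, False, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["resseq", "has_amide", "k_pred", "lnP"])


def scatter_plot(paired: pd.DataFrame, path: str | Path) -> None:
    """Predicted-vs-experimental scatter with the identity diagonal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for fid, g in paired.groupby("fragment_id"):
        ax.plot(g.D_exp, g.D_pred, "o", ms=4, label=str(fid))
    ax.plot([0, 1], [0, 1], "k-", lw=1)
    ax.set_xlabel("experimental D(t)")
    ax.set_ylabel("predicted D(t)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
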