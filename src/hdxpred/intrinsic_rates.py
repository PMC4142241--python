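"""Intrinsic (unprotected) amide exchange rates.

The intrinsic rate k_int of a fully exposed backbone amide depends on the
side chains of the residue itself and of its predecessor, on pH and on
temperature.  It is the sum of acid-, base- and water-catalysed channels,

    k_int = kA * F_A * 10^(-pD)  +  kB * F_B * 10^(pD - pK_D)  +  kW * F_W,

where the reference rates kA, kB, kW are the calibrated poly-DL-alanine
values, the F's are products of decadic neighbour factors (the residue's
own "lambda" factor and the predecessor's "rho" factor; the water channel
shares the base factors), and each channel is scaled from the 293 K
reference with its own Arrhenius activation energy.  Titratable side chains
(Asp, Glu, His) blend their protonated and deprotonated factors with
Henderson-Hasselbalch populations at the working pD.

Rates are per minute internally (the convention of the source tables);
:data:`PER_MINUTE_TO_PER_SECOND` converts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ExchangeConditions",
    "IntrinsicRateTable",
    "load_rate_table",
    "k_int",
    "k_int_profile",
    "PER_MINUTE_TO_PER_SECOND",
]

PER_MINUTE_TO_PER_SECOND = 1.0 / 60.0


@dataclass(frozen=True)
class ExchangeConditions:
    """Solution conditions of the labelling step.

    ``pD_correction`` applies the electrode reading correction
    pD = pH_read + 0.4 before use; it is off by default, so ``pH`` is used
    verbatim in the rate law.
    """

    pH: float = 7.9
    temperature: float = 298.0  # K
    pD_correction: bool = False
    exchange_direction: str = "H_to_D"

    def __post_init__(self) -> None:
        if not (0.0 < self.pH < 14.0):
            raise ValueError("pH must be in (0, 14)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.exchange_direction != "H_to_D":
            raise ValueError("only H_to_D exchange is supported")

    @property
    def pD(self) -> float:
        return self.pH + 0.4 if self.pD_correction else self.pH


class IntrinsicRateTable:
    """Vendored reference parameters (neighbour factors, reference rates,
    activation energies).  Swappable: pass another JSON file with the same
    schema to :func:`load_rate_table`."""

    def __init__(self, raw: dict):
        self.raw = raw
        self.factors: dict[str, list] = raw["factors"]
        self.log_kA = raw["log10_kA_ref"]
        self.log_kB = raw["log10_kB_ref"]
        self.log_kW = raw["log10_kW_ref"]
        self.pKD_water = raw["pKD_water"]
        self.T_ref = raw["reference_temperature_K"]
        self.Ea = raw["activation_energy_cal_per_mol"]
        self.R = raw["gas_constant_cal_per_mol_K"]
        self.side_pKD = raw["side_chain_pKD"]
        for aa in "ARNDCGQEHILKMFPSTWYV":
            if aa not in self.factors and f"{aa}_protonated" not in self.factors:
                raise ValueError(f"rate table lacks residue {aa}")

    # -- neighbour factors ------------------------------------------------

    def _blended(self, aa: str, pD: float) -> list[float]:
        """Four log-factors for one side chain, blending titratable forms
        by their populations at the working pD (in linear space)."""
        if aa in self.side_pKD:
            pK = self.side_pKD[aa]
            f_prot = 1.0 / (1.0 + 10.0 ** (pD - pK))
            prot = self.factors[f"{aa}_protonated"]
            deprot = self.factors[f"{aa}_deprotonated"]
            out = []
            for p, d in zip(prot, deprot):
                if p is None or d is None:
                    out.append(None)
                else:
                    out.append(float(np.log10(f_prot * 10.0 ** p + (1 - f_prot) * 10.0 ** d)))
            return out
        return self.factors[aa]

    def log_factors(self, own: str, prev: str, pD: float,
                    n_terminal_neighbor: bool, c_terminal: bool) -> tuple[float, float]:
        """(acid, base) summed log-factors for the amide of residue ``own``
        preceded by ``prev``; terminal-group contributions included."""
        own_f = self._blended(own, pD)
        prev_f = self._blended(prev, pD)
        if own_f[0] is None or own_f[2] is None:
            raise ValueError(f"residue {own} has no amide hydrogen")
        acid = own_f[0] + prev_f[1]
        base = own_f[2] + prev_f[3]
        if n_terminal_neighbor:
            nt = self.factors["N_terminal_amine"]
            acid += nt[1]
            base += nt[3]
        if c_terminal:
            ct = self.factors["C_terminal_carboxylate"]
            acid += ct[0]
            base += ct[2]
        return acid, base

    # -- Arrhenius --------------------------------------------------------

    def temperature_factor(self, channel: str, T: float) -> float:
        Ea = self.Ea[channel]
        return float(np.exp(-Ea / self.R * (1.0 / T - 1.0 / self.T_ref)))


def load_rate_table(path: Optional[str | Path] = None) -> IntrinsicRateTable:
    if path is None:
        raw = json.loads(
            resources.files("hdxpred.data").joinpath("bai1993_rates.json").read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    return IntrinsicRateTable(raw)


_DEFAULT_TABLE: Optional[IntrinsicRateTable] = None


def _default_table() -> IntrinsicRateTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_rate_table()
    return _DEFAULT_TABLE


def k_int(
    sequence: str,
    position: int,
    cond: ExchangeConditions = ExchangeConditions(),
    table: Optional[IntrinsicRateTable] = None,
) -> float:
    """Intrinsic exchange rate (1/min) of the amide of ``sequence[position]``.

    ``position`` is a 0-based index into the 1-letter sequence.  The first
    residue (free amine, no backbone amide) and prolines raise.
    """
    table = table or _default_table()
    n = len(sequence)
    if not (0 <= position < n):
        raise IndexError("position outside sequence")
    aa = sequence[position]
    if position == 0:
        raise ValueError("the N-terminal residue has no backbone amide")
    if aa == "P":
        raise ValueError("proline has no amide hydrogen")
    prev = sequence[position - 1]
    for code in (aa, prev):
        if code not in table.factors and f"{code}_protonated" not in table.factors:
            raise ValueError(f"unknown residue code {code!r}")
    pD = cond.pD
    acid_f, base_f = table.log_factors(
        aa, prev, pD,
        n_terminal_neighbor=(position == 1),
        c_terminal=(position == n - 1),
    )
    k_acid = 10.0 ** (table.log_kA + acid_f - pD)
    k_base = 10.0 ** (table.log_kB + base_f + pD - table.pKD_water)
    k_water = 10.0 ** (table.log_kW + base_f)
    T = cond.temperature
    return (
        k_acid * table.temperature_factor("acid", T)
        + k_base * table.temperature_factor("base", T)
        + k_water * table.temperature_factor("water", T)
    )


def k_int_profile(
    sequence: str,
    cond: ExchangeConditions = ExchangeConditions(),
    table: Optional[IntrinsicRateTable] = None,
) -> np.ndarray:
    """Per-residue intrinsic rates (1/min) for a chain sequence.

    Non-exchanging positions (the first residue and prolines) are NaN.
    """
    table = table or _default_table()
    out = np.full(len(sequence), np.nan)
    for i, aa in enumerate(sequence):
        if i == 0 or aa == "P":
            continue
        out[i] = k_int(sequence, i, cond, table)
    return out
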