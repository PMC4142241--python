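"""Residue- and fragment-level deuterium uptake curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdxpred.fixtures import FixtureSpec, make_ensemble, make_structure
from hdxpred.intrinsic_rates import ExchangeConditions
from hdxpred.protection import ProtectionParams, average_protection, lnP_frame
from hdxpred.structure_model import Ensemble
from hdxpred.uptake import (
    DEFAULT_TIME_GRID_S,
    Fragment,
    fragment_uptake,
    k_int_map,
    perframe_uptake_series,
    predict_uptake,
    residue_uptake,
    uptake_table,
)

TIMES = np.array([1.0, 10.0, 100.0, 1000.0])


class TestResidueUptake:
    def test_saturating_exponential_shape(self):
        curve = residue_uptake(lnP=2.0, k_int=0.1, times=[0.0, 1e9])
        assert curve.values[0] == 0.0
        assert curve.values[-1] == pytest.approx(1.0)

    def test_half_life_identity(self):
        """D = 1/2 exactly at t = P ln2 / k_int."""
        lnP, k = 3.0, 0.05
        t_half = np.exp(lnP) * np.log(2.0) / k
        curve = residue_uptake(lnP, k, [t_half / 2, t_half])
        assert curve.values[-1] == pytest.approx(0.5, rel=1e-12)

    def test_unprotected_residue_exchanges_at_intrinsic_rate(self):
        k = 0.01
        curve = residue_uptake(0.0, k, TIMES)
        assert np.allclose(curve.values, 1.0 - np.exp(-k * TIMES))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            residue_uptake(1.0, 0.1, [-1.0])

    @settings(deadline=None, max_examples=50)
    @given(
        lnP=st.floats(0.0, 20.0),
        k=st.floats(1e-6, 10.0),
    )
    def test_curves_monotone_and_bounded(self, lnP, k):
        t = np.logspace(-1, 6, 30)
        curve = residue_uptake(lnP, k, t)
        assert np.all(np.diff(curve.values) >= -1e-15)
        assert curve.values.min() >= 0.0 and curve.values.max() <= 1.0


def _profile_and_rates(frame, cond=ExchangeConditions()):
    prof = average_protection(Ensemble([frame]))
    rates = k_int_map(frame, cond)
    return prof, rates


class TestFragmentUptake:
    def test_single_amide_fragment_equals_residue_curve(self, helix20):
        prof, rates = _profile_and_rates(helix20)
        frag = Fragment(id="f", start_resseq=8, end_resseq=8)
        curve = fragment_uptake(frag, prof, rates, TIMES)
        lnP = prof.lnP_by_residue()[8]
        ref = residue_uptake(lnP, rates[8], TIMES)
        assert np.allclose(curve.values, ref.values)

    def test_two_amides_average(self):
        """Fragment value is the unweighted mean of residue fractions."""
        import pandas as pd

        from hdxpred.protection import ProtectionProfile
        per_res = pd.DataFrame(
            {"resseq": [2, 3], "aa": ["A", "A"], "mean_Nc": [0, 0],
             "mean_Nh": [0, 0], "mean_lnP": [0.0, 0.0],
             "n_frames": [1, 1], "n_chains": [1, 1]}
        )
        per_frame = pd.DataFrame(
            {"frame": [0, 0], "chain": ["A", "A"], "resseq": [2, 3],
             "aa": ["A", "A"], "Nc": [0, 0], "Nh": [0, 0],
             "lnP": [0.0, 0.0], "weight": [1.0, 1.0]}
        )
        prof = ProtectionProfile(per_frame, per_res, ProtectionParams())
        t = np.array([100.0])
        # choose rates giving D = 0.2 and 0.4 at t
        k1 = -np.log(0.8) / 100.0
        k2 = -np.log(0.6) / 100.0
        curve = fragment_uptake(
            Fragment(id="f", start_resseq=2, end_resseq=3),
            prof, {2: k1, 3: k2}, t,
        )
        assert curve.values[0] == pytest.approx(0.3, rel=1e-12)

    def test_modes_agree_on_single_frame_single_chain(self, helix20):
        prof, rates = _profile_and_rates(helix20)
        frag = Fragment(id="f", start_resseq=4, end_resseq=12)
        a = fragment_uptake(frag, prof, rates, TIMES, mode="mean_lnP")
        b = fragment_uptake(frag, prof, rates, TIMES, mode="mean_D")
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_fragment_bracketed_by_extreme_residues(self, hexamer):
        prof, rates = _profile_and_rates(hexamer)
        frag = Fragment(id="f", start_resseq=3, end_resseq=10)
        curve = fragment_uptake(frag, prof, rates, TIMES)
        residue_curves = []
        for r in range(3, 11):
            if r in prof.lnP_by_residue() and r in rates:
                residue_curves.append(
                    residue_uptake(prof.lnP_by_residue()[r], rates[r], TIMES).values
                )
        lo = np.min(residue_curves, axis=0)
        hi = np.max(residue_curves, axis=0)
        assert np.all(curve.values >= lo - 1e-12)
        assert np.all(curve.values <= hi + 1e-12)

    def test_increasing_lnP_never_speeds_up_fragment(self, helix20):
        prof, rates = _profile_and_rates(helix20)
        frag = Fragment(id="f", start_resseq=5, end_resseq=10)
        base = fragment_uptake(frag, prof, rates, TIMES)
        prof.per_residue.loc[prof.per_residue.resseq == 7, "mean_lnP"] += 1.5
        slower = fragment_uptake(frag, prof, rates, TIMES)
        assert np.all(slower.values <= base.values + 1e-15)

    def test_errors(self, helix20):
        prof, rates = _profile_and_rates(helix20)
        with pytest.raises(ValueError):
            fragment_uptake(
                Fragment(id="x", start_resseq=100, end_resseq=120), prof, rates, TIMES
            )
        with pytest.raises(ValueError):
            # proline-only fragment has no amides
            fragment_uptake(
                Fragment(id="x", start_resseq=1, end_resseq=1), prof, rates, TIMES
            )


class TestPerFrame:
    def test_static_ensemble_constant_series(self, helix20):
        ens = Ensemble([helix20.copy() for _ in range(4)])
        for i, f in enumerate(ens.frames):
            f.frame_index = i
        frag = Fragment(id="f", start_resseq=4, end_resseq=10)
        out = perframe_uptake_series(ens, frag, t_star=480.0)
        assert np.allclose(out["series"], out["series"][0])
        assert out["min"] == pytest.approx(out["max"])

    def test_series_mean_equals_mean_D_value(self, jittered_helix_ensemble):
        ens = jittered_helix_ensemble
        frag = Fragment(id="f", start_resseq=4, end_resseq=10)
        out = perframe_uptake_series(ens, frag, t_star=480.0, chain_id="A")
        table, profile, rates = predict_uptake(
            ens, [frag], times=np.array([480.0]), mode="mean_D"
        )
        assert out["mean"] == pytest.approx(table.D_pred.iloc[0], rel=1e-9)

    def test_jensen_gap_mean_D_exceeds_D_of_mean_lnP(self, jittered_helix_ensemble):
        """With lnP variance across frames and fractions below the convexity
        bound (D < 1 - 1/e), per-frame averaging exchanges faster."""
        ens = jittered_helix_ensemble
        frag = Fragment(id="f", start_resseq=6, end_resseq=12)
        t = np.array([30.0])
        tab_D, prof, rates = predict_uptake(ens, [frag], times=t, mode="mean_D")
        tab_lnP = uptake_table([frag], prof, rates, t, mode="mean_lnP")
        d_meanD = tab_D.D_pred.iloc[0]
        d_meanlnP = tab_lnP.D_pred.iloc[0]
        assert d_meanD < 1 - 1 / np.e  # inside the convex region
        lnp_var = prof.per_frame.query("6 <= resseq <= 12").groupby("resseq").lnP.var()
        assert (lnp_var > 0).all()
        assert d_meanD >= d_meanlnP - 1e-12


class TestTable:
    def test_table_shape_and_bounds(self, hexamer):
        prof, rates = _profile_and_rates(hexamer)
        frags = [
            Fragment(id=str(i), start_resseq=2 + i, end_resseq=6 + i)
            for i in range(5)
        ]
        tab = uptake_table(frags, prof, rates)
        assert len(tab) == 5 * len(DEFAULT_TIME_GRID_S)
        assert tab.D_pred.between(0, 1).all()

    def test_empty_fragment_list(self, helix20):
        prof, rates = _profile_and_rates(helix20)
        assert len(uptake_table([], prof, rates)) == 0

    def test_single_time_grid(self, helix20):
        prof, rates = _profile_and_rates(helix20)
        tab = uptake_table(
            [Fragment(id="f", start_resseq=3, end_resseq=9)], prof, rates, [480.0]
        )
        assert len(tab) == 1
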