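"""Simulation contract: baseline, stimulation, normalization, dose response."""

import numpy as np
import pytest

from bcrsignal import (StimulusProtocol, conserved_totals, dose_response,
                       nominal_parameters, normalize_relative_to_basal,
                       normalize_relative_to_final, rhs, run_to_steady_state,
                       simulate_stimulation)
from bcrsignal.errors import NormalizationError, ValidationError
from bcrsignal.model import STATE_INDEX
from bcrsignal.simulate import DOWNSTREAM_OUTPUTS, default_t_grid

from conftest import FAST

TOL = 1e-8


def test_baseline_is_steady_and_downstream_zero(params, wt_baseline, wt_ledger):
    assert np.max(np.abs(rhs(wt_baseline, params, 0, 0, wt_ledger))) <= 1e-9
    proto = StimulusProtocol(0.0, 0.0, "WT")
    tc = simulate_stimulation(wt_baseline, params, proto, ledger=wt_ledger)
    for out in DOWNSTREAM_OUTPUTS:
        assert tc.basal(out) <= TOL
    # the Syk pool is intact before stimulation
    assert conserved_totals(wt_baseline, params)["Syk"] == pytest.approx(
        params.get("Syk_total"))


def test_equilibrium_persists_without_ligand(params, wt_baseline, wt_ledger):
    proto = StimulusProtocol(0.0, 0.0, "WT")
    tc = simulate_stimulation(wt_baseline, params, proto, ledger=wt_ledger)
    assert np.allclose(tc.states, wt_baseline[None, :], atol=1e-7)


def test_ligand_induces_erkp(params, wt_baseline, wt_ledger):
    proto = StimulusProtocol(20.0, 0.0, "WT")
    tc = simulate_stimulation(wt_baseline, params, proto, ledger=wt_ledger)
    assert tc.output("Erkp").max() > 1e-3
    assert tc.completed


def test_inhibited_syk_nondecreasing(params, aql_baseline, aql_ledger):
    proto = StimulusProtocol(20.0, 1.0, "AQL")
    tc = simulate_stimulation(aql_baseline, params, proto, ledger=aql_ledger,
                              **FAST)
    inh = tc.states[:, STATE_INDEX["Syk_inh"]]
    assert np.all(np.diff(inh) >= -1e-9)


def test_first_row_equals_baseline(params, wt_baseline, wt_ledger):
    proto = StimulusProtocol(20.0, 0.0, "WT")
    tc = simulate_stimulation(wt_baseline, params, proto, ledger=wt_ledger)
    assert np.allclose(tc.states[0], wt_baseline)


def test_determinism(params, wt_baseline, wt_ledger):
    proto = StimulusProtocol(20.0, 0.0, "WT")
    a = simulate_stimulation(wt_baseline, params, proto, ledger=wt_ledger)
    b = simulate_stimulation(wt_baseline, params, proto, ledger=wt_ledger)
    assert np.array_equal(a.states, b.states)


def test_grid_refinement_stability(params, wt_baseline, wt_ledger):
    coarse = StimulusProtocol(20.0, 0.0, "WT", t_grid=np.arange(0.0, 31.0))
    fine = StimulusProtocol(20.0, 0.0, "WT", t_grid=np.arange(0.0, 30.5, 0.5))
    a = simulate_stimulation(wt_baseline, params, coarse, ledger=wt_ledger)
    b = simulate_stimulation(wt_baseline, params, fine, ledger=wt_ledger)
    assert np.allclose(a.output("Erkp"), b.output("Erkp")[::2], rtol=1e-5, atol=1e-8)


def test_conservation_along_trajectory(params, wt_baseline, wt_ledger):
    proto = StimulusProtocol(50.0, 0.0, "WT")
    tc = simulate_stimulation(wt_baseline, params, proto, ledger=wt_ledger)
    t0 = conserved_totals(tc.states[0], params)
    bcr_prev = t0["BCR"]
    for row in tc.states[1:]:
        tk = conserved_totals(row, params)
        for pool in ("Syk", "Lyn", "BLNK", "BTK", "PLC2g", "Clathrin",
                     "Erk", "MEK", "NFkB"):
            assert tk[pool] == pytest.approx(t0[pool], rel=1e-7)
        assert tk["BCR"] <= bcr_prev + 1e-9
        bcr_prev = tk["BCR"]


def test_protocol_validation():
    with pytest.raises(ValidationError):
        StimulusProtocol(-1.0)
    with pytest.raises(ValidationError):
        StimulusProtocol(1.0, t_grid=np.array([1.0, 2.0]))      # must start at 0
    with pytest.raises(ValidationError):
        StimulusProtocol(1.0, t_grid=np.array([0.0, 2.0, 1.0]))  # must increase


class TestNormalization:
    def test_relative_to_basal_identity_and_floor(self, params, wt_baseline, wt_ledger):
        proto = StimulusProtocol(20.0, 0.0, "WT")
        tc = simulate_stimulation(wt_baseline, params, proto, ledger=wt_ledger)
        # an output whose basal exceeds the floor normalizes to 1 at t=0
        assert normalize_relative_to_basal(tc, "IkB_nondegraded", 0.0) == pytest.approx(1.0)
        # a structurally-zero basal hits the floor: y = x / eps
        x5 = tc.output("Erkp")[5]
        assert normalize_relative_to_basal(tc, "Erkp", 5.0, eps_basal=1e-6) == \
            pytest.approx(x5 / 1e-6)
        # homogeneity: doubling the floor halves the value
        assert normalize_relative_to_basal(tc, "Erkp", 5.0, eps_basal=2e-6) == \
            pytest.approx(x5 / 2e-6)

    def test_relative_to_final(self, params, wt_baseline, wt_ledger):
        proto = StimulusProtocol(10.0, 0.0, "WT")
        tc = simulate_stimulation(wt_baseline, params, proto, ledger=wt_ledger)
        assert normalize_relative_to_final(tc, "Erkp", 30.0, 30.0) == pytest.approx(1.0)
        erkp = tc.output("Erkp")
        for t in (5.0, 15.0, 25.0):
            want = erkp[int(t)] / erkp[30]
            assert normalize_relative_to_final(tc, "Erkp", t, 30.0) == pytest.approx(want)
        # monotone rising output stays at or below its final value
        assert all(normalize_relative_to_final(tc, "Erkp", t, 30.0) <= 1.0 + 1e-9
                   for t in tc.t)

    def test_relative_to_final_zero_raises(self, params, wt_baseline, wt_ledger):
        proto = StimulusProtocol(0.0, 0.0, "WT")
        tc = simulate_stimulation(wt_baseline, params, proto, ledger=wt_ledger)
        with pytest.raises(NormalizationError):
            normalize_relative_to_final(tc, "Erkp", 5.0, 30.0)

    def test_unknown_output_rejected(self, params, wt_baseline, wt_ledger):
        proto = StimulusProtocol(0.0, 0.0, "WT")
        tc = simulate_stimulation(wt_baseline, params, proto, ledger=wt_ledger)
        with pytest.raises(NormalizationError):
            normalize_relative_to_basal(tc, "NotAnOutput", 0.0)


class TestDoseResponse:
    def test_single_dose_max_norm_is_one(self, params):
        df = dose_response(params, "WT", [20.0], output="Erkp", t_obs=5.0,
                           normalization="max_dose", **FAST)
        assert df["value"].iloc[0] == pytest.approx(1.0)

    def test_zero_oi_curve_ends_at_one(self, params):
        df = dose_response(params, "AQL", [5.5, 50.0, 150.0],
                           oi_levels=[0.0, 1.0], output="Erkp", t_obs=5.0,
                           normalization="max_dose", **FAST)
        zero_oi = df[df["oi"] == 0.0]["value"].to_numpy()
        assert zero_oi[-1] == pytest.approx(1.0)

    def test_monotone_in_dose_and_oi(self, params):
        df = dose_response(params, "AQL", [5.5, 16.5, 50.0, 150.0],
                           oi_levels=[0.0, 0.5, 1.0], output="Erkp", t_obs=5.0,
                           normalization="max_dose", **FAST)
        for oi, grp in df.groupby("oi"):
            assert np.all(np.diff(grp["value"].to_numpy()) >= -1e-9)
        pivot = df.pivot(index="dose", columns="oi", values="value").to_numpy()
        assert np.all(np.diff(pivot, axis=1) <= 1e-9)  # more OI, weaker response

    def test_empty_dose_list_rejected(self, params):
        with pytest.raises(ValidationError):
            dose_response(params, "WT", [])
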