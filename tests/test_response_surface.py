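"""Contour grids, power-law affinity, collapse recovery, Syk allocation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrsignal import (StimulusProtocol, amplification, assemble_model,
                       collapse_exponent, evaluate_grid, partition_regions,
                       power_law_affinity, run_to_steady_state,
                       simulate_stimulation, syk_allocation)
from bcrsignal.errors import DomainError, ValidationError
from bcrsignal.simulate import default_t_grid

from conftest import FAST


class TestPowerLawAffinity:
    def test_alpha_one_is_standard_affinity(self):
        assert power_law_affinity(2.0, 4.0, 1.0) == pytest.approx(0.5)

    def test_three_quarters_example(self):
        assert power_law_affinity(8.0, 16.0, 0.75) == pytest.approx(1.0)

    @given(st.floats(0.01, 100), st.floats(0.0, 1.5))
    @settings(deadline=None, max_examples=50)
    def test_unit_reverse_rate_gives_kf(self, kf, alpha):
        assert power_law_affinity(kf, 1.0, alpha) == pytest.approx(kf)

    def test_positive_rates_required(self):
        with pytest.raises(DomainError):
            power_law_affinity(0.0, 1.0, 0.75)


@pytest.fixture(scope="module")
def wt_surface(params):
    return evaluate_grid(params, "WT", 0.0, n_per_axis=8, budget_per_point=60.0)


class TestGrid:
    def test_grid_point_matches_single_run(self, params, wt_surface):
        """A grid cell equals an independent simulation at the same rates."""
        i, j = 3, 5
        p = params.updated({"rw0_kf": 10.0 ** wt_surface.log_kf[j],
                            "rw0_kr": 10.0 ** wt_surface.log_kr[i]})
        ledger = assemble_model(p, "WT")
        base = run_to_steady_state(p, "WT", ledger=ledger, **FAST)
        tc = simulate_stimulation(base, p, StimulusProtocol(20.0, 0.0, "WT"),
                                  ledger=ledger, **FAST)
        erkp = tc.output("Erkp")[5]
        nfkb = tc.output("NFkB")[15]
        assert erkp == pytest.approx(wt_surface.erkp[i, j], rel=1e-6)
        assert nfkb == pytest.approx(wt_surface.nfkb[i, j], rel=1e-6)

    def test_wt_normalization_peaks_at_one(self, wt_surface):
        assert np.nanmax(wt_surface.erkp / wt_surface.normalizers[0]) == pytest.approx(1.0)
        assert np.nanmax(wt_surface.nfkb / wt_surface.normalizers[1]) == pytest.approx(1.0)

    def test_low_kr_region_depends_on_kf_only(self, wt_surface):
        low, _ = partition_regions(wt_surface, -0.5)
        rows = wt_surface.log_kr <= -0.5
        sub = wt_surface.metric[rows, :]
        var_along_kr = np.mean(np.var(sub, axis=0))
        var_along_kf = np.mean(np.var(sub, axis=1))
        assert var_along_kr < 0.10 * var_along_kf

    def test_mutant_with_oi_suppresses_nfkb_not_erkp(self, params, wt_surface):
        mut = evaluate_grid(params, "AQL", 1.0, n_per_axis=8,
                            budget_per_point=60.0,
                            wt_normalizers=wt_surface.normalizers)
        assert np.all(mut.nfkb <= wt_surface.nfkb + 1e-9)
        erkp_plateau_wt = np.nanmax(wt_surface.erkp) / wt_surface.normalizers[0]
        erkp_plateau_mut = np.nanmax(mut.erkp) / wt_surface.normalizers[0]
        assert erkp_plateau_mut >= 0.8 * erkp_plateau_wt

    def test_validation(self, params):
        with pytest.raises(ValidationError):
            evaluate_grid(params, "WT", 0.0, n_per_axis=1)
        with pytest.raises(ValidationError):
            evaluate_grid(params, "AQL", 1.0, n_per_axis=2)  # needs normalizers


class TestPartition:
    def test_masks_disjoint_and_exhaustive(self, wt_surface):
        low, high = partition_regions(wt_surface, -0.5)
        assert not np.any(low & high)
        assert np.all(low | high)

    def test_split_at_axis_minimum_empties_nothing_low(self, wt_surface):
        low, high = partition_regions(wt_surface, wt_surface.log_kr[0])
        assert low[0].all() and not low[1:].any()

    def test_split_outside_range_rejected(self, wt_surface):
        with pytest.raises(ValidationError):
            partition_regions(wt_surface, 99.0)


class TestCollapse:
    @pytest.mark.parametrize("alpha0", [0.5, 0.75, 1.0])
    def test_recovers_constructed_exponent(self, alpha0):
        lkf, lkr = np.meshgrid(np.linspace(-2, 2, 15), np.linspace(-2, 2, 15))
        vals = np.tanh(lkf - alpha0 * lkr)
        fit = collapse_exponent(None, None,
                                points=(lkf.ravel(), lkr.ravel(), vals.ravel()))
        step = fit.alpha_grid[1] - fit.alpha_grid[0]
        assert abs(fit.alpha_hat - alpha0) <= step + 1e-12

    def test_forward_rate_only_surface_prefers_alpha_zero(self):
        lkf, lkr = np.meshgrid(np.linspace(-2, 2, 12), np.linspace(-2, 2, 12))
        vals = 1.0 / (1.0 + np.exp(-2 * lkf))
        fit = collapse_exponent(None, None,
                                points=(lkf.ravel(), lkr.ravel(), vals.ravel()))
        assert fit.alpha_hat == pytest.approx(0.0, abs=1e-12)
        assert np.nanargmax(fit.quality) == 0

    def test_constant_surface_degenerate(self):
        lkf, lkr = np.meshgrid(np.linspace(-2, 2, 6), np.linspace(-2, 2, 6))
        fit = collapse_exponent(None, None,
                                points=(lkf.ravel(), lkr.ravel(),
                                        np.full(lkf.size, 0.3)))
        assert fit.degenerate
        assert fit.alpha_hat is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            collapse_exponent(None, None,
                              points=(np.zeros(5), np.zeros(5), np.zeros(5)))


class TestSykAllocation:
    def test_wild_type_has_no_inhibited_fraction(self, params):
        df = syk_allocation(params, "WT", 0.0, np.logspace(-1, 1, 4), **FAST)
        assert np.all(df["inhibited"] == 0.0)

    def test_fractions_sum_to_one(self, params):
        df = syk_allocation(params, "AQL", 1.0, np.logspace(-1, 1, 4), **FAST)
        total = df[["Sykb", "Syk342", "Syk317", "inhibited", "other"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-6)

    def test_inhibited_fraction_monotone_in_oi(self, params):
        fr = [syk_allocation(params, "AQL", oi, [1.0], **FAST)["inhibited"].iloc[0]
              for oi in (0.0, 0.3, 1.0, 3.0, 10.0)]
        assert np.all(np.diff(fr) >= -1e-9)
        assert fr[0] == 0.0
        assert fr[-1] > 0.99  # saturating inhibitor captures essentially all Syk


class TestAmplification:
    def _courses(self, params, oi):
        lw = assemble_model(params, "WT")
        la = assemble_model(params, "AQL")
        bw = run_to_steady_state(params, "WT", ledger=lw, **FAST)
        ba = run_to_steady_state(params, "AQL", ledger=la, **FAST)
        tw = simulate_stimulation(bw, params, StimulusProtocol(20.0, 0.0, "WT"),
                                  ledger=lw, **FAST)
        tm = simulate_stimulation(ba, params, StimulusProtocol(20.0, oi, "AQL"),
                                  ledger=la, **FAST)
        return tw, tm

    def test_arithmetic(self, params):
        tw, tm = self._courses(params, 1.0)
        i = 5
        out_drop = 1 - tm.output("Erkp")[i] / tw.output("Erkp")[i]
        dag_drop = 1 - tm.output("DAG")[i] / tw.output("DAG")[i]
        assert amplification(tw, tm, "Erkp", 5.0) == pytest.approx(out_drop / dag_drop)

    def test_unchanged_output_gives_zero(self, params):
        from dataclasses import replace

        from bcrsignal.model import STATE_INDEX

        tw, tm = self._courses(params, 1.0)
        # mutant course with the wild-type Erkp but its own (reduced) DAG
        states = tm.states.copy()
        for name in ("Erkp1", "Erkp2"):
            states[:, STATE_INDEX[name]] = tw.states[:, STATE_INDEX[name]]
        tm_same_out = replace(tm, states=states)
        assert amplification(tw, tm_same_out, "Erkp", 5.0) == pytest.approx(0.0)
        # equal fractional drops in output and DAG give exactly 1
        assert amplification(tw, tm, "DAG", 5.0) == pytest.approx(1.0)
        # identical courses leave DAG unchanged: undefined amplification
        with pytest.raises(DomainError):
            amplification(tw, tw, "Erkp", 5.0)

    def test_nfkb_amplified_more_than_erkp(self, params):
        """Under partial Syk inhibition NF-kB tracks the DAG drop ~1:1 while
        the saturated MAPK cascade buffers Erkp."""
        tw, tm = self._courses(params, 1.0)
        amp_erkp = amplification(tw, tm, "Erkp", 5.0)
        amp_nfkb = amplification(tw, tm, "NFkB", 5.0)
        assert amp_nfkb > amp_erkp
        assert 0.0 < amp_erkp < 1.0
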