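"""Model-core checks: ledger structure, RHS correctness, conservation."""

import numpy as np
import pytest

from bcrsignal import (ALIASES, N_STATES, POOLS, ParameterSet, assemble_model,
                       conserved_totals, nominal_parameters, rhs)
from bcrsignal.errors import (ConfigurationError, DomainError, IntegrityError,
                              ValidationError)
from bcrsignal.model import (IMPLIED_SPECIES, RATE_GROUPS, STATE_INDEX,
                             STATE_NAMES, CompiledModel)

from _reference import reference_rhs
from conftest import random_nonneg_state


@pytest.mark.parametrize("scenario", ["WT", "AQL"])
def test_state_inventory_is_32_and_stable(params, scenario):
    ledger = assemble_model(params, scenario)
    assert ledger.n_states == 32
    assert len(STATE_NAMES) == 32 == len(set(STATE_NAMES))
    # the name -> index map round-trips
    assert all(STATE_NAMES[i] == n for n, i in STATE_INDEX.items())


def test_oi_reactions_present_only_under_aql(params, wt_ledger, aql_ledger):
    wt_oi = [r for r in wt_ledger.reactions if r.rate == "r_oi_association"]
    aql_oi = [r for r in aql_ledger.reactions if r.rate == "r_oi_association"]
    assert wt_oi == []
    assert len(aql_oi) == 4  # one association per Syk form
    assert {r.reactants[0] for r in aql_oi} == {"Sykb", "Syk342", "Syk317", "Syk_free"}


def test_assemble_model_validates_inputs(params):
    with pytest.raises(ConfigurationError):
        assemble_model(params, "XYZ")
    with pytest.raises(ValidationError):
        nominal_parameters().updated({"rw0_kf": -1.0})


@pytest.mark.parametrize("scenario", ["WT", "AQL"])
def test_ledger_rhs_matches_hand_transcription(params, scenario, rng):
    """The assembled RHS equals an independent equation-by-equation transcription."""
    ledger = assemble_model(params, scenario)
    for _ in range(100):
        y = random_nonneg_state(rng, params)
        ligand = rng.uniform(0.0, 1.0)
        oi = rng.uniform(0.0, 2.0)
        got = rhs(y, params, ligand, oi, ledger)
        want = reference_rhs(y, params, ligand, oi, scenario)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-12)


def test_rhs_single_active_term():
    """One ligand-binding flux: d(BCRb) = +1, d(BCRfree) = -1, rest zero."""
    # CD45 at zero keeps the regulatory module quiescent so only the
    # association term is active
    p = nominal_parameters().updated({"CD45_level": 0.0})
    y = np.zeros(N_STATES)
    y[STATE_INDEX["BCRfree"]] = 5.0
    ligand = 0.2 / p.get("r_association")  # so that r_association * L = 0.2
    d = rhs(y, p, ligand=ligand, oi=0.0)
    assert d[STATE_INDEX["BCRb"]] == pytest.approx(1.0)
    assert d[STATE_INDEX["BCRfree"]] == pytest.approx(-1.0)
    others = [i for i in range(N_STATES)
              if i not in (STATE_INDEX["BCRb"], STATE_INDEX["BCRfree"])]
    assert np.all(d[others] == 0.0)


def test_empty_system_is_at_rest():
    p = nominal_parameters().updated({"CD45_level": 0.0})
    d = rhs(np.zeros(N_STATES), p, ligand=0.0, oi=0.0)
    assert np.all(d == 0.0)


def test_syk_mass_balance_closes_under_oi(params, aql_ledger, rng):
    """Explicit Syk forms plus implied free Syk have zero net derivative."""
    idx = [STATE_INDEX[n] for n in ("Sykb", "Syk342", "Syk317", "Syk_inh")]
    cm = CompiledModel(aql_ledger, params)
    for _ in range(25):
        y = random_nonneg_state(rng, params)
        cm.set_inputs(rng.uniform(0, 1), rng.uniform(0.1, 2.0))
        d = cm.rhs(0.0, y)
        # d(free)/dt = -d(sum of explicit)/dt by conservation; the explicit
        # derivative must equal the total influx from the free pool
        free = cm.implied(y)[list(IMPLIED_SPECIES).index("Syk_free")]
        explicit = d[idx].sum()
        # recompute the free-pool exchange terms directly from the state
        binding = (params.get("r_syk_bcr_binding1") * y[STATE_INDEX["BCRp1"]]
                   + params.get("r_syk_bcr_binding2") * y[STATE_INDEX["BCRp2"]]) * free
        unbinding = params.get("r_syk_bcr_unbinding") * y[STATE_INDEX["Sykb"]]
        oi_free = params.get("r_oi_association") * cm._ext[cm._st.oi_idx] * free
        assert explicit == pytest.approx(binding - unbinding + oi_free, rel=1e-10, abs=1e-12)


@pytest.mark.parametrize("scenario", ["WT", "AQL"])
def test_pool_stoichiometry_zero_except_flagged(params, scenario):
    """Every reaction is pool-neutral unless flagged as that pool's source/sink."""
    ledger = assemble_model(params, scenario)
    for pool, info in POOLS.items():
        allowed = set(info["sources"]) | set(info["sinks"])
        for rxn in ledger.reactions:
            net = ledger.pool_net(pool, rxn)
            if rxn.name in allowed:
                assert net != 0.0, (pool, rxn.name)
            else:
                assert net == 0.0, (pool, rxn.name)


def test_rhs_linear_in_each_rate(params, rng):
    """Mass action is multilinear: d(rhs)/d(rate) matches finite differences."""
    ledger = assemble_model(params, "AQL")
    y = random_nonneg_state(rng, params)
    for name in ("r_association", "r_syk342_auto", "r_erk_phos", "r_oi_association"):
        base = params.get(name)
        d1 = rhs(y, params, 0.5, 0.5, ledger)
        p2 = params.updated({name: 2.0 * base})
        d2 = rhs(y, p2, 0.5, 0.5, ledger)
        # doubling the rate doubles exactly the fluxes carrying it
        dd = d2 - d1
        p3 = params.updated({name: 3.0 * base})
        d3 = rhs(y, p3, 0.5, 0.5, ledger)
        assert np.allclose(d3 - d1, 2.0 * dd, rtol=1e-10, atol=1e-14)


def test_rhs_rejects_invalid_inputs(params):
    y = np.zeros(N_STATES)
    y[0] = -0.1
    with pytest.raises(DomainError):
        rhs(y, params)
    with pytest.raises(DomainError):
        rhs(np.zeros(N_STATES), params, ligand=-1.0)
    bad = np.zeros(N_STATES)
    bad[STATE_INDEX["SHP1Star"]] = 2.0 * params.get("SHP1_total")
    with pytest.raises(IntegrityError):
        rhs(bad, params)


def test_missing_rate_symbol_is_named():
    vals = dict(nominal_parameters().values)
    del vals["r_erk_phos"]
    with pytest.raises(ConfigurationError, match="r_erk_phos"):
        ParameterSet(vals)


def test_aliases_resolve_to_grouped_rates(params):
    for alias, target in ALIASES.items():
        assert params.get(alias) == params.get(target)
        assert target in RATE_GROUPS
    # group labels follow the natural subsystem divisions
    assert ParameterSet.group_of("rw0_kf") == 1
    assert ParameterSet.group_of("rw9_kf") == 2
    assert ParameterSet.group_of("rw15_kf") == 4
    assert ParameterSet.group_of("r13_kf") == 5
    assert ParameterSet.group_of("r18_kf") == 6
    assert ParameterSet.group_of("r38_kf") == 7


def test_parameter_roundtrip(tmp_path, params):
    for ext in ("yaml", "json"):
        path = tmp_path / f"params.{ext}"
        params.save(path)
        again = ParameterSet.load(path)
        assert again.values == params.values


def test_conserved_totals_at_baseline(params, wt_baseline):
    totals = conserved_totals(wt_baseline, params)
    assert totals["Syk"] == pytest.approx(params.get("Syk_total"))
    assert totals["BCR"] == pytest.approx(params.get("BCR_total"))
    assert totals["Lyn"] == pytest.approx(params.get("Lyn_total"))


def test_bcr_pool_decreases_with_degradation(params):
    y = np.zeros(N_STATES)
    y[STATE_INDEX["BCRi"]] = 0.5
    d = rhs(y, params)
    bcr_members = ("BCRfree", "BCRb", "BCRp1", "BCRp2", "BCRi",
                   "Sykb", "Syk342", "Syk317")
    net = sum(d[STATE_INDEX[m]] for m in bcr_members)
    # recycling moves mass within the pool; degradation drains it
    assert net == pytest.approx(-params.get("r_degradation") * 0.5)


def test_ledger_export_table(params, aql_ledger):
    df = aql_ledger.to_frame()
    assert len(df) == len(aql_ledger.reactions)
    assert set(df.columns) == {"reaction", "rate", "reactants", "products", "modifiers"}
    assert df["reaction"].is_unique
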