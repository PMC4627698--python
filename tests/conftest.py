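import numpy as np
import pytest

from bcrsignal import assemble_model, nominal_parameters, run_to_steady_state

# fast-but-accurate tolerances shared by the ODE-heavy tests
FAST = dict(rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="session")
def params():
    return nominal_parameters()


@pytest.fixture(scope="session")
def wt_ledger(params):
    return assemble_model(params, "WT")


@pytest.fixture(scope="session")
def aql_ledger(params):
    return assemble_model(params, "AQL")


@pytest.fixture(scope="session")
def wt_baseline(params, wt_ledger):
    return run_to_steady_state(params, "WT", ledger=wt_ledger)


@pytest.fixture(scope="session")
def aql_baseline(params, aql_ledger):
    return run_to_steady_state(params, "AQL", ledger=aql_ledger)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_nonneg_state(rng, params, scale=0.3):
    """Random nonnegative state respecting every conservation constraint."""
    from bcrsignal.model import IMPLIED_SPECIES, N_STATES, STATE_INDEX

    y = rng.uniform(0.0, scale, N_STATES)
    # rescale each conserved family so explicit members never exceed the total
    for total_sym, members in IMPLIED_SPECIES.values():
        idx = [STATE_INDEX[m] for m in members]
        used = y[idx].sum()
        cap = 0.9 * params.get(total_sym)
        if used > cap:
            y[idx] *= cap / used
    # BCR family: five explicit receptor states plus receptor carried by bound Syk
    bcr_idx = [STATE_INDEX[m] for m in
               ("BCRfree", "BCRb", "BCRp1", "BCRp2", "BCRi")]
    syk_idx = [STATE_INDEX[m] for m in ("Sykb", "Syk342", "Syk317")]
    used = y[bcr_idx].sum() + y[syk_idx].sum()
    cap = params.get("BCR_total")
    if used > cap:
        y[bcr_idx] *= 0.5 * cap / used
    return y
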