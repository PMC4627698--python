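"""Objective function, noise model, acceptance rule and LHS parameter screening.

A candidate parameter vector is judged against observation tables via the
standardized residual

    J = (y_obs - y_sim) / sigma,

and accepted when |J| <= eta for every observation, with a per-dataset
threshold eta (the dose-response screens use |J_Erkp| <= 1 and
|J_IkB| <= 2; the time-course screen uses eta = 1).  Measurement
uncertainty for blot-style dose-response data follows the linear model

    sigma = 0.0127 + 0.3084 * y_obs,

while replicate time courses carry the sample standard deviation of the
replicates.  Candidates are drawn by Latin hypercube sampling in log10
space, by default two decades either side of nominal, over the sensitive
parameter list only.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .errors import ConfigurationError, DomainError, ValidationError
from .model import ParameterSet, assemble_model
from .simulate import (StimulusProtocol, normalize_relative_to_basal,
                       normalize_relative_to_final, run_to_steady_state,
                       simulate_stimulation)

SIGMA_INTERCEPT = 0.0127
SIGMA_SLOPE = 0.3084

NORMALIZATION_MODES = ("relative_to_basal", "relative_to_final", "WT_max")

OBSERVATION_COLUMNS = ("dataset", "output", "dose", "oi", "scenario",
                       "t", "y", "sigma", "mode", "rep")


def sigma_model(y_obs: float, intercept: float = SIGMA_INTERCEPT,
                slope: float = SIGMA_SLOPE) -> float:
    """Linear measurement-uncertainty model sigma(y) = intercept + slope * y."""
    y = np.asarray(y_obs, dtype=float)
    if np.any(y < 0):
        raise DomainError("y_obs must be nonnegative")
    out = intercept + slope * y
    return float(out) if out.ndim == 0 else out


def objective_J(y_obs: float, y_sim: float, sigma: float):
    """Signed standardized residual (y_obs - y_sim) / sigma."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise DomainError("sigma must be strictly positive")
    out = (np.asarray(y_obs, dtype=float) - np.asarray(y_sim, dtype=float)) / sigma
    return float(out) if out.ndim == 0 else out


def accept(J, eta: float) -> bool:
    """Boundary-inclusive acceptance: |J| <= eta."""
    if eta <= 0:
        raise DomainError("eta must be positive")
    return bool(np.all(np.abs(np.asarray(J, dtype=float)) <= eta))


def lhs_sample(param_names, log_ranges, n: int, seed: int | None = None) -> pd.DataFrame:
    """Latin hypercube sample in log10 space; one point per stratum per dimension."""
    names = tuple(param_names)
    if n < 1:
        raise ValidationError("n must be at least 1")
    lo = np.array([log_ranges[k][0] for k in names])
    hi = np.array([log_ranges[k][1] for k in names])
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValidationError("log ranges must be finite")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    return pd.DataFrame(qmc.scale(unit, lo, hi), columns=list(names))


def tune_parameter(params: ParameterSet, name: str, factor: float) -> ParameterSet:
    """Return a copy with one rate multiplied by ``factor`` (provenance noted).

    Supports the manual retuning workflow used to carry a wild-type fit over
    to the mutant (e.g. raising the Y317 phosphorylation rate ``rw9_kf``, or
    halving ``Syk_total`` to mimic reduced kinase expression).
    """
    return params.scaled(name, factor, note=f"tuned {name} x {factor:g}")


# --------------------------------------------------------------------------- observations

def observation_table(rows) -> pd.DataFrame:
    """Validate and normalize an observation table."""
    df = pd.DataFrame(rows)
    for col in ("dataset", "output", "dose", "t", "y", "sigma", "mode"):
        if col not in df.columns:
            raise ConfigurationError(f"observation table lacks column {col!r}")
    if "oi" not in df.columns:
        df["oi"] = 0.0
    if "scenario" not in df.columns:
        df["scenario"] = "WT"
    if "rep" not in df.columns:
        df["rep"] = 0
    bad_mode = set(df["mode"]) - set(NORMALIZATION_MODES)
    if bad_mode:
        raise ConfigurationError(f"unknown normalization mode(s) {sorted(bad_mode)}")
    if (df["sigma"] <= 0).any():
        raise ValidationError("sigma must be strictly positive")
    if (df["t"] < 0).any():
        raise ValidationError("t must be nonnegative")
    return df[list(OBSERVATION_COLUMNS)].copy()


def write_observations(df: pd.DataFrame, path) -> None:
    observation_table(df).to_csv(path, sep="\t", index=False)


def read_observations(path) -> pd.DataFrame:
    return observation_table(pd.read_csv(path, sep="\t"))


# --------------------------------------------------------------------------- simulation glue

def _t_grid_for(df: pd.DataFrame, horizon: float = 30.0) -> np.ndarray:
    ts = set(np.asarray(df["t"], dtype=float))
    ts |= set(np.arange(0.0, horizon + 0.5))
    return np.array(sorted(ts))


def simulated_observations(params: ParameterSet, datasets: pd.DataFrame, *,
                           eps_basal: float = 1e-6, rtol: float = 1e-6,
                           atol: float = 1e-9, deadline: float | None = None,
                           baseline_cache: dict | None = None) -> np.ndarray:
    """y_sim for every row of ``datasets`` under ``params``.

    Simulations are shared across rows that need the same (scenario, dose,
    oi) condition.  ``baseline_cache`` maps scenario -> pre-equilibrated
    state and may be shared across candidates whose perturbed parameters do
    not touch the unstimulated baseline.
    """
    datasets = observation_table(datasets)
    t_grid = _t_grid_for(datasets)
    ledgers = {s: assemble_model(params, s) for s in datasets["scenario"].unique()}
    baselines = baseline_cache if baseline_cache is not None else {}

    def get_baseline(scen):
        if scen not in baselines:
            baselines[scen] = run_to_steady_state(params, scen,
                                                  ledger=ledgers.get(scen) or
                                                  assemble_model(params, scen),
                                                  rtol=rtol, atol=atol)
        return baselines[scen]

    # WT_max rows need a wild-type reference at the dataset's maximum dose
    wtmax = datasets[datasets["mode"] == "WT_max"]
    ref_needed = {(ds, out): grp["dose"].max()
                  for (ds, out), grp in wtmax.groupby(["dataset", "output"])}
    if ref_needed and "WT" not in ledgers:
        ledgers["WT"] = assemble_model(params, "WT")

    conditions = {(r.scenario, r.dose, r.oi) for r in datasets.itertuples()}
    conditions |= {("WT", dose, 0.0) for dose in ref_needed.values()}
    tcs = {}
    for scen, dose, oi in sorted(conditions):
        proto = StimulusProtocol(ligand_dose=dose, oi_dose=oi, scenario=scen,
                                 t_grid=t_grid)
        tcs[(scen, dose, oi)] = simulate_stimulation(
            get_baseline(scen), params, proto, rtol=rtol, atol=atol,
            ledger=ledgers[scen], deadline=deadline)

    y_sim = np.empty(len(datasets))
    t_final_by_ds = datasets.groupby("dataset")["t"].max()
    for i, row in enumerate(datasets.itertuples()):
        tc = tcs[(row.scenario, row.dose, row.oi)]
        if row.mode == "relative_to_basal":
            y_sim[i] = normalize_relative_to_basal(tc, row.output, row.t, eps_basal)
        elif row.mode == "relative_to_final":
            y_sim[i] = normalize_relative_to_final(tc, row.output, row.t,
                                                   t_final_by_ds[row.dataset])
        else:  # WT_max
            ref_tc = tcs[("WT", ref_needed[(row.dataset, row.output)], 0.0)]
            ref = ref_tc.output(row.output)[np.argmax(np.isclose(ref_tc.t, row.t))]
            if ref <= 0:
                raise ValidationError("WT reference response is zero")
            y_sim[i] = tc.output(row.output)[np.argmax(np.isclose(tc.t, row.t))] / ref
    return y_sim


# --------------------------------------------------------------------------- screening

@dataclass
class ScreeningResult:
    """Outcome of screening LHS candidates against observation tables."""

    param_names: tuple[str, ...]
    candidates: pd.DataFrame       # log10 offsets from nominal, one row per candidate
    table: pd.DataFrame            # per-candidate max |J| per dataset, accepted, cause
    thresholds: dict[str, float]
    seed: int | None = None

    @property
    def accepted(self) -> np.ndarray:
        return self.table["accepted"].to_numpy()

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))


def screen(candidates: pd.DataFrame, datasets: pd.DataFrame,
           params_nominal: ParameterSet, scenario: str = "WT", *,
           thresholds: dict[str, float] | None = None, eta_default: float = 1.0,
           eps_basal: float = 1e-6, rtol: float = 1e-6, atol: float = 1e-9,
           budget_per_candidate: float | None = None,
           seed: int | None = None) -> ScreeningResult:
    """Evaluate every candidate (log10 offsets from nominal) against the data.

    A candidate is accepted when, for every dataset, max |J| <= that
    dataset's threshold.  Integration failures and wall-budget overruns are
    recorded as rejections with a cause.  The ``scenario`` argument sets the
    scenario used for rows whose table does not override it.
    """
    datasets = observation_table(datasets)
    if datasets.empty:
        raise ValidationError("datasets must be nonempty")
    names = tuple(candidates.columns)
    thresholds = dict(thresholds or {})
    for ds in datasets["dataset"].unique():
        thresholds.setdefault(ds, eta_default)

    nominal_logs = np.array([np.log10(params_nominal.get(n)) for n in names])
    # the baseline can be shared across candidates unless a screened
    # parameter participates in the unstimulated regulatory equilibrium
    baseline_inert = all(ParameterSet.group_of(n) != 3 for n in names)
    shared_cache: dict = {}

    rows = []
    for idx, offs in enumerate(np.asarray(candidates, dtype=float)):
        values = {n: 10.0 ** (nominal_logs[j] + offs[j]) for j, n in enumerate(names)}
        p = params_nominal.updated(values)
        deadline = (time.monotonic() + budget_per_candidate
                    if budget_per_candidate is not None else None)
        cache = dict(shared_cache) if baseline_inert else {}
        rec = {"candidate": idx, "accepted": False, "cause": ""}
        try:
            y_sim = simulated_observations(p, datasets, eps_basal=eps_basal,
                                           rtol=rtol, atol=atol, deadline=deadline,
                                           baseline_cache=cache)
        except Exception as exc:  # halted or integrator failure -> rejection
            from .errors import SimulationHalted
            rec["cause"] = ("halted" if isinstance(exc, SimulationHalted)
                            else f"error: {type(exc).__name__}")
            for ds in thresholds:
                rec[f"Jmax_{ds}"] = np.nan
            rows.append(rec)
            continue
        if baseline_inert and not shared_cache:
            shared_cache.update(cache)
        J = objective_J(datasets["y"].to_numpy(), y_sim, datasets["sigma"].to_numpy())
        ok = True
        for ds, grp_idx in datasets.groupby("dataset").groups.items():
            jmax = float(np.max(np.abs(J[datasets.index.get_indexer(grp_idx)])))
            rec[f"Jmax_{ds}"] = jmax
            ok = ok and jmax <= thresholds[ds]
        rec["accepted"] = ok
        rows.append(rec)

    table = pd.DataFrame(rows)
    return ScreeningResult(param_names=names, candidates=candidates.copy(),
                           table=table, thresholds=thresholds, seed=seed)
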