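"""Pre-equilibration, stimulation protocols and output normalization.

The workflow mirrors the study design: run the unstimulated model to steady
state (downstream outputs are structurally zero there), record basal output
levels, then apply ligand (and, under the AQL scenario, orthogonal
inhibitor) at t = 0 and integrate the stiff system over a 30-minute window.

Normalization conventions supported:

* relative to basal - output at the observation time divided by its basal
  value (with a small floor ``eps_basal``, because downstream basal levels
  are structurally zero);
* relative to final - output divided by its own value at the final time
  point (used for replicate time-course data);
* maximum-dose / WT-maximum - dose-response curves scaled by the response at
  the maximum dose (of the same scenario, or of wild type).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import (DomainError, NonConvergenceError, NormalizationError,
                     SimulationHalted, ValidationError)
from .model import (N_STATES, STATE_INDEX, CompiledModel, ParameterSet,
                    ReactionLedger, assemble_model)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_EPS_BASAL = 1e-6
DEFAULT_T_GRID = np.arange(0.0, 31.0)  # minutes


def default_t_grid(horizon: int = 30) -> np.ndarray:
    return np.arange(0.0, float(horizon) + 0.5)


@dataclass(frozen=True)
class StimulusProtocol:
    """Ligand/OI doses applied at t = 0 and held constant thereafter."""

    ligand_dose: float = 0.0          # ug/mL
    oi_dose: float = 0.0              # uM
    scenario: str = "WT"
    t_grid: np.ndarray = field(default_factory=lambda: DEFAULT_T_GRID.copy())

    def __post_init__(self):
        if self.ligand_dose < 0 or self.oi_dose < 0:
            raise ValidationError("doses must be nonnegative")
        t = np.asarray(self.t_grid, dtype=float)
        if t.ndim != 1 or len(t) < 1 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValidationError("t_grid must be strictly increasing and start at 0")
        object.__setattr__(self, "t_grid", t)


class _Halt(Exception):
    pass


@dataclass
class TimeCourse:
    """Simulated trajectory on a reporting grid plus basal bookkeeping."""

    t: np.ndarray
    states: np.ndarray | None          # (len(t), 32); None if halted before output
    params: ParameterSet
    scenario: str
    ligand_dose: float
    oi_dose: float
    baseline: np.ndarray               # pre-equilibrated state (32,)
    completed: bool = True
    wall_time: float = 0.0

    _output_fns = {}

    def output(self, name: str) -> np.ndarray:
        """Derived output trajectory (Erkp, NFkB, IkB_nondegraded, DAG or a state)."""
        if self.states is None:
            raise SimulationHalted("time course was halted before producing output")
        return _eval_output(name, self.states, self.params)

    def basal(self, name: str) -> float:
        return float(_eval_output(name, self.baseline[None, :], self.params)[0])

    def to_frame(self, outputs=("Erkp", "NFkB", "IkB_nondegraded", "DAG")) -> pd.DataFrame:
        rows = []
        for out in outputs:
            vals = self.output(out)
            for ti, v in zip(self.t, vals):
                rows.append({"t": ti, "oi": self.oi_dose, "dose": self.ligand_dose,
                             "output": out, "value": v})
        return pd.DataFrame(rows)


def _eval_output(name: str, states: np.ndarray, params: ParameterSet) -> np.ndarray:
    if name == "Erkp":
        return states[:, STATE_INDEX["Erkp1"]] + states[:, STATE_INDEX["Erkp2"]]
    if name == "IkB_nondegraded":
        # free IkB plus IkB sequestered in the NF-kB complex (by conservation)
        return states[:, STATE_INDEX["IkB"]] + (
            params.get("NFkB_total") - states[:, STATE_INDEX["NFkB"]])
    if name in STATE_INDEX:
        return states[:, STATE_INDEX[name]]
    raise NormalizationError(f"unknown output {name!r}")


OUTPUT_NAMES = ("Erkp", "NFkB", "IkB_nondegraded", "DAG", "IKKStar")

#: downstream outputs that are structurally zero at the unstimulated steady state
DOWNSTREAM_OUTPUTS = ("Erkp", "NFkB", "DAG", "IKKStar")


def initial_state(params: ParameterSet) -> np.ndarray:
    """Fresh unstimulated state: all receptor in the free form, rest at zero."""
    y = np.zeros(N_STATES)
    y[STATE_INDEX["BCRfree"]] = params.get("BCR_total")
    return y


def run_to_steady_state(params: ParameterSet, scenario: str = "WT",
                        tol: float = 1e-10, t_max: float = 1e6,
                        ledger: ReactionLedger | None = None,
                        rtol: float = DEFAULT_RTOL,
                        atol: float = DEFAULT_ATOL) -> np.ndarray:
    """Equilibrate the unstimulated model (no ligand, no OI).

    Returns the baseline state once the sup-norm of the RHS is below ``tol``
    (a.u./min); raises :class:`NonConvergenceError` carrying the final
    residual if ``t_max`` minutes elapse first.
    """
    if ledger is None:
        ledger = assemble_model(params, scenario)
    cm = CompiledModel(ledger, params)
    cm.set_inputs(0.0, 0.0)
    y = initial_state(params)
    residual = float(np.max(np.abs(cm.rhs(0.0, y))))
    if residual <= tol:
        return y
    horizon = 100.0
    elapsed = 0.0
    while elapsed < t_max:
        span = min(horizon, t_max - elapsed)
        sol = solve_ivp(cm.rhs, (0.0, span), y, method="BDF", rtol=rtol, atol=atol)
        if not sol.success:
            raise NonConvergenceError(f"integrator failed during equilibration: {sol.message}",
                                      residual=residual)
        y = np.clip(sol.y[:, -1], 0.0, None)
        residual = float(np.max(np.abs(cm.rhs(0.0, y))))
        if residual <= tol:
            return y
        elapsed += span
        horizon *= 10.0
    raise NonConvergenceError(
        f"no steady state within t_max={t_max:g} min (residual {residual:.3e})",
        residual=residual)


def simulate_stimulation(baseline: np.ndarray, params: ParameterSet,
                         protocol: StimulusProtocol, *,
                         rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                         ledger: ReactionLedger | None = None,
                         wall_budget: float | None = None,
                         deadline: float | None = None) -> TimeCourse:
    """Integrate the model from ``baseline`` with ligand/OI applied at t = 0.

    The integration uses an adaptive implicit (BDF) method.  If
    ``wall_budget`` seconds (or an absolute ``deadline`` from
    ``time.monotonic()``) elapse first, the returned time course is flagged
    ``completed=False`` with no states.
    """
    if ledger is None:
        ledger = assemble_model(params, protocol.scenario)
    elif ledger.scenario != protocol.scenario:
        raise ValidationError("ledger scenario does not match protocol scenario")
    cm = CompiledModel(ledger, params)
    ligand = protocol.ligand_dose * params.get("ligand_scale")
    oi = protocol.oi_dose * params.get("oi_scale")
    cm.set_inputs(ligand, oi)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != (N_STATES,):
        raise DomainError(f"baseline must have shape ({N_STATES},)")

    start = time.monotonic()
    if deadline is None and wall_budget is not None:
        deadline = start + wall_budget

    if deadline is None:
        fun = cm.rhs
    else:
        def fun(t, y, _rhs=cm.rhs, _deadline=deadline):
            if time.monotonic() > _deadline:
                raise _Halt()
            return _rhs(t, y)

    t_grid = protocol.t_grid
    try:
        sol = solve_ivp(fun, (t_grid[0], t_grid[-1]), baseline, method="BDF",
                        t_eval=t_grid, rtol=rtol, atol=atol)
    except _Halt:
        return TimeCourse(t=t_grid, states=None, params=params,
                          scenario=protocol.scenario,
                          ligand_dose=protocol.ligand_dose, oi_dose=protocol.oi_dose,
                          baseline=baseline, completed=False,
                          wall_time=time.monotonic() - start)
    if not sol.success:
        raise NonConvergenceError(
            f"integrator failed at t={sol.t[-1] if len(sol.t) else 0.0:.3g} min: {sol.message}")
    return TimeCourse(t=t_grid, states=sol.y.T.copy(), params=params,
                      scenario=protocol.scenario,
                      ligand_dose=protocol.ligand_dose, oi_dose=protocol.oi_dose,
                      baseline=baseline, completed=True,
                      wall_time=time.monotonic() - start)


# --------------------------------------------------------------------------- normalization

def _t_index(tc: TimeCourse, t_obs: float) -> int:
    idx = np.nonzero(np.isclose(tc.t, t_obs))[0]
    if len(idx) == 0:
        raise NormalizationError(f"t_obs={t_obs} not on the reporting grid")
    return int(idx[0])


def normalize_relative_to_basal(tc: TimeCourse, output: str, t_obs: float,
                                eps_basal: float = DEFAULT_EPS_BASAL) -> float:
    """Output at ``t_obs`` divided by its basal value, floored at ``eps_basal``.

    The floor guards the downstream outputs whose basal value is
    structurally zero.
    """
    i = _t_index(tc, t_obs)
    basal = max(tc.basal(output), eps_basal)
    return float(tc.output(output)[i] / basal)


def normalize_relative_to_final(tc: TimeCourse, output: str, t_obs: float,
                                t_final: float) -> float:
    """Output at ``t_obs`` divided by its value at ``t_final``."""
    i = _t_index(tc, t_obs)
    j = _t_index(tc, t_final)
    vals = tc.output(output)
    if vals[j] == 0:
        raise NormalizationError(f"{output} is zero at t_final={t_final}")
    return float(vals[i] / vals[j])


def dose_response(params: ParameterSet, scenario: str, doses, oi_levels=(0.0,),
                  output: str = "Erkp", t_obs: float = 5.0,
                  normalization: str = "max_dose", *,
                  rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                  t_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Dose-response table of ``output`` at ``t_obs`` over doses x OI levels.

    ``normalization="max_dose"`` scales by the zero-OI response at the
    maximum dose (same scenario), so that curve ends at exactly 1.0;
    ``"WT_max"`` scales by the wild-type zero-OI response at the maximum
    dose; ``"none"`` returns raw values.
    """
    doses = list(doses)
    if not doses:
        raise ValidationError("dose list must be nonempty")
    if sorted(doses) != doses:
        raise ValidationError("doses must be ascending")
    if t_grid is None:
        t_grid = default_t_grid(max(30, int(np.ceil(t_obs))))

    ledger = assemble_model(params, scenario)
    baseline = run_to_steady_state(params, scenario, ledger=ledger, rtol=rtol, atol=atol)

    def response(dose, oi, scen, ledg, base):
        proto = StimulusProtocol(ligand_dose=dose, oi_dose=oi, scenario=scen, t_grid=t_grid)
        tc = simulate_stimulation(base, params, proto, rtol=rtol, atol=atol, ledger=ledg)
        return tc.output(output)[_t_index(tc, t_obs)]

    if normalization == "max_dose":
        ref = response(doses[-1], 0.0, scenario, ledger, baseline)
    elif normalization == "WT_max":
        wt_ledger = assemble_model(params, "WT")
        wt_base = run_to_steady_state(params, "WT", ledger=wt_ledger, rtol=rtol, atol=atol)
        ref = response(doses[-1], 0.0, "WT", wt_ledger, wt_base)
    elif normalization == "none":
        ref = 1.0
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    if normalization != "none" and ref <= 0:
        raise NormalizationError("reference response is zero; cannot normalize")

    rows = []
    for oi in oi_levels:
        for dose in doses:
            val = response(dose, oi, scenario, ledger, baseline) / ref
            rows.append({"dose": dose, "oi": oi, "output": output,
                         "t_obs": t_obs, "value": float(val)})
    return pd.DataFrame(rows)
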