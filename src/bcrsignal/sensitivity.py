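"""First-order (primary) Sobol sensitivity with a time-median screening rule.

The primary Sobol index of an output Y with respect to parameter p_k is

    S_k = Var(E[Y | p_k]) / Var(Y),

the fraction of output variance explained by p_k alone.  Parameters are
sampled uniformly in log10 space over a stated decade range; indices are
estimated with a Saltelli-style pick-freeze Monte-Carlo scheme (estimator
S_k ~ mean(f(B) * (f(AB_k) - f(A))) / Var(Y)), which handles vector-valued
outputs so a whole time course costs the same number of model runs as a
scalar.

For the signaling model, the screened output is the basal-normalized
readout at each integer minute of the 30-minute window; a parameter is
retained when the median of S(t) over the window is at least the screening
threshold (default 0.15).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StiffnessError, ValidationError
from .model import RATE_GROUPS, ParameterSet, assemble_model
from .nominal import nominal_parameters
from .simulate import (StimulusProtocol, default_t_grid,
                       normalize_relative_to_basal, run_to_steady_state,
                       simulate_stimulation)

SCREEN_THRESHOLD = 0.15

#: parameter groups whose members influence the unstimulated baseline
#: (the Lyn/SHP1/Csk/Cbp module is the only part active before stimulation)
BASELINE_ACTIVE_GROUPS = frozenset({3})


@dataclass
class SobolEstimate:
    """First-order indices for one sampling campaign."""

    param_names: tuple[str, ...]
    S: np.ndarray              # (n_params, n_outputs)
    n_samples: int
    seed: int | None
    n_failed: int = 0

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: self.S[i] for i, n in enumerate(self.param_names)}


@dataclass
class SensitivityResult:
    """Per-parameter sensitivity series and screening verdict."""

    name: str
    group: int
    t: np.ndarray
    S: np.ndarray              # S(t), same length as t
    median: float
    sensitive: bool
    n_samples: int
    seed: int | None


def sobol_first_order(output_fn, param_names, log_ranges, n_samples: int,
                      seed: int | None = None, *,
                      on_failure: str = "raise",
                      min_cv: float = 1e-4) -> SobolEstimate:
    """Monte-Carlo first-order Sobol indices of ``output_fn``.

    ``output_fn`` receives a dict of linear-scale parameter values (sampled
    uniformly in log10 over ``log_ranges``) and returns a scalar or a 1-D
    array; indices are computed per output component.  Outputs are centered
    by their grand mean before the pick-freeze products are formed, which
    keeps the estimator stable when the output mean dwarfs its spread.  When
    the output's coefficient of variation falls below ``min_cv`` the signal
    is below integration noise and the indices are defined as 0 (this also
    covers the exactly-constant case).  ``on_failure="mask"`` drops sample
    rows where any evaluation raised, instead of propagating.
    """
    names = tuple(param_names)
    d = len(names)
    if n_samples < 2:
        raise ValidationError("n_samples must be at least 2")
    lo = np.array([log_ranges[n][0] for n in names])
    hi = np.array([log_ranges[n][1] for n in names])
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValidationError("log ranges must be finite")
    rng = np.random.default_rng(seed)
    A = rng.uniform(lo, hi, size=(n_samples, d))
    B = rng.uniform(lo, hi, size=(n_samples, d))

    failed = np.zeros(n_samples, dtype=bool)

    def evaluate(block: np.ndarray) -> np.ndarray:
        rows = []
        for j, logs in enumerate(block):
            sample = {n: 10.0 ** v for n, v in zip(names, logs)}
            try:
                y = np.atleast_1d(np.asarray(output_fn(sample), dtype=float))
            except Exception:
                if on_failure == "raise":
                    raise
                failed[j] = True
                y = None
            rows.append(y)
        sizes = [len(r) for r in rows if r is not None]
        if not sizes:
            raise StiffnessError("every sample point failed to evaluate")
        m = sizes[0]
        return np.vstack([r if r is not None else np.full(m, np.nan) for r in rows])

    fA = evaluate(A)
    fB = evaluate(B)
    fAB = np.empty((d, n_samples, fA.shape[1]))
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fAB[i] = evaluate(ABi)

    keep = ~failed
    if not np.any(keep):
        raise StiffnessError("every sample point failed to evaluate")
    fA, fB, fAB = fA[keep], fB[keep], fAB[:, keep, :]

    pooled = np.vstack([fA, fB])
    mean = np.mean(pooled, axis=0)
    var = np.var(pooled, axis=0)
    scale = np.maximum(np.abs(mean), np.max(np.abs(pooled), axis=0))
    nz = var > (min_cv * scale) ** 2
    fA = fA - mean
    fB = fB - mean
    S = np.zeros((d, fA.shape[1]))
    for i in range(d):
        num = np.mean(fB * ((fAB[i] - mean) - fA), axis=0)
        S[i, nz] = num[nz] / var[nz]
    return SobolEstimate(param_names=names, S=S, n_samples=int(np.sum(keep)),
                         seed=seed, n_failed=int(np.sum(failed)))


def median_screen(S_series: dict[str, np.ndarray],
                  threshold: float = SCREEN_THRESHOLD) -> list[str]:
    """Parameters whose median sensitivity over time is >= ``threshold``.

    The exclusion rule is strict (< threshold), so a median exactly at the
    threshold is retained.
    """
    kept = []
    for name, series in S_series.items():
        series = np.asarray(series, dtype=float)
        if series.size == 0:
            raise ValidationError(f"empty sensitivity series for {name!r}")
        if not np.median(series) < threshold:
            kept.append(name)
    return kept


def group_members(group_id: int) -> list[str]:
    return [r for r, g in RATE_GROUPS.items() if g == group_id]


def group_sensitivity_run(params: ParameterSet | None = None, group_id: int = 1, *,
                          stimulus_dose: float = 20.0, scenario: str = "WT",
                          range_decades: float = 1.0, n_samples: int = 64,
                          seed: int | None = 0, output: str = "Erkp",
                          horizon: int = 30, eps_basal: float = 1e-6,
                          threshold: float = SCREEN_THRESHOLD,
                          rtol: float = 1e-6, atol: float = 1e-9,
                          max_failure_frac: float = 0.2) -> list[SensitivityResult]:
    """Sobol screen of one parameter group on the basal-normalized output.

    Each group member is varied +-``range_decades`` in log10 around its
    current value; the output is the stimulated ``output`` divided by its
    basal value, reported at every integer minute of the window.  If more
    than ``max_failure_frac`` of the model evaluations fail to integrate, a
    :class:`StiffnessError` is raised (the regulatory-enzyme group is prone
    to this).
    """
    if params is None:
        params = nominal_parameters()
    if not 1 <= group_id <= 7:
        raise ValidationError("group_id must be in 1..7")
    names = group_members(group_id)
    log_ranges = params.log_ranges(names, range_decades)
    t_grid = default_t_grid(horizon)

    reuse_baseline = group_id not in BASELINE_ACTIVE_GROUPS
    ledger = assemble_model(params, scenario)
    shared_baseline = (run_to_steady_state(params, scenario, ledger=ledger,
                                           rtol=rtol, atol=atol)
                       if reuse_baseline else None)

    def output_fn(sample: dict[str, float]) -> np.ndarray:
        p = params.updated(sample)
        if reuse_baseline:
            base = shared_baseline
        else:
            base = run_to_steady_state(p, scenario, rtol=rtol, atol=atol)
        proto = StimulusProtocol(ligand_dose=stimulus_dose, scenario=scenario,
                                 t_grid=t_grid)
        tc = simulate_stimulation(base, p, proto, rtol=rtol, atol=atol,
                                  ledger=assemble_model(p, scenario))
        return np.array([normalize_relative_to_basal(tc, output, t, eps_basal)
                         for t in t_grid])

    est = sobol_first_order(output_fn, names, log_ranges, n_samples, seed,
                            on_failure="mask")
    n_evals = n_samples * (len(names) + 2)
    if est.n_failed > max_failure_frac * n_samples:
        raise StiffnessError(
            f"group {group_id}: {est.n_failed}/{n_samples} sample rows failed to "
            f"integrate ({n_evals} evaluations attempted); the system is too stiff "
            "over this range")

    results = []
    for i, name in enumerate(est.param_names):
        series = est.S[i]
        med = float(np.median(series))
        results.append(SensitivityResult(
            name=name, group=group_id, t=t_grid, S=series, median=med,
            sensitive=not med < threshold, n_samples=est.n_samples, seed=seed))
    return results


def results_to_frame(results: list[SensitivityResult]):
    """Long-format table (parameter, group, t, S) for serialization."""
    import pandas as pd

    rows = []
    for r in results:
        for t, s in zip(r.t, r.S):
            rows.append({"parameter": r.name, "group": r.group, "t": t, "S": s})
    return pd.DataFrame(rows)
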