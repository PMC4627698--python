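"""Binding-rate response surfaces, power-law affinity collapse, Syk allocation.

The contour analysis varies the forward and reverse ligand-binding rates
over a product grid (evenly spaced in log10), simulates a fixed-dose
stimulation at every grid point, and maps the anergy-relevant metric

    normalized Erkp - normalized NF-kB

(each output at its readout time, divided by its maximum over the wild-type
zero-inhibitor surface).  Points whose simulation exceeds a wall-time
budget are flagged halted and filled by scattered linear interpolation over
the completed points (nearest-neighbor outside their hull).

At low reverse rates the response depends on the forward rate alone; at
high reverse rates it collapses onto a power-law affinity

    K_{a,alpha} = kf / kr**alpha,

i.e. a 1-D function of log10(kf) - alpha*log10(kr).  The collapse exponent
is estimated by scanning candidate alphas and scoring the variance
explained by the best monotone 1-D curve of the metric against
log10(K_{a,alpha}).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from sklearn.isotonic import IsotonicRegression

from .errors import DomainError, SurfaceError, ValidationError
from .model import STATE_INDEX, ParameterSet, assemble_model
from .simulate import (StimulusProtocol, default_t_grid, run_to_steady_state,
                       simulate_stimulation)


def power_law_affinity(kf, kr, alpha: float):
    """Power-law affinity K_{a,alpha} = kf / kr**alpha (alpha=1 is standard affinity)."""
    kf = np.asarray(kf, dtype=float)
    kr = np.asarray(kr, dtype=float)
    if np.any(kf <= 0) or np.any(kr <= 0):
        raise DomainError("binding rates must be strictly positive")
    out = kf / kr ** alpha
    return float(out) if out.ndim == 0 else out


@dataclass
class ResponseSurface:
    """Metric values over a log-spaced product grid of binding rates.

    ``metric``/``erkp``/``nfkb`` are (n_kr, n_kf) matrices indexed
    [i_kr, j_kf]; ``halted`` marks budget-exceeded points whose values were
    filled by interpolation.
    """

    log_kf: np.ndarray
    log_kr: np.ndarray
    erkp: np.ndarray
    nfkb: np.ndarray
    metric: np.ndarray
    halted: np.ndarray
    interpolated: np.ndarray
    scenario: str
    dose: float
    oi_dose: float
    normalizers: tuple[float, float]   # (max WT Erkp, max WT NFkB)
    t_obs: tuple[float, float]         # readout times (Erkp, NFkB)

    def points(self, mask: np.ndarray | None = None):
        """Flattened (log_kf, log_kr, metric) triples, optionally masked."""
        KF, KR = np.meshgrid(self.log_kf, self.log_kr)
        if mask is None:
            mask = np.ones_like(self.metric, dtype=bool)
        return KF[mask], KR[mask], self.metric[mask]

    def to_frame(self) -> pd.DataFrame:
        KF, KR = np.meshgrid(self.log_kf, self.log_kr)
        return pd.DataFrame({
            "log10_kf": KF.ravel(), "log10_kr": KR.ravel(),
            "erkp": self.erkp.ravel(), "nfkb": self.nfkb.ravel(),
            "metric": self.metric.ravel(),
            "halted": self.halted.ravel(), "interpolated": self.interpolated.ravel(),
        })


def evaluate_grid(params: ParameterSet, scenario: str = "WT", oi_dose: float = 0.0,
                  kf_range: tuple[float, float] = (1e-2, 1e2),
                  kr_range: tuple[float, float] = (1e-2, 1e2),
                  n_per_axis: int = 8, dose: float = 20.0, *,
                  budget_per_point: float = 30.0,
                  t_obs: tuple[float, float] = (5.0, 15.0),
                  wt_normalizers: tuple[float, float] | None = None,
                  rtol: float = 1e-6, atol: float = 1e-9) -> ResponseSurface:
    """Simulate the model over a log-spaced grid of (kf, kr) binding rates.

    Raw Erkp and NF-kB readouts are recorded per grid point; the metric is
    their difference after normalization by the maxima of the wild-type
    zero-inhibitor surface (``wt_normalizers``, computed from this surface
    when it is itself that reference).  Halted points are filled by linear
    interpolation on a triangulation of the completed points.
    """
    if n_per_axis < 2:
        raise ValidationError("n_per_axis must be at least 2")
    if min(kf_range) <= 0 or min(kr_range) <= 0:
        raise ValidationError("rate ranges must be positive")
    log_kf = np.linspace(np.log10(kf_range[0]), np.log10(kf_range[1]), n_per_axis)
    log_kr = np.linspace(np.log10(kr_range[0]), np.log10(kr_range[1]), n_per_axis)

    ledger = assemble_model(params, scenario)
    # binding rates only multiply ligand-dependent fluxes, which vanish in
    # the unstimulated model, so one baseline serves the whole grid
    baseline = run_to_steady_state(params, scenario, ledger=ledger,
                                   rtol=rtol, atol=atol)
    t_grid = default_t_grid(int(np.ceil(max(t_obs) + 0.0)) if max(t_obs) > 30 else 30)
    i_erk = int(np.argmax(np.isclose(t_grid, t_obs[0])))
    i_nfkb = int(np.argmax(np.isclose(t_grid, t_obs[1])))

    n = n_per_axis
    erkp = np.full((n, n), np.nan)
    nfkb = np.full((n, n), np.nan)
    halted = np.zeros((n, n), dtype=bool)
    for i, lkr in enumerate(log_kr):
        for j, lkf in enumerate(log_kf):
            p = params.updated({"rw0_kf": 10.0 ** lkf, "rw0_kr": 10.0 ** lkr})
            proto = StimulusProtocol(ligand_dose=dose, oi_dose=oi_dose,
                                     scenario=scenario, t_grid=t_grid)
            tc = simulate_stimulation(baseline, p, proto, rtol=rtol, atol=atol,
                                      ledger=ledger,
                                      deadline=time.monotonic() + budget_per_point)
            if not tc.completed:
                halted[i, j] = True
                continue
            erkp[i, j] = tc.output("Erkp")[i_erk]
            nfkb[i, j] = tc.output("NFkB")[i_nfkb]

    if halted.all():
        raise SurfaceError("every grid point exceeded the simulation budget")

    interpolated = halted.copy()
    if halted.any():
        KF, KR = np.meshgrid(log_kf, log_kr)
        pts = np.column_stack([KF[~halted], KR[~halted]])
        want = np.column_stack([KF[halted], KR[halted]])
        for mat in (erkp, nfkb):
            fill = griddata(pts, mat[~halted], want, method="linear")
            nearest = griddata(pts, mat[~halted], want, method="nearest")
            fill = np.where(np.isnan(fill), nearest, fill)
            mat[halted] = fill

    if wt_normalizers is None:
        if scenario != "WT" or oi_dose != 0.0:
            raise ValidationError(
                "wt_normalizers are required for non-wild-type surfaces")
        wt_normalizers = (float(np.nanmax(erkp)), float(np.nanmax(nfkb)))
    if min(wt_normalizers) <= 0:
        raise SurfaceError("wild-type normalizers must be positive")

    metric = erkp / wt_normalizers[0] - nfkb / wt_normalizers[1]
    return ResponseSurface(log_kf=log_kf, log_kr=log_kr, erkp=erkp, nfkb=nfkb,
                           metric=metric, halted=halted, interpolated=interpolated,
                           scenario=scenario, dose=dose, oi_dose=oi_dose,
                           normalizers=wt_normalizers, t_obs=t_obs)


def partition_regions(surface: ResponseSurface,
                      log10_kr_split: float = -0.5) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive masks (low-kr, high-kr) split at ``log10_kr_split``."""
    kr = surface.log_kr
    if not (kr[0] <= log10_kr_split <= kr[-1]):
        raise ValidationError(
            f"split {log10_kr_split} outside kr axis range [{kr[0]}, {kr[-1]}]")
    low_rows = kr <= log10_kr_split
    low = np.zeros_like(surface.metric, dtype=bool)
    low[low_rows, :] = True
    return low, ~low


@dataclass
class CollapseFit:
    """Profile of collapse quality over candidate exponents."""

    alpha_grid: np.ndarray
    quality: np.ndarray        # variance explained by the best monotone curve
    alpha_hat: float | None
    degenerate: bool
    fit_kind: str = "isotonic"


def _monotone_r2(u: np.ndarray, v: np.ndarray) -> float:
    order = np.argsort(u)
    u, v = u[order], v[order]
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    if ss_tot <= 0:
        return np.nan
    best = -np.inf
    for increasing in (True, False):
        fit = IsotonicRegression(increasing=increasing).fit(u, v).predict(u)
        r2 = 1.0 - float(np.sum((v - fit) ** 2)) / ss_tot
        best = max(best, r2)
    return best


def collapse_exponent(surface: ResponseSurface | None, region: np.ndarray,
                      alpha_grid=None, *, points=None) -> CollapseFit:
    """Find the exponent that best collapses the metric onto a 1-D curve.

    For each candidate alpha, the metric at the region's points is regressed
    (monotone, isotonic) against log10(kf) - alpha*log10(kr); the quality is
    the variance explained.  ``points=(log_kf, log_kr, values)`` may be
    passed instead of a surface (used for constructed ground-truth checks).
    """
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.0, 1.51, 0.05), 10)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if points is not None:
        lkf, lkr, vals = (np.asarray(a, dtype=float) for a in points)
        if region is not None:
            lkf, lkr, vals = lkf[region], lkr[region], vals[region]
    else:
        lkf, lkr, vals = surface.points(region)
    if len(vals) < 10:
        raise ValidationError("need at least 10 points to fit a collapse exponent")

    if np.ptp(vals) == 0 or np.std(vals) == 0:
        return CollapseFit(alpha_grid=alpha_grid,
                           quality=np.full(len(alpha_grid), np.nan),
                           alpha_hat=None, degenerate=True)
    quality = np.array([_monotone_r2(lkf - a * lkr, vals) for a in alpha_grid])
    return CollapseFit(alpha_grid=alpha_grid, quality=quality,
                       alpha_hat=float(alpha_grid[int(np.nanargmax(quality))]),
                       degenerate=False)


def syk_allocation(params: ParameterSet, scenario: str, oi_dose: float,
                   affinity_sweep, *, alpha: float = 0.75, kr_fixed: float | None = None,
                   dose: float = 20.0, t_read: float = 30.0,
                   rtol: float = 1e-6, atol: float = 1e-9) -> pd.DataFrame:
    """Fractions of total Syk in each form along a power-law-affinity sweep.

    The sweep realizes each affinity K_{a,alpha} with the reverse rate held
    at ``kr_fixed`` (nominal by default) and kf = K * kr**alpha.  Fractions
    of {Sykb, Syk342, Syk317, inhibited, other} are read at ``t_read``
    minutes of stimulation and sum to one by Syk conservation.
    """
    kr = kr_fixed if kr_fixed is not None else params.get("rw0_kr")
    ledger = assemble_model(params, scenario)
    baseline = run_to_steady_state(params, scenario, ledger=ledger,
                                   rtol=rtol, atol=atol)
    t_grid = default_t_grid(int(np.ceil(t_read)))
    syk_total = params.get("Syk_total")
    rows = []
    for K in affinity_sweep:
        kf = K * kr ** alpha  # inverts K_{a,alpha} = kf / kr**alpha at fixed kr
        p = params.updated({"rw0_kf": kf, "rw0_kr": kr})
        proto = StimulusProtocol(ligand_dose=dose, oi_dose=oi_dose,
                                 scenario=scenario, t_grid=t_grid)
        tc = simulate_stimulation(baseline, p, proto, rtol=rtol, atol=atol,
                                  ledger=ledger)
        s = tc.states[int(np.argmax(np.isclose(t_grid, t_read)))]
        sykb = s[STATE_INDEX["Sykb"]] / syk_total
        syk342 = s[STATE_INDEX["Syk342"]] / syk_total
        syk317 = s[STATE_INDEX["Syk317"]] / syk_total
        inhibited = s[STATE_INDEX["Syk_inh"]] / syk_total
        rows.append({"K_a_alpha": K, "kf": kf, "kr": kr,
                     "Sykb": sykb, "Syk342": syk342, "Syk317": syk317,
                     "inhibited": inhibited,
                     "other": 1.0 - (sykb + syk342 + syk317 + inhibited)})
    return pd.DataFrame(rows)


def amplification(tc_wt, tc_mut, output: str, t_obs: float) -> float:
    """Signal amplification of ``output`` relative to DAG between scenarios.

    Computed as [(out_WT - out_mut)/out_WT] / [(DAG_WT - DAG_mut)/DAG_WT] at
    ``t_obs``: the fractional response change normalized by the fractional
    change of DAG, the last species feeding both readout pathways.
    """
    if not np.allclose(tc_wt.t, tc_mut.t):
        raise ValidationError("time courses must share a reporting grid")
    i = int(np.argmax(np.isclose(tc_wt.t, t_obs)))
    if not np.isclose(tc_wt.t[i], t_obs):
        raise ValidationError(f"t_obs={t_obs} not on the reporting grid")
    out_wt = tc_wt.output(output)[i]
    dag_wt = tc_wt.output("DAG")[i]
    if out_wt == 0 or dag_wt == 0:
        raise DomainError("wild-type output/DAG is zero; amplification undefined")
    dag_drop = (dag_wt - tc_mut.output("DAG")[i]) / dag_wt
    if dag_drop == 0:
        raise DomainError("DAG is unchanged; amplification undefined")
    out_drop = (out_wt - tc_mut.output(output)[i]) / out_wt
    return float(out_drop / dag_drop)
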