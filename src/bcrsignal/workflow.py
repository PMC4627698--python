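"""End-to-end workflow orchestration over the five pipeline stages.

Stages run in a fixed order (synthesize -> sensitivity -> screen ->
dose_response -> contour); each writes delimited-text/JSON artifacts into
the configured output directory and records their content hashes in a
manifest, so a rerun with the same config and seed reproduces the same
manifest byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, stage_seed
from .errors import ConfigurationError, DependencyError
from .model import ParameterSet
from .nominal import SENSITIVE_PARAMETERS
from .screening import lhs_sample, read_observations, screen, write_observations
from .sensitivity import group_sensitivity_run, results_to_frame
from .simulate import dose_response
from .surface import collapse_exponent, evaluate_grid, partition_regions
from .synthetic import SyntheticDatasetSpec, generate

log = logging.getLogger("bcrsignal.workflow")

STAGE_ORDER = ("synthesize", "sensitivity", "screen", "dose_response", "contour")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=float))


def _data_path(config: RunConfig, outdir: Path) -> Path:
    if config.data_path:
        return Path(config.data_path)
    return outdir / "synthetic_observations.tsv"


# --------------------------------------------------------------------------- stages

def _stage_synthesize(config: RunConfig, params: ParameterSet, outdir: Path) -> list[Path]:
    seed = stage_seed(config.seed, "synthesize")
    rng = np.random.default_rng(seed)
    names = SENSITIVE_PARAMETERS
    offsets = {n: float(rng.uniform(-config.synthetic.perturbation_decades,
                                    config.synthetic.perturbation_decades))
               for n in names}
    theta = params.updated({n: params.get(n) * 10.0 ** o for n, o in offsets.items()},
                           note="workflow generating vector")
    spec = SyntheticDatasetSpec(shape=config.synthetic.shape,
                                theta_star=theta,
                                noise=config.synthetic.noise,
                                replicates=config.synthetic.replicates,
                                seed=seed)
    table = generate(spec, eps_basal=config.simulate.eps_basal,
                     rtol=config.screening.rtol, atol=config.screening.atol)
    data_file = _data_path(config, outdir)
    write_observations(table, data_file)
    meta = outdir / "synthetic_meta.json"
    _write_json(meta, {"seed": seed, "shape": spec.shape, "offsets": offsets})
    return [data_file, meta]


def _stage_sensitivity(config: RunConfig, params: ParameterSet, outdir: Path) -> list[Path]:
    seed = stage_seed(config.seed, "sensitivity")
    results = group_sensitivity_run(
        params, config.sensitivity.group,
        stimulus_dose=config.sensitivity.stimulus_dose,
        scenario=config.scenario,
        range_decades=config.sensitivity.range_decades,
        n_samples=config.sensitivity.n_samples, seed=seed,
        horizon=config.simulate.horizon, eps_basal=config.simulate.eps_basal)
    tsv = outdir / "sensitivity.tsv"
    results_to_frame(results).to_csv(tsv, sep="\t", index=False)
    summary = outdir / "sensitivity_summary.json"
    _write_json(summary, {r.name: {"group": r.group, "median": r.median,
                                   "sensitive": bool(r.sensitive)}
                          for r in results})
    return [tsv, summary]


def _stage_screen(config: RunConfig, params: ParameterSet, outdir: Path) -> list[Path]:
    data_file = _data_path(config, outdir)
    if not data_file.exists():
        raise DependencyError(
            f"screen stage needs observations at {data_file}; run synthesize first "
            "or set data_path")
    data = read_observations(data_file)
    seed = stage_seed(config.seed, "screen")
    names = SENSITIVE_PARAMETERS
    candidates = lhs_sample(
        names, {n: (-config.screening.decades, config.screening.decades) for n in names},
        config.screening.n_candidates, seed=seed)
    result = screen(candidates, data, params, config.scenario,
                    thresholds=config.screening.thresholds,
                    eta_default=config.screening.eta_default,
                    eps_basal=config.simulate.eps_basal,
                    rtol=config.screening.rtol, atol=config.screening.atol,
                    budget_per_candidate=config.screening.budget_per_candidate,
                    seed=seed)
    cand_file = outdir / "screen_candidates.tsv"
    result.candidates.to_csv(cand_file, sep="\t", index=False)
    table_file = outdir / "screen_results.tsv"
    result.table.to_csv(table_file, sep="\t", index=False)
    summary = outdir / "screen_summary.json"
    _write_json(summary, {"seed": seed, "n_candidates": len(result.candidates),
                          "n_accepted": int(result.accepted.sum()),
                          "acceptance_rate": result.acceptance_rate,
                          "thresholds": result.thresholds})
    return [cand_file, table_file, summary]


def _stage_dose_response(config: RunConfig, params: ParameterSet, outdir: Path) -> list[Path]:
    sim = config.simulate
    frames = []
    for output, t_obs in (("Erkp", sim.t_obs_erkp), ("NFkB", sim.t_obs_ikb)):
        df = dose_response(params, config.scenario, sim.doses,
                           oi_levels=sim.oi_levels, output=output, t_obs=t_obs,
                           normalization="max_dose", rtol=sim.rtol, atol=sim.atol)
        frames.append(df)
    out = outdir / "dose_response.tsv"
    pd.concat(frames, ignore_index=True).to_csv(out, sep="\t", index=False)
    return [out]


def _stage_contour(config: RunConfig, params: ParameterSet, outdir: Path) -> list[Path]:
    ct = config.contour
    wt = evaluate_grid(params, "WT", 0.0,
                       kf_range=(10.0 ** ct.log_kf[0], 10.0 ** ct.log_kf[1]),
                       kr_range=(10.0 ** ct.log_kr[0], 10.0 ** ct.log_kr[1]),
                       n_per_axis=ct.n_per_axis, dose=ct.dose,
                       budget_per_point=ct.budget_per_point,
                       t_obs=(config.simulate.t_obs_erkp, config.simulate.t_obs_ikb))
    surf = wt
    if config.scenario != "WT" or ct.oi_dose > 0:
        surf = evaluate_grid(params, config.scenario, ct.oi_dose,
                             kf_range=(10.0 ** ct.log_kf[0], 10.0 ** ct.log_kf[1]),
                             kr_range=(10.0 ** ct.log_kr[0], 10.0 ** ct.log_kr[1]),
                             n_per_axis=ct.n_per_axis, dose=ct.dose,
                             budget_per_point=ct.budget_per_point,
                             t_obs=(config.simulate.t_obs_erkp, config.simulate.t_obs_ikb),
                             wt_normalizers=wt.normalizers)
    grid_file = outdir / "contour_grid.tsv"
    surf.to_frame().to_csv(grid_file, sep="\t", index=False)
    summary: dict = {"scenario": surf.scenario, "oi_dose": surf.oi_dose,
                     "normalizers": list(surf.normalizers),
                     "halted_fraction": float(surf.halted.mean())}
    try:
        _, high = partition_regions(surf, ct.log10_kr_split)
        fit = collapse_exponent(surf, high)
        summary["alpha_hat"] = fit.alpha_hat
        summary["alpha_profile"] = {f"{a:.2f}": (None if np.isnan(q) else float(q))
                                    for a, q in zip(fit.alpha_grid, fit.quality)}
        summary["degenerate"] = fit.degenerate
    except Exception as exc:  # too few points on a tiny grid is not fatal
        summary["alpha_hat"] = None
        summary["collapse_error"] = f"{type(exc).__name__}: {exc}"
    summary_file = outdir / "contour_summary.json"
    _write_json(summary_file, summary)
    return [grid_file, summary_file]


_STAGES = {
    "synthesize": _stage_synthesize,
    "sensitivity": _stage_sensitivity,
    "screen": _stage_screen,
    "dose_response": _stage_dose_response,
    "contour": _stage_contour,
}


def run_workflow(config: RunConfig, stages=()) -> dict:
    """Execute the requested stages in pipeline order and write a manifest.

    Returns the manifest: per stage, the artifact paths and their sha256
    content hashes.  Rerunning with the same config and seed produces an
    identical manifest.  An empty stage list succeeds with an empty
    manifest.
    """
    stages = list(stages)
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stage(s) {unknown}; valid: {STAGE_ORDER}")
    ordered = [s for s in STAGE_ORDER if s in stages]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.parameters()

    manifest: dict = {"seed": config.seed, "stages": {}}
    for stage in ordered:
        log.info("running stage %s", stage)
        files = _STAGES[stage](config, params, outdir)
        manifest["stages"][stage] = {
            str(f.relative_to(outdir) if f.is_relative_to(outdir) else f): _sha256(f)
            for f in files}
    _write_json(outdir / "manifest.json", manifest)
    return manifest
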