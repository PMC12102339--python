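"""End-to-end pipeline: twin construction, calibration, prediction,
risk accounting and regimen optimization.

The first two imaging visits calibrate the digital state; the third is
held out and predicted.  All stages are deterministic given the config
seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .calibrate import (
    PatientData,
    abc_rejection,
    abc_smc,
    default_priors,
    epsilon_floor,
    lm_fit,
    posterior_predict,
)
from .config import RunConfig
from .control import OCProblem, optimize
from .forward import assign_auc_maps
from .grids import VoxelGrid, adc_to_cellularity
from .regimen import RegimenWindow, TreatmentRegimen, canonicalize
from .risk import compare_risk, risk_profile
from .rom import ReducedModel, build_snapshots, pod_basis, project_operators, reduce_proliferation

log = logging.getLogger("tumortwin")


def build_reduced_model(
    grid: VoxelGrid,
    theta_cap: float,
    n_v1: np.ndarray,
    n_v2: np.ndarray,
    auc_maps: list[np.ndarray],
    visit_days: tuple[float, float],
    energy: float = 0.995,
    n_pseudo: int = 8,
    smoothing_widths: tuple[float, ...] = (1.0, 2.0),
    kl_n_mc: int = 200,
    seed: int = 0,
) -> ReducedModel:
    """Snapshots -> POD basis -> KL proliferation map -> projected operators."""
    snaps = build_snapshots(n_v1, n_v2, grid, visit_days, n_pseudo, smoothing_widths)
    basis = pod_basis(snaps, energy)
    k_map = reduce_proliferation(basis, n_mc=kl_n_mc, seed=seed)
    rom = project_operators(grid, basis, auc_maps, theta_cap, k_map)
    log.info("ROM built: rank %d (%.4f energy) on %d voxels", rom.rank, basis.energy, grid.n_masked)
    return rom


def calibrate_twin(
    rom: ReducedModel,
    data: PatientData,
    config: RunConfig | None = None,
) -> tuple:
    """LM tolerance fit followed by ABC; returns (ensemble, theta_LM, epsilon)."""
    cfg = config or RunConfig()
    priors = default_priors(rom.k_map)
    theta_lm, eps_lm, converged = lm_fit(rom, data, priors, n_starts=cfg.lm_starts, seed=cfg.seed)
    if not converged:
        log.warning("least-squares tolerance fit did not fully converge; using best iterate")
    epsilon = max(eps_lm, epsilon_floor(data, cfg.epsilon_floor_frac))
    log.info("tolerance epsilon = %.4g (LM fit %.4g, floor applied: %s)", epsilon, eps_lm, epsilon > eps_lm)
    sampler = abc_smc if cfg.abc_mode == "smc" else abc_rejection
    kwargs = dict(n_accept=cfg.ensemble_size, seed=cfg.seed)
    if cfg.abc_mode == "rejection":
        kwargs.update(max_attempts=cfg.abc_max_attempts, rate_floor=cfg.abc_rate_floor)
    ensemble = sampler(rom, data, priors, epsilon, **kwargs)
    log.info("ABC accepted %d samples in %d attempts", len(ensemble), ensemble.attempts)
    return ensemble, theta_lm, epsilon


def load_patient_data(patient: io.PatientDir):
    """Build grid, reduced-space calibration inputs and regimen from disk."""
    grid = patient.grid()
    theta = patient.theta_cap
    adc_w, adc_min = patient.meta["adc_w"], patient.meta["adc_min"]
    visits = sorted(patient.visit_days, key=patient.visit_days.get)
    cellularity = {
        v: adc_to_cellularity(patient.adc(v), grid.tumor_masks[v], adc_w, adc_min, theta)
        for v in visits
    }
    auc = [grid.flatten(patient.auc(v)) for v in visits]
    regimen = canonicalize(patient.regimen())
    return grid, theta, cellularity, auc, regimen, visits


def run_pipeline(config: RunConfig) -> dict:
    """Calibrate, predict the held-out visit, score risk, optimize.

    Writes every artifact (ROM, ensemble, predictions, risk report,
    optimized regimens) under ``config.output_dir`` and returns them
    in memory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    patient = io.PatientDir(config.patient_dir)
    grid, theta, cellularity, auc, regimen, visits = load_patient_data(patient)
    v1, v2, v3 = visits[:3]
    days = patient.visit_days

    n_v1 = grid.flatten(cellularity[v1]) / theta
    n_v2 = grid.flatten(cellularity[v2]) / theta
    rom = build_reduced_model(
        grid, theta, n_v1, n_v2, auc, (days[v1], days[v2]),
        energy=config.pod_energy, n_pseudo=config.n_pseudo,
        smoothing_widths=config.smoothing_widths, kl_n_mc=config.kl_n_mc, seed=config.seed,
    )
    io.save_rom(out / "rom.h5", rom)

    data = PatientData(
        u0=rom.reduce(n_v1),
        data_v2=rom.reduce(n_v2),
        visit_days=(days[v1], days[v2]),
        regimen=regimen,
        auc_assign=assign_auc_maps(regimen, days),
    )
    ensemble, theta_lm, epsilon = calibrate_twin(rom, data, config)
    io.save_ensemble(out / "ensemble.h5", ensemble)

    # predict through the held-out visit
    pred = posterior_predict(rom, ensemble, regimen, data.auc_assign, data.u0, (days[v1], days[v3]))
    pd.DataFrame({
        "time": pred.times,
        "cells_median": pred.cells_median,
        "cells_q1": pred.cells_iqr[0],
        "cells_q3": pred.cells_iqr[1],
        "volume_median": pred.volumes_median,
        "volume_q1": pred.volumes_iqr[0],
        "volume_q3": pred.volumes_iqr[1],
    }).to_csv(out / "prediction.csv", index=False)

    soc_risk = risk_profile(regimen, ensemble.beta, name="soc")
    results = {"rom": rom, "ensemble": ensemble, "epsilon": epsilon, "prediction": pred, "soc_risk": soc_risk}

    # optimization window from the delivered last two cycles
    tau = regimen.times["A"]
    window = RegimenWindow(tau3=float(tau[2]), tau4=float(tau[3]))
    first_two = (float(tau[0]), float(tau[1]))
    opt_results = {}
    for kind in config.problems:
        problem = OCProblem(
            kind=kind, rom=rom, ensemble=ensemble, u0=data.u0, window=window,
            first_two_days=first_two, visit_days=days, t_start=days[v1],
            subsample=config.subsample, subsample_seed=config.seed,
            constraint_tol=config.constraint_tol, cobyla_maxiter=config.cobyla_maxiter,
        )
        res = optimize(problem, seed=config.seed, n_hops=config.n_hops)
        opt_results[kind] = res
        (out / f"regimen_{kind}.json").write_text(res.best_regimen.to_json())
        opt_risk = res.comparison["_distributions"]["optimized"]["risk"]
        summary = {
            "objective": res.objective,
            "soc_objective": res.soc_objective,
            "feasible": res.feasible,
            "constraints": res.constraints,
            "comparison": {
                k: v for k, v in res.comparison.items() if k != "_distributions"
            },
            "risk_vs_soc": compare_risk(soc_risk, opt_risk),
        }
        (out / f"optimization_{kind}.json").write_text(json.dumps(summary, indent=2, default=float))
    results["optimization"] = opt_results
    log.info("pipeline complete; artifacts in %s", out)
    return results
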