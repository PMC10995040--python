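"""End-to-end pipeline: patient record → waveforms → hyperemic FFR and MBF.

Stages, in order: derive the waveform parameters from the resting record;
build the aortic and effective pressure curves; map the record to the
hyperemic state; calibrate the microvascular conductances at rest against
the population inflow target (resting tree, time-averaged resting
effective pressure); dilate the tree and quadruple the conductances for
hyperemia; simulate one hyperemic beat of the coupled tree/Darcy system;
report landmark FFR and mean MBF.  All intermediate artifacts are written
to the output directory and the run is deterministic for a fixed config
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .errors import ValidationError
from .hyperemia import StressMapCoefficients, rest_to_stress
from .patient import PatientRecord, derive_all
from .perfusion import DarcyGrid, DarcyParams, calibrate_rest, scale_to_stress, solve_darcy
from .tree import (
    CoronaryTree,
    PerfusionContext,
    TreeSupply,
    assign_territories,
    compute_ffr,
    default_tree,
    dilate,
    find_peak_diastolic_time,
    run_beat,
)
from .waveform import build_aortic_waveform, build_effective_waveform

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs."""

    patient: PatientRecord
    out_dir: Path
    state: str = "stress"
    dt: float = 1e-3
    grid: DarcyGrid = field(default_factory=lambda: DarcyGrid(20, 20, 10, 2e-3))
    params: DarcyParams = field(default_factory=DarcyParams)
    tree: CoronaryTree = field(default_factory=default_tree)
    coeffs: StressMapCoefficients = field(default_factory=StressMapCoefficients.default)
    target_inflow: float = 1.0  # mL/min/g at rest
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.target_inflow <= 0:
            raise ValidationError("dt and target_inflow must be positive")
        if self.state not in ("rest", "stress"):
            raise ValidationError(f"state must be 'rest' or 'stress', got {self.state!r}")

    def hash(self) -> str:
        return io.config_hash(
            {
                "patient": self.patient.__dict__,
                "state": self.state,
                "dt": self.dt,
                "grid": (self.grid.nx, self.grid.ny, self.grid.nz, self.grid.h, self.grid.density),
                "params": self.params.__dict__,
                "tree": [s.__dict__ for s in self.tree.segments],
                "stenoses": [s.__dict__ for s in self.tree.stenoses],
                "coeffs": self.coeffs.as_dict(),
                "target_inflow": self.target_inflow,
                "seed": self.seed,
            }
        )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and return (and write) the JSON summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    seed = config.seed

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"pipeline stage '{name}' failed: {exc}") from exc

    rest = config.patient
    if rest.state != "rest":
        raise ValidationError("pipeline expects a resting patient record as input")
    io.write_patient(rest, out / "patient_rest.json", h, seed)

    # rest waveforms
    timings_r, pressures_r = _stage("derive_all(rest)", derive_all, rest)
    par_r = _stage("build_aortic(rest)", build_aortic_waveform, timings_r, pressures_r)
    peff_r = _stage("build_effective(rest)", build_effective_waveform, par_r, timings_r)
    for name, curve in (("par_rest", par_r), ("peff_rest", peff_r)):
        t, p = curve.sample(config.dt)
        io.write_series_csv(out / f"{name}.csv", t, p, h, seed)

    # hyperemic record and waveforms
    stress = _stage("rest_to_stress", rest_to_stress, rest, config.coeffs)
    io.write_patient(stress, out / "patient_stress.json", h, seed)
    timings_s, pressures_s = _stage("derive_all(stress)", derive_all, stress)
    par_s = _stage("build_aortic(stress)", build_aortic_waveform, timings_s, pressures_s)
    peff_s = _stage("build_effective(stress)", build_effective_waveform, par_s, timings_s)
    for name, curve in (("par_stress", par_s), ("peff_stress", peff_s)):
        t, p = curve.sample(config.dt)
        io.write_series_csv(out / f"{name}.csv", t, p, h, seed)

    # resting "blinded" calibration of the microvascular conductances
    territories = assign_territories(config.grid)
    supply = TreeSupply(
        tree=config.tree, inlet_pressure=peff_r.mean(), territory_field=territories
    )
    cal = _stage(
        "calibrate_rest",
        calibrate_rest,
        config.grid,
        config.params,
        supply,
        target_inflow=config.target_inflow,
    )
    io.write_json(
        out / "calibration.json",
        {
            "lambda": cal.lam,
            "achieved_inflow_ml_min_g": cal.achieved_inflow,
            "target_inflow_ml_min_g": cal.target_inflow,
            "n_evaluations": len(cal.iterations),
        },
        h,
        seed,
    )

    # hyperemic configuration and one coupled beat
    if config.state == "stress":
        beat_tree = _stage("dilate", dilate, config.tree)
        beat_params = _stage("scale_to_stress", scale_to_stress, cal.params)
        peff, timings = peff_s, timings_s
        hr = stress.HR
    else:
        beat_tree, beat_params, peff, timings, hr = config.tree, cal.params, peff_r, timings_r, rest.HR
    ctx = PerfusionContext(grid=config.grid, params=beat_params, territory_field=territories)
    solution = _stage("run_beat", run_beat, beat_tree, peff, ctx, dt=config.dt)

    t_star = find_peak_diastolic_time(peff, timings)
    ffr = _stage("compute_ffr", compute_ffr, solution, t_star)
    io.write_json(
        out / "ffr.json",
        {"t_eval_s": ffr.t_eval, "landmarks": ffr.landmarks, "nodes": ffr.node_ffr},
        h,
        seed,
    )

    # beat-averaged Darcy state for the field output
    q_mean = {t: float(np.mean(solution.territory_outflow[t])) for t in solution.territory_outflow}
    g_avg = np.zeros(config.grid.shape)
    for terr, q in q_mean.items():
        mask = territories == terr
        g_avg += np.where(mask, q / (mask.sum() * config.grid.cell_volume), 0.0)
    state_avg = solve_darcy(config.grid, beat_params, g_avg)
    io.write_darcy_csv(out / "darcy_beat_avg.csv", state_avg, h, seed)

    inflow_ml_per_beat = solution.per_beat_inflow_ml()
    summary = {
        "state": config.state,
        "calibration_lambda": cal.lam,
        "rest_inflow_ml_min_g": cal.achieved_inflow,
        "landmark_ffr": ffr.landmarks,
        "ffr_time_s": ffr.t_eval,
        "mean_mbf_ml_min_100g": solution.mean_mbf,
        "per_beat_inflow_ml": inflow_ml_per_beat,
        "total_inflow_ml_min": inflow_ml_per_beat * hr,
        "diastolic_flow_fraction_left": solution.diastolic_flow_fraction("left"),
    }
    io.write_json(out / "summary.json", summary, h, seed)
    return summary
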