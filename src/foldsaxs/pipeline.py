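"""Config-driven orchestration of the full degree-of-folding workflow.

Stages, in order: (1) identify accessible conformational states from the
trajectory's interval-averaged Rg; (2) compute a theoretical SAXS profile
for each state ensemble; (3) fit the weighted combination of those profiles
to the experimental curve. Every stage writes its table/curve into the run
directory together with a manifest echoing the configuration and seed, so a
rerun on identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import analysis, geometry, io, populations, saxs, states
from .models import FoldsaxsError, ScatteringCurve, ValidationError

__all__ = ["RunConfig", "run_protocol", "report_degree_of_folding"]

logger = logging.getLogger("foldsaxs")


@dataclass
class RunConfig:
    """All knobs of one protocol run.

    Defaults follow the protocol constants where one exists: 1 ns intervals,
    500 orientational q-vectors, 334 e/nm³ solvent electron density.
    """

    topology: str = ""
    trajectory: str = ""
    experimental_curve: str = ""
    frame_time_step: float = 0.1  # ns
    interval_length: float = 1.0  # ns
    rg_weighting: str = "mass"
    threshold_nm: Optional[float] = None  # None -> auto (2-means midpoint)
    q_max: Optional[float] = None  # Å⁻¹, e.g. 0.4
    method: str = "debye"  # {"debye", "mc"}
    n_vectors: int = saxs.DEFAULT_N_VECTORS
    solvent_mode: str = "vacuum"  # {"vacuum", "excluded_volume"}
    electron_density: float = saxs.WATER_ELECTRON_DENSITY  # e/nm³
    stride: int = 1
    fit_background: bool = False
    bootstrap_n: int = 0  # 0 disables the bootstrap
    qrg_limit: float = 1.3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for label, path in (
            ("topology", self.topology),
            ("trajectory", self.trajectory),
            ("experimental_curve", self.experimental_curve),
        ):
            if not path:
                raise ValidationError(f"config field {label!r} is required")
            if not os.path.exists(path):
                raise ValidationError(f"{label} file not found: {path}")
        if self.interval_length < self.frame_time_step:
            raise ValidationError("interval_length must be >= frame_time_step")


def _write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_degree_of_folding(result: populations.PopulationFitResult) -> dict:
    """Human-readable summary: populations as whole percents, raw weights kept."""
    def pct(w: float) -> str:  # nearest integer percent, halves round up
        return f"{int(np.floor(100.0 * w + 0.5))}%"

    percents = {name: pct(float(w)) for name, w in zip(result.state_names, result.weights)}
    return {
        "degree_of_folding": percents.get("fc", pct(result.degree_of_folding)),
        "populations_percent": percents,
        "raw": result.as_dict(),
    }


def run_protocol(config: RunConfig, out_dir: str) -> dict:
    """Execute stages (1)–(3) and write all tables/curves into ``out_dir``.

    Returns the final report dict (also written as ``report.json``). Stage
    failures are re-raised with the stage name; partial outputs are kept.
    """
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    _write_json({"config": asdict(config)}, os.path.join(out_dir, "manifest.json"))
    stage = "load-inputs"
    try:
        traj = io.read_trajectory(
            config.topology, config.trajectory, frame_time_step=config.frame_time_step
        )
        experimental = io.read_scattering_curve(config.experimental_curve)

        stage = "state-assignment"
        rg = geometry.rg_series(traj, config.rg_weighting)
        np.savetxt(
            os.path.join(out_dir, "rg_series.dat"),
            np.column_stack([np.arange(len(rg)) * config.frame_time_step, rg.values]),
            header="time[ns]  Rg[nm]",
            fmt="%.6f",
        )
        intervals = states.partition_intervals(rg, config.frame_time_step, config.interval_length)
        if config.threshold_nm is None:
            auto = states.auto_threshold([iv.mean_rg for iv in intervals])
            threshold = auto.threshold
            logger.info(
                "auto threshold %.4f nm (centroids %.4f/%.4f, bimodality %.2f)",
                threshold, *auto.centroids, auto.bimodality,
            )
        else:
            threshold = config.threshold_nm
        assignment = states.assign_states(intervals, threshold, config.interval_length)
        states.export_assignment_table(
            assignment, config.frame_time_step, os.path.join(out_dir, "state_assignment.dat")
        )
        md_fraction = states.md_folded_fraction(assignment)

        stage = "experimental-analysis"
        guinier = analysis.guinier_fit(experimental, qrg_limit=config.qrg_limit)
        io.write_scattering_curve(
            analysis.kratky_transform(experimental), os.path.join(out_dir, "kratky_exp.dat")
        )

        stage = "forward-prediction"
        exp_fit = (
            populations.truncate_q_range(experimental, config.q_max)
            if config.q_max is not None
            else experimental
        )
        table = saxs.load_default_table()
        solvent = saxs.SolventModel(config.electron_density, config.solvent_mode)
        state_curves: dict[str, ScatteringCurve] = {}
        for state in (states.FOLDED, states.UNFOLDED):
            ensemble = states.concatenate_state_frames(traj, assignment, state)
            curve = saxs.ensemble_intensity(
                ensemble,
                exp_fit.q,
                table,
                solvent,
                method=config.method,
                stride=config.stride,
                n_vectors=config.n_vectors,
                seed=config.seed + 1,
            )
            state_curves[state] = curve
            io.write_scattering_curve(curve, os.path.join(out_dir, f"predicted_{state}.dat"))
            io.write_scattering_curve(
                analysis.kratky_transform(curve), os.path.join(out_dir, f"kratky_{state}.dat")
            )

        stage = "population-fit"
        result = populations.fit_populations(
            exp_fit, state_curves, q_max=None, fit_background=config.fit_background
        )
        if config.bootstrap_n >= 10:
            populations.fold_fraction_uncertainty(
                result, exp_fit, state_curves, n_boot=config.bootstrap_n, seed=config.seed + 2
            )
    except FoldsaxsError as err:
        raise type(err)(f"[stage {stage}] {err}") from err

    report = {
        "seed": config.seed,
        "n_frames": traj.n_frames,
        "n_intervals": len(assignment.intervals),
        "threshold_nm": threshold,
        "md_folded_fraction": md_fraction,
        "guinier": {
            "rg_A": guinier.rg,
            "i0": guinier.i0,
            "q_range": list(guinier.q_range_used),
            "fit_points": guinier.fit_points,
            "r_squared": guinier.r_squared,
        },
        "fit": report_degree_of_folding(result),
    }
    _write_json(report, os.path.join(out_dir, "report.json"))
    return report
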