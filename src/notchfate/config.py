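"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` (YAML or JSON document) fully determines a run:
parameter/wiring files, protocol, solver options, feature thresholds and
analysis settings.  ``run_pipeline`` executes the requested stages and
writes a manifest (inputs, outputs, hashes, wall-clock) so a run can be
reproduced bit-for-bit from its config echo.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CostSettings, calibrate
from .experiments import (
    delta_duration_battery,
    pair_scan,
    pulse_battery,
    run_baseline,
    single_parameter_scan,
)
from .features import oscillation_features
from .model import DeltaNotchModel
from .parameters import ParameterSet, table2_parameters
from .protocols import Protocol
from .sensitivity import dgsm
from .simulation import SolverOptions
from .wiring import Wiring, default_wiring

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "calibrate", "gsa", "experiments")


@dataclass
class RunConfig:
    parameters: str | None = None  # path; None = packaged calibrated optimum
    wiring: str | None = None  # path; None = packaged default
    protocol: dict = field(default_factory=dict)
    horizon: float = 3000.0
    solver: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)  # eps_amp, theta_low, prominence
    calibration: dict = field(default_factory=dict)  # m, skip, span, target_period...
    gsa: dict = field(default_factory=dict)  # n_samples, fd_step, cutoff, ...
    experiments: dict = field(default_factory=dict)  # batteries: [delta, pulse, ...]
    out_dir: str = "notchfate_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    # ---- factories ----

    def parameter_set(self) -> ParameterSet:
        return ParameterSet.load(self.parameters) if self.parameters else table2_parameters()

    def wiring_obj(self) -> Wiring:
        return Wiring.load(self.wiring) if self.wiring else default_wiring()

    def solver_options(self) -> SolverOptions:
        return SolverOptions(**self.solver) if self.solver else SolverOptions()

    def model(self) -> DeltaNotchModel:
        return DeltaNotchModel(
            params=self.parameter_set(),
            wiring=self.wiring_obj(),
            options=self.solver_options(),
        )

    def protocol_obj(self) -> Protocol:
        return Protocol.from_dict(self.protocol) if self.protocol else Protocol()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, default=str))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, stages: tuple[str, ...]) -> dict:
    """Execute the requested stages in canonical order; returns (and
    writes) the manifest."""
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; expected subset of {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": list(stages),
        "artefacts": {},
        "complete": False,
    }
    model = config.model()
    t0 = time.time()
    try:
        if "simulate" in stages:
            traj = model.simulate(config.horizon, protocol=config.protocol_obj())
            traj_path = out / "trajectory.csv"
            traj.save(traj_path)
            w = (max(0.0, config.horizon - 1000.0), config.horizon)
            feats = {
                sp: oscillation_features(traj, sp, w).to_dict()
                for sp in ("hes1_prot_nuc", "mash1_prot_nuc", "hes6_prot_nuc")
            }
            _write_json(out / "features.json", feats)
            manifest["artefacts"]["trajectory"] = {
                "path": str(traj_path),
                "sha": _hash_file(traj_path),
            }
            manifest["artefacts"]["features"] = {"path": str(out / "features.json")}
        if "calibrate" in stages:
            cal_kwargs = dict(config.calibration)
            m = int(cal_kwargs.pop("m", 10))
            skip = int(cal_kwargs.pop("skip", 1))
            span = float(cal_kwargs.pop("span", 0.9))
            settings = CostSettings(**cal_kwargs) if cal_kwargs else CostSettings()
            res = calibrate(
                model.parameter_space(span), m=m, skip=skip, settings=settings,
                wiring=model.wiring,
            )
            res.best_params.save(out / "best_parameters.json")
            res.table.to_csv(out / "calibration_evaluations.csv", index=False)
            import pandas as pd

            pd.DataFrame(
                {"evaluation": range(1, res.n_evaluations + 1), "running_min": res.running_min}
            ).to_csv(out / "calibration_convergence.csv", index=False)
            manifest["artefacts"]["calibration"] = {
                "best_cost": res.best_cost,
                "best_index": res.best_index,
                "evaluations": res.n_evaluations,
            }
        if "gsa" in stages:
            gsa_kwargs = dict(config.gsa)
            cutoff = float(gsa_kwargs.pop("cutoff", 0.1))
            res = dgsm(model.parameter_space(), wiring=model.wiring, **gsa_kwargs)
            res.indices.to_csv(out / "gsa_indices.csv")
            _write_json(out / "gsa_significant.json", res.significant(cutoff))
            manifest["artefacts"]["gsa"] = {
                "significant": res.significant(cutoff),
                "n_samples": res.n_samples,
            }
        if "experiments" in stages:
            batteries = config.experiments.get("batteries", ["delta", "pulse", "single", "pairs"])
            baseline = run_baseline(model)
            results: dict = {}
            if "delta" in batteries:
                results["delta"] = [o.to_dict() for o in delta_duration_battery(model, baseline=baseline)]
            if "pulse" in batteries:
                results["pulse"] = [o.to_dict() for o in pulse_battery(model, baseline=baseline)]
            if "single" in batteries:
                results["single"] = [o.to_dict() for o in single_parameter_scan(model, baseline=baseline)]
            if "pairs" in batteries:
                outs, potent = pair_scan(model, baseline=baseline)
                results["pairs"] = [o.to_dict() for o in outs]
                results["potent_pairs"] = {str(k): v for k, v in potent.items()}
            _write_json(out / "experiments.json", results)
            manifest["artefacts"]["experiments"] = {"path": str(out / "experiments.json")}
        manifest["complete"] = True
    finally:
        manifest["wall_clock_s"] = round(time.time() - t0, 2)
        _write_json(out / "manifest.json", manifest)
    return manifest
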