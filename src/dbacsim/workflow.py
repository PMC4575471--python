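"""Two-button treatment orchestration: Start D&L and Start Therapy.

The whole treatment sequence runs unattended from a single configuration:
(1) ``start_dl`` renders the compounded Doppler volume and runs the
detection/localization chain, reporting bifurcation and bleeder counts;
(2) ``start_therapy`` takes each reported bleeder in order through tile
selection and power equalization, closed-loop focus correction, and the
temperature-feedback dose controller, aggregating pass/fail against the
thermal requirements. Phase timings are logged (JSON lines) but never gated:
simulation wall-clock is not comparable to the hardware time limits.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import constants as C
from .acoustics import deposition_from_plan
from .bioheat import DoseRecord
from .control import (ThermometryConfig, correct_targeting, dose_controller,
                      make_thermometry_corpus, train_estimator)
from .cuff import CuffGeometry, build_cuff
from .detection import DLReport, run_dl
from .phantoms import LimbPhantom, make_limb_phantom
from .planning import PlanningFailure, plan_dose


@dataclass
class RunConfig:
    """Configuration for one unattended treatment run."""

    limb_diameter_cm: float = 15.0
    n_bifurcations: int = 2
    n_bleeders: int = 1
    n_panels: int = 5
    seed: int = 0
    voxel_size_mm: float = 0.3
    ri_threshold: float = C.RI_BLEEDER_THRESHOLD
    dt_threshold_c: float = 5.0
    targeting_tol_mm: float = C.TARGETING_TOL_MM
    max_iter: int = 5
    thermometry: str = "tsi"               # tsi | rnn
    therapy_voxel_mm: float = 1.0
    therapy_box_mm: float = 32.0
    out_dir: str = "dbac_run"
    phantom_json: str | None = None        # load instead of generating
    cuff_json: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**d)
        for name in ("phantom_json", "cuff_json"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not resolve: {p}")
        return cfg


class _JsonlLogger:
    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)

    def log(self, event: str, **kw) -> None:
        rec = {"event": event, **kw}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def _materialize(cfg: RunConfig) -> tuple[LimbPhantom, CuffGeometry]:
    if cfg.phantom_json:
        phantom = LimbPhantom.load(cfg.phantom_json)
    else:
        phantom = make_limb_phantom(cfg.limb_diameter_cm, cfg.n_bifurcations,
                                    cfg.n_bleeders, cfg.seed)
    if cfg.cuff_json:
        cuff = CuffGeometry.load(cfg.cuff_json)
    else:
        cuff = build_cuff(cfg.n_panels, cfg.limb_diameter_cm)
    return phantom, cuff


def start_dl(cfg: RunConfig) -> DLReport:
    """Button 1: run detection & localization and persist the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _JsonlLogger(out / "run_log.jsonl")
    phantom, cuff = _materialize(cfg)
    log.log("start_dl", seed=cfg.seed, limb_diameter_cm=phantom.diameter_cm)
    report = run_dl(phantom, cuff, seed=cfg.seed, voxel_size_mm=cfg.voxel_size_mm)
    report.save(out / "dl_report.json")
    log.log("dl_done", n_bifurcations=report.n_bifurcations,
            n_bleeders=len(report.bleeders),
            phase_durations_s=report.phase_durations_s)
    return report


@dataclass
class RunReport:
    """Aggregate of one full two-button treatment sequence."""

    dl: DLReport
    dose_records: list[DoseRecord] = field(default_factory=list)
    targeting_converged: list[bool] = field(default_factory=list)
    planning_failures: list[str] = field(default_factory=list)
    pass_matrix: list[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "dl": self.dl.to_json_dict(),
            "dose_records": [r.to_json_dict() for r in self.dose_records],
            "targeting_converged": self.targeting_converged,
            "planning_failures": self.planning_failures,
            "pass_matrix": self.pass_matrix,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))


def start_therapy(cfg: RunConfig, dl_report: DLReport) -> RunReport:
    """Button 2: plan, correct targeting, and dose every reported bleeder."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _JsonlLogger(out / "run_log.jsonl")
    phantom, cuff = _materialize(cfg)
    report = RunReport(dl_report)
    if not dl_report.bleeders:
        log.log("start_therapy", note="no bleeders reported; nothing to treat")
        report.save(out / "run_report.json")
        return report

    thermo = ThermometryConfig(method=cfg.thermometry)
    if cfg.thermometry == "rnn":
        streams, truths = make_thermometry_corpus(120, seed=cfg.seed)
        thermo.estimator = train_estimator(streams, truths, seed=cfg.seed)

    rng = np.random.default_rng(cfg.seed)
    for bi, bleeder in enumerate(dl_report.bleeders):
        t0 = time.perf_counter()
        target = np.asarray(bleeder.target_coordinate_mm, dtype=float)
        try:
            plan = plan_dose(cuff, phantom, target)
        except (PlanningFailure, ValueError) as exc:
            report.planning_failures.append(f"bleeder {bi}: {exc}")
            log.log("planning_failure", bleeder=bi, error=str(exc))
            continue
        # Closed-loop focus correction for each recruited tile.
        all_conv = True
        for tid in plan.tile_ids:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            trial = correct_targeting(rng.uniform(3.0, 8.0) * u,
                                      max_iter=cfg.max_iter,
                                      tol_mm=cfg.targeting_tol_mm,
                                      seed=int(rng.integers(2**31)))
            all_conv &= trial.converged
        report.targeting_converged.append(all_conv)

        half = cfg.therapy_box_mm / 2.0
        origin = target - half
        n = int(round(cfg.therapy_box_mm / cfg.therapy_voxel_mm)) + 1
        dep = deposition_from_plan(plan, phantom, origin, (n, n, n),
                                   cfg.therapy_voxel_mm)
        rec = dose_controller(plan, phantom, dep, thermo, cfg.dt_threshold_c,
                              noise_seed=int(rng.integers(2**31)))
        report.dose_records.append(rec)
        report.pass_matrix.append({
            "bleeder": bi,
            "min_td": rec.passes_min_td,
            "mtsd": rec.passes_mtsd,
            "targeting": all_conv,
            "shutoff": rec.shutoff_cause,
        })
        log.log("dose_done", bleeder=bi, t_dose_s=rec.t_dose_s,
                shutoff=rec.shutoff_cause,
                wall_s=time.perf_counter() - t0)
    report.save(out / "run_report.json")
    return report


def run_all(cfg: RunConfig) -> RunReport:
    """The full two-button sequence with no human input in between."""
    dl = start_dl(cfg)
    return start_therapy(cfg, dl)
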