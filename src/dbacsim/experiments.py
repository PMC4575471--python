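"""Reference desk-scale experiments reproducing the system's quantitative
benchmarks: minimum absorbed power for the thermal-dose floor, maximal-dose
skin temperature, closed-loop targeting convergence, and time-of-flight
registration accuracy.

Each experiment builds its own inputs from the package's generators and runs
the full method; nothing is looked up. Problem sizes (grids, trial counts)
are chosen for single-CPU desk-scale runs and documented in the methods
note.
"""

from __future__ import annotations

import numpy as np

from . import constants as C
from .acoustics import DepositionMap, deposition_from_plan
from .bioheat import mtv_stats, skin_peak, solve_bioheat
from .control import targeting_campaign
from .cuff import build_cuff
from .phantoms import make_limb_phantom
from .planning import plan_dose
from .tof import perturb_cuff, registration_error, simulate_tof, solve_poses


def _three_tile_plan(phantom, cuff, target):
    plan = plan_dose(cuff, phantom, target)
    for attr in ("tile_ids", "weights", "output_powers_w", "candidates"):
        setattr(plan, attr, getattr(plan, attr)[:3])
    return plan


def find_min_absorbed_power(seed: int = 0, voxel_mm: float = 0.5,
                            box_half_mm: float = 20.0, t_dose_s: float = 30.0,
                            n_bisect: int = 10,
                            target_min_dt_c: float = C.MIN_TD_DT_LOW_C) -> dict:
    """Absorbed power at the target that just reaches the MinTD floor.

    An equalized 3-tile dose into a 15-cm phantom (target at 7.5-cm depth on
    the limb axis) is dithered over the 8-mm MTV and run through the bioheat
    solver for 30 s; the total absorbed power — the planning quantity
    Q = sum_m Q_m of Eq. (planning), i.e. arriving power times the MTV-slab
    absorption — is bisected until the minimum end-of-dose rise over the MTV
    equals 33 degC. Also reports the deposition-map integral actually inside
    the MTV sphere (the geometric beam tails put part of the arriving power
    just outside it).
    """
    phantom = make_limb_phantom(15.0, 2, 1, seed=seed, with_bone=False)
    cuff = build_cuff(5, 15.0)
    target = np.zeros(3)
    plan = _three_tile_plan(phantom, cuff, target)
    q_plan = plan.per_tile_absorbed_w * len(plan.tile_ids)
    n = int(round(2 * box_half_mm / voxel_mm)) + 1
    dep = deposition_from_plan(plan, phantom, target - box_half_mm,
                               (n, n, n), voxel_mm)
    in_mtv = dep.absorbed_in_sphere_w(target, C.MTV_DIAMETER_MM)

    def min_dt(power_w: float) -> float:
        scaled = DepositionMap(dep.q_w_cm3 * (power_w / q_plan),
                               voxel_mm, dep.origin_mm)
        field = solve_bioheat(phantom, scaled, t_dose_s)
        return mtv_stats(field, target)[0]

    lo, hi = 1.0, 10.0
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if min_dt(mid) < target_min_dt_c:
            lo = mid
        else:
            hi = mid
    power = 0.5 * (lo + hi)
    scaled = DepositionMap(dep.q_w_cm3 * (power / q_plan), voxel_mm, dep.origin_mm)
    field = solve_bioheat(phantom, scaled, t_dose_s)
    mn, me, mx = mtv_stats(field, target)
    return {
        "absorbed_power_w": float(power),
        "in_mtv_absorbed_w": float(in_mtv * power / q_plan),
        "mtv_dt_min_c": mn, "mtv_dt_mean_c": me, "mtv_dt_max_c": mx,
        "n_tiles": len(plan.tile_ids), "dither_pattern": plan.dither_pattern,
    }


def mtsd_skin_experiment(seed: int = 0, power_per_tile_w: float = 55.0,
                         voxel_mm: float = 2.0, t_dose_s: float = 30.0) -> dict:
    """Peak skin temperature rise under a maximal dose: three tiles at 55 W
    acoustic each, confocal on a target 7.5 cm deep in a 15-cm phantom."""
    phantom = make_limb_phantom(15.0, 2, 1, seed=seed, with_bone=False)
    cuff = build_cuff(5, 15.0)
    target = np.zeros(3)
    plan = _three_tile_plan(phantom, cuff, target)
    plan.output_powers_w = [power_per_tile_w] * len(plan.tile_ids)
    R = phantom.radius_mm
    half_xy = R + 2 * voxel_mm
    nx = int(round(2 * half_xy / voxel_mm)) + 1
    nz = int(round(70.0 / voxel_mm)) + 1
    origin = np.array([-half_xy, -half_xy, -35.0])
    dep = deposition_from_plan(plan, phantom, origin, (nx, nx, nz), voxel_mm)
    field = solve_bioheat(phantom, dep, t_dose_s, dt_s=0.5,
                          snapshot_every_s=1.0)
    mn, me, mx = mtv_stats(field, target)
    return {"skin_dt_max_c": skin_peak(field, phantom),
            "target_dt_min_c": mn, "target_dt_max_c": mx,
            "power_per_tile_w": power_per_tile_w}


def targeting_experiment(seed: int = 0, n_trials: int = 50,
                         max_iter: int = 5) -> dict:
    """Closed-loop targeting campaign: initial offsets 3-10 mm, 0.5-mm
    localization noise; reports the worst final focus-target distance among
    converged trials and the convergence rates at 3 and 5 iterations."""
    trials5 = targeting_campaign(n_trials, seed=seed, max_iter=max_iter)
    trials3 = targeting_campaign(n_trials, seed=seed, max_iter=3)
    conv_final = [t.final_offset_mm for t in trials5 if t.converged]
    return {
        "n_trials": n_trials,
        "n_converged": len(conv_final),
        "max_final_offset_mm": float(max(conv_final)) if conv_final else float("nan"),
        "rate_5_iter": len(conv_final) / n_trials,
        "rate_3_iter": sum(t.converged for t in trials3) / n_trials,
    }


def tof_experiment(seed: int = 0, degraded: bool = False,
                   jitter_sd_s: float = 0.4e-6) -> dict:
    """Time-of-flight registration on a seven-panel cuff around a 25-cm
    phantom with two-layer media and 0.4-us timing jitter.

    ``degraded`` removes one therapy tile and one imaging probe from the
    measurement set (20/21 tiles, 5/6 probes functional).
    """
    phantom = make_limb_phantom(25.0, 2, 1, seed=seed, with_bone=False)
    nominal = build_cuff(7, 25.0)
    cuff = perturb_cuff(nominal, seed=seed + 1)
    kw = {}
    if degraded:
        kw = {"exclude_tiles": (20,), "exclude_probes": (5,)}
    tof = simulate_tof(cuff, phantom, jitter_sd_s, seed=seed, **kw)
    est = solve_poses(tof, 7, seed=seed)
    err = registration_error(est, tof)
    tx = np.array([a.startswith("tx") for a in est.array_ids])
    return {
        "n_sides": est.n_sides,
        "c_tissue_m_s": est.c_tissue_m_s,
        "c_water_m_s": est.c_water_m_s,
        "median_ix_tx_distance_error_mm": err.median_ix_tx_distance_error_mm,
        "median_tx_normal_error_deg": float(np.median(err.normal_errors_deg[tx])),
        "max_position_error_mm": err.max_position_error_mm,
        "residual_rms_us": est.residual_rms_s * 1e6,
    }
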