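"""Therapy-tile selection and power equalization for a dose target.

Given a target coordinate, the planner filters the cuff's tiles to those
within steering and focal range with unobstructed acoustic paths, scores
each by transport efficiency, and evaluates the absorbed power each can put
into the 8-mm minimum therapeutic volume (MTV):

    Q_m = Q_0 * eta_m * (1 - exp(-2 * alpha * d_0)),

where Q_0 is the tile's maximum (electrical) power capacity, eta_m the
transport efficiency (electroacoustic efficiency x steering directivity x
tissue attenuation along the path), alpha the tissue attenuation coefficient
at the therapy frequency, and d_0 the MTV diameter. Candidates are ranked by
achievable Q_m; for each group size k in [minTx, maxTx] the top-k group is
power-equalized to its weakest member and the group with the greatest total
absorbed power wins.

"Equalized" means every recruited tile contributes the same absorbed power
at the target, set by the k-th largest achievable contribution, which is the
only reading consistent with weights 0 < w <= 1 and with comparing group
totals k * Q_(k).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import constants as C
from .cuff import CuffGeometry, TxTile
from .phantoms import LimbPhantom

ELECTROACOUSTIC_EFFICIENCY = 0.5   # acoustic-out / electrical-in, per tile
MTV_D0_CM = C.MTV_DIAMETER_MM / 10.0
DEFAULT_MIN_TX = 2
DEFAULT_MAX_TX = 6
FOCAL_RANGE_MM = (10.0, 160.0)

# Steering directivity: cosine-power falloff fitted to the element-summation
# beam model's focal-gain reduction on a 5-degree steer grid (the baffled
# cosine element factor dominates; see acoustics.fit_directivity_exponents).
DIRECTIVITY_EXP_AZ = 1.0
DIRECTIVITY_EXP_EL = 1.0


def steering_directivity(az_deg: float, el_deg: float,
                         p_az: float = DIRECTIVITY_EXP_AZ,
                         p_el: float = DIRECTIVITY_EXP_EL) -> float:
    """Relative power delivered at a steered focus, 1.0 when unsteered."""
    ca = np.cos(np.deg2rad(az_deg))
    ce = np.cos(np.deg2rad(el_deg))
    if ca <= 0 or ce <= 0:
        return 0.0
    return float(ca ** p_az * ce ** p_el)


@dataclass
class TileCandidate:
    """One therapy tile's acoustic relationship to the target."""

    tile: TxTile
    distance_cm: float
    az_deg: float
    el_deg: float
    water_path_cm: float
    tissue_path_cm: float
    obstructed: bool
    eta_m: float = 0.0
    q_cap_w: float = 0.0      # achievable absorbed power at the tile's cap

    @property
    def tile_id(self) -> int:
        return self.tile.tile_id


def _path_split_cm(tile_pos: np.ndarray, target: np.ndarray,
                   limb_radius_mm: float) -> tuple[float, float]:
    """(water, tissue) path lengths in cm for the straight tile->target ray."""
    d = target - tile_pos
    L = float(np.linalg.norm(d))
    # 2D circle intersection in the x-y plane
    p2, d2 = tile_pos[:2], d[:2]
    a = float(d2 @ d2)
    tissue = 0.0
    if a > 1e-12:
        b = 2.0 * float(p2 @ d2)
        c = float(p2 @ p2) - limb_radius_mm ** 2
        disc = b * b - 4 * a * c
        if disc > 0:
            sq = np.sqrt(disc)
            t0 = np.clip((-b - sq) / (2 * a), 0.0, 1.0)
            t1 = np.clip((-b + sq) / (2 * a), 0.0, 1.0)
            tissue = (t1 - t0) * L
    return (L - tissue) / 10.0, tissue / 10.0


def available_tiles(cuff: CuffGeometry, phantom: LimbPhantom,
                    target_mm: np.ndarray,
                    focal_range_mm: tuple[float, float] = FOCAL_RANGE_MM,
                    f_c_mhz: float | None = None) -> list[TileCandidate]:
    """Tiles within steering and focal range of the target with unobstructed
    acoustic paths, scored by transport efficiency and achievable Q_m."""
    target = np.asarray(target_mm, dtype=float)
    if not phantom.contains(target):
        raise ValueError("target lies outside the phantom")
    out: list[TileCandidate] = []
    for tile in cuff.tiles:
        az, el = tile.steering_angles_to(target)
        dist_mm = float(np.linalg.norm(target - tile.position_mm))
        if abs(az) > tile.steer_limit_az_deg or abs(el) > tile.steer_limit_el_deg:
            continue
        if not (focal_range_mm[0] <= dist_mm <= focal_range_mm[1]):
            continue
        obstructed = any(b.blocks_segment(tile.position_mm, target)
                         for b in phantom.bones)
        if obstructed:
            continue
        water_cm, tissue_cm = _path_split_cm(tile.position_mm, target,
                                             phantom.radius_mm)
        cand = TileCandidate(tile, dist_mm / 10.0, az, el, water_cm, tissue_cm,
                             obstructed=False)
        fc = f_c_mhz if f_c_mhz is not None else tile.f_c_mhz
        cand.eta_m = transport_efficiency(cand, fc, phantom.tissue)
        alpha = phantom.tissue.attenuation_np_cm(fc)
        q0_electrical = tile.power_cap_w / ELECTROACOUSTIC_EFFICIENCY
        cand.q_cap_w = absorbed_power(q0_electrical, cand.eta_m, alpha, MTV_D0_CM)
        out.append(cand)
    return out


def transport_efficiency(candidate: TileCandidate, f_c_mhz: float,
                         tissue=None,
                         electroacoustic: float = ELECTROACOUSTIC_EFFICIENCY) -> float:
    """Transport efficiency eta_m: acoustic power reaching the target per unit
    input electrical power.

    eta_m = electroacoustic efficiency x steering directivity x
    exp(-2 alpha f_c d_tissue); water-path absorption is negligible at 1 MHz.
    """
    if tissue is None:
        from .phantoms import TissueProperties
        tissue = TissueProperties()
    alpha = tissue.attenuation_np_cm(f_c_mhz)
    att = np.exp(-2.0 * alpha * candidate.tissue_path_cm)
    return float(electroacoustic
                 * steering_directivity(candidate.az_deg, candidate.el_deg) * att)


def absorbed_power(q0_w: float, eta_m: float, alpha_np_cm: float,
                   d0_cm: float = MTV_D0_CM) -> float:
    """Absorbed acoustic power (W) within a spherical volume of diameter d_0:
    Q_m = Q_0 * eta_m * (1 - exp(-2 alpha d_0))."""
    if min(q0_w, eta_m, alpha_np_cm, d0_cm) < 0:
        raise ValueError("absorbed_power inputs must be nonnegative")
    return q0_w * eta_m * (1.0 - np.exp(-2.0 * alpha_np_cm * d0_cm))


@dataclass
class DosePlan:
    """Recruited tiles, equalized weights and per-tile output powers."""

    target_mm: np.ndarray
    tile_ids: list[int]
    weights: list[float]                  # (0, 1] per recruited tile
    output_powers_w: list[float]          # per-tile acoustic output
    per_tile_absorbed_w: float            # equalized absorbed contribution
    total_absorbed_w: float
    alpha_np_cm: float
    d0_cm: float = MTV_D0_CM
    dither_pattern: str = ""
    dither_points_mm: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    t_dose_s: float = C.MAX_DOSE_TIME_S
    candidates: list[TileCandidate] = field(default_factory=list, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "target_mm": self.target_mm.tolist(),
            "tile_ids": self.tile_ids,
            "weights": self.weights,
            "output_powers_w": self.output_powers_w,
            "per_tile_absorbed_w": self.per_tile_absorbed_w,
            "total_absorbed_w": self.total_absorbed_w,
            "alpha_np_cm": self.alpha_np_cm,
            "d0_cm": self.d0_cm,
            "dither_pattern": self.dither_pattern,
            "dither_points_mm": self.dither_points_mm.tolist(),
            "t_dose_s": self.t_dose_s,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))


class PlanningFailure(RuntimeError):
    """Raised when fewer than minTx unobstructed candidates exist."""


def select_tile_group(candidates: list[TileCandidate],
                      min_tx: int = DEFAULT_MIN_TX,
                      max_tx: int = DEFAULT_MAX_TX,
                      target_mm: np.ndarray | None = None,
                      alpha_np_cm: float | None = None) -> DosePlan:
    """Choose the tile group and equalized powers maximizing total absorbed
    power at the target.

    Candidates are ranked by achievable Q_m (descending). For each k in
    [minTx, maxTx] the top-k group equalizes every member to the k-th largest
    Q_m, giving total k * Q_(k); the maximizing k wins (ties go to more
    tiles, which shapes the heated volume more spherically). Weights are
    w_i = Q_(k) / Q_i <= 1 and per-tile output power is w_i x cap_i.
    """
    usable = [c for c in candidates if not c.obstructed and c.q_cap_w > 0]
    if len(usable) < min_tx:
        raise PlanningFailure(
            f"only {len(usable)} usable tiles; minTx={min_tx} required")
    ranked = sorted(usable, key=lambda c: c.q_cap_w, reverse=True)
    k_hi = min(max_tx, len(ranked))
    best_k, best_total = None, -np.inf
    for k in range(min_tx, k_hi + 1):
        qk = ranked[k - 1].q_cap_w
        total = k * qk
        if total >= best_total - 1e-12:     # ties -> larger k
            if total > best_total + 1e-12 or best_k is None or k > best_k:
                best_k, best_total = k, max(total, best_total)
    group = ranked[:best_k]
    qk = group[-1].q_cap_w
    weights = [qk / c.q_cap_w for c in group]
    powers = [w * c.tile.power_cap_w for w, c in zip(weights, group)]
    tgt = np.asarray(target_mm, dtype=float) if target_mm is not None else np.zeros(3)
    alpha = alpha_np_cm if alpha_np_cm is not None else 0.05
    depth_cm = 0.0
    if group:
        depth_cm = float(np.mean([c.tissue_path_cm for c in group]))
    pattern, pts = select_dither(max(depth_cm, 0.1))
    return DosePlan(tgt, [c.tile_id for c in group], weights, powers,
                    per_tile_absorbed_w=qk, total_absorbed_w=float(best_total),
                    alpha_np_cm=alpha, dither_pattern=pattern,
                    dither_points_mm=pts + tgt[None, :], candidates=group)


DITHER_SWITCH_RATE_HZ = 10_000.0


def select_dither(depth_cm: float) -> tuple[str, np.ndarray]:
    """Dithering pattern for a focal depth: 12 points (double ring) at depths
    <= 7 cm, 9 points (3 x 3 grid) deeper. Points span the 8-mm MTV laterally
    (offsets in the x-y plane relative to the focus)."""
    if depth_cm <= 0:
        raise ValueError("depth must be positive")
    if depth_cm <= 7.0:
        angles_outer = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        outer = 3.2 * np.stack([np.cos(angles_outer), np.sin(angles_outer)], axis=1)
        angles_inner = np.linspace(0, 2 * np.pi, 4, endpoint=False) + np.pi / 4
        inner = 1.6 * np.stack([np.cos(angles_inner), np.sin(angles_inner)], axis=1)
        pts2 = np.vstack([outer, inner])
        name = "ring12"
    else:
        g = np.array([-2.8, 0.0, 2.8])
        X, Y = np.meshgrid(g, g, indexing="ij")
        pts2 = np.stack([X.ravel(), Y.ravel()], axis=1)
        name = "grid9"
    pts = np.concatenate([pts2, np.zeros((len(pts2), 1))], axis=1)
    return name, pts


def plan_dose(cuff: CuffGeometry, phantom: LimbPhantom, target_mm: np.ndarray,
              min_tx: int = DEFAULT_MIN_TX, max_tx: int = DEFAULT_MAX_TX,
              t_dose_s: float = C.MAX_DOSE_TIME_S) -> DosePlan:
    """End-to-end planning: availability filtering, ranking, equalization and
    dither selection for one target."""
    cands = available_tiles(cuff, phantom, target_mm)
    alpha = phantom.tissue.attenuation_np_cm(1.0)
    plan = select_tile_group(cands, min_tx, max_tx, target_mm=target_mm,
                             alpha_np_cm=alpha)
    plan.t_dose_s = min(t_dose_s, C.MAX_DOSE_TIME_S)
    depth_cm = phantom.depth_of(target_mm)
    plan.dither_pattern, pts = select_dither(max(depth_cm, 0.1))
    plan.dither_points_mm = pts + np.asarray(target_mm, dtype=float)[None, :]
    return plan
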