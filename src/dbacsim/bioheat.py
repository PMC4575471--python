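"""Pennes bioheat finite-difference solver and thermal-dose metrics.

Solves, for the temperature elevation dT above baseline on a regular grid,

    rho c_p d(dT)/dt = k_t lap(dT) - rho_b c_b w_b dT + q_dep,

with an explicit 6-point stencil (stability-checked), Dirichlet dT = 0 at
the outer boundary (the water jacket is an effective heat sink) or insulated
(zero-flux) boundaries for conservation tests. Deposition is constant in
time until the controller switches power off. Vessel lumen voxels can
optionally carry an enhanced local heat sink standing in for intraluminal
advective cooling (enough to reproduce the cold-lumen thermometry bias, not
a CFD solve).

Dose metrics: end-of-dose statistics over the 8-mm minimum therapeutic
volume (MTV), peak skin temperature rise, the lateral-confinement (MTTD)
check, and CEM43 cumulative equivalent minutes at 43 degC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import constants as C
from .acoustics import DepositionMap
from .phantoms import LimbPhantom

BLOOD_RHO_C = 1050.0 * 3617.0     # rho_b * c_b for the perfusion sink, J/(m^3 K)
# Effective lumen sink standing in for advective cooling by flowing blood:
# strong enough that lumen voxels track baseline on the dose timescale.
VESSEL_SINK_W_M3K = 5.0e6


def stable_dt_s(voxel_size_mm: float, tissue, safety: float = 0.9) -> float:
    """Largest stable explicit time step: dt <= h^2 rho c_p / (6 k_t) x safety."""
    h = voxel_size_mm * 1e-3
    return safety * h * h * tissue.density_kg_m3 * tissue.specific_heat_j_kgk \
        / (6.0 * tissue.conductivity_w_mk)


@dataclass
class ThermalField:
    """Time-resolved temperature-elevation grids from one bioheat run."""

    snapshots: list[np.ndarray]          # dT (degC) at snapshot_times
    snapshot_times_s: list[float]
    dt_s: float
    voxel_size_mm: float
    origin_mm: np.ndarray
    boundary: str
    baseline_temperature_c: float = 37.0

    @property
    def final(self) -> np.ndarray:
        return self.snapshots[-1]

    def point_history(self, point_mm: np.ndarray) -> np.ndarray:
        idx = tuple(np.round((np.asarray(point_mm) - self.origin_mm)
                             / self.voxel_size_mm).astype(int))
        return np.array([s[idx] for s in self.snapshots])

    def tc_log_csv(self, path: str | Path, point_mm: np.ndarray) -> None:
        """Thermocouple-style log of the rise at one point."""
        hist = self.point_history(point_mm)
        with open(path, "w") as fh:
            fh.write("time_s,dT_C\n")
            for t, v in zip(self.snapshot_times_s, hist):
                fh.write(f"{t:.3f},{v:.4f}\n")

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "a") as fh:
            for i, (t, s) in enumerate(zip(self.snapshot_times_s, self.snapshots)):
                name = f"/dT/t{i:04d}"
                if name in fh:
                    del fh[name]
                ds = fh.create_dataset(name, data=s.astype(np.float32),
                                       compression="gzip")
                ds.attrs["time_s"] = t
                ds.attrs["voxel_size_mm"] = self.voxel_size_mm
                ds.attrs["origin_mm"] = self.origin_mm


class BioheatSolver:
    """Steppable explicit Pennes solver (used directly by the dose controller)."""

    def __init__(self, phantom: LimbPhantom, deposition: DepositionMap,
                 dt_s: float | None = None, boundary: str = "dirichlet",
                 vessel_sink: bool = False):
        self.tissue = phantom.tissue
        self.h_m = deposition.voxel_size_mm * 1e-3
        bound = stable_dt_s(deposition.voxel_size_mm, self.tissue)
        if dt_s is None:
            dt_s = bound
        elif dt_s > bound:
            raise ValueError(
                f"dt={dt_s:.4g} s unstable for the explicit scheme; the "
                f"stable bound at h={deposition.voxel_size_mm} mm is "
                f"{bound:.4g} s (choose dt below it)")
        if boundary not in ("dirichlet", "insulated"):
            raise ValueError("boundary must be 'dirichlet' or 'insulated'")
        self.dt = dt_s
        self.boundary = boundary
        self.q_w_m3 = deposition.q_w_cm3 * 1e6
        self.voxel_size_mm = deposition.voxel_size_mm
        self.origin_mm = deposition.origin_mm
        self.dT = np.zeros_like(self.q_w_m3)
        self.t = 0.0
        self.rho_c = self.tissue.density_kg_m3 * self.tissue.specific_heat_j_kgk
        self.k = self.tissue.conductivity_w_mk
        self.perf = BLOOD_RHO_C * self.tissue.perfusion_1_s
        self.power_on = True
        self.sink = None
        if vessel_sink:
            self.sink = self._lumen_sink_mask(phantom)

    def _lumen_sink_mask(self, phantom: LimbPhantom) -> np.ndarray:
        from .phantoms import rasterize_lumen
        mask, _, _ = rasterize_lumen(phantom.vessel_tree, self.voxel_size_mm,
                                     self.origin_mm, self.q_w_m3.shape)
        return mask

    def _laplacian(self, f: np.ndarray) -> np.ndarray:
        out = np.zeros_like(f)
        core = out[1:-1, 1:-1, 1:-1]
        core += f[2:, 1:-1, 1:-1] + f[:-2, 1:-1, 1:-1]
        core += f[1:-1, 2:, 1:-1] + f[1:-1, :-2, 1:-1]
        core += f[1:-1, 1:-1, 2:] + f[1:-1, 1:-1, :-2]
        core -= 6.0 * f[1:-1, 1:-1, 1:-1]
        if self.boundary == "insulated":
            # mirror ghost cells: zero-flux faces
            pad = np.pad(f, 1, mode="edge")
            lap = (pad[2:, 1:-1, 1:-1] + pad[:-2, 1:-1, 1:-1]
                   + pad[1:-1, 2:, 1:-1] + pad[1:-1, :-2, 1:-1]
                   + pad[1:-1, 1:-1, 2:] + pad[1:-1, 1:-1, :-2]
                   - 6.0 * pad[1:-1, 1:-1, 1:-1])
            return lap / self.h_m ** 2
        return out / self.h_m ** 2

    def step(self, n: int = 1) -> None:
        for _ in range(n):
            rate = self.k * self._laplacian(self.dT) - self.perf * self.dT
            if self.power_on:
                rate = rate + self.q_w_m3
            if self.sink is not None:
                rate = rate - VESSEL_SINK_W_M3K * self.dT * self.sink
            self.dT += self.dt / self.rho_c * rate
            if self.boundary == "dirichlet":
                for ax in range(3):
                    sl = [slice(None)] * 3
                    sl[ax] = 0
                    self.dT[tuple(sl)] = 0.0
                    sl[ax] = -1
                    self.dT[tuple(sl)] = 0.0
            self.t += self.dt

    def run(self, t_end_s: float, snapshot_every_s: float = 0.5) -> ThermalField:
        snaps = [self.dT.copy()]
        times = [self.t]
        next_snap = self.t + snapshot_every_s
        while self.t < t_end_s - 1e-9:
            n = max(1, int(round((min(next_snap, t_end_s) - self.t) / self.dt)))
            self.step(n)
            snaps.append(self.dT.copy())
            times.append(self.t)
            next_snap = self.t + snapshot_every_s
        return ThermalField(snaps, times, self.dt, self.voxel_size_mm,
                            self.origin_mm, self.boundary,
                            self.tissue.baseline_temperature_c)


def solve_bioheat(phantom: LimbPhantom, deposition: DepositionMap,
                  t_dose_s: float, dt_s: float | None = None,
                  boundary: str = "dirichlet", snapshot_every_s: float = 0.5,
                  vessel_sink: bool = False) -> ThermalField:
    """Run the Pennes solver for ``t_dose_s`` with snapshots every 0.5 s."""
    solver = BioheatSolver(phantom, deposition, dt_s, boundary, vessel_sink)
    return solver.run(t_dose_s, snapshot_every_s)


def _sphere_mask(field: ThermalField, center_mm: np.ndarray,
                 diameter_mm: float) -> np.ndarray:
    shape = field.final.shape
    h = field.voxel_size_mm
    c = np.asarray(center_mm, dtype=float)
    x = field.origin_mm[0] + np.arange(shape[0]) * h
    y = field.origin_mm[1] + np.arange(shape[1]) * h
    z = field.origin_mm[2] + np.arange(shape[2]) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    return ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
            <= (diameter_mm / 2.0) ** 2)


def mtv_stats(field: ThermalField, center_mm: np.ndarray,
              diameter_mm: float = C.MTV_DIAMETER_MM) -> tuple[float, float, float]:
    """(min, mean, max) end-of-dose temperature rise over MTV voxels."""
    mask = _sphere_mask(field, center_mm, diameter_mm)
    c = np.asarray(center_mm)
    lo = field.origin_mm + diameter_mm / 2.0
    hi = field.origin_mm + (np.array(field.final.shape) - 1) * field.voxel_size_mm \
        - diameter_mm / 2.0
    if np.any(c < lo) or np.any(c > hi):
        raise ValueError("MTV sphere clipped by the solution domain")
    vals = field.final[mask]
    return float(vals.min()), float(vals.mean()), float(vals.max())


def skin_peak(field: ThermalField, phantom: LimbPhantom) -> float:
    """Maximum temperature rise over skin-surface voxels across all times."""
    shape = field.final.shape
    h = field.voxel_size_mm
    x = field.origin_mm[0] + np.arange(shape[0]) * h
    y = field.origin_mm[1] + np.arange(shape[1]) * h
    X, Y = np.meshgrid(x, y, indexing="ij")
    r = np.hypot(X, Y)
    skin2d = np.abs(r - phantom.radius_mm) <= h * 0.75
    if not skin2d.any():
        raise ValueError("solution grid does not reach the skin surface")
    peak = 0.0
    for s in field.snapshots:
        peak = max(peak, float(s[skin2d, :].max()))
    return peak


def mttd_check(field: ThermalField, target_mm: np.ndarray,
               radius_mm: float = C.MTTD_RADIUS_MM,
               axis: np.ndarray | None = None,
               significant_fraction: float = 0.2) -> tuple[bool, dict]:
    """Lateral heating confinement check.

    Passes iff the maximum end-of-dose rise at lateral distance beyond
    ``radius_mm`` from the beam axis through the target stays below
    ``significant_fraction`` of the MTV mean rise ("no significant heating"
    operationalized as < 20 % of the target heating). Returns the verdict
    and a lateral profile (max rise vs lateral distance bin).
    """
    if axis is None:
        axis = np.array([0.0, 0.0, 1.0])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    shape = field.final.shape
    h = field.voxel_size_mm
    t = np.asarray(target_mm, dtype=float)
    x = field.origin_mm[0] + np.arange(shape[0]) * h
    y = field.origin_mm[1] + np.arange(shape[1]) * h
    z = field.origin_mm[2] + np.arange(shape[2]) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    d = np.stack([X - t[0], Y - t[1], Z - t[2]], axis=-1)
    s = d @ axis
    lat = np.sqrt(np.maximum(np.einsum("...i,...i->...", d, d) - s ** 2, 0.0))
    _, mtv_mean, _ = mtv_stats(field, target_mm)
    outside = lat > radius_mm
    max_outside = float(field.final[outside].max()) if outside.any() else 0.0
    ok = (mtv_mean <= 0) or (max_outside < significant_fraction * mtv_mean)
    bins = np.arange(0.0, lat.max() + 2.0, 2.0)
    prof = [float(field.final[(lat >= a) & (lat < b)].max())
            if ((lat >= a) & (lat < b)).any() else 0.0
            for a, b in zip(bins[:-1], bins[1:])]
    return bool(ok), {"bins_mm": bins[:-1].tolist(), "max_dT": prof,
                      "max_outside": max_outside, "mtv_mean": mtv_mean}


def cem43(dT_history: np.ndarray, times_s: np.ndarray,
          baseline_c: float = 37.0) -> float:
    """Cumulative equivalent minutes at 43 degC for one point's history.

    Sapareto-Dewey convention: R = 0.5 for T >= 43 degC, R = 0.25 below.
    """
    T = baseline_c + np.asarray(dT_history, dtype=float)
    dt_min = np.diff(np.asarray(times_s, dtype=float), prepend=times_s[0]) / 60.0
    R = np.where(T >= 43.0, 0.5, 0.25)
    return float(np.sum(dt_min * R ** (43.0 - T)))


@dataclass
class DoseRecord:
    """Outcome of one controlled dose against the thermal requirements."""

    plan_tile_ids: list[int]
    t_dose_s: float
    mtv_dt_min_c: float
    mtv_dt_mean_c: float
    mtv_dt_max_c: float
    skin_dt_max_c: float | None
    cem43_target_min: float
    shutoff_cause: str                   # threshold | time-limit
    estimated_dt_at_shutoff_c: float | None = None
    true_target_dt_at_shutoff_c: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def passes_min_td(self) -> bool:
        return C.MIN_TD_DT_LOW_C <= self.mtv_dt_min_c and \
            self.mtv_dt_max_c <= C.MIN_TD_DT_HIGH_C

    @property
    def passes_mtsd(self) -> bool:
        return self.skin_dt_max_c is None or self.skin_dt_max_c <= C.MTSD_DT_C

    def to_json_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "extra"}
        d["passes_min_td"] = self.passes_min_td
        d["passes_mtsd"] = self.passes_mtsd
        d.update(self.extra)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))
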