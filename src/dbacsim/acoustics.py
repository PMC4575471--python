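"""Focused-beam fields and dose deposition maps.

Two beam representations are used at different scales:

* :func:`beam_field` — monochromatic far-field element summation over the
  tile's 96 x 48 element grid (baffled-piston cosine element factor, uniform
  apodization, focusing delays). This resolves diffraction structure (focal
  widths, side lobes) and is used on small grids.
* :func:`deposition_from_plan` — an energy-conserving converging-beam
  envelope (Gaussian lateral profile with a hyperbolic waist, attenuation
  along the tissue path, steering directivity) that turns a dose plan into a
  volumetric absorbed-power-density map for the bioheat solver. Dither
  patterns enter as time-averaged weights over the pattern points.

Propagation is monochromatic and linear throughout: the dosing regime is
deliberately constrained to linear thermal mechanisms, so no nonlinear or
cavitation modelling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .cuff import TxTile
from .phantoms import LimbPhantom
from .planning import DosePlan, steering_directivity

DEFAULT_SOUND_SPEED_M_S = 1515.0


@dataclass
class BeamSpec:
    """One focused transmission from a tile."""

    tile: TxTile
    focus_mm: np.ndarray
    f_c_mhz: float = 1.0
    sound_speed_m_s: float = DEFAULT_SOUND_SPEED_M_S

    @property
    def wavelength_mm(self) -> float:
        return self.sound_speed_m_s / (self.f_c_mhz * 1e3)

    @property
    def focal_distance_mm(self) -> float:
        return float(np.linalg.norm(self.focus_mm - self.tile.position_mm))

    @property
    def f_number(self) -> float:
        return self.focal_distance_mm / self.tile.aperture_az_mm

    @property
    def steer_deg(self) -> tuple[float, float]:
        return self.tile.steering_angles_to(self.focus_mm)


def beam_field(spec: BeamSpec, points_mm: np.ndarray,
               chunk: int = 4000) -> np.ndarray:
    """Normalized intensity of a focused beam at arbitrary field points.

    Far-field summation of monochromatic point sources at every element with
    focusing delays and a baffled cos(theta) element factor; the result is
    normalized so the focal point has intensity 1. Raises if the focus is
    outside the tile's steering limits (the planner should have filtered it).
    """
    az, el = spec.steer_deg
    if abs(az) > spec.tile.steer_limit_az_deg or abs(el) > spec.tile.steer_limit_el_deg:
        raise ValueError(f"focus at steer ({az:.1f}, {el:.1f}) deg exceeds "
                         "the tile steering limits")
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    elems = spec.tile.element_positions()
    k = 2.0 * np.pi / spec.wavelength_mm
    normal = spec.tile.normal
    # focusing delays: phase advance equal to element-focus path
    r_focus = np.linalg.norm(spec.focus_mm[None, :] - elems, axis=1)

    def _pressure(p: np.ndarray) -> np.ndarray:
        acc = np.zeros(len(p), dtype=np.complex128)
        for s in range(0, len(elems), 1024):
            e = elems[s:s + 1024]
            d = p[:, None, :] - e[None, :, :]
            r = np.linalg.norm(d, axis=2)
            r = np.maximum(r, 1e-6)
            cos_t = np.clip((d @ normal) / r, 0.0, None)
            acc += np.sum(cos_t / r * np.exp(1j * k * (r - r_focus[s:s + 1024])),
                          axis=1)
        return acc

    out = np.empty(len(pts))
    for s in range(0, len(pts), chunk):
        out[s:s + chunk] = np.abs(_pressure(pts[s:s + chunk])) ** 2
    p_f = np.abs(_pressure(spec.focus_mm[None, :]))[0] ** 2
    return out / p_f


SIDELOBE_FLOOR_DB = -100.0


def sidelobe_ratio(intensity: np.ndarray, coords_mm: np.ndarray,
                   focus_mm: np.ndarray, exclusion_radius_mm: float) -> float:
    """Strongest intensity outside the exclusion radius around the focus,
    in dB relative to the focal peak (negative; floored at -100 dB)."""
    pts = np.atleast_2d(coords_mm)
    inten = np.asarray(intensity, dtype=float).ravel()
    d = np.linalg.norm(pts - np.asarray(focus_mm, dtype=float)[None, :], axis=1)
    peak = float(inten[np.argmin(d)])
    outside = inten[d > exclusion_radius_mm]
    if outside.size == 0 or outside.max() <= 0 or peak <= 0:
        return SIDELOBE_FLOOR_DB
    db = 10.0 * np.log10(outside.max() / peak)
    return float(max(db, SIDELOBE_FLOOR_DB))


def fit_directivity_exponents(tile: TxTile | None = None,
                              focal_mm: float = 75.0,
                              f_c_mhz: float = 1.0,
                              grid_deg: float = 5.0) -> tuple[float, float]:
    """Fit cosine-power exponents to the element-summation steering loss.

    Delivered focal power at steer angle theta is taken as peak intensity
    times the 3-dB width in the steer plane (beam broadening partially
    offsets the element-factor amplitude loss); exponents are fitted on a
    ``grid_deg`` grid up to the steering limits.
    """
    from .cuff import TxTile as _T
    if tile is None:
        tile = _T(0, np.zeros(3), np.array([0.0, 0.0, 1.0]),
                  np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))

    def _delivered(axis: np.ndarray, lateral: np.ndarray, ang_deg: float) -> float:
        ang = np.deg2rad(ang_deg)
        focus = tile.position_mm + focal_mm * (
            np.cos(ang) * tile.normal + np.sin(ang) * axis)
        spec = BeamSpec(tile, focus, f_c_mhz)
        offs = np.linspace(-6.0, 6.0, 241)
        pts = focus[None, :] + offs[:, None] * lateral[None, :]
        prof = beam_field(spec, pts)
        peak = prof.max()
        half = prof >= peak / 2.0
        width = offs[half].max() - offs[half].min()
        return float(peak * width)

    def _fit(axis: np.ndarray) -> float:
        lateral = axis
        angles = np.arange(grid_deg, 45.0 + 1e-9, grid_deg)
        base = _delivered(axis, lateral, 0.0)
        ratios = np.array([_delivered(axis, lateral, a) for a in angles]) / base
        cosines = np.cos(np.deg2rad(angles))
        p = np.polyfit(np.log(cosines), np.log(np.maximum(ratios, 1e-6)), 1)[0]
        return float(p)

    return _fit(tile.az_axis), _fit(tile.el_axis)


# ---------------------------------------------------------------------------
# Deposition maps
# ---------------------------------------------------------------------------


@dataclass
class DepositionMap:
    """Volumetric absorbed acoustic power density on a regular grid."""

    q_w_cm3: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3

    def total_absorbed_w(self) -> float:
        return float(self.q_w_cm3.sum() * self.voxel_volume_cm3)

    def absorbed_in_sphere_w(self, center_mm: np.ndarray, diameter_mm: float) -> float:
        nx, ny, nz = self.q_w_cm3.shape
        h = self.voxel_size_mm
        x = self.origin_mm[0] + np.arange(nx) * h
        y = self.origin_mm[1] + np.arange(ny) * h
        z = self.origin_mm[2] + np.arange(nz) * h
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        c = np.asarray(center_mm, dtype=float)
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        inside = r2 <= (diameter_mm / 2.0) ** 2
        return float(self.q_w_cm3[inside].sum() * self.voxel_volume_cm3)

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "a") as fh:
            if "/qdep" in fh:
                del fh["/qdep"]
            ds = fh.create_dataset("/qdep", data=self.q_w_cm3, compression="gzip")
            ds.attrs["voxel_size_mm"] = self.voxel_size_mm
            ds.attrs["origin_mm"] = self.origin_mm
            ds.attrs["units"] = "W/cm^3"


def _envelope_beam_q(grid_pts: np.ndarray, tile_pos: np.ndarray,
                     focus: np.ndarray, p_acoustic_w: float,
                     alpha_np_cm: float, limb_radius_mm: float,
                     wavelength_mm: float, aperture_mm: float) -> np.ndarray:
    """Absorbed power density (W/cm^3) of one focused beam at grid points.

    Converging/diverging Gaussian envelope: waist from the 3-dB focal width
    (f-number x wavelength), hyperbolic spread reaching the aperture radius
    at the tile face, power attenuated along the in-tissue path, heating
    q = 2 alpha I inside the limb only.
    """
    axis = focus - tile_pos
    s_f = float(np.linalg.norm(axis))
    axis = axis / s_f
    f_num = s_f / aperture_mm
    fwhm = f_num * wavelength_mm
    w_f = fwhm / 1.177  # Gaussian 1/e^2-amplitude radius from intensity FWHM
    w_ap = aperture_mm / 2.0
    z_r = s_f / np.sqrt(max((w_ap / w_f) ** 2 - 1.0, 1e-9))

    d = grid_pts - tile_pos
    s = d @ axis
    r2 = np.einsum("ij,ij->i", d, d) - s ** 2
    np.clip(r2, 0.0, None, out=r2)
    w = w_f * np.sqrt(1.0 + ((s - s_f) / z_r) ** 2)

    # tissue path length from the tile to each point's axial station s
    entry = _cylinder_entry_mm(tile_pos, axis, limb_radius_mm)
    d_tissue_cm = np.clip(s - entry, 0.0, None) / 10.0
    pos_r2 = np.einsum("ij,ij->i", grid_pts[:, :2], grid_pts[:, :2])
    in_tissue = pos_r2 <= limb_radius_mm ** 2

    p_s = p_acoustic_w * np.exp(-2.0 * alpha_np_cm * d_tissue_cm)
    w_cm = w / 10.0
    intensity = 2.0 * p_s / (np.pi * w_cm ** 2) * np.exp(-2.0 * r2 / w ** 2)
    q = 2.0 * alpha_np_cm * intensity
    q[~in_tissue] = 0.0
    q[s <= 0] = 0.0
    return q


def _cylinder_entry_mm(origin: np.ndarray, direction: np.ndarray,
                       radius_mm: float) -> float:
    """Ray parameter (mm) at which the ray enters the limb cylinder."""
    p2, d2 = origin[:2], direction[:2]
    a = float(d2 @ d2)
    if a < 1e-12:
        return 0.0
    b = 2.0 * float(p2 @ d2)
    c = float(p2 @ p2) - radius_mm ** 2
    disc = b * b - 4 * a * c
    if disc <= 0:
        return np.inf
    return (-b - np.sqrt(disc)) / (2 * a)


def deposition_from_plan(plan: DosePlan, phantom: LimbPhantom,
                         grid_origin_mm: np.ndarray,
                         grid_shape: tuple[int, int, int],
                         voxel_size_mm: float,
                         cuff=None, f_c_mhz: float = 1.0) -> DepositionMap:
    """Build the dither-averaged absorbed-power-density map for a dose plan.

    Each recruited tile contributes one envelope beam per dither point
    (weight 1/n_points); per-tile emitted acoustic power is the plan's
    weighted output scaled by the steering directivity at emission. Dither
    offsets are interpreted in each beam's lateral frame (electronic
    steering shifts the focus laterally in the beam's own coordinates), so
    the union of beams from around the cuff fills the therapeutic volume.
    """
    tiles = {c.tile_id: c for c in plan.candidates}
    if not tiles and cuff is not None:
        for t in cuff.tiles:
            if t.tile_id in plan.tile_ids:
                tiles[t.tile_id] = None
    h = voxel_size_mm
    nx, ny, nz = grid_shape
    x = grid_origin_mm[0] + np.arange(nx) * h
    y = grid_origin_mm[1] + np.arange(ny) * h
    z = grid_origin_mm[2] + np.arange(nz) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    alpha = plan.alpha_np_cm
    wavelength = 1515.0 / (f_c_mhz * 1e3)
    q = np.zeros(len(pts))
    offsets = plan.dither_points_mm - plan.target_mm[None, :]
    if len(offsets) == 0:
        offsets = np.zeros((1, 3))
    wgt = 1.0 / len(offsets)
    for tid, power in zip(plan.tile_ids, plan.output_powers_w):
        cand = tiles.get(tid)
        if cand is not None:
            tile = cand.tile
        elif cuff is not None:
            tile = next(t for t in cuff.tiles if t.tile_id == tid)
        else:
            raise ValueError("plan lacks tile candidates; pass cuff=")
        if power <= 0:
            continue
        az, el = tile.steering_angles_to(plan.target_mm)
        p_emit = power * steering_directivity(az, el)
        axis = plan.target_mm - tile.position_mm
        axis = axis / np.linalg.norm(axis)
        e1 = np.array([0.0, 0.0, 1.0]) - axis[2] * axis
        n1 = np.linalg.norm(e1)
        e1 = e1 / n1 if n1 > 1e-6 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(axis, e1)
        for off in offsets:
            focus = plan.target_mm + off[0] * e1 + off[1] * e2
            q += wgt * _envelope_beam_q(pts, tile.position_mm, focus, p_emit,
                                        alpha, phantom.radius_mm, wavelength,
                                        tile.aperture_az_mm)
    return DepositionMap(q.reshape(grid_shape), voxel_size_mm,
                         np.asarray(grid_origin_mm, dtype=float),
                         provenance={"tile_ids": plan.tile_ids,
                                     "dither_pattern": plan.dither_pattern,
                                     "n_dither": len(offsets)})
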