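"""Polygonal multi-panel cuff geometry: therapy-tile and imaging-probe
placement, element accounting, skin-intensity power caps, and coverage maps.

The cuff wraps the limb as a regular polygon of 4-7 rigid panels tangent to
the (limb + water-jacket) cylinder. Each panel carries three therapy tiles
(Tx) laid out axially and at most one 3D imaging probe (Ix). All tile normals
point at the limb axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import constants as C
from .phantoms import LimbPhantom

# Therapy-tile architecture: four 52 x 13 mm acoustic modules (96 x 12
# elements each) stacked in elevation and beamformed as one 2D array.
AM_APERTURE_AZ_MM = 52.0
AM_APERTURE_EL_MM = 13.0
AM_ELEMENTS_AZ = 96
AM_ELEMENTS_EL = 12
MODULES_PER_TILE = 4
TILE_ELEMENTS = MODULES_PER_TILE * AM_ELEMENTS_AZ * AM_ELEMENTS_EL  # 4608
TILE_APERTURE_AZ_MM = AM_APERTURE_AZ_MM
TILE_APERTURE_EL_MM = MODULES_PER_TILE * AM_APERTURE_EL_MM          # 52 mm
TILE_APERTURE_AREA_CM2 = MODULES_PER_TILE * (AM_APERTURE_AZ_MM / 10.0) * (AM_APERTURE_EL_MM / 10.0)

THERAPY_FC_MHZ = 1.0
IMAGING_FC_MHZ = 2.5
STEER_LIMIT_AZ_DEG = 60.0
STEER_LIMIT_EL_DEG = 45.0

TILES_PER_PANEL = 3
INTER_TILE_GAP_MM = 2.0
MAX_PROBES = 6          # two 3-probe imaging systems drive at most six probes


@dataclass
class TxTile:
    """One therapy tile: pose, aperture, steering limits and power cap."""

    tile_id: int
    position_mm: np.ndarray      # aperture center
    normal: np.ndarray           # unit, points into the limb
    az_axis: np.ndarray          # unit, azimuth (96-element) direction
    el_axis: np.ndarray          # unit, elevation direction
    f_c_mhz: float = THERAPY_FC_MHZ
    steer_limit_az_deg: float = STEER_LIMIT_AZ_DEG
    steer_limit_el_deg: float = STEER_LIMIT_EL_DEG
    power_cap_w: float = C.SKIN_INTENSITY_LIMIT_W_CM2 * TILE_APERTURE_AREA_CM2

    n_elements: int = TILE_ELEMENTS
    aperture_az_mm: float = TILE_APERTURE_AZ_MM
    aperture_el_mm: float = TILE_APERTURE_EL_MM

    def element_positions(self) -> np.ndarray:
        """World positions (N, 3) of all element centers on the tile face."""
        n_az, n_el = AM_ELEMENTS_AZ, MODULES_PER_TILE * AM_ELEMENTS_EL
        da = self.aperture_az_mm / n_az
        de = self.aperture_el_mm / n_el
        a = (np.arange(n_az) - (n_az - 1) / 2.0) * da
        e = (np.arange(n_el) - (n_el - 1) / 2.0) * de
        A, E = np.meshgrid(a, e, indexing="ij")
        return (self.position_mm[None, :]
                + A.ravel()[:, None] * self.az_axis[None, :]
                + E.ravel()[:, None] * self.el_axis[None, :])

    def steering_angles_to(self, target_mm: np.ndarray) -> tuple[float, float]:
        """(azimuth, elevation) steering angles (deg) toward a world point."""
        d = np.asarray(target_mm, dtype=float) - self.position_mm
        z = float(d @ self.normal)
        a = float(d @ self.az_axis)
        e = float(d @ self.el_axis)
        az = np.degrees(np.arctan2(a, z))
        el = np.degrees(np.arctan2(e, z))
        return az, el


@dataclass
class IxProbe:
    """3D imaging probe with a pyramidal sector image volume."""

    probe_id: int
    position_mm: np.ndarray
    normal: np.ndarray
    az_axis: np.ndarray
    el_axis: np.ndarray
    f_c_mhz: float = IMAGING_FC_MHZ
    sector_az_deg: float = 70.0
    sector_el_deg: float = 70.0
    max_depth_mm: float = 250.0

    def covers(self, point_mm: np.ndarray) -> bool:
        d = np.asarray(point_mm, dtype=float) - self.position_mm
        z = float(d @ self.normal)
        if z <= 0 or np.linalg.norm(d) > self.max_depth_mm:
            return False
        az = np.degrees(np.arctan2(abs(float(d @ self.az_axis)), z))
        el = np.degrees(np.arctan2(abs(float(d @ self.el_axis)), z))
        return az <= self.sector_az_deg / 2 and el <= self.sector_el_deg / 2


@dataclass
class CuffGeometry:
    """Regular-polygon cuff of panels holding therapy tiles and probes."""

    n_panels: int
    limb_diameter_cm: float
    standoff_cm: float
    panel_centers_mm: np.ndarray          # (n, 3) face centers
    panel_normals: np.ndarray             # (n, 3) inward unit normals
    tiles: list[TxTile] = field(default_factory=list)
    probes: list[IxProbe] = field(default_factory=list)

    @property
    def inradius_mm(self) -> float:
        """Apothem of the panel polygon = limb radius + standoff."""
        return self.limb_diameter_cm * 5.0 + self.standoff_cm * 10.0

    def to_json_dict(self) -> dict:
        def pose(o):
            return {"position_mm": o.position_mm.tolist(), "normal": o.normal.tolist(),
                    "az_axis": o.az_axis.tolist(), "el_axis": o.el_axis.tolist()}
        return {
            "n_panels": self.n_panels,
            "limb_diameter_cm": self.limb_diameter_cm,
            "standoff_cm": self.standoff_cm,
            "panel_centers_mm": self.panel_centers_mm.tolist(),
            "panel_normals": self.panel_normals.tolist(),
            "tiles": [dict(tile_id=t.tile_id, power_cap_w=t.power_cap_w, **pose(t))
                      for t in self.tiles],
            "probes": [dict(probe_id=p.probe_id, **pose(p)) for p in self.probes],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "CuffGeometry":
        d = json.loads(Path(path).read_text())
        cuff = cls(d["n_panels"], d["limb_diameter_cm"], d["standoff_cm"],
                   np.asarray(d["panel_centers_mm"]), np.asarray(d["panel_normals"]))
        for t in d["tiles"]:
            cuff.tiles.append(TxTile(t["tile_id"], np.asarray(t["position_mm"]),
                                     np.asarray(t["normal"]), np.asarray(t["az_axis"]),
                                     np.asarray(t["el_axis"]),
                                     power_cap_w=t["power_cap_w"]))
        for p in d["probes"]:
            cuff.probes.append(IxProbe(p["probe_id"], np.asarray(p["position_mm"]),
                                       np.asarray(p["normal"]), np.asarray(p["az_axis"]),
                                       np.asarray(p["el_axis"])))
        return cuff


def build_cuff(n_panels: int, limb_diameter_cm: float,
               standoff_cm: float = 1.0) -> CuffGeometry:
    """Build a regular-polygon cuff tangent to the limb + water jacket.

    Panels sit at the apothem distance (limb radius + standoff) with inward
    normals through the limb axis; three tiles per panel are laid out axially
    with a 2-mm gap, and up to six probes occupy one panel each.
    """
    if n_panels not in (4, 5, 6, 7):
        raise ValueError("n_panels must be one of {4, 5, 6, 7} "
                         "(square through heptagon cross-sections)")
    cuff = CuffGeometry(n_panels, limb_diameter_cm, standoff_cm,
                        np.zeros((n_panels, 3)), np.zeros((n_panels, 3)))
    apothem = cuff.inradius_mm
    z_hat = np.array([0.0, 0.0, 1.0])
    tile_pitch = TILE_APERTURE_AZ_MM + INTER_TILE_GAP_MM
    tid = pid = 0
    for k in range(n_panels):
        phi = 2.0 * np.pi * k / n_panels
        outward = np.array([np.cos(phi), np.sin(phi), 0.0])
        center = apothem * outward
        normal = -outward
        cuff.panel_centers_mm[k] = center
        cuff.panel_normals[k] = normal
        el_axis = np.cross(normal, z_hat)  # circumferential
        for j in range(TILES_PER_PANEL):
            z_off = (j - (TILES_PER_PANEL - 1) / 2.0) * tile_pitch
            cuff.tiles.append(TxTile(tid, center + z_off * z_hat, normal.copy(),
                                     z_hat.copy(), el_axis.copy()))
            tid += 1
        if pid < MAX_PROBES:
            # beside the central tile, where the sector overlaps the region
            # the therapy tiles can reach
            probe_z = 30.0
            cuff.probes.append(IxProbe(pid, center + probe_z * z_hat, normal.copy(),
                                       z_hat.copy(), el_axis.copy()))
            pid += 1
    return cuff


def total_elements(cuff: CuffGeometry) -> int:
    """Total therapeutic array elements across the cuff (4608 per tile)."""
    return sum(t.n_elements for t in cuff.tiles)


def tile_power_cap(tile: TxTile, skin_intensity_limit_w_cm2: float) -> float:
    """Acoustic power cap for one tile from the skin-intensity limit.

    The cap is the limit times the full tile aperture area (4 x 5.2 x 1.3
    cm^2): the largest output for which even an unfocused beam cannot exceed
    the skin intensity ceiling directly under the tile.
    """
    if skin_intensity_limit_w_cm2 <= 0:
        raise ValueError("intensity limit must be positive")
    return skin_intensity_limit_w_cm2 * TILE_APERTURE_AREA_CM2


@dataclass
class CoverageReport:
    """Per-voxel imaging-sector and therapy-steering coverage of the tissue."""

    voxel_size_mm: float
    origin_mm: np.ndarray
    probe_counts: np.ndarray     # sectors covering each tissue voxel
    tile_counts: np.ndarray      # tiles with the voxel in steering range
    tissue_mask: np.ndarray
    deep_two_probe_fraction: float  # tissue at depth >= 5 cm seen by >= 2 probes


def coverage(cuff: CuffGeometry, phantom: LimbPhantom,
             voxel_size_mm: float = 5.0,
             focal_range_mm: tuple[float, float] = (10.0, 160.0)) -> CoverageReport:
    """Count, per tissue voxel, covering image sectors and in-range tiles.

    Bone occlusion removes a probe's or tile's view of a voxel. Reports the
    fraction of tissue at depth >= 5 cm covered by at least two probes.
    """
    if cuff.inradius_mm < phantom.radius_mm:
        raise ValueError("cuff does not enclose the phantom")
    R = phantom.radius_mm
    zr = phantom.length_cm * 5.0
    h = voxel_size_mm
    xs = np.arange(-R, R + h, h)
    zs = np.arange(-zr, zr + h, h)
    X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    tissue = np.hypot(pts[:, 0], pts[:, 1]) <= R

    def _visible(src: np.ndarray, p: np.ndarray) -> bool:
        return not any(b.blocks_segment(src, p) for b in phantom.bones)

    probe_counts = np.zeros(len(pts), dtype=np.int16)
    tpts = pts[tissue]
    for probe in cuff.probes:
        covered = np.fromiter((probe.covers(p) and _visible(probe.position_mm, p)
                               for p in tpts), dtype=bool, count=len(tpts))
        probe_counts[tissue] += covered

    tile_counts = np.zeros(len(pts), dtype=np.int16)
    for tile in cuff.tiles:
        ok = np.zeros(len(tpts), dtype=bool)
        for i, p in enumerate(tpts):
            az, el = tile.steering_angles_to(p)
            dist = np.linalg.norm(p - tile.position_mm)
            ok[i] = (abs(az) <= tile.steer_limit_az_deg
                     and abs(el) <= tile.steer_limit_el_deg
                     and focal_range_mm[0] <= dist <= focal_range_mm[1]
                     and _visible(tile.position_mm, p))
        tile_counts[tissue] += ok

    depth_cm = (R - np.hypot(tpts[:, 0], tpts[:, 1])) / 10.0
    deep = depth_cm >= 5.0
    if deep.any():
        frac = float(np.mean(probe_counts[tissue][deep] >= 2))
    else:
        frac = float("nan")
    shape = X.shape
    return CoverageReport(h, np.array([-R, -R, -zr]),
                          probe_counts.reshape(shape), tile_counts.reshape(shape),
                          tissue.reshape(shape), frac)
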