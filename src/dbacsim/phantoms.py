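"""Synthetic limb phantoms: tissue cylinders, vascular trees, pulsatile flow
waveforms, and the imaging observables (compounded power-Doppler volumes and
spectral-Doppler gate samples) consumed by the detection pipeline.

Conventions
-----------
Right-handed coordinates in millimeters; the limb axis is +z with the origin
at the limb-axis midpoint. Voxel indices are 0-based with half-open extents.
All randomness flows through explicit integer seeds; identical seeds yield
bit-identical phantoms, waveforms and volumes.

The power-Doppler renderer is geometric: lumen rasterization scaled by a
Doppler-angle factor per imaging probe, compounded by taking the best view
across probes, plus additive Gaussian noise. It is intended to exercise the
detection and localization logic, not to emulate RF-level ultrasound physics.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from . import constants as C

# ---------------------------------------------------------------------------
# Tissue properties
# ---------------------------------------------------------------------------


@dataclass
class TissueProperties:
    """Acoustic and thermal bulk properties of the soft-tissue surrogate.

    Defaults describe the gel tissue-mimicking material used for phantom
    work: 1515 m/s sound speed, soft-tissue-like attenuation with linear
    frequency scaling, and documented soft-tissue thermal surrogates.
    Perfusion is zero in phantom mode.
    """

    sound_speed_m_s: float = 1515.0
    attenuation_np_cm_mhz: float = 0.05   # Np/cm at 1 MHz, scales ~ f**freq_exponent
    freq_exponent: float = 1.0
    density_kg_m3: float = 1050.0
    specific_heat_j_kgk: float = 3600.0
    conductivity_w_mk: float = 0.55
    perfusion_1_s: float = 0.0
    baseline_temperature_c: float = 37.0

    def __post_init__(self) -> None:
        if not (1400.0 <= self.sound_speed_m_s <= 1650.0):
            raise ValueError("sound speed must lie in [1400, 1650] m/s")
        for name in ("attenuation_np_cm_mhz", "density_kg_m3",
                     "specific_heat_j_kgk", "conductivity_w_mk"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.perfusion_1_s < 0:
            raise ValueError("perfusion must be >= 0")

    def attenuation_np_cm(self, f_mhz: float) -> float:
        """Attenuation coefficient (Np/cm) at frequency ``f_mhz``."""
        return self.attenuation_np_cm_mhz * f_mhz ** self.freq_exponent


WATER_SOUND_SPEED_M_S = 1482.0  # degassed water in the coupling jacket, ~20 degC


# ---------------------------------------------------------------------------
# Flow waveforms
# ---------------------------------------------------------------------------

_N_WAVEFORM_SAMPLES = 256


def _systolic_pulse_shape(n: int) -> np.ndarray:
    """Normalized arterial pulse shape over one cycle: sharp systolic upstroke
    with a dicrotic shoulder, scaled to [0, 1]."""
    u = np.linspace(0.0, 1.0, n, endpoint=False)
    s = np.exp(-0.5 * ((u - 0.18) / 0.07) ** 2) + 0.35 * np.exp(-0.5 * ((u - 0.45) / 0.10) ** 2)
    s -= s.min()
    s /= s.max()
    return s


@dataclass
class FlowWaveform:
    """One cardiac cycle of centerline blood velocity at a vessel site."""

    time_s: np.ndarray
    velocity_cm_s: np.ndarray
    profile: str = "normal"   # normal | bleeder | irregular-slow

    @property
    def v_systole(self) -> float:
        return float(np.max(self.velocity_cm_s))

    @property
    def v_diastole(self) -> float:
        return float(np.min(self.velocity_cm_s))

    @property
    def mean_velocity(self) -> float:
        return float(np.mean(self.velocity_cm_s))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "velocity_cm_s"])
            for t, v in zip(self.time_s, self.velocity_cm_s):
                w.writerow([f"{t:.6f}", f"{v:.6f}"])

    @classmethod
    def from_csv(cls, path: str | Path, profile: str = "normal") -> "FlowWaveform":
        t, v = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                t.append(float(row["time_s"]))
                v.append(float(row["velocity_cm_s"]))
        return cls(np.asarray(t), np.asarray(v), profile)


def make_flow_waveform(profile: str, mean_velocity_cm_s: float,
                       heart_rate_bpm: float = 60.0, seed: int = 0) -> FlowWaveform:
    """Construct a pulsatile flow waveform with a prescribed mean velocity.

    The resistive index RI = (V_sys - V_dia)/V_sys is drawn per-profile and
    the waveform built as V_dia + (V_sys - V_dia) * pulse(t), which pins the
    constructed RI exactly:

    * ``normal``  draws RI in [0.82, 0.95] (high peripheral resistance),
    * ``bleeder`` draws RI in [0.55, 0.70] (vented branch, sustained
      diastolic run-off),
    * ``irregular-slow`` emulates the slow (<= 4 cm/s) bleeders whose
      waveforms were aperiodic and poorly described by RI.
    """
    if mean_velocity_cm_s <= 0:
        raise ValueError("mean velocity must be positive")
    if profile not in ("normal", "bleeder", "irregular-slow"):
        raise ValueError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(seed)
    period = 60.0 / heart_rate_bpm
    t = np.linspace(0.0, period, _N_WAVEFORM_SAMPLES, endpoint=False)
    pulse = _systolic_pulse_shape(_N_WAVEFORM_SAMPLES)
    pulse_mean = float(np.mean(pulse))

    if profile == "irregular-slow":
        mean_v = min(mean_velocity_cm_s, 4.0)
        # Aperiodic modulation: smooth random walk with non-harmonic content.
        base = rng.normal(0.0, 1.0, _N_WAVEFORM_SAMPLES)
        kernel = np.exp(-0.5 * (np.arange(-32, 33) / 10.0) ** 2)
        smooth = np.convolve(base, kernel / kernel.sum(), mode="same")
        smooth -= smooth.min()
        floor = rng.uniform(0.1, 0.7)        # erratic diastolic floor
        v = floor * mean_v + smooth * (1.2 * mean_v / max(smooth.max(), 1e-9))
        v *= mean_v / np.mean(v)
        v = np.clip(v, 0.0, None)
        return FlowWaveform(t, v, profile)

    if profile == "normal":
        ri = rng.uniform(0.82, 0.95)
    else:  # bleeder
        ri = rng.uniform(0.55, 0.70)
    # mean = V_sys * ((1 - RI) + RI * mean(pulse))  =>  solve for V_sys
    v_sys = mean_velocity_cm_s / ((1.0 - ri) + ri * pulse_mean)
    v_dia = (1.0 - ri) * v_sys
    v = v_dia + (v_sys - v_dia) * pulse
    return FlowWaveform(t, v, profile)


# ---------------------------------------------------------------------------
# Vessel trees
# ---------------------------------------------------------------------------

TC_MARKER_ARCLENGTH_MM = 20.0  # thermocouple junction distance downstream of bifurcation


@dataclass
class VesselBranch:
    """A polyline branch of the vascular tree."""

    branch_id: int
    points: np.ndarray            # (n, 3) mm, ordered in flow direction
    radius_mm: float
    flag: str = "normal"          # normal | bleeder
    waveform: Optional[FlowWaveform] = None

    @property
    def length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def point_at_arclength(self, s_mm: float) -> np.ndarray:
        """Point on the branch centerline at arclength ``s_mm`` from its start."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = float(np.clip(s_mm, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg) - 1)
        f = (s - cum[i]) / max(seg[i], 1e-12)
        return self.points[i] + f * (self.points[i + 1] - self.points[i])


@dataclass
class VesselTree:
    """Centerline-graph ground truth for the phantom vasculature.

    Branches meet at bifurcation points; bleeder branches are straight vented
    stubs terminating in a leaf, each carrying a thermocouple marker 20 mm
    downstream of its bifurcation.
    """

    branches: list[VesselBranch] = field(default_factory=list)
    bifurcations: list[np.ndarray] = field(default_factory=list)
    # branch ids feeding each bifurcation: {bif index: (parent_id, child_ids)}
    topology: dict[int, tuple[int, list[int]]] = field(default_factory=dict)

    @property
    def tc_markers(self) -> dict[int, np.ndarray]:
        out = {}
        for b in self.branches:
            if b.flag == "bleeder":
                out[b.branch_id] = b.point_at_arclength(TC_MARKER_ARCLENGTH_MM)
        return out

    @property
    def bleeder_ids(self) -> list[int]:
        return [b.branch_id for b in self.branches if b.flag == "bleeder"]

    def branch(self, branch_id: int) -> VesselBranch:
        for b in self.branches:
            if b.branch_id == branch_id:
                return b
        raise KeyError(branch_id)

    def nearest_branch(self, point_mm: np.ndarray) -> tuple[int, float]:
        """(branch id, distance mm) of the centerline nearest to ``point_mm``."""
        best_id, best_d = -1, np.inf
        p = np.asarray(point_mm, dtype=float)
        for b in self.branches:
            d = _point_polyline_distance(p, b.points)
            if d < best_d:
                best_id, best_d = b.branch_id, d
        return best_id, best_d

    def bounding_box(self, margin_mm: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
        pts = np.vstack([b.points for b in self.branches])
        return pts.min(axis=0) - margin_mm, pts.max(axis=0) + margin_mm

    def to_json_dict(self) -> dict:
        return {
            "branches": [
                {
                    "branch_id": b.branch_id,
                    "points_mm": b.points.tolist(),
                    "radius_mm": b.radius_mm,
                    "flag": b.flag,
                    "waveform": None if b.waveform is None else {
                        "profile": b.waveform.profile,
                        "time_s": b.waveform.time_s.tolist(),
                        "velocity_cm_s": b.waveform.velocity_cm_s.tolist(),
                    },
                }
                for b in self.branches
            ],
            "bifurcations_mm": [p.tolist() for p in self.bifurcations],
            "topology": {str(k): [v[0], v[1]] for k, v in self.topology.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "VesselTree":
        branches = []
        for bd in d["branches"]:
            wf = None
            if bd.get("waveform"):
                wf = FlowWaveform(np.asarray(bd["waveform"]["time_s"]),
                                  np.asarray(bd["waveform"]["velocity_cm_s"]),
                                  bd["waveform"]["profile"])
            branches.append(VesselBranch(bd["branch_id"], np.asarray(bd["points_mm"]),
                                         bd["radius_mm"], bd["flag"], wf))
        bifs = [np.asarray(p) for p in d["bifurcations_mm"]]
        topo = {int(k): (v[0], list(v[1])) for k, v in d.get("topology", {}).items()}
        return cls(branches, bifs, topo)


def _point_polyline_distance(p: np.ndarray, poly: np.ndarray) -> float:
    a, b = poly[:-1], poly[1:]
    ab = b - a
    denom = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-12)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


# ---------------------------------------------------------------------------
# Limb phantom
# ---------------------------------------------------------------------------


@dataclass
class BoneCylinder:
    """Cylindrical bone surrogate parallel to the limb axis."""

    center_xy_mm: np.ndarray   # (2,) axis position in the x-y plane
    radius_mm: float
    z_range_mm: tuple[float, float] = (-1e9, 1e9)

    def blocks_segment(self, p: np.ndarray, q: np.ndarray) -> bool:
        """True if the segment p->q intersects the bone cylinder."""
        p2, q2 = p[:2] - self.center_xy_mm, q[:2] - self.center_xy_mm
        d = q2 - p2
        a = float(d @ d)
        if a < 1e-12:
            return bool(p2 @ p2 <= self.radius_mm ** 2)
        t = float(np.clip(-(p2 @ d) / a, 0.0, 1.0))
        closest = p2 + t * d
        if closest @ closest > self.radius_mm ** 2:
            return False
        z = p[2] + t * (q[2] - p[2])
        return self.z_range_mm[0] <= z <= self.z_range_mm[1]


@dataclass
class LimbPhantom:
    """Cylindrical tissue domain with embedded vasculature and bone surrogates."""

    diameter_cm: float
    length_cm: float
    tissue: TissueProperties
    vessel_tree: VesselTree
    bones: list[BoneCylinder] = field(default_factory=list)
    water_jacket_thickness_cm: float = 1.0

    @property
    def radius_mm(self) -> float:
        return self.diameter_cm * 10.0 / 2.0

    @property
    def max_target_depth_cm(self) -> float:
        return self.diameter_cm / 2.0

    def contains(self, point_mm: np.ndarray) -> bool:
        p = np.asarray(point_mm, dtype=float)
        r = np.hypot(p[0], p[1])
        return r <= self.radius_mm and abs(p[2]) <= self.length_cm * 5.0

    def depth_of(self, point_mm: np.ndarray) -> float:
        """Depth below the skin surface (cm) of an interior point."""
        p = np.asarray(point_mm, dtype=float)
        return (self.radius_mm - np.hypot(p[0], p[1])) / 10.0

    def save(self, json_path: str | Path) -> None:
        d = {
            "diameter_cm": self.diameter_cm,
            "length_cm": self.length_cm,
            "water_jacket_thickness_cm": self.water_jacket_thickness_cm,
            "tissue": vars(self.tissue),
            "bones": [
                {"center_xy_mm": b.center_xy_mm.tolist(), "radius_mm": b.radius_mm,
                 "z_range_mm": list(b.z_range_mm)}
                for b in self.bones
            ],
            "vessel_tree": self.vessel_tree.to_json_dict(),
        }
        Path(json_path).write_text(json.dumps(d))

    @classmethod
    def load(cls, json_path: str | Path) -> "LimbPhantom":
        d = json.loads(Path(json_path).read_text())
        return cls(
            diameter_cm=d["diameter_cm"],
            length_cm=d["length_cm"],
            tissue=TissueProperties(**d["tissue"]),
            vessel_tree=VesselTree.from_json_dict(d["vessel_tree"]),
            bones=[BoneCylinder(np.asarray(b["center_xy_mm"]), b["radius_mm"],
                                tuple(b["z_range_mm"])) for b in d["bones"]],
            water_jacket_thickness_cm=d["water_jacket_thickness_cm"],
        )


def make_limb_phantom(diameter_cm: float, n_bifurcations: int, n_bleeders: int,
                      seed: int, length_cm: float = 20.0,
                      tissue: Optional[TissueProperties] = None,
                      with_bone: bool = True,
                      slow_bleeders: bool = False,
                      bleeder_radius_mm: Optional[float] = None) -> LimbPhantom:
    """Generate a reproducible limb phantom with an embedded vascular tree.

    The tree is grown by recursive binary branching from a main artery running
    near the limb axis. Child radii follow a Murray-like law with exponent 2.5;
    branching angles scale down with limb diameter (the narrow branching of
    small limbs is a documented detection failure mode). Bleeder branches are
    straight vented stubs of length >= 30 mm so the 20-mm thermocouple marker
    fits on the branch. When ``n_bleeders >= 1`` the first bleeder bifurcation
    is placed deeper than ``diameter/4``.
    """
    if not (C.MIN_LIMB_DIAMETER_CM <= diameter_cm <= C.MAX_LIMB_DIAMETER_CM):
        raise ValueError(
            f"limb diameter {diameter_cm} cm outside the supported radius-of-"
            f"curvature range MinRC={C.MIN_RC_CM} cm to MaxRC={C.MAX_RC_CM} cm")
    if n_bleeders > n_bifurcations:
        raise ValueError("n_bleeders cannot exceed n_bifurcations")
    rng = np.random.default_rng(seed)
    tissue = tissue or TissueProperties()
    R = diameter_cm * 10.0 / 2.0
    L = length_cm * 10.0

    tree = VesselTree()
    next_id = [0]

    def _add_branch(points: np.ndarray, radius: float, flag: str,
                    waveform: FlowWaveform) -> int:
        bid = next_id[0]
        next_id[0] += 1
        tree.branches.append(VesselBranch(bid, points, radius, flag, waveform))
        return bid

    # Main artery: gentle sinusoid near the axis, running along +z.
    z0, z1 = -0.42 * L, 0.42 * L
    nseg = 40
    zs = np.linspace(z0, z1, nseg)
    amp = min(0.12 * R, 4.0)
    phase = rng.uniform(0, 2 * np.pi)
    main_pts = np.stack([amp * np.sin(2 * np.pi * zs / L + phase),
                         amp * np.cos(2 * np.pi * zs / L + phase), zs], axis=1)
    root_radius = max(1.5, min(2.5, 0.02 * R * 10))  # 1.5-2.5 mm main artery
    mean_v = rng.uniform(15.0, 30.0)
    root_wf = make_flow_waveform("normal", mean_v, 60.0, int(rng.integers(2**31)))

    # Bifurcation sites spread along the main artery.
    n_bif = max(n_bifurcations, 1) if n_bifurcations > 0 else 0
    bif_fracs = np.linspace(0.2, 0.8, n_bif) if n_bif else np.array([])
    # Branching half-angle scales with limb diameter: ~15 deg at 7.5 cm up to
    # ~35 deg at 25 cm.
    half_angle = np.deg2rad(15.0 + 20.0 * (diameter_cm - 7.5) / 17.5)

    root_id = _add_branch(main_pts, root_radius, "normal", root_wf)

    bleeders_left = n_bleeders
    for bi, frac in enumerate(bif_fracs):
        idx = int(frac * (nseg - 1))
        origin = main_pts[idx]
        tangent = main_pts[min(idx + 1, nseg - 1)] - main_pts[max(idx - 1, 0)]
        tangent = tangent / np.linalg.norm(tangent)
        make_bleeder = bleeders_left > 0
        # Daughter directions: tilted off the parent tangent by the branching
        # angle, with outward-biased lateral components so the daughters
        # separate from the parent lumen instead of running alongside it.
        perp1 = np.cross(tangent, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp1) < 1e-6:
            perp1 = np.array([1.0, 0.0, 0.0])
        perp1 /= np.linalg.norm(perp1)
        perp2 = np.cross(tangent, perp1)
        out_xy = origin[:2].copy()
        if np.linalg.norm(out_xy) < 1.0:
            th = rng.uniform(0, 2 * np.pi)
            out_xy = np.array([np.cos(th), np.sin(th)])
        outward = np.array([out_xy[0], out_xy[1], 0.0])
        outward -= (outward @ tangent) * tangent
        outward /= max(np.linalg.norm(outward), 1e-9)
        az0 = float(np.arctan2(outward @ perp2, outward @ perp1))
        child_radius = root_radius / 2.0 ** (1.0 / 2.5)  # Murray-like split
        child_radius = max(child_radius, C.MSR_MM / 2.0)
        for ci in range(2):
            # lateral azimuths at +/- ~60 deg around the outward direction
            az = az0 + (1 if ci == 0 else -1) * np.deg2rad(60.0 + rng.uniform(-15, 15))
            direction = (np.cos(half_angle) * tangent
                         + np.sin(half_angle) * (np.cos(az) * perp1 + np.sin(az) * perp2))
            direction /= np.linalg.norm(direction)
            is_bleeder = make_bleeder and ci == 0
            length = rng.uniform(32.0, 45.0) if is_bleeder else rng.uniform(20.0, 35.0)

            def _max_run(o: np.ndarray, u: np.ndarray) -> float:
                """Largest straight run from o along u staying inside the
                tissue cylinder (radial 0.88 R, axial 0.46 L)."""
                t_ax = np.inf
                if abs(u[2]) > 1e-9:
                    t_ax = ((0.46 * L if u[2] > 0 else -0.46 * L) - o[2]) / u[2]
                a = u[0] ** 2 + u[1] ** 2
                t_rad = np.inf
                if a > 1e-12:
                    b = 2.0 * (o[0] * u[0] + o[1] * u[1])
                    cc = o[0] ** 2 + o[1] ** 2 - (0.88 * R) ** 2
                    disc = b * b - 4 * a * cc
                    if disc > 0:
                        t_rad = (-b + np.sqrt(disc)) / (2 * a)
                return max(min(t_ax, t_rad), 0.0)

            run = _max_run(origin, direction)
            min_len = 31.0 if is_bleeder else 12.0
            if run < min_len:
                # steer more axially so the branch fits inside the cylinder
                direction = 0.8 * tangent + 0.2 * direction
                direction /= np.linalg.norm(direction)
                run = _max_run(origin, direction)
            length = min(length, 0.97 * run)
            npts = 12
            pts = origin + np.outer(np.linspace(0, length, npts), direction)
            if is_bleeder:
                if bleeder_radius_mm is not None:
                    radius = max(bleeder_radius_mm, C.MSR_MM / 2.0)
                else:
                    radius = max(rng.uniform(0.4, 0.9) * child_radius, C.MSR_MM / 2.0)
                profile = "irregular-slow" if slow_bleeders else "bleeder"
                wf_mean = min(mean_v * 0.5, 4.0) if slow_bleeders else mean_v * rng.uniform(0.5, 0.9)
                wf = make_flow_waveform(profile, wf_mean, 60.0, int(rng.integers(2**31)))
                flag = "bleeder"
            else:
                radius = child_radius
                wf = make_flow_waveform("normal", mean_v * rng.uniform(0.6, 1.0),
                                        60.0, int(rng.integers(2**31)))
                flag = "normal"
            bid = _add_branch(pts, radius, flag, wf)
            if bi in tree.topology:
                tree.topology[bi][1].append(bid)
            else:
                tree.topology[bi] = (root_id, [bid])
        tree.bifurcations.append(origin.copy())
        if make_bleeder:
            bleeders_left -= 1

    bones = []
    if with_bone:
        # One bone surrogate offset from the axis, clear of the vessel tree.
        bone_r = 0.12 * R
        offset = 0.55 * R
        ang = phase + np.pi  # opposite side from the main-artery sinusoid bias
        bones.append(BoneCylinder(np.array([offset * np.cos(ang), offset * np.sin(ang)]),
                                  bone_r))

    phantom = LimbPhantom(diameter_cm, length_cm, tissue, tree, bones)

    # The main artery (and hence every bifurcation) runs within ~0.15 R of
    # the axis, so bleeder branch points near their bifurcations sit deeper
    # than diameter/4; verify on the thermocouple markers.
    if n_bleeders >= 1:
        depths = [phantom.depth_of(p) for p in tree.tc_markers.values()]
        if not any(d > diameter_cm / 4.0 for d in depths):
            raise RuntimeError("generated tree has no bleeder deeper than "
                               "diameter/4; adjust the seed")
    return phantom


# ---------------------------------------------------------------------------
# Power-Doppler rendering
# ---------------------------------------------------------------------------


@dataclass
class DopplerVolume:
    """Compounded 3D power-Doppler intensity volume (arbitrary units)."""

    grid: np.ndarray          # (nx, ny, nz) float32 intensity >= 0
    voxel_size_mm: float
    origin_mm: np.ndarray     # world position of voxel (0,0,0) center
    modality: str = "P-mode"

    def world_to_index(self, p_mm: np.ndarray) -> tuple[int, int, int]:
        idx = np.round((np.asarray(p_mm) - self.origin_mm) / self.voxel_size_mm).astype(int)
        return tuple(idx)

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin_mm + np.asarray(idx, dtype=float) * self.voxel_size_mm

    def save_h5(self, path: str | Path, dataset: str = "/pmode") -> None:
        with h5py.File(path, "a") as fh:
            if dataset in fh:
                del fh[dataset]
            ds = fh.create_dataset(dataset, data=self.grid, compression="gzip")
            ds.attrs["voxel_size_mm"] = self.voxel_size_mm
            ds.attrs["origin_mm"] = self.origin_mm
            ds.attrs["modality"] = self.modality

    @classmethod
    def load_h5(cls, path: str | Path, dataset: str = "/pmode") -> "DopplerVolume":
        with h5py.File(path, "r") as fh:
            ds = fh[dataset]
            return cls(ds[()], float(ds.attrs["voxel_size_mm"]),
                       np.asarray(ds.attrs["origin_mm"]),
                       str(ds.attrs.get("modality", "P-mode")))


DOPPLER_INTENSITY_GAIN = 20.0      # a.u. per (cm/s) of detected flow
DOPPLER_ANGLE_FLOOR = 0.3          # |cos(beam, flow)| giving usable Doppler signal
DEFAULT_DOPPLER_NOISE_SD = 2.0     # additive noise, a.u.


def rasterize_lumen(tree: VesselTree, voxel_size_mm: float,
                    origin_mm: np.ndarray, shape: tuple[int, int, int]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize the vessel lumen onto a regular grid.

    Returns ``(mask, speed, flow_dir)``: a boolean lumen mask, the branch mean
    flow speed (cm/s) per lumen voxel, and the unit flow direction per voxel.
    """
    mask = np.zeros(shape, dtype=bool)
    speed = np.zeros(shape, dtype=np.float32)
    fdir = np.zeros(shape + (3,), dtype=np.float32)
    h = voxel_size_mm
    for b in tree.branches:
        v_mean = b.waveform.mean_velocity if b.waveform is not None else 0.0
        for a, c in zip(b.points[:-1], b.points[1:]):
            seg = c - a
            seg_len = np.linalg.norm(seg)
            if seg_len < 1e-9:
                continue
            u = seg / seg_len
            lo = np.minimum(a, c) - b.radius_mm - h
            hi = np.maximum(a, c) + b.radius_mm + h
            i0 = np.maximum(np.floor((lo - origin_mm) / h).astype(int), 0)
            i1 = np.minimum(np.ceil((hi - origin_mm) / h).astype(int) + 1, shape)
            if np.any(i0 >= i1):
                continue
            xs = origin_mm[0] + np.arange(i0[0], i1[0]) * h
            ys = origin_mm[1] + np.arange(i0[1], i1[1]) * h
            zs = origin_mm[2] + np.arange(i0[2], i1[2]) * h
            X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
            px = np.stack([X - a[0], Y - a[1], Z - a[2]], axis=-1)
            t = np.clip(px @ u, 0.0, seg_len)
            closest = np.multiply.outer(t, u)
            d2 = np.sum((px - closest) ** 2, axis=-1)
            inside = d2 <= b.radius_mm ** 2
            sub = (slice(i0[0], i1[0]), slice(i0[1], i1[1]), slice(i0[2], i1[2]))
            mask[sub] |= inside
            spd = speed[sub]
            upd = inside & (spd < v_mean)
            spd[upd] = v_mean
            speed[sub] = spd
            fd = fdir[sub]
            fd[upd] = u.astype(np.float32)
            fdir[sub] = fd
    return mask, speed, fdir


def render_power_doppler(phantom: LimbPhantom, cuff, voxel_size_mm: float = 0.25,
                         noise_seed: int = 0,
                         noise_sd: float = DEFAULT_DOPPLER_NOISE_SD,
                         region: Optional[tuple[np.ndarray, np.ndarray]] = None,
                         ) -> DopplerVolume:
    """Render a compounded 360-degree power-Doppler volume of the phantom.

    Per-probe Doppler-angle dropout is simulated by scaling lumen intensity by
    ``|cos(theta)|`` between the probe beam direction and the local flow
    direction; compounding takes the best view across probes, so dropout is
    removed whenever at least one probe sees the flow at ``|cos| >= 0.3``.
    Additive Gaussian noise (clipped at zero) models the P-mode noise floor.

    ``region`` restricts the rendered box (defaults to the vessel-tree
    bounding box padded by 3 mm — rendering the full limb at sub-MSR voxels
    is wasteful for detection work).
    """
    from .cuff import CuffGeometry  # local import to avoid a cycle

    if isinstance(cuff, CuffGeometry) and cuff.inradius_mm < phantom.radius_mm:
        raise ValueError("cuff does not enclose the phantom")
    if region is None:
        lo, hi = phantom.vessel_tree.bounding_box(margin_mm=3.0)
    else:
        lo, hi = region
    shape = tuple(np.maximum(np.ceil((hi - lo) / voxel_size_mm).astype(int), 1))
    mask, speed, fdir = rasterize_lumen(phantom.vessel_tree, voxel_size_mm, lo, shape)

    probes = list(getattr(cuff, "probes", []) or [])
    if probes:
        idx = np.argwhere(mask)
        pts = lo + idx * voxel_size_mm
        flow_u = fdir[mask]
        best_cos = np.zeros(len(idx), dtype=np.float32)
        for probe in probes:
            beam = pts - probe.position_mm
            beam /= np.maximum(np.linalg.norm(beam, axis=1, keepdims=True), 1e-9)
            cosv = np.abs(np.einsum("ij,ij->i", beam, flow_u))
            np.maximum(best_cos, cosv.astype(np.float32), out=best_cos)
        angle_factor = np.where(best_cos >= DOPPLER_ANGLE_FLOOR, best_cos, best_cos * 0.1)
        intensity = np.zeros(shape, dtype=np.float32)
        intensity[mask] = DOPPLER_INTENSITY_GAIN * speed[mask] * angle_factor
    else:
        intensity = DOPPLER_INTENSITY_GAIN * speed

    if noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        intensity = intensity + rng.normal(0.0, noise_sd, shape).astype(np.float32)
        np.clip(intensity, 0.0, None, out=intensity)
    return DopplerVolume(intensity.astype(np.float32), voxel_size_mm, lo.astype(float))


# ---------------------------------------------------------------------------
# Spectral-Doppler sampling
# ---------------------------------------------------------------------------

GATE_CAPTURE_RADIUS_MM = 2.0


class NoSignal:
    """Sentinel result for a spectral gate placed away from any vessel."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NoSignal()"


NO_SIGNAL = NoSignal()


def sample_spectral_doppler(gate_location_mm: np.ndarray, tree: VesselTree,
                            noise_seed: int = 0, noise_sd: float = 0.05,
                            capture_radius_mm: float = GATE_CAPTURE_RADIUS_MM
                            ) -> FlowWaveform | NoSignal:
    """Sample the spectral-Doppler waveform at a gate location.

    Returns the underlying branch waveform corrupted by multiplicative
    speckle-like noise, or :data:`NO_SIGNAL` if the gate is farther than the
    capture radius from every branch centerline.
    """
    bid, dist = tree.nearest_branch(gate_location_mm)
    if bid < 0 or dist > capture_radius_mm:
        return NO_SIGNAL
    wf = tree.branch(bid).waveform
    if wf is None:
        return NO_SIGNAL
    v = wf.velocity_cm_s.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        v = v * (1.0 + rng.normal(0.0, noise_sd, v.shape))
    return FlowWaveform(wf.time_s.copy(), v, wf.profile)
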