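"""Time-of-flight array registration: simulate sub-aperture arrival times
through the two-layer (water jacket + tissue) medium and recover array
positions, orientations and the layer sound speeds by multilateration.

Each array face carries five 3 x 3 mm sub-apertures (four inset corners plus
the center). Arrival times follow a two-segment straight-ray model: the chord
of the emitter-receiver segment inside the limb cylinder travels at the
tissue speed, the remainder at the water speed, plus Gaussian timing jitter.
The solver jointly fits all sub-aperture positions and the two speeds by
sparse nonlinear least squares, initialized from the polygon prior, and
derives each array's pose from the best-fit rigid frame over its five
sub-apertures.

With the forward and inverse models sharing the straight two-segment ray,
Snell bending at the water/tissue boundary cancels out of the error metrics
and is not modelled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares

from .cuff import CuffGeometry, IxProbe, TxTile
from .phantoms import WATER_SOUND_SPEED_M_S, LimbPhantom

DEFAULT_JITTER_S = 1.0 / 2.5e6   # one carrier period at the 2.5-MHz imaging frequency
SUB_APERTURE_MM = 3.0
PROBE_APERTURE_MM = 20.0         # footprint used for probe sub-aperture spread


def _sub_aperture_offsets(half_az: float, half_el: float) -> np.ndarray:
    """Local (az, el) offsets of the five sub-apertures: corners + center."""
    f = 0.8  # corners inset to keep the 3-mm patches on the face
    return np.array([
        [0.0, 0.0],
        [+f * half_az, +f * half_el],
        [+f * half_az, -f * half_el],
        [-f * half_az, +f * half_el],
        [-f * half_az, -f * half_el],
    ])


def array_sub_apertures(arr: TxTile | IxProbe) -> np.ndarray:
    """World positions (5, 3) of the sub-aperture centers on an array face."""
    if isinstance(arr, TxTile):
        off = _sub_aperture_offsets(arr.aperture_az_mm / 2, arr.aperture_el_mm / 2)
    else:
        off = _sub_aperture_offsets(PROBE_APERTURE_MM / 2, PROBE_APERTURE_MM / 2)
    return (arr.position_mm[None, :]
            + off[:, 0:1] * arr.az_axis[None, :]
            + off[:, 1:2] * arr.el_axis[None, :])


@dataclass
class ToFSet:
    """Simulated sub-aperture arrival times and the geometry they imply."""

    array_ids: list[str]                    # e.g. tx0..tx20, ix0..ix5
    sub_positions_true: np.ndarray          # (n_arrays, 5, 3) ground truth, mm
    normals_true: np.ndarray                # (n_arrays, 3)
    pairs: np.ndarray                       # (n_obs, 2) flat sub-aperture indices
    arrival_times_s: np.ndarray             # (n_obs,)
    limb_radius_mm: float
    c_water_true_m_s: float
    c_tissue_true_m_s: float
    jitter_sd_s: float

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["emitter", "receiver", "t_s"])
            for (i, j), t in zip(self.pairs, self.arrival_times_s):
                w.writerow([int(i), int(j), f"{t:.9e}"])


def _tissue_chord_mm(p: np.ndarray, q: np.ndarray, radius_mm: float) -> np.ndarray:
    """Length of each segment p[k]->q[k] inside the limb cylinder (mm).

    The cylinder is |(x, y)| <= radius about the z axis; the in-cylinder
    parameter interval comes from the 2D quadratic, scaled by 3D length.
    """
    d2 = q[:, :2] - p[:, :2]
    a = np.einsum("ij,ij->i", d2, d2)
    b = 2.0 * np.einsum("ij,ij->i", p[:, :2], d2)
    c = np.einsum("ij,ij->i", p[:, :2], p[:, :2]) - radius_mm ** 2
    disc = b * b - 4.0 * a * c
    L3 = np.linalg.norm(q - p, axis=1)
    out = np.zeros(len(p))
    ok = (disc > 0) & (a > 1e-12)
    sq = np.sqrt(np.maximum(disc[ok], 0.0))
    t0 = np.clip((-b[ok] - sq) / (2 * a[ok]), 0.0, 1.0)
    t1 = np.clip((-b[ok] + sq) / (2 * a[ok]), 0.0, 1.0)
    out[ok] = (t1 - t0) * L3[ok]
    return out


def perturb_cuff(cuff: CuffGeometry, seed: int, panel_shift_mm: float = 2.0,
                 panel_tilt_deg: float = 2.0) -> CuffGeometry:
    """Rigidly perturb each panel's arrays: a flexible conformal cuff does not
    sit on the exact polygon the prior assumes."""
    rng = np.random.default_rng(seed)
    out = CuffGeometry(cuff.n_panels, cuff.limb_diameter_cm, cuff.standoff_cm,
                       cuff.panel_centers_mm.copy(), cuff.panel_normals.copy())

    def _rot(axis: np.ndarray, ang: float) -> np.ndarray:
        axis = axis / np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)

    shifts, rots = {}, {}
    for k in range(cuff.n_panels):
        shifts[k] = rng.normal(0.0, panel_shift_mm, 3)
        ax = rng.normal(size=3)
        rots[k] = _rot(ax, np.deg2rad(rng.normal(0.0, panel_tilt_deg)))

    def _panel_of(pos: np.ndarray) -> int:
        return int(np.argmax(cuff.panel_centers_mm[:, :2] @ pos[:2]
                             / (np.linalg.norm(pos[:2]) + 1e-9)))

    for t in cuff.tiles:
        k = _panel_of(t.position_mm)
        ctr = cuff.panel_centers_mm[k]
        R, s = rots[k], shifts[k]
        out.tiles.append(TxTile(t.tile_id, R @ (t.position_mm - ctr) + ctr + s,
                                R @ t.normal, R @ t.az_axis, R @ t.el_axis,
                                power_cap_w=t.power_cap_w))
    for p in cuff.probes:
        k = _panel_of(p.position_mm)
        ctr = cuff.panel_centers_mm[k]
        R, s = rots[k], shifts[k]
        out.probes.append(IxProbe(p.probe_id, R @ (p.position_mm - ctr) + ctr + s,
                                  R @ p.normal, R @ p.az_axis, R @ p.el_axis))
    return out


def simulate_tof(cuff: CuffGeometry, phantom: LimbPhantom,
                 jitter_sd_s: float = DEFAULT_JITTER_S, seed: int = 0,
                 c_water_m_s: float = WATER_SOUND_SPEED_M_S,
                 exclude_tiles: tuple[int, ...] = (),
                 exclude_probes: tuple[int, ...] = (),
                 max_incidence_deg: float = 72.0) -> ToFSet:
    """Simulate pairwise sub-aperture arrival times across the cuff.

    Pairs must be roughly facing (incidence within ``max_incidence_deg`` of
    both face normals) and unblocked by bone; blocked or grazing pairs are
    dropped, as the hardware drops transmissions with no usable signal.
    """
    rng = np.random.default_rng(seed)
    arrays: list[tuple[str, np.ndarray, np.ndarray]] = []
    for t in cuff.tiles:
        if t.tile_id in exclude_tiles:
            continue
        arrays.append((f"tx{t.tile_id}", array_sub_apertures(t), t.normal))
    for p in cuff.probes:
        if p.probe_id in exclude_probes:
            continue
        arrays.append((f"ix{p.probe_id}", array_sub_apertures(p), p.normal))

    ids = [a[0] for a in arrays]
    subs = np.stack([a[1] for a in arrays])            # (n, 5, 3)
    normals = np.stack([a[2] for a in arrays])
    n_arr = len(arrays)
    flat = subs.reshape(-1, 3)
    arr_of = np.repeat(np.arange(n_arr), 5)

    ii, jj = np.triu_indices(len(flat), k=1)
    keep = arr_of[ii] != arr_of[jj]
    ii, jj = ii[keep], jj[keep]
    p, q = flat[ii], flat[jj]
    d = q - p
    L = np.linalg.norm(d, axis=1)
    u = d / L[:, None]
    cos_lim = np.cos(np.deg2rad(max_incidence_deg))
    facing = (np.einsum("ij,ij->i", u, normals[arr_of[ii]]) > cos_lim) & \
             (np.einsum("ij,ij->i", -u, normals[arr_of[jj]]) > cos_lim)
    ii, jj, p, q, L = ii[facing], jj[facing], p[facing], q[facing], L[facing]

    if phantom.bones:
        clear = np.fromiter(
            (not any(b.blocks_segment(pi, qi) for b in phantom.bones)
             for pi, qi in zip(p, q)), dtype=bool, count=len(p))
        ii, jj, p, q, L = ii[clear], jj[clear], p[clear], q[clear], L[clear]

    c_t = phantom.tissue.sound_speed_m_s
    lt = _tissue_chord_mm(p, q, phantom.radius_mm)
    lw = L - lt
    times = lw / (c_water_m_s * 1000.0) + lt / (c_t * 1000.0)  # mm / (mm/s)
    if jitter_sd_s > 0:
        times = times + rng.normal(0.0, jitter_sd_s, times.shape)
    return ToFSet(ids, subs, normals, np.stack([ii, jj], axis=1), times,
                  phantom.radius_mm, c_water_m_s, c_t, jitter_sd_s)


@dataclass
class PoseEstimate:
    """Recovered array poses, layer sound speeds and fit residual."""

    array_ids: list[str]
    positions_mm: np.ndarray          # (n_arrays, 3) face centers
    normals: np.ndarray               # (n_arrays, 3) unit
    sub_positions_mm: np.ndarray      # (n_arrays, 5, 3)
    c_water_m_s: float
    c_tissue_m_s: float
    residual_rms_s: float
    n_sides: int
    diagnostics: dict = field(default_factory=dict)


def _estimate_side_count(normals: np.ndarray, tol_deg: float = 12.0) -> int:
    """Cluster tile-normal azimuths to count distinct panel orientations."""
    az = np.degrees(np.arctan2(normals[:, 1], normals[:, 0])) % 360.0
    order = np.argsort(az)
    az_sorted = az[order]
    clusters = 1
    for a, b in zip(az_sorted[:-1], az_sorted[1:]):
        if b - a > tol_deg:
            clusters += 1
    # wrap-around: first and last may be the same panel
    if clusters > 1 and (az_sorted[0] + 360.0 - az_sorted[-1]) <= tol_deg:
        clusters -= 1
    return clusters


def solve_poses(tof: ToFSet, polygon_prior: int,
                init_cuff: CuffGeometry | None = None,
                prior_noise_mm: float = 5.0, seed: int = 0,
                max_nfev: int = 60) -> PoseEstimate:
    """Recover sub-aperture positions and layer speeds from arrival times.

    Joint sparse nonlinear least squares over all sub-aperture coordinates
    plus the two layer speeds; residuals are predicted-minus-measured times
    in microseconds. Initialization is the nominal polygon-prior cuff (built
    from ``polygon_prior`` sides) with small Gaussian perturbation, standing
    in for the calibration-file initial estimate. Array pose follows from the
    best-fit rigid frame over each array's five sub-apertures.
    """
    n_arr = len(tof.array_ids)
    n_pts = n_arr * 5
    # Determinacy check: every sub-aperture needs >= 3 observations.
    counts = np.bincount(tof.pairs.ravel(), minlength=n_pts)
    if (counts < 3).any():
        bad = np.nonzero(counts < 3)[0]
        raise ValueError(
            f"under-determined geometry: sub-apertures {bad.tolist()} have "
            f"fewer than 3 time measurements (condition diagnostic)")

    rng = np.random.default_rng(seed)
    if init_cuff is None:
        from .cuff import build_cuff
        init_cuff = build_cuff(polygon_prior, tof.limb_radius_mm / 5.0)
    init_map: dict[str, np.ndarray] = {}
    for t in init_cuff.tiles:
        init_map[f"tx{t.tile_id}"] = array_sub_apertures(t)
    for p in init_cuff.probes:
        init_map[f"ix{p.probe_id}"] = array_sub_apertures(p)
    x0_pts = np.stack([init_map[a] for a in tof.array_ids]).reshape(-1, 3)
    x0_pts = x0_pts + rng.normal(0.0, prior_noise_mm, x0_pts.shape)

    ii = tof.pairs[:, 0]
    jj = tof.pairs[:, 1]
    t_meas_us = tof.arrival_times_s * 1e6
    R_limb = tof.limb_radius_mm

    def residuals(x: np.ndarray) -> np.ndarray:
        pts = x[:-2].reshape(-1, 3)
        c_w, c_t = x[-2], x[-1]           # m/s == mm/ms; mm/us = c/1000
        p, q = pts[ii], pts[jj]
        L = np.linalg.norm(q - p, axis=1)
        lt = _tissue_chord_mm(p, q, R_limb)
        lw = L - lt
        t_pred_us = lw / (c_w * 1e-3) + lt / (c_t * 1e-3)
        return t_pred_us - t_meas_us

    x0 = np.concatenate([x0_pts.ravel(), [WATER_SOUND_SPEED_M_S, 1540.0]])

    # Sparsity: each residual touches 6 coordinates + the 2 speeds.
    n_obs = len(ii)
    rows = np.repeat(np.arange(n_obs), 8)
    cols = np.empty((n_obs, 8), dtype=int)
    for k in range(3):
        cols[:, k] = ii * 3 + k
        cols[:, 3 + k] = jj * 3 + k
    cols[:, 6] = n_pts * 3
    cols[:, 7] = n_pts * 3 + 1
    spar = sparse.coo_matrix((np.ones(n_obs * 8), (rows, cols.ravel())),
                             shape=(n_obs, n_pts * 3 + 2))

    scale = np.concatenate([np.full(n_pts * 3, 1.0), [10.0, 10.0]])
    sol = least_squares(residuals, x0, jac_sparsity=spar, x_scale=scale,
                        tr_solver="lsmr", max_nfev=max_nfev, verbose=0)
    pts = sol.x[:-2].reshape(n_arr, 5, 3)
    c_w, c_t = float(sol.x[-2]), float(sol.x[-1])
    rms_s = float(np.sqrt(np.mean(sol.fun ** 2)) * 1e-6)

    # Pose per array: rigid fit of the known local sub-aperture layout.
    positions = pts[:, 0, :].copy()       # center sub-aperture = face center
    normals = np.zeros((n_arr, 3))
    for a in range(n_arr):
        centered = pts[a] - pts[a].mean(axis=0)
        # plane normal = smallest singular vector; sign toward the limb axis
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        n = vt[2]
        if n @ positions[a] > 0:
            n = -n
        normals[a] = n / np.linalg.norm(n)

    tx_mask = np.array([a.startswith("tx") for a in tof.array_ids])
    n_sides = _estimate_side_count(normals[tx_mask])
    return PoseEstimate(list(tof.array_ids), positions, normals, pts, c_w, c_t,
                        rms_s, n_sides,
                        diagnostics={"cost": float(sol.cost), "nfev": sol.nfev,
                                     "status": sol.status})


@dataclass
class RegistrationErrorReport:
    """Pose-estimate accuracy after rigid alignment to ground truth."""

    position_errors_mm: np.ndarray
    normal_errors_deg: np.ndarray
    ix_tx_distance_errors_mm: np.ndarray
    max_position_error_mm: float
    median_position_error_mm: float
    max_normal_error_deg: float
    median_normal_error_deg: float
    median_ix_tx_distance_error_mm: float


def _rigid_align(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch best-fit rotation R and translation t mapping src -> dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cd - R @ cs


def registration_error(est: PoseEstimate, tof: ToFSet) -> RegistrationErrorReport:
    """Errors of the pose estimate versus the simulation's ground truth.

    Estimated positions are rigidly aligned to the true face centers first
    (registration is defined up to the global frame); Ix-Tx distance errors
    are computed pre-alignment since distances are gauge-invariant.
    """
    truth_pos = tof.sub_positions_true[:, 0, :]
    R, t = _rigid_align(est.positions_mm, truth_pos)
    aligned = est.positions_mm @ R.T + t
    pos_err = np.linalg.norm(aligned - truth_pos, axis=1)

    n_est = est.normals @ R.T
    cosang = np.abs(np.einsum("ij,ij->i", n_est, tof.normals_true))
    norm_err = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    ix = [k for k, a in enumerate(est.array_ids) if a.startswith("ix")]
    tx = [k for k, a in enumerate(est.array_ids) if a.startswith("tx")]
    derr = []
    for i in ix:
        for j in tx:
            d_est = np.linalg.norm(est.positions_mm[i] - est.positions_mm[j])
            d_true = np.linalg.norm(truth_pos[i] - truth_pos[j])
            derr.append(abs(d_est - d_true))
    derr = np.asarray(derr) if derr else np.zeros(0)
    return RegistrationErrorReport(
        pos_err, norm_err, derr,
        float(pos_err.max()), float(np.median(pos_err)),
        float(norm_err.max()), float(np.median(norm_err)),
        float(np.median(derr)) if len(derr) else float("nan"))
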