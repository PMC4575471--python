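"""Phantom synthesis: waveforms, vessel trees, rendering, spectral gates."""

import numpy as np
import pytest

from dbacsim import (NoSignal, compute_ri, make_flow_waveform,
                     make_limb_phantom, render_power_doppler,
                     sample_spectral_doppler)
from dbacsim.cuff import IxProbe
from dbacsim.phantoms import (TC_MARKER_ARCLENGTH_MM, FlowWaveform,
                              TissueProperties, VesselBranch, VesselTree,
                              rasterize_lumen)


def _straight_tube_tree(radius_mm=1.5, length_mm=40.0, mean_v=20.0, seed=0):
    pts = np.stack([np.zeros(9), np.zeros(9), np.linspace(0, length_mm, 9)], axis=1)
    wf = make_flow_waveform("normal", mean_v, 60.0, seed)
    tree = VesselTree()
    tree.branches.append(VesselBranch(0, pts, radius_mm, "normal", wf))
    return tree


class _BareCuff:
    """Probe holder for rendering tests outside a full cuff geometry."""

    def __init__(self, probes):
        self.probes = probes


def _probe(pid, pos, look_at):
    n = np.asarray(look_at, float) - np.asarray(pos, float)
    n = n / np.linalg.norm(n)
    a = np.array([0.0, 0.0, 1.0])
    if abs(n @ a) > 0.9:
        a = np.array([1.0, 0.0, 0.0])
    a = a - (a @ n) * n
    a /= np.linalg.norm(a)
    return IxProbe(pid, np.asarray(pos, float), n, a, np.cross(n, a))


# ---------------------------------------------------------------------------
# Flow waveforms
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("profile,ri_lo,ri_hi", [
    ("normal", 0.80, 1.0),
    ("bleeder", 0.0, 0.70),
])
def test_waveform_profiles_pin_resistive_index(profile, ri_lo, ri_hi):
    for seed in range(20):
        w = make_flow_waveform(profile, 20.0, 60.0, seed)
        ri = compute_ri(w)
        assert ri_lo <= ri <= ri_hi
        assert w.v_systole == pytest.approx(np.max(w.velocity_cm_s))
        assert w.v_diastole == pytest.approx(np.min(w.velocity_cm_s))
        assert w.mean_velocity == pytest.approx(20.0, rel=1e-9)


def test_bleeder_waveforms_always_classify_below_threshold():
    # round-trip with the detection module's classifier for many seeds
    for seed in range(50):
        w = make_flow_waveform("bleeder", 10.0, 60.0, seed)
        assert compute_ri(w) < 0.75


def test_slow_irregular_profile_caps_mean_velocity():
    w = make_flow_waveform("irregular-slow", 3.0, 60.0, 2)
    assert w.mean_velocity == pytest.approx(3.0, rel=1e-6)
    w9 = make_flow_waveform("irregular-slow", 9.0, 60.0, 2)
    assert w9.mean_velocity <= 4.0 + 1e-9
    assert np.all(w9.velocity_cm_s >= 0)


def test_waveform_rejects_nonpositive_mean():
    with pytest.raises(ValueError):
        make_flow_waveform("normal", 0.0, 60.0, 0)


def test_waveform_csv_roundtrip(tmp_path):
    w = make_flow_waveform("bleeder", 12.0, 72.0, 3)
    p = tmp_path / "wf.csv"
    w.to_csv(p)
    w2 = FlowWaveform.from_csv(p, profile="bleeder")
    assert np.allclose(w.velocity_cm_s, w2.velocity_cm_s, atol=1e-6)
    assert p.read_text().splitlines()[0] == "time_s,velocity_cm_s"


# ---------------------------------------------------------------------------
# Limb phantoms
# ---------------------------------------------------------------------------


def test_phantom_diameter_bounds_named_in_error():
    with pytest.raises(ValueError, match="MinRC"):
        make_limb_phantom(5.0, 1, 0, seed=0)
    with pytest.raises(ValueError, match="MaxRC"):
        make_limb_phantom(30.0, 1, 0, seed=0)


def test_phantom_is_reproducible_and_inside_cylinder():
    a = make_limb_phantom(25.0, 4, 1, seed=7)
    b = make_limb_phantom(25.0, 4, 1, seed=7)
    for ba, bb in zip(a.vessel_tree.branches, b.vessel_tree.branches):
        assert np.array_equal(ba.points, bb.points)
        assert np.array_equal(ba.waveform.velocity_cm_s, bb.waveform.velocity_cm_s)
    for br in a.vessel_tree.branches:
        r_xy = np.hypot(br.points[:, 0], br.points[:, 1])
        assert np.all(r_xy < a.radius_mm)
        assert br.radius_mm >= 0.3  # 0.6-mm minimum representable diameter


def test_phantom_depth_limits_and_deep_bleeder():
    ph25 = make_limb_phantom(25.0, 4, 1, seed=7)
    assert ph25.max_target_depth_cm == pytest.approx(12.5)
    depths = [ph25.depth_of(p) for p in ph25.vessel_tree.tc_markers.values()]
    assert max(depths) <= 12.5
    assert max(depths) > 25.0 / 4.0

    ph75 = make_limb_phantom(7.5, 2, 1, seed=7)
    assert ph75.radius_mm == pytest.approx(37.5)
    for br in ph75.vessel_tree.branches:
        assert np.all(np.hypot(br.points[:, 0], br.points[:, 1]) <= 37.5)


def test_tc_markers_sit_20mm_downstream_on_bleeders():
    ph = make_limb_phantom(15.0, 3, 2, seed=13, with_bone=False)
    tree = ph.vessel_tree
    assert set(tree.tc_markers) == set(tree.bleeder_ids)
    for bid, marker in tree.tc_markers.items():
        br = tree.branch(bid)
        assert br.length_mm >= 30.0
        expected = br.point_at_arclength(TC_MARKER_ARCLENGTH_MM)
        assert np.linalg.norm(marker - expected) < 1e-9
        start = br.points[0]
        assert np.linalg.norm(marker - start) <= TC_MARKER_ARCLENGTH_MM + 1e-6


def test_phantom_json_roundtrip(tmp_path, phantom15):
    p = tmp_path / "ph.json"
    phantom15.save(p)
    from dbacsim import LimbPhantom
    ph2 = LimbPhantom.load(p)
    assert ph2.diameter_cm == phantom15.diameter_cm
    assert len(ph2.vessel_tree.branches) == len(phantom15.vessel_tree.branches)
    assert np.allclose(ph2.vessel_tree.branches[0].points,
                       phantom15.vessel_tree.branches[0].points)


def test_tissue_properties_validation():
    with pytest.raises(ValueError):
        TissueProperties(sound_speed_m_s=1000.0)
    with pytest.raises(ValueError):
        TissueProperties(perfusion_1_s=-0.1)
    tp = TissueProperties()
    assert tp.attenuation_np_cm(2.0) == pytest.approx(0.1)


# ---------------------------------------------------------------------------
# Rasterization and rendering
# ---------------------------------------------------------------------------


def test_rasterized_tube_volume_matches_analytic():
    tree = _straight_tube_tree(radius_mm=1.5, length_mm=40.0)
    lo = np.array([-4.0, -4.0, -2.0])
    shape = (32, 32, 180)
    mask, _, _ = rasterize_lumen(tree, 0.25, lo, shape)
    vol = mask.sum() * 0.25 ** 3
    analytic = np.pi * 1.5 ** 2 * 40.0
    assert vol == pytest.approx(analytic, rel=0.10)


def test_thin_branch_resolved_across_lumen():
    # 0.6-mm-diameter tube at 0.25-mm voxels: >= 1 voxel across everywhere
    tree = _straight_tube_tree(radius_mm=0.3, length_mm=20.0)
    lo = np.array([-2.0, -2.0, 0.0])
    mask, _, _ = rasterize_lumen(tree, 0.25, lo, (16, 16, 80))
    hit = mask.any(axis=(0, 1))
    zs = lo[2] + np.arange(80) * 0.25
    assert hit[(zs > 0.5) & (zs < 19.5)].all()


def test_noiseless_render_equals_rasterized_lumen():
    tree = _straight_tube_tree()
    from dbacsim.phantoms import LimbPhantom
    ph = LimbPhantom(7.5, 10.0, TissueProperties(), tree)
    # probe at 45 degrees so the Doppler angle is usable everywhere
    cuff = _BareCuff([_probe(0, [80.0, 0.0, -40.0], [0.0, 0.0, 20.0])])
    vol = render_power_doppler(ph, cuff, 0.25, noise_sd=0.0)
    mask, _, _ = rasterize_lumen(tree, 0.25, vol.origin_mm, vol.grid.shape)
    assert np.array_equal(vol.grid > 0, mask)


def test_contralateral_doppler_blind_spot():
    # two facing probes, both orthogonal to the flow: compounding cannot
    # recover the lumen (simulated blind spot)
    tree = _straight_tube_tree()
    from dbacsim.phantoms import LimbPhantom
    ph = LimbPhantom(7.5, 10.0, TissueProperties(), tree)
    cuff = _BareCuff([_probe(0, [60.0, 0.0, 20.0], [0.0, 0.0, 20.0]),
                      _probe(1, [-60.0, 0.0, 20.0], [0.0, 0.0, 20.0])])
    vol = render_power_doppler(ph, cuff, 0.25, noise_sd=0.0)
    mask, speed, _ = rasterize_lumen(tree, 0.25, vol.origin_mm, vol.grid.shape)
    # central slab: near the tube ends the oblique view angle recovers signal
    zs = vol.origin_mm[2] + np.arange(vol.grid.shape[2]) * 0.25
    central = np.zeros_like(mask)
    central[:, :, np.abs(zs - 20.0) <= 8.0] = True
    lumen_center = vol.grid[mask & (speed > 0) & central]
    full = 20.0 * speed[mask].max()
    assert lumen_center.max() < 0.25 * full  # heavily suppressed vs full signal


def test_render_rejects_non_enclosing_cuff(phantom25, cuff4):
    with pytest.raises(ValueError, match="enclose"):
        render_power_doppler(phantom25, cuff4, 0.5)


def test_render_determinism(phantom75, cuff4):
    v1 = render_power_doppler(phantom75, cuff4, 0.3, noise_seed=5)
    v2 = render_power_doppler(phantom75, cuff4, 0.3, noise_seed=5)
    assert np.array_equal(v1.grid, v2.grid)


# ---------------------------------------------------------------------------
# Spectral-Doppler sampling
# ---------------------------------------------------------------------------


def test_gate_on_branch_noiseless_returns_exact_ri(phantom15):
    tree = phantom15.vessel_tree
    bid = tree.bleeder_ids[0]
    gate = tree.branch(bid).point_at_arclength(10.0)
    wf = sample_spectral_doppler(gate, tree, noise_sd=0.0)
    assert not isinstance(wf, NoSignal)
    assert compute_ri(wf) == pytest.approx(compute_ri(tree.branch(bid).waveform))


def test_gate_far_from_vessels_gives_no_signal(phantom15):
    tree = phantom15.vessel_tree
    pt = tree.branch(0).points[0] + np.array([10.0, 10.0, 0.0])
    assert isinstance(sample_spectral_doppler(pt, tree), NoSignal)


def test_noisy_gate_ri_within_tolerance_95pct(phantom15):
    tree = phantom15.vessel_tree
    br = tree.branch(0)
    gate = br.point_at_arclength(20.0)
    ri_true = compute_ri(br.waveform)
    hits = 0
    for seed in range(200):
        wf = sample_spectral_doppler(gate, tree, noise_seed=seed, noise_sd=0.05)
        hits += abs(compute_ri(wf) - ri_true) <= 0.05
    assert hits >= 0.95 * 200
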