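"""Detection & localization: segmentation, centerlines, gates, RI, full chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbacsim import (classify_branch, compute_ri, detect_bifurcations,
                     extract_centerlines, make_flow_waveform,
                     make_limb_phantom, run_dl, segment_vessels)
from dbacsim.cuff import build_cuff
from dbacsim.detection import place_sd_gates
from dbacsim.phantoms import (DopplerVolume, FlowWaveform, VesselBranch,
                              VesselTree, rasterize_lumen,
                              render_power_doppler, sample_spectral_doppler)


def _tree_from_polylines(polys, radii, flags=None, mean_v=20.0):
    tree = VesselTree()
    flags = flags or ["normal"] * len(polys)
    for k, (pts, r, fl) in enumerate(zip(polys, radii, flags)):
        profile = "bleeder" if fl == "bleeder" else "normal"
        wf = make_flow_waveform(profile, mean_v, 60.0, seed=k)
        tree.branches.append(VesselBranch(k, np.asarray(pts, float), r, fl, wf))
    return tree


def _volume_from_tree(tree, voxel=0.25, margin=3.0, noise_sd=0.0, seed=0):
    lo, hi = tree.bounding_box(margin)
    shape = tuple(np.ceil((hi - lo) / voxel).astype(int))
    mask, speed, _ = rasterize_lumen(tree, voxel, lo, shape)
    grid = (20.0 * speed).astype(np.float32)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid = np.clip(grid + rng.normal(0, noise_sd, shape), 0, None).astype(np.float32)
    return DopplerVolume(grid, voxel, lo), mask


def _y_tree(angle_deg=45.0, branch_len=15.0, radius=0.5):
    a = np.deg2rad(angle_deg)
    stem = [[0, 0, -15.0], [0, 0, 0]]
    b1 = [[0, 0, 0], [branch_len * np.sin(a), 0, branch_len * np.cos(a)]]
    b2 = [[0, 0, 0], [-branch_len * np.sin(a), 0, branch_len * np.cos(a)]]
    return _tree_from_polylines([stem, b1, b2], [radius] * 3,
                                ["normal", "bleeder", "normal"])


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def test_noiseless_tube_segments_to_lumen():
    tree = _tree_from_polylines([[[0, 0, 0], [0, 0, 30.0]]], [1.0])
    vol, mask = _volume_from_tree(tree)
    seg = segment_vessels(vol)
    assert np.array_equal(seg, mask)


def test_background_volume_gives_empty_mask():
    vol = DopplerVolume(np.zeros((20, 20, 20), np.float32), 0.25, np.zeros(3))
    assert not segment_vessels(vol).any()


def test_snr5_segmentation_dice(phantom15, cuff5):
    vol = render_power_doppler(phantom15, cuff5, 0.3, noise_seed=3, noise_sd=2.0)
    seg = segment_vessels(vol)
    gt, _, _ = rasterize_lumen(phantom15.vessel_tree, 0.3, vol.origin_mm,
                               vol.grid.shape)
    dice = 2 * (seg & gt).sum() / (seg.sum() + gt.sum())
    assert dice >= 0.9


def test_fixed_threshold_mode():
    tree = _tree_from_polylines([[[0, 0, 0], [0, 0, 20.0]]], [1.0])
    vol, mask = _volume_from_tree(tree)
    seg = segment_vessels(vol, threshold_mode="fixed", threshold_value=1.0)
    assert np.array_equal(seg, mask)
    with pytest.raises(ValueError):
        segment_vessels(vol, threshold_mode="fixed")


# ---------------------------------------------------------------------------
# Centerlines and bifurcations
# ---------------------------------------------------------------------------


def test_straight_tube_has_no_bifurcations():
    tree = _tree_from_polylines([[[0, 0, 0], [0, 0, 30.0]]], [0.8])
    vol, mask = _volume_from_tree(tree)
    graph = extract_centerlines(mask, 0.25, vol.origin_mm)
    assert detect_bifurcations(graph) == []
    assert graph.graph.number_of_edges() >= 1


def test_y_junction_found_within_1mm():
    tree = _y_tree()
    vol, mask = _volume_from_tree(tree)
    graph = extract_centerlines(mask, 0.25, vol.origin_mm)
    bifs = detect_bifurcations(graph)
    assert len(bifs) == 1
    assert np.linalg.norm(bifs[0] - np.zeros(3)) <= 1.0


def test_empty_mask_raises():
    with pytest.raises(ValueError):
        extract_centerlines(np.zeros((5, 5, 5), bool), 0.25, np.zeros(3))


def test_four_branch_tree_recovers_terminals(phantom25, cuff7):
    vol = render_power_doppler(phantom25, cuff7, 0.3, noise_seed=1)
    seg = segment_vessels(vol)
    graph = extract_centerlines(seg, 0.3, vol.origin_mm)
    leaves = [n for n in graph.graph.nodes if graph.graph.degree[n] == 1]
    assert len(leaves) >= 4


# ---------------------------------------------------------------------------
# Gates, RI, classification
# ---------------------------------------------------------------------------


def test_symmetric_y_gates_at_5mm():
    tree = _y_tree(branch_len=12.0)
    vol, mask = _volume_from_tree(tree)
    graph = extract_centerlines(mask, 0.25, vol.origin_mm)
    node = graph.bifurcation_nodes[0]
    gates = place_sd_gates(node, graph, gate_distance_mm=5.0, tree=tree)
    assert len(gates) == 3
    origin = graph.node_point(node)
    for g in gates:
        assert not g.flagged_short_branch
        assert np.linalg.norm(g.location_mm - origin) == pytest.approx(5.0, abs=1.0)
    roles = {g.role for g in gates}
    assert roles == {"proximal", "in-the-bleeder", "distal"}


def test_short_branch_gate_at_midpoint_flagged():
    # one branch only ~4 mm long
    tree = _tree_from_polylines(
        [[[0, 0, -15.0], [0, 0, 0]],
         [[0, 0, 0], [3.0, 0, 3.0]],
         [[0, 0, 0], [-8.0, 0, 8.0]]],
        [0.5, 0.5, 0.5])
    vol, mask = _volume_from_tree(tree)
    graph = extract_centerlines(mask, 0.25, vol.origin_mm)
    node = graph.bifurcation_nodes[0]
    gates = place_sd_gates(node, graph, gate_distance_mm=5.0)
    short = [g for g in gates if g.flagged_short_branch]
    assert len(short) >= 1
    origin = graph.node_point(node)
    for g in short:
        assert np.linalg.norm(g.location_mm - origin) < 5.0


def test_gates_feed_spectral_sampling_without_no_signal():
    tree = _y_tree(branch_len=14.0)
    vol, mask = _volume_from_tree(tree)
    graph = extract_centerlines(mask, 0.25, vol.origin_mm)
    gates = place_sd_gates(graph.bifurcation_nodes[0], graph, tree=tree)
    for g in gates:
        wf = sample_spectral_doppler(g.location_mm, tree, noise_sd=0.02)
        assert isinstance(wf, FlowWaveform)


def test_gate_placement_requires_bifurcation():
    tree = _tree_from_polylines([[[0, 0, 0], [0, 0, 30.0]]], [0.8])
    vol, mask = _volume_from_tree(tree)
    graph = extract_centerlines(mask, 0.25, vol.origin_mm)
    leaf = [n for n in graph.graph.nodes if graph.graph.degree[n] == 1][0]
    with pytest.raises(ValueError):
        place_sd_gates(leaf, graph)


@pytest.mark.parametrize("v_sys,v_dia,expected", [
    (10.0, 3.0, 0.70), (10.0, 10.0, 0.0), (10.0, 0.0, 1.0)])
def test_resistive_index_arithmetic(v_sys, v_dia, expected):
    t = np.linspace(0, 1, 8, endpoint=False)
    v = np.full(8, v_dia)
    v[2] = v_sys
    w = FlowWaveform(t, v)
    assert compute_ri(w) == pytest.approx(expected)


def test_undefined_ri_raises():
    w = FlowWaveform(np.linspace(0, 1, 4), np.zeros(4))
    with pytest.raises(ValueError):
        compute_ri(w)


@pytest.mark.parametrize("ri,expected", [
    (0.70, "bleeder"), (0.75, "normal"), (0.95, "normal"), (0.7499999, "bleeder")])
def test_classification_strict_threshold(ri, expected):
    assert classify_branch(ri) == expected


@given(ri=st.floats(-5.0, 1.0), thr=st.floats(0.1, 0.9))
@settings(max_examples=200, deadline=None)
def test_classification_pure_function_of_ri(ri, thr):
    a = classify_branch(ri, thr)
    assert a == classify_branch(ri, thr)        # idempotent
    assert a == ("bleeder" if ri < thr else "normal")


def test_irregular_slow_flow_degrades_classification():
    # the known failure mode at the minimum detectable velocity: RI on
    # aperiodic slow bleeds misclassifies far more often than on pulsatile
    # vented-branch waveforms
    def accuracy(profile, mean_v):
        hits = 0
        for seed in range(60):
            w = make_flow_waveform(profile, mean_v, 60.0, seed)
            hits += classify_branch(compute_ri(w)) == "bleeder"
        return hits / 60
    assert accuracy("irregular-slow", 3.0) < accuracy("bleeder", 10.0)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def dl_report_25(phantom25, cuff7):
    return run_dl(phantom25, cuff7, seed=1, voxel_size_mm=0.3)


def test_run_dl_finds_the_single_bleeder(phantom25, dl_report_25):
    found = {b.branch_id for b in dl_report_25.bleeders}
    assert found == set(phantom25.vessel_tree.bleeder_ids)


def test_run_dl_target_within_3mm_of_branch(phantom25, dl_report_25):
    tree = phantom25.vessel_tree
    for b in dl_report_25.bleeders:
        br = tree.branch(b.branch_id)
        d = min(np.linalg.norm(b.target_coordinate_mm - p) for p in br.points)
        from dbacsim.phantoms import _point_polyline_distance
        d = _point_polyline_distance(b.target_coordinate_mm, br.points)
        assert d <= 3.0


def test_run_dl_timing_sums(dl_report_25):
    assert dl_report_25.total_time_s == pytest.approx(
        sum(dl_report_25.phase_durations_s.values()))
    assert set(dl_report_25.phase_durations_s) == {
        "acquisition", "segmentation", "centerlines", "characterization"}


def test_run_dl_reports_zero_bleeders_when_none_exist():
    ph = make_limb_phantom(7.5, 2, 0, seed=11, with_bone=False)
    rep = run_dl(ph, build_cuff(4, 7.5), seed=1, voxel_size_mm=0.25)
    assert rep.bleeders == []


def test_run_dl_detects_msr_bleeder_in_15cm_phantom():
    # minimum-structure-resolution case: 0.6-mm-diameter bleeder branch
    ph = make_limb_phantom(15.0, 2, 1, seed=9, with_bone=False,
                           bleeder_radius_mm=0.3)
    rep = run_dl(ph, build_cuff(5, 15.0), seed=1, voxel_size_mm=0.25)
    assert {b.branch_id for b in rep.bleeders} == set(ph.vessel_tree.bleeder_ids)
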