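"""Closed-loop control: strain localization, iterative targeting, echo
thermometry, and the feedback dose controller."""

import numpy as np
import pytest

from dbacsim import (ThermometryConfig, correct_targeting, dose_controller,
                     estimate_temperature, localize_focus,
                     make_thermometry_corpus, simulate_features,
                     simulate_strain_volume, targeting_campaign,
                     train_estimator)
from dbacsim.control import LAMBDA_STRAIN_PER_C, FeatureStream, strain_response


def _beam_blob(axis, n=41, vox=0.5, peak_c=20.0, lat_sigma=1.0, ax_sigma=5.0):
    x = (np.arange(n) - n // 2) * vox
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    s = pts @ axis
    lat2 = np.sum(pts ** 2, axis=-1) - s ** 2
    dT = peak_c * np.exp(-lat2 / (2 * lat_sigma ** 2) - s ** 2 / (2 * ax_sigma ** 2))
    return dT, np.full(3, -(n // 2) * vox), vox


# ---------------------------------------------------------------------------
# Strain volumes and focus localization
# ---------------------------------------------------------------------------


def test_zero_temperature_gives_pure_noise_volume():
    sv = simulate_strain_volume(np.zeros((15, 15, 15)), 0.5, np.zeros(3),
                                noise_seed=1, noise_sd=0.001)
    assert abs(sv.strain.mean()) < 5e-4
    assert sv.strain.std() == pytest.approx(0.001, rel=0.2)


def test_noiseless_blob_peak_located_exactly():
    axis = np.array([0.0, 0.0, 1.0])
    dT, origin, vox = _beam_blob(axis)
    sv = simulate_strain_volume(dT, vox, origin, noise_sd=0.0)
    fix = localize_focus(sv, threshold=0.005)
    assert np.linalg.norm(fix.focus_mm) < vox


def test_axis_fit_on_45_degree_beam():
    axis = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
    dT, origin, vox = _beam_blob(axis)
    sv = simulate_strain_volume(dT, vox, origin, noise_sd=0.0)
    fix = localize_focus(sv, threshold=0.005)
    ang = np.degrees(np.arccos(abs(fix.axis_direction @ axis)))
    assert ang <= 1.0


def test_noise_only_volume_gives_no_fix():
    sv = simulate_strain_volume(np.zeros((21, 21, 21)), 0.5, np.zeros(3),
                                noise_seed=1, noise_sd=0.002)
    assert localize_focus(sv, threshold=0.02) is None


def test_off_axis_hot_speck_does_not_break_axis_fit():
    axis = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
    dT, origin, vox = _beam_blob(axis)
    dT[5, 35, 5] = 40.0        # isolated hot voxel far off-axis
    sv = simulate_strain_volume(dT, vox, origin, noise_sd=0.0)
    fix = localize_focus(sv, threshold=0.005)
    ang = np.degrees(np.arccos(abs(fix.axis_direction @ axis)))
    assert ang < 2.0


def test_peak_localization_error_at_snr10():
    axis = np.array([0.0, 0.0, 1.0])
    dT, origin, vox = _beam_blob(axis)
    peak_strain = LAMBDA_STRAIN_PER_C * 20.0
    errs = []
    for seed in range(100):
        sv = simulate_strain_volume(dT, vox, origin, noise_seed=seed,
                                    noise_sd=peak_strain / 10.0)
        fix = localize_focus(sv, threshold=0.005)
        errs.append(np.linalg.norm(fix.focus_mm))
    assert np.mean(errs) <= 1.0


# ---------------------------------------------------------------------------
# Iterative focus correction
# ---------------------------------------------------------------------------


def test_injected_offset_converges_within_tolerance():
    trial = correct_targeting(np.array([3.0, 4.0, 0.0]), max_iter=5,
                              noise_sd_mm=0.5, seed=0)
    assert trial.converged
    assert trial.final_offset_mm < 3.0


def test_zero_offset_converges_at_iteration_zero():
    trial = correct_targeting(np.zeros(3), max_iter=5, noise_sd_mm=0.5, seed=1)
    assert trial.converged and trial.iterations == 0


def test_noiseless_contraction_is_immediate():
    trial = correct_targeting(np.array([8.0, 0.0, 0.0]), max_iter=5,
                              noise_sd_mm=0.0, seed=0)
    mags = [np.linalg.norm(o) for o in trial.offsets_mm]
    assert all(b < a for a, b in zip(mags[:-1], mags[1:]))
    assert trial.converged and trial.final_offset_mm < 1e-9


def test_no_fix_measurement_aborts_trial():
    trial = correct_targeting(np.array([5.0, 0.0, 0.0]),
                              measure=lambda off, rng: None)
    assert not trial.converged and trial.iterations == 0


def test_more_iterations_never_hurt_convergence():
    r5 = sum(t.converged for t in targeting_campaign(100, seed=5, max_iter=5))
    r3 = sum(t.converged for t in targeting_campaign(100, seed=5, max_iter=3))
    assert r5 >= r3


def test_all_converged_trials_end_inside_tolerance():
    trials = targeting_campaign(50, seed=2)
    assert all(t.final_offset_mm < 3.0 for t in trials if t.converged)


# ---------------------------------------------------------------------------
# Echo features and thermometry
# ---------------------------------------------------------------------------


def test_features_at_baseline_without_heating():
    s = simulate_features(np.zeros(20), noise_sd=0.0,
                          power_history=np.zeros(20))
    assert not s.strain.any()
    assert not s.displacement.any()
    assert not s.backscatter.any()
    assert np.allclose(s.correlation, 1.0)


def test_strain_saturates_above_10_degrees():
    assert strain_response(np.array([5.0]))[0] == pytest.approx(5.0)
    resp30 = strain_response(np.array([30.0]))[0]
    assert resp30 <= 0.8 * 30.0         # >= 20 % underestimation when read linearly
    ramp = np.linspace(0, 30, 61)
    s = simulate_features(ramp, noise_sd=0.0)
    linear_readout = s.strain[-1] / LAMBDA_STRAIN_PER_C
    assert linear_readout <= 0.8 * 30.0


def test_feature_stream_reproducible_under_seed():
    a = simulate_features(np.linspace(0, 20, 40), noise_seed=9)
    b = simulate_features(np.linspace(0, 20, 40), noise_seed=9)
    for f in ("strain", "displacement", "backscatter", "correlation"):
        assert np.array_equal(getattr(a, f), getattr(b, f))
    assert np.all(np.abs(a.correlation) <= 1.0)


def test_tsi_exact_on_unsaturated_linear_ramp():
    ramp = np.linspace(0, 8, 30)     # below saturation, noiseless
    s = simulate_features(ramp, noise_sd=0.0)
    est = estimate_temperature(s, ThermometryConfig("tsi"))
    assert np.allclose(est, ramp, atol=1e-6)


def test_tsi_division():
    s = FeatureStream(np.arange(4.0), np.zeros(4), np.full(4, 0.012),
                      np.zeros(4), np.ones(4))
    est = estimate_temperature(s, ThermometryConfig("tsi", tsi_poly_order=0))
    assert est == pytest.approx(np.full(4, 10.0))


def test_untrained_recurrent_estimator_rejected():
    s = simulate_features(np.linspace(0, 5, 10))
    with pytest.raises(ValueError, match="not trained"):
        estimate_temperature(s, ThermometryConfig("rnn"))


def test_training_is_deterministic_and_reports_bands():
    streams, truths = make_thermometry_corpus(60, seed=4)
    e1 = train_estimator(streams, truths, seed=4)
    e2 = train_estimator(streams, truths, seed=4)
    assert np.array_equal(e1.w_out, e2.w_out)
    assert set(e1.band_mae_c) == {"0-10", "11-30"}
    assert np.isfinite(e1.heldout_mae_c)


def test_training_on_easy_regime_reaches_low_mae():
    # noiseless streams confined below the saturation knee
    streams, truths = make_thermometry_corpus(60, seed=8, noise_sd=0.0)
    keep = [i for i, y in enumerate(truths) if y.max() <= 9.0]
    streams = [streams[i] for i in keep]
    truths = [truths[i] for i in keep]
    est = train_estimator(streams, truths, seed=8)
    assert est.heldout_mae_c < 0.5


def test_recurrent_estimator_beats_tsi_at_high_temperature():
    streams, truths = make_thermometry_corpus(200, seed=3)
    est = train_estimator(streams, truths, seed=3)
    s_hold, y_hold = make_thermometry_corpus(50, seed=77)
    tsi_cfg = ThermometryConfig("tsi")
    rnn_cfg = ThermometryConfig("rnn", estimator=est)
    e_tsi, e_rnn = [], []
    for s, y in zip(s_hold, y_hold):
        band = (y > 10.0) & (y <= 30.0)
        if not band.any():
            continue
        e_tsi.append(np.mean(np.abs(estimate_temperature(s, tsi_cfg)[band] - y[band])))
        e_rnn.append(np.mean(np.abs(estimate_temperature(s, rnn_cfg)[band] - y[band])))
    assert np.mean(e_rnn) < np.mean(e_tsi)


# ---------------------------------------------------------------------------
# Closed-loop dose controller
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def dose_setup():
    import dbacsim as D
    from dbacsim.acoustics import deposition_from_plan
    from dbacsim.planning import plan_dose
    ph = D.make_limb_phantom(15.0, 2, 1, seed=7, with_bone=False)
    cuff = D.build_cuff(5, 15.0)
    br = ph.vessel_tree.branch(0)
    target = br.point_at_arclength(br.length_mm / 2)  # on the main artery
    plan = plan_dose(cuff, ph, target)
    for attr in ("tile_ids", "weights", "output_powers_w", "candidates"):
        setattr(plan, attr, getattr(plan, attr)[:3])
    half, vox = 16.0, 0.8
    n = int(round(2 * half / vox)) + 1
    dep = deposition_from_plan(plan, ph, target - half, (n, n, n), vox)
    dep.q_w_cm3 *= 6.0 / (plan.per_tile_absorbed_w * 3)
    return ph, plan, dep


def test_threshold_shutoff_before_time_limit(dose_setup):
    ph, plan, dep = dose_setup
    rec = dose_controller(plan, ph, dep, ThermometryConfig("tsi"),
                          dT_threshold_c=5.0, noise_seed=2)
    assert rec.shutoff_cause == "threshold"
    assert rec.t_dose_s < 30.0
    assert rec.estimated_dt_at_shutoff_c >= 5.0


def test_infinite_threshold_runs_full_exposure(dose_setup):
    ph, plan, dep = dose_setup
    rec = dose_controller(plan, ph, dep, ThermometryConfig("tsi"),
                          dT_threshold_c=np.inf, noise_seed=2)
    assert rec.shutoff_cause == "time-limit"
    assert rec.t_dose_s == pytest.approx(30.0)


def test_controller_never_exceeds_exposure_limit(dose_setup):
    ph, plan, dep = dose_setup
    for thr in (0.5, 3.0, 50.0):
        rec = dose_controller(plan, ph, dep, ThermometryConfig("tsi"),
                              dT_threshold_c=thr, noise_seed=1)
        assert rec.t_dose_s <= 30.0 + 1e-9


def test_cold_lumen_biases_shutoff_low(dose_setup):
    # vessel running through the MTV: advective cooling keeps the lumen cold,
    # dragging the spatial-average estimate down, so the wall overshoots the
    # threshold-implied temperature before power-off
    ph, plan, dep = dose_setup
    cfg = ThermometryConfig("tsi")
    plain = dose_controller(plan, ph, dep, cfg, 5.0, noise_seed=2,
                            vessel_sink=False)
    sink = dose_controller(plan, ph, dep, cfg, 5.0, noise_seed=2,
                           vessel_sink=True)
    assert sink.t_dose_s >= plain.t_dose_s
    assert sink.extra["wall_dt_at_shutoff_c"] > 5.0
    assert sink.extra["wall_dt_at_shutoff_c"] > sink.true_target_dt_at_shutoff_c
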