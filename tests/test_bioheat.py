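"""Pennes bioheat solver: closed-form oracles, conservation, dose metrics."""

import numpy as np
import pytest
from scipy.integrate import quad

from dbacsim import cem43, mtv_stats, mttd_check, skin_peak, solve_bioheat
from dbacsim.acoustics import DepositionMap
from dbacsim.bioheat import BioheatSolver, ThermalField, stable_dt_s
from dbacsim.phantoms import LimbPhantom, TissueProperties, VesselTree


def _phantom(**tissue_kw):
    return LimbPhantom(15.0, 16.0, TissueProperties(**tissue_kw), VesselTree())


def _uniform_dep(q_w_cm3, n=21, vox=1.0):
    half = (n - 1) * vox / 2.0
    return DepositionMap(np.full((n, n, n), q_w_cm3), vox, np.full(3, -half))


def test_zero_deposition_stays_zero():
    field = solve_bioheat(_phantom(), _uniform_dep(0.0), 5.0)
    for s in field.snapshots:
        assert not s.any()


def test_unstable_dt_rejected_with_bound():
    ph = _phantom()
    bound = stable_dt_s(1.0, ph.tissue)
    with pytest.raises(ValueError, match="stable bound"):
        solve_bioheat(ph, _uniform_dep(1.0), 5.0, dt_s=2.0 * bound)


def test_uniform_adiabatic_heating_closed_form():
    # uniform deposition + insulated boundaries: the laplacian vanishes and
    # dT = q t / (rho c_p) pointwise
    ph = _phantom()
    q = 2.0  # W/cm^3
    field = solve_bioheat(ph, _uniform_dep(q), 10.0, boundary="insulated")
    rho_c = ph.tissue.density_kg_m3 * ph.tissue.specific_heat_j_kgk
    expected = q * 1e6 * field.snapshot_times_s[-1] / rho_c
    assert np.allclose(field.final, expected, rtol=1e-3)


def test_gaussian_source_matches_greens_function_oracle():
    # continuous Gaussian source in an effectively infinite medium; the
    # analytic solution is a 1D time integral of spreading Gaussians
    ph = _phantom()
    vox, n = 1.0, 61
    half = (n - 1) * vox / 2.0
    x = np.arange(n) * vox - half
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    r2 = X ** 2 + Y ** 2 + Z ** 2
    s_mm = 2.0
    P = 1.0  # W
    q = np.exp(-r2 / (2 * s_mm ** 2))
    q *= P / (q.sum() * (vox / 10.0) ** 3)
    dep = DepositionMap(q, vox, np.full(3, -half))
    t_end = 8.0
    field = solve_bioheat(ph, dep, t_end, dt_s=0.1)

    rho_c = ph.tissue.density_kg_m3 * ph.tissue.specific_heat_j_kgk
    kappa = ph.tissue.conductivity_w_mk / rho_c       # m^2/s

    def analytic(r_mm):
        r = r_mm * 1e-3
        s = s_mm * 1e-3

        def integrand(tau):
            var = s ** 2 + 2 * kappa * tau
            return np.exp(-r ** 2 / (2 * var)) / (2 * np.pi * var) ** 1.5
        val, _ = quad(integrand, 0, field.snapshot_times_s[-1])
        return P / rho_c * val

    t_actual = field.snapshot_times_s[-1]
    assert t_actual == pytest.approx(t_end, abs=0.3)
    center = n // 2
    for r_vox in (2, 4, 6):
        sim = field.final[center + r_vox, center, center]
        ref = analytic(r_vox * vox)
        assert sim == pytest.approx(ref, rel=0.03)


def test_enthalpy_conservation_insulated():
    ph = _phantom()
    rng = np.random.default_rng(0)
    q = np.zeros((25, 25, 25))
    q[8:17, 8:17, 8:17] = rng.uniform(0.0, 3.0, (9, 9, 9))
    dep = DepositionMap(q, 1.0, np.full(3, -12.0))
    field = solve_bioheat(ph, dep, 6.0, boundary="insulated")
    rho_c = ph.tissue.density_kg_m3 * ph.tissue.specific_heat_j_kgk
    vox_m3 = (1e-3) ** 3
    enthalpy = rho_c * field.final.sum() * vox_m3
    injected = q.sum() * 1e6 * vox_m3 * field.snapshot_times_s[-1]
    assert enthalpy == pytest.approx(injected, rel=0.01)


def test_maximum_principle_nonnegative():
    ph = _phantom()
    q = np.zeros((21, 21, 21))
    q[10, 10, 10] = 5.0
    field = solve_bioheat(ph, DepositionMap(q, 1.0, np.full(3, -10.0)), 10.0)
    for s in field.snapshots:
        assert (s >= -1e-12).all()


def test_linearity_in_deposition():
    ph = _phantom()
    q = np.zeros((21, 21, 21))
    q[8:13, 8:13, 8:13] = 1.5
    d1 = DepositionMap(q, 1.0, np.full(3, -10.0))
    d2 = DepositionMap(2 * q, 1.0, np.full(3, -10.0))
    f1 = solve_bioheat(ph, d1, 8.0)
    f2 = solve_bioheat(ph, d2, 8.0)
    s1 = np.array(mtv_stats(f1, np.zeros(3)))
    s2 = np.array(mtv_stats(f2, np.zeros(3)))
    assert np.allclose(s2, 2 * s1, rtol=1e-9)


def test_grid_convergence_under_refinement():
    ph = _phantom()

    def target_dt(vox):
        n = int(round(30.0 / vox)) + 1
        half = (n - 1) * vox / 2.0
        x = np.arange(n) * vox - half
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        q = 2.0 * np.exp(-(X ** 2 + Y ** 2 + Z ** 2) / (2 * 3.0 ** 2))
        dep = DepositionMap(q, vox, np.full(3, -half))
        field = solve_bioheat(ph, dep, 10.0)
        return mtv_stats(field, np.zeros(3))[1]

    coarse, fine = target_dt(1.0), target_dt(0.5)
    assert abs(fine - coarse) / fine < 0.05


def test_mtv_stats_uniform_field_and_clipping():
    field = ThermalField([np.full((21, 21, 21), 33.0)], [30.0], 0.1, 1.0,
                         np.full(3, -10.0), "dirichlet")
    assert mtv_stats(field, np.zeros(3)) == pytest.approx((33.0, 33.0, 33.0))
    with pytest.raises(ValueError, match="clipped"):
        mtv_stats(field, np.array([9.0, 0.0, 0.0]))


def test_skin_peak_zero_without_deposition():
    ph = _phantom()
    n, vox = 81, 2.0
    half = (n - 1) * vox / 2.0
    dep = DepositionMap(np.zeros((n, n, 21)), vox,
                        np.array([-half, -half, -20.0]))
    field = solve_bioheat(ph, dep, 2.0, dt_s=0.5)
    assert skin_peak(field, ph) == 0.0


def test_skin_peak_requires_grid_reaching_skin():
    ph = _phantom()
    dep = _uniform_dep(0.0)
    field = solve_bioheat(ph, dep, 1.0)
    with pytest.raises(ValueError, match="skin"):
        skin_peak(field, ph)


def test_mttd_focused_passes_defocused_fails():
    ph = _phantom()
    n, vox = 41, 1.0
    half = (n - 1) * vox / 2.0
    x = np.arange(n) * vox - half
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")

    tight = 3.0 * np.exp(-(X ** 2 + Y ** 2) / (2 * 2.0 ** 2)
                         - Z ** 2 / (2 * 6.0 ** 2))
    f_ok = solve_bioheat(ph, DepositionMap(tight, vox, np.full(3, -half)), 10.0)
    ok, prof = mttd_check(f_ok, np.zeros(3))
    assert ok and prof["max_outside"] < 0.2 * prof["mtv_mean"]

    spread = 3.0 * (np.exp(-((X - 7.5) ** 2 + Y ** 2) / (2 * 2.0 ** 2)
                           - Z ** 2 / 72.0)
                    + np.exp(-((X + 7.5) ** 2 + Y ** 2) / (2 * 2.0 ** 2)
                             - Z ** 2 / 72.0))
    f_bad = solve_bioheat(ph, DepositionMap(spread, vox, np.full(3, -half)), 10.0)
    bad, _ = mttd_check(f_bad, np.zeros(3))
    assert not bad

    f_zero = solve_bioheat(ph, DepositionMap(np.zeros_like(tight), vox,
                                             np.full(3, -half)), 1.0)
    vac, _ = mttd_check(f_zero, np.zeros(3))
    assert vac


@pytest.mark.parametrize("dT,minutes,expected", [
    (6.0, 10.0, 10.0),      # constant 43 C for 10 min -> 10 CEM43 min
    (8.0, 10.0, 40.0),      # constant 45 C -> R^-2 = 4x
])
def test_cem43_closed_forms(dT, minutes, expected):
    n = 601
    times = np.linspace(0, minutes * 60.0, n)
    hist = np.full(n, dT)
    assert cem43(hist, times, baseline_c=37.0) == pytest.approx(expected, rel=2e-3)


def test_cem43_body_temperature_negligible():
    times = np.linspace(0, 600.0, 101)
    hist = np.zeros(101)  # 37 C throughout
    assert cem43(hist, times) <= 0.25 ** 6 * 10.0


def test_solver_boundary_validation():
    ph = _phantom()
    with pytest.raises(ValueError, match="boundary"):
        BioheatSolver(ph, _uniform_dep(1.0), boundary="periodic")
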