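import numpy as np
import pytest

from htsim import bioheat, em
from htsim.materials import WATER_THERMAL_K
from htsim.phantom import HeatingSetting
from htsim.volumes import FieldVolume, LabelVolume, Tissue

H = 0.001


def _perfused_slab(n: int = 100, h: float = H) -> LabelVolume:
    """Dirichlet bolus | muscle column | Dirichlet bolus along y."""
    seq = ([int(Tissue.OVERLAY_BOLUS)] + [int(Tissue.MUSCLE)] * n
           + [int(Tissue.OVERLAY_BOLUS)])
    arr = np.tile(np.array(seq, dtype=np.int16)[None, :, None], (1, 1, 1))
    return LabelVolume(arr, h)


def test_assemble_pennes_sources_and_sinks(coarse_phantom, table):
    """Volumetric source rho*(SAR+q_m) and the unit-converted perfusion sink."""
    sar = FieldVolume.like(coarse_phantom,
                           np.full(coarse_phantom.shape, 5.0), "sar")
    co = bioheat.assemble_pennes(coarse_phantom, table, sar,
                                 bioheat.ThermalSetting())
    muscle = coarse_phantom.labels == int(Tissue.MUSCLE)
    assert np.allclose(co.source_vol[muscle], 1090 * 5.91)
    fat = coarse_phantom.labels == int(Tissue.FAT_SUBCUTANEOUS)
    assert np.allclose(co.sink_vol[fat],
                       911 * (32.7e-6 / 60) * 1050 * 3617, rtol=1e-12)
    ob = coarse_phantom.labels == int(Tissue.OVERLAY_BOLUS)
    assert np.all(co.dirichlet[ob])
    assert np.allclose(co.dirichlet_temp[ob], 5.0)
    igc_free = ~np.any(coarse_phantom.labels == int(Tissue.IGC_BOLUS))
    assert igc_free  # conventional arm has no cleft bolus


def test_rb_dirichlet_only_when_contacting_skin(coarse_config, table):
    from htsim.phantom import build_phantom
    ts = bioheat.ThermalSetting()
    with_ob = build_phantom(coarse_config, HeatingSetting())
    co = bioheat.assemble_pennes(with_ob, table, None, ts, rb_temperature=10.0)
    rb = with_ob.labels == int(Tissue.REGULAR_BOLUS)
    assert not np.any(co.dirichlet[rb])  # RB rests on the OB, not on skin
    no_ob = build_phantom(coarse_config, HeatingSetting(use_overlay_bolus=False))
    co2 = bioheat.assemble_pennes(no_ob, table, None, ts, rb_temperature=5.0)
    rb2 = no_ob.labels == int(Tissue.REGULAR_BOLUS)
    assert np.all(co2.dirichlet[rb2])
    assert np.allclose(co2.dirichlet_temp[rb2], 5.0)


def test_uniform_dirichlet_no_source_is_isothermal(table):
    vol = _perfused_slab(30)
    ts = bioheat.ThermalSetting(ob_boundary_temperature=37.0)
    co = bioheat.assemble_pennes(vol, table, None, ts)
    co.source_vol[:] = 0.0  # drop metabolic heat; T_b = 37 everywhere
    T = bioheat.solve_steady(co)
    assert np.allclose(T.values[co.unknown], 37.0, atol=1e-9)


def test_steady_matches_1d_cosh_sinh_solution(table):
    """Constant-coefficient perfused slab vs the analytic solution."""
    n = 100
    vol = _perfused_slab(n)
    k, P, S, tb = 0.49, 4.0, 50.0, 37.0
    t_end = 30.0
    ts = bioheat.ThermalSetting(ob_boundary_temperature=t_end, ambient_h=0.0)
    co = bioheat.assemble_pennes(vol, table, None, ts)
    co.k[:] = k  # override bolus water k too: uniform-k slab
    co.sink_vol[:] = np.where(co.unknown, P, 0.0)
    co.source_vol[:] = np.where(co.unknown, S, 0.0)
    T = bioheat.solve_steady(co)
    x = (np.arange(n) + 1) * H
    x0, xl = 0.0, (n + 1) * H
    m = np.sqrt(P / k)
    t_inf = tb + S / P
    u0, ul = t_end - t_inf, t_end - t_inf
    u = (ul * np.sinh(m * (x - x0)) + u0 * np.sinh(m * (xl - x))) / np.sinh(m * (xl - x0))
    exact = t_inf + u
    got = T.values[0, 1:-1, 0]
    assert np.max(np.abs(got - exact)) / np.max(np.abs(exact)) <= 1e-6


def test_energy_balance_closes(coarse_solution):
    eb = bioheat.energy_balance(coarse_solution["coeffs"],
                                coarse_solution["temp"])
    assert abs(eb["imbalance_w"]) <= 1e-6 * abs(eb["source_w"])


def test_superposition_and_v_squared_scaling(coarse_solution, table):
    """dT is linear in SAR, hence quadratic in the drive potential."""
    vol, adm = coarse_solution["vol"], coarse_solution["adm"]
    ts = coarse_solution["thermal"]
    setting = coarse_solution["setting"]
    sar1 = coarse_solution["sar"]
    t1 = coarse_solution["temp"]
    t0 = bioheat.solve_steady(bioheat.assemble_pennes(
        vol, table, None, ts, rb_temperature=setting.rb_temperature))
    sar2 = FieldVolume.like(vol, 4.0 * sar1.values, "sar")
    t2 = bioheat.solve_steady(bioheat.assemble_pennes(
        vol, table, sar2, ts, rb_temperature=setting.rb_temperature))
    lhs = t2.values - t0.values
    rhs = 4.0 * (t1.values - t0.values)
    scale = np.nanmax(np.abs(lhs))
    assert np.nanmax(np.abs(lhs - rhs)) <= 1e-8 * scale


def test_maximum_principle_without_source(coarse_solution, table):
    vol = coarse_solution["vol"]
    setting = coarse_solution["setting"]
    ts = coarse_solution["thermal"]
    co = bioheat.assemble_pennes(vol, table, None, ts,
                                 rb_temperature=setting.rb_temperature)
    co.source_vol[:] = 0.0
    T = bioheat.solve_steady(co)
    bounds = [ts.ob_boundary_temperature, ts.ambient_temperature, co.t_b]
    vals = T.values[co.unknown]
    assert vals.min() >= min(bounds) - 1e-9
    assert vals.max() <= max(bounds) + 1e-9


def test_singular_system_raises(table):
    labels = np.full((4, 6, 3), int(Tissue.IGC_BOLUS), dtype=np.int16)
    vol = LabelVolume(labels, 0.005)
    ts = bioheat.ThermalSetting(ambient_h=0.0)
    co = bioheat.assemble_pennes(vol, table, None, ts)
    # IGC bolus has no perfusion and there is no boundary anywhere
    with pytest.raises(ValueError, match="singular"):
        bioheat.solve_steady(co)


def test_transient_constant_under_uniform_equilibrium(table):
    vol = _perfused_slab(20)
    ts = bioheat.ThermalSetting(ob_boundary_temperature=37.0, duration=50.0)
    co = bioheat.assemble_pennes(vol, table, None, ts)
    co.source_vol[:] = 0.0
    res = bioheat.solve_transient(co, ts)
    assert np.allclose(res.final.values[co.unknown], 37.0, atol=1e-9)
    assert res.steadiness <= 1e-9


def test_transient_monotone_approach_to_steady(coarse_solution):
    """Max-norm distance to the steady solution is non-increasing in time."""
    co = coarse_solution["coeffs"]
    steady = coarse_solution["temp"]
    ts = bioheat.ThermalSetting(duration=600.0)
    res = bioheat.solve_transient(co, ts, snapshot_every=100.0)
    dists = [np.nanmax(np.abs(s.values - steady.values)) for s in res.snapshots]
    assert all(b <= a + 1e-12 for a, b in zip(dists, dists[1:]))


def test_transient_approaches_steady(coarse_solution):
    """After 3000 s the transient field is close to the direct steady state
    (residual set by the slowest perfusion-conduction mode)."""
    co = coarse_solution["coeffs"]
    res = bioheat.solve_transient(co, bioheat.ThermalSetting(duration=3000.0))
    diff = np.nanmax(np.abs(res.final.values - coarse_solution["temp"].values))
    assert diff <= 0.5
    assert res.steadiness <= 0.01


def test_resolution_convergence_of_tumor_temperature(table):
    """Steady tumor mean changes <0.2 K when halving the voxel spacing."""
    from htsim.phantom import PhantomConfig, build_phantom
    means = {}
    setting = HeatingSetting()
    for h in (0.004, 0.002):
        vol = build_phantom(PhantomConfig.fast_2d(spacing=h), setting)
        adm = em.assemble_admittivity(vol, table, setting)
        phi = em.solve_potential(adm, potential=55.0)
        sar = em.compute_sar(phi, adm, table, vol)
        ts = bioheat.ThermalSetting()
        T = bioheat.solve_steady(bioheat.assemble_pennes(
            vol, table, sar, ts, rb_temperature=setting.rb_temperature))
        means[h] = float(np.mean(T.values[vol.labels == int(Tissue.TUMOR)]))
    assert abs(means[0.004] - means[0.002]) < 0.2


def test_bolus_water_conductivity_used_on_dirichlet_faces(coarse_phantom, table):
    co = bioheat.assemble_pennes(coarse_phantom, table, None,
                                 bioheat.ThermalSetting())
    ob = coarse_phantom.labels == int(Tissue.OVERLAY_BOLUS)
    assert np.allclose(co.k[ob], WATER_THERMAL_K)
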