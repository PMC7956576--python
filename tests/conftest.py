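import numpy as np
import pytest

from htsim import bioheat, em
from htsim.experiments import ArmPipeline
from htsim.materials import MaterialTable
from htsim.phantom import HeatingSetting, PhantomConfig, build_phantom


@pytest.fixture(scope="session")
def table() -> MaterialTable:
    return MaterialTable.default()


@pytest.fixture(scope="session")
def coarse_config() -> PhantomConfig:
    """5 mm thin-slab profile: fast enough for per-module solver tests."""
    return PhantomConfig.fast_2d(spacing=0.005)


@pytest.fixture(scope="session")
def coarse_phantom(coarse_config):
    return build_phantom(coarse_config, HeatingSetting())


@pytest.fixture(scope="session")
def coarse_pipeline(coarse_config) -> ArmPipeline:
    return ArmPipeline(coarse_config)


@pytest.fixture(scope="session")
def coarse_solution(coarse_phantom, table):
    """One solved conventional arm (EM + SAR + steady T) at 55 V, 5 mm slab."""
    setting = HeatingSetting()
    adm = em.assemble_admittivity(coarse_phantom, table, setting)
    phi = em.solve_potential(adm, potential=55.0)
    sar = em.compute_sar(phi, adm, table, coarse_phantom)
    ts = bioheat.ThermalSetting()
    coeffs = bioheat.assemble_pennes(coarse_phantom, table, sar, ts,
                                     rb_temperature=setting.rb_temperature)
    temp = bioheat.solve_steady(coeffs)
    return {"setting": setting, "vol": coarse_phantom, "adm": adm, "phi": phi,
            "sar": sar, "coeffs": coeffs, "temp": temp, "thermal": ts}


def slab_1d(labels_1d: list[int], h: float = 0.005, width: int = 4):
    """Small pseudo-1D column volume (layers stacked along y)."""
    from htsim.volumes import LabelVolume

    arr = np.tile(np.array(labels_1d, dtype=np.int16)[None, :, None],
                  (width, 1, 3))
    return LabelVolume(arr, h)
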