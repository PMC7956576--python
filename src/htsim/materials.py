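"""Dielectric and thermal material properties at 8 MHz.

Ships the per-tissue property tables used throughout the simulation chain as
human-readable CSV inside the package (``htsim/data``): electric conductivity
sigma (S/m), relative permittivity eps_r, mass density rho (kg/m^3), specific
heat c (J/(kg K)), thermal conductivity k (W/(m K)), metabolic heat generation
q_m (W/kg) and blood perfusion w (mL/(min kg)).  The deep-target tumor carries
muscle properties; saline boluses are looked up by (NaCl concentration %,
temperature degC) with no interpolation between the tabulated pairs —
untabulated pairs raise, preventing silent extrapolation.

Perfusion enters the Pennes equation as a volumetric sink
``rho_tissue * w_SI * rho_b * c_b * (T - T_b)`` with
``w_SI = w * 1e-6 / 60`` (m^3 blood per second per kg tissue); the conversion
is applied once at table load (:meth:`ThermalProps.w_si`).
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import Tissue

#: Thermal conductivity of the circulating bolus water, W/(m K).  Used only to
#: couple the fixed-temperature bolus nodes to the skin surface.
WATER_THERMAL_K = 0.6

#: Dielectric properties of ambient air (excluded from the thermal domain).
AIR_DENSITY = 1.2


@dataclasses.dataclass(frozen=True)
class DielectricProps:
    """sigma (S/m), eps_r (-), rho (kg/m^3)."""

    sigma: float
    eps_r: float
    rho: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.eps_r < 1:
            raise ValueError(f"eps_r must be >= 1, got {self.eps_r}")
        if self.rho <= 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")


@dataclasses.dataclass(frozen=True)
class ThermalProps:
    """c (J/(kg K)), k (W/(m K)), q_m (W/kg), w (mL/(min kg))."""

    c: float
    k: float
    q_m: float
    w: float

    def __post_init__(self) -> None:
        if self.c <= 0 or self.k <= 0:
            raise ValueError("c and k must be > 0")
        if self.q_m < 0 or self.w < 0:
            raise ValueError("q_m and w must be >= 0")

    @property
    def w_si(self) -> float:
        """Perfusion in SI units: m^3 blood / (s kg tissue)."""
        return self.w * 1e-6 / 60.0


@dataclasses.dataclass(frozen=True)
class BloodConstants:
    """Arterial blood constants closing the Pennes perfusion sink.

    Standard literature values; configurable because they are not tissue-table
    entries.
    """

    rho_b: float = 1050.0  # kg/m^3
    c_b: float = 3617.0    # J/(kg K)
    t_b: float = 37.0      # degC

    def __post_init__(self) -> None:
        if self.rho_b <= 0 or self.c_b <= 0 or self.t_b <= 0:
            raise ValueError("blood constants must be positive")
        if not 30.0 <= self.t_b <= 40.0:
            raise ValueError(f"arterial temperature {self.t_b} outside [30, 40] degC")


_NAME_TO_TISSUE = {
    "muscle": Tissue.MUSCLE,
    "fat_subcutaneous": Tissue.FAT_SUBCUTANEOUS,
    "fat_other": Tissue.FAT_OTHER,
    "bone": Tissue.BONE,
    "tumor": Tissue.TUMOR,
    "igc_bolus": Tissue.IGC_BOLUS,
    "air": Tissue.AIR,
}
_TISSUE_TO_NAME = {v: k for k, v in _NAME_TO_TISSUE.items()}


class MaterialTable:
    """Lookup of material properties by tissue label and by saline pair."""

    def __init__(
        self,
        tissues: dict[Tissue, tuple[DielectricProps, ThermalProps | None]],
        saline: dict[tuple[float, float], DielectricProps],
        blood: BloodConstants | None = None,
    ) -> None:
        self.tissues = dict(tissues)
        self.saline = dict(saline)
        self.blood = blood or BloodConstants()
        self._validate()

    def _validate(self) -> None:
        tum = self.tissues.get(Tissue.TUMOR)
        mus = self.tissues.get(Tissue.MUSCLE)
        if tum is None or mus is None:
            raise ValueError("table must contain muscle and tumor entries")
        if tum != mus:
            raise ValueError("tumor properties must equal muscle properties")
        # saline conductivity must rise strictly with concentration at fixed T
        by_temp: dict[float, list[tuple[float, float]]] = {}
        for (conc, temp), d in self.saline.items():
            by_temp.setdefault(temp, []).append((conc, d.sigma))
        for temp, rows in by_temp.items():
            rows.sort()
            sigmas = [s for _, s in rows]
            if any(b <= a for a, b in zip(sigmas, sigmas[1:])):
                raise ValueError(
                    f"saline sigma not strictly increasing with concentration at {temp} degC"
                )

    # -- lookups ----------------------------------------------------------
    def tissue_props(self, label: Tissue | int) -> tuple[DielectricProps, ThermalProps | None]:
        label = Tissue(label)
        try:
            return self.tissues[label]
        except KeyError:
            raise KeyError(f"no material entry for label {label.name!r}") from None

    def saline_props(self, concentration: float, temperature: float) -> DielectricProps:
        key = (float(concentration), float(temperature))
        try:
            return self.saline[key]
        except KeyError:
            tab = sorted(self.saline)
            raise KeyError(
                f"saline pair (concentration={concentration}%, T={temperature} degC) "
                f"is not tabulated; available pairs: {tab} (no interpolation)"
            ) from None

    def igc_bolus_props(self) -> tuple[DielectricProps, ThermalProps]:
        """Intergluteal-cleft bolus: 5% NaCl at 10 degC dielectric, passive thermal."""
        d = self.saline_props(5, 10)
        t = self.tissues[Tissue.IGC_BOLUS][1]
        assert t is not None
        return d, t

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def default(cls, blood: BloodConstants | None = None) -> "MaterialTable":
        """Load the packaged CSV tables."""
        root = resources.files("htsim.data")
        with resources.as_file(root / "tissues.csv") as p_t, \
                resources.as_file(root / "saline.csv") as p_s:
            return cls.from_csv(p_t, p_s, blood=blood)

    @classmethod
    def from_csv(cls, tissues_path: str | Path, saline_path: str | Path,
                 blood: BloodConstants | None = None) -> "MaterialTable":
        tdf = pd.read_csv(tissues_path)
        sdf = pd.read_csv(saline_path)
        tissues: dict[Tissue, tuple[DielectricProps, ThermalProps | None]] = {}
        for row in tdf.itertuples(index=False):
            label = _NAME_TO_TISSUE[str(row.label)]
            d = DielectricProps(float(row.sigma), float(row.eps_r), float(row.rho))
            if pd.isna(row.c):
                th = None
            else:
                th = ThermalProps(float(row.c), float(row.k), float(row.q_m), float(row.w))
            tissues[label] = (d, th)
        saline = {
            (float(r.concentration_pct), float(r.temperature_c)):
                DielectricProps(float(r.sigma), float(r.eps_r), float(r.rho))
            for r in sdf.itertuples(index=False)
        }
        return cls(tissues, saline, blood=blood)

    def to_csv(self, tissues_path: str | Path, saline_path: str | Path) -> None:
        trows = []
        for label, (d, th) in self.tissues.items():
            row = {"label": _TISSUE_TO_NAME[label], "sigma": d.sigma,
                   "eps_r": d.eps_r, "rho": d.rho}
            if th is None:
                row.update({"c": np.nan, "k": np.nan, "q_m": np.nan, "w": np.nan})
            else:
                row.update({"c": th.c, "k": th.k, "q_m": th.q_m, "w": th.w})
            trows.append(row)
        pd.DataFrame(trows).to_csv(tissues_path, index=False)
        srows = [
            {"concentration_pct": c, "temperature_c": t, "sigma": d.sigma,
             "eps_r": d.eps_r, "rho": d.rho}
            for (c, t), d in self.saline.items()
        ]
        pd.DataFrame(srows).to_csv(saline_path, index=False)
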