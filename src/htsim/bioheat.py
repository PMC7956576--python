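"""Pennes bioheat solver on the voxel grid.

Solves

    rho c dT/dt = div(k grad T) - rho w_SI rho_b c_b (T - T_b) + rho (SAR + q_m)

over the body (plus the passive intergluteal-cleft bolus) with the study's
boundary conditions: overlay boluses held at their circulating-fluid
temperature (Dirichlet), regular boluses Dirichlet only when they contact
skin directly (the no-overlay arm), exposed skin coupled to ambient air by a
convective (Robin) boundary, electrodes adiabatic.  A direct steady-state
solve is provided alongside the backward-Euler transient path (the implicit
scheme is unconditionally stable, so the 1 s step does not face the explicit
diffusion limit at millimetre spacing).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from ._assembly import build_diffusion_system, face_slices, harmonic_mean
from .materials import MaterialTable, WATER_THERMAL_K
from .volumes import FieldVolume, LabelVolume, TISSUE_LABELS, Tissue


@dataclasses.dataclass
class ThermalSetting:
    """Thermal boundary conditions and transient controls.

    Units: temperatures degC, ``ambient_h`` W/(m^2 K), times s.
    """

    ob_boundary_temperature: float = 5.0
    ambient_temperature: float = 25.0
    ambient_h: float = 10.0
    initial_body_temperature: float = 37.0
    igc_initial_temperature: float = 10.0
    duration: float = 3000.0
    dt: float = 1.0
    steady_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0 or self.steady_tol <= 0:
            raise ValueError("duration, dt and steady_tol must be positive")


@dataclasses.dataclass
class PennesCoefficients:
    """Per-voxel coefficient grids of the discrete Pennes operator."""

    vol: LabelVolume
    k: np.ndarray            # W/(m K); 0 in excluded voxels
    rho: np.ndarray          # kg/m^3
    c: np.ndarray            # J/(kg K)
    source_vol: np.ndarray   # rho*(SAR + q_m), W/m^3
    sink_vol: np.ndarray     # rho*w_SI*rho_b*c_b, W/(m^3 K)
    t_b: float
    unknown: np.ndarray
    dirichlet: np.ndarray
    dirichlet_temp: np.ndarray
    air: np.ndarray
    initial_temp: np.ndarray
    setting: ThermalSetting

    def __post_init__(self) -> None:
        for name in ("k", "rho", "c", "source_vol", "sink_vol"):
            if getattr(self, name).shape != self.vol.shape:
                raise ValueError(f"{name} grid does not match the LabelVolume")
        if np.any(self.sink_vol < 0):
            raise ValueError("perfusion sink coefficient must be >= 0")


def assemble_pennes(vol: LabelVolume, table: MaterialTable,
                    sar: FieldVolume | None, setting: ThermalSetting,
                    rb_temperature: float = 5.0) -> PennesCoefficients:
    """Build the Pennes coefficient grids for one arm.

    ``rb_temperature`` is the regular-bolus circulating-fluid temperature,
    applied as a Dirichlet condition only when the RB touches skin (no
    overlay boluses present); with overlay boluses the RB rests on the OB and
    is excluded from the thermal domain.
    """
    labels = vol.labels
    blood = table.blood
    shape = vol.shape

    unknown = vol.mask(*TISSUE_LABELS, Tissue.IGC_BOLUS)
    ob = labels == int(Tissue.OVERLAY_BOLUS)
    rb = labels == int(Tissue.REGULAR_BOLUS)

    dirichlet = np.zeros(shape, bool)
    dirichlet_temp = np.zeros(shape, float)
    if ob.any():
        dirichlet |= ob
        dirichlet_temp[ob] = setting.ob_boundary_temperature
    if rb.any():
        touches_skin = bool(np.any(ndimage.binary_dilation(rb) & vol.body_mask()))
        if touches_skin:
            dirichlet |= rb
            dirichlet_temp[rb] = rb_temperature

    k = np.zeros(shape)
    rho = np.ones(shape)
    c = np.ones(shape)
    q_m = np.zeros(shape)
    sink = np.zeros(shape)
    for label in np.unique(labels):
        t = Tissue(int(label))
        m = labels == label
        if t in (Tissue.OVERLAY_BOLUS, Tissue.REGULAR_BOLUS):
            k[m] = WATER_THERMAL_K
            rho[m] = 1000.0
            c[m] = 4180.0
            continue
        if t in (Tissue.AIR, Tissue.ELECTRODE):
            continue
        d, th = table.tissue_props(t)
        if th is None:
            raise KeyError(f"label {t.name!r} has no thermal properties")
        k[m] = th.k
        rho[m] = d.rho
        c[m] = th.c
        q_m[m] = th.q_m
        sink[m] = d.rho * th.w_si * blood.rho_b * blood.c_b

    sar_vals = np.zeros(shape) if sar is None else np.asarray(sar.values, float)
    if sar is not None and sar.shape != shape:
        raise ValueError("SAR field is not co-registered with the LabelVolume")
    source = np.where(unknown, rho * (sar_vals + q_m), 0.0)
    sink = np.where(unknown, sink, 0.0)

    init = np.full(shape, setting.initial_body_temperature)
    init[labels == int(Tissue.IGC_BOLUS)] = setting.igc_initial_temperature
    init[dirichlet] = dirichlet_temp[dirichlet]

    return PennesCoefficients(
        vol=vol, k=k, rho=rho, c=c, source_vol=source, sink_vol=sink,
        t_b=blood.t_b, unknown=unknown, dirichlet=dirichlet,
        dirichlet_temp=dirichlet_temp, air=labels == int(Tissue.AIR),
        initial_temp=init, setting=setting)


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------

def _face_conductances(k: np.ndarray, unknown: np.ndarray, dirichlet: np.ndarray,
                       spacing: tuple[float, float, float]) -> list[np.ndarray]:
    """Harmonic-mean k*A/h on faces joining two active (unknown or Dirichlet)
    voxels; zero elsewhere (excluded regions and air are handled separately)."""
    active = unknown | dirichlet
    coefs = []
    for ax in range(3):
        lo, hi = face_slices(ax)
        kf = harmonic_mean(k[lo], k[hi])
        kf = np.where(active[lo] & active[hi], kf, 0.0)
        a_over_h = (np.prod(spacing) / spacing[ax]) / spacing[ax]
        coefs.append(kf * a_over_h)
    return coefs


def _robin_terms(coeffs: "PennesCoefficients", shape, unknown, air, k,
                 spacing, idx, n) -> tuple[np.ndarray, np.ndarray]:
    """Convective coupling of exposed tissue faces to ambient air.

    Series resistance of the half cell and the convective film:
    U = 1 / (h/2k + 1/h_amb), applied per exposed face.
    """
    st = coeffs.setting
    diag = np.zeros(n)
    rhs = np.zeros(n)
    if st.ambient_h <= 0:
        return diag, rhs
    for ax in range(3):
        area = np.prod(spacing) / spacing[ax]
        half = spacing[ax] / 2.0
        lo, hi = face_slices(ax)
        for me, nb in ((lo, hi), (hi, lo)):
            sel = unknown[me] & air[nb]
            if not np.any(sel):
                continue
            u = 1.0 / (half / k[me][sel] + 1.0 / st.ambient_h)
            rows = idx[me][sel]
            np.add.at(diag, rows, u * area)
            np.add.at(rhs, rows, u * area * st.ambient_temperature)
    return diag, rhs


def _build_steady_system(coeffs: PennesCoefficients, sl=None):
    """Assemble A T = b for the (optionally z-sliced) coefficient grids."""
    if sl is None:
        sl = (slice(None),) * 3
    vol = coeffs.vol
    k = coeffs.k[sl]
    unknown = coeffs.unknown[sl]
    dirichlet = coeffs.dirichlet[sl]
    dvals = coeffs.dirichlet_temp[sl]
    air = coeffs.air[sl]
    spacing = vol.spacing
    vcell = float(np.prod(spacing))

    coefs = _face_conductances(k, unknown, dirichlet, spacing)
    A, b, idx = build_diffusion_system(coefs, unknown, dirichlet, dvals)
    n = A.shape[0]
    if n == 0:
        raise ValueError("empty thermal domain")

    sinkv = coeffs.sink_vol[sl][unknown] * vcell
    srcv = coeffs.source_vol[sl][unknown] * vcell
    rdiag, rrhs = _robin_terms(coeffs, k.shape, unknown, air, k, spacing, idx, n)

    if not dirichlet.any() and np.all(sinkv == 0) and np.all(rdiag == 0):
        raise ValueError("singular thermal system: no boundary condition anywhere")

    A = A + sp.diags(sinkv + rdiag)
    b = b + srcv + sinkv * coeffs.t_b + rrhs
    return A, b, idx, unknown, dirichlet, dvals, sl


def _slab_slice(coeffs: PennesCoefficients):
    vol = coeffs.vol
    if not vol.slab_2d:
        return None
    for arr in (coeffs.k, coeffs.unknown, coeffs.dirichlet, coeffs.source_vol):
        if not np.all(arr == arr[:, :, :1]):
            return None
    mid = vol.shape[2] // 2
    return (slice(None), slice(None), slice(mid, mid + 1))


def _expand(vol: LabelVolume, field2d: np.ndarray) -> np.ndarray:
    return np.repeat(field2d, vol.shape[2], axis=2)


def solve_steady(coeffs: PennesCoefficients, tol: float = 1e-8) -> FieldVolume:
    """Direct steady-state solve of the Pennes system.

    Returns the temperature field (degC); voxels outside the thermal domain
    are NaN, Dirichlet voxels carry their prescribed temperatures.
    """
    sl = _slab_slice(coeffs)
    A, b, idx, unknown, dirichlet, dvals, used_sl = _build_steady_system(coeffs, sl)
    x = spla.spsolve(A.tocsc(), b)
    res = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300))
    if res > tol:
        raise RuntimeError(f"steady bioheat residual {res:.2e} exceeds {tol}")
    block = np.full(unknown.shape, np.nan)
    block[unknown] = x
    block[dirichlet] = dvals[dirichlet]
    T = _expand(coeffs.vol, block) if sl is not None else block
    return FieldVolume.like(coeffs.vol, T, "temperature",
                            meta={"residual": res, "solver": "steady-direct"})


@dataclasses.dataclass
class TransientResult:
    times: np.ndarray
    snapshots: list[FieldVolume]
    final: FieldVolume
    steadiness: float  # max |dT| over the last 10 steps, K


def solve_transient(coeffs: PennesCoefficients,
                    setting: ThermalSetting | None = None,
                    snapshot_every: float | None = None) -> TransientResult:
    """Backward-Euler transient integration from the initial temperatures.

    Factorizes (M/dt + A) once and reuses it for every step; reports the
    maximum temperature change over the last 10 steps as the steadiness
    measure.
    """
    setting = setting or coeffs.setting
    sl = _slab_slice(coeffs)
    A, b, idx, unknown, dirichlet, dvals, used_sl = _build_steady_system(coeffs, sl)
    if sl is None:
        sl = (slice(None),) * 3
    vcell = float(np.prod(coeffs.vol.spacing))
    m = (coeffs.rho[sl][unknown] * coeffs.c[sl][unknown] * vcell) / setting.dt

    lu = spla.splu((A + sp.diags(m)).tocsc())
    T = coeffs.initial_temp[sl][unknown].astype(float)

    nsteps = int(round(setting.duration / setting.dt))
    times = []
    snapshots: list[FieldVolume] = []
    deltas: list[float] = []

    def to_field(tvec: np.ndarray) -> FieldVolume:
        block = np.full(unknown.shape, np.nan)
        block[unknown] = tvec
        block[dirichlet] = dvals[dirichlet]
        full = _expand(coeffs.vol, block) if coeffs.vol.slab_2d and block.shape[2] == 1 else block
        return FieldVolume.like(coeffs.vol, full, "temperature",
                                meta={"solver": "transient-be"})

    next_snap = snapshot_every
    for step in range(1, nsteps + 1):
        Tn = lu.solve(m * T + b)
        deltas.append(float(np.max(np.abs(Tn - T))) if T.size else 0.0)
        T = Tn
        t = step * setting.dt
        if snapshot_every is not None and next_snap is not None and t >= next_snap - 1e-9:
            times.append(t)
            snapshots.append(to_field(T))
            next_snap += snapshot_every

    steadiness = float(max(deltas[-10:])) if deltas else 0.0
    final = to_field(T)
    final.meta["steadiness_k"] = steadiness
    final.meta["duration_s"] = nsteps * setting.dt
    return TransientResult(times=np.asarray(times), snapshots=snapshots,
                           final=final, steadiness=steadiness)


def energy_balance(coeffs: PennesCoefficients, temp: FieldVolume) -> dict[str, float]:
    """Steady-state power bookkeeping, W.

    ``source`` should equal ``perfusion + boundary`` (Dirichlet conduction +
    Robin convection) at steady state.
    """
    vol = coeffs.vol
    sl = (slice(None),) * 3
    spacing = vol.spacing
    vcell = float(np.prod(spacing))
    unknown = coeffs.unknown
    dirichlet = coeffs.dirichlet
    T = temp.values

    source = float(np.sum(coeffs.source_vol[unknown]) * vcell)
    perf = float(np.sum(coeffs.sink_vol[unknown] * (T[unknown] - coeffs.t_b)) * vcell)

    coefs = _face_conductances(coeffs.k, unknown, dirichlet, spacing)
    boundary = 0.0
    for ax in range(3):
        lo, hi = face_slices(ax)
        C = coefs[ax]
        for me, nb in ((lo, hi), (hi, lo)):
            sel = unknown[me] & dirichlet[nb]
            if np.any(sel):
                boundary += float(np.sum(
                    C[sel] * (T[me][sel] - coeffs.dirichlet_temp[nb][sel])))
        area = np.prod(spacing) / spacing[ax]
        half = spacing[ax] / 2.0
        st = coeffs.setting
        if st.ambient_h > 0:
            for me, nb in ((lo, hi), (hi, lo)):
                sel = unknown[me] & coeffs.air[nb]
                if np.any(sel):
                    u = 1.0 / (half / coeffs.k[me][sel] + 1.0 / st.ambient_h)
                    boundary += float(np.sum(
                        u * area * (T[me][sel] - st.ambient_temperature)))
    return {"source_w": source, "perfusion_w": perf, "boundary_w": boundary,
            "imbalance_w": source - perf - boundary}
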