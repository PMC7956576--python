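"""Electro-quasistatic field and SAR computation on the voxel grid.

At 8 MHz the body is small compared with the wavelength and tissue
conductivities are comparable to the displacement term, so Maxwell's
equations reduce to the complex scalar-potential problem

    div( (sigma + i omega eps0 eps_r) grad phi ) = 0,

with the electrode potential prescribed (Dirichlet +-V/2 on the two disks)
and insulating (zero normal current) conditions on the grid boundary.  The
discretization is a 7-point finite volume with harmonic-mean face
admittivities (exact for series layered media); electrodes are perfect
conductors, coupled through the half-cell admittivity of the adjacent
material.  The prescribed potential is interpreted as an RMS value, so
SAR = sigma |grad phi|^2 / rho with no factor 1/2.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._assembly import build_diffusion_system, face_slices, harmonic_mean
from .materials import AIR_DENSITY, MaterialTable
from .phantom import HeatingSetting
from .volumes import FieldVolume, LabelVolume, Tissue

#: Angular frequency of the 8 MHz drive, rad/s.
OMEGA = 2.0 * np.pi * 8.0e6
#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12

_DIRECT_LIMIT = 400_000  # unknowns above which the iterative path is used


@dataclasses.dataclass
class AdmittivityMap:
    """Per-voxel complex admittivity gamma = sigma + i omega eps0 eps_r (S/m).

    Carries the mass-density grid (needed by SAR) and the electrode mask;
    electrode voxels hold gamma = 0 and are treated as perfect conductors.
    """

    gamma: np.ndarray
    rho: np.ndarray
    electrode: np.ndarray
    vol: LabelVolume

    def __post_init__(self) -> None:
        if np.any(self.gamma.real < 0) or np.any(self.gamma.imag < 0):
            raise ValueError("admittivity must have non-negative real and imaginary parts")


def _dielectric_for_label(label: int, table: MaterialTable,
                          setting: HeatingSetting):
    t = Tissue(label)
    if t == Tissue.OVERLAY_BOLUS:
        return table.saline_props(setting.ob_concentration, setting.ob_temperature)
    if t == Tissue.REGULAR_BOLUS:
        return table.saline_props(setting.rb_concentration, setting.rb_temperature)
    if t == Tissue.IGC_BOLUS:
        return table.igc_bolus_props()[0]
    if t == Tissue.ELECTRODE:
        return None
    return table.tissue_props(t)[0]


def assemble_admittivity(vol: LabelVolume, table: MaterialTable,
                         setting: HeatingSetting) -> AdmittivityMap:
    """Map tissue labels and the arm's saline choices onto gamma and rho."""
    gamma = np.zeros(vol.shape, dtype=np.complex128)
    rho = np.full(vol.shape, AIR_DENSITY, dtype=np.float64)
    for label in np.unique(vol.labels):
        m = vol.labels == label
        d = _dielectric_for_label(int(label), table, setting)
        if d is None:  # electrode: perfect conductor, handled via Dirichlet
            continue
        gamma[m] = d.sigma + 1j * OMEGA * EPS0 * d.eps_r
        rho[m] = d.rho
    return AdmittivityMap(gamma=gamma, rho=rho,
                          electrode=vol.labels == int(Tissue.ELECTRODE), vol=vol)


def electrode_sets(vol: LabelVolume) -> tuple[np.ndarray, np.ndarray]:
    """Split electrode voxels into the dorsal (+y) and ventral (-y) plates."""
    elec = vol.labels == int(Tissue.ELECTRODE)
    if not elec.any():
        raise ValueError("volume contains no electrode voxels")
    ys = vol.axis_coords(1)
    dorsal = elec & (ys[None, :, None] > 0)
    ventral = elec & (ys[None, :, None] < 0)
    if not dorsal.any() or not ventral.any():
        raise ValueError("need electrode voxels on both sides of the body")
    return dorsal, ventral


def _face_admittances(gamma: np.ndarray, electrode: np.ndarray,
                      spacing: tuple[float, float, float]) -> list[np.ndarray]:
    """Face conductances gamma_f * A / h per axis.

    Harmonic mean between material voxels; a face against a perfect-conductor
    electrode carries 2*gamma of the material side (half-cell distance).
    """
    coefs = []
    for ax in range(3):
        lo, hi = face_slices(ax)
        g1, g2 = gamma[lo], gamma[hi]
        e1, e2 = electrode[lo], electrode[hi]
        gf = harmonic_mean(g1, g2)
        gf = np.where(e2 & ~e1, 2.0 * g1, gf)
        gf = np.where(e1 & ~e2, 2.0 * g2, gf)
        gf = np.where(e1 & e2, 0.0, gf)
        a_over_h = (np.prod(spacing) / spacing[ax]) / spacing[ax]
        coefs.append(gf * a_over_h)
    return coefs


def solve_potential(adm: AdmittivityMap,
                    electrodes: tuple[np.ndarray, np.ndarray] | None = None,
                    potential: float = 55.0,
                    method: str = "auto",
                    tol: float = 1e-8,
                    gauge_offset: float = 0.0) -> FieldVolume:
    """Solve the electro-quasistatic potential for a drive of ``potential`` V.

    Dirichlet ``gauge_offset`` +V/2 on the first electrode set and
    ``gauge_offset`` -V/2 on the second (only the difference is physical);
    Neumann on the grid boundary.  Returns the complex potential with the
    convergence residual in ``meta``.
    """
    vol = adm.vol
    if electrodes is None:
        electrodes = electrode_sets(vol)
    pos, neg = electrodes
    if np.any(pos & neg):
        raise ValueError("electrode sets overlap")
    if not pos.any() or not neg.any():
        raise ValueError("both electrode sets must be nonempty")
    if potential < 0:
        raise ValueError("potential must be >= 0")

    if vol.slab_2d and _z_invariant(adm.gamma) and _z_invariant(pos) and _z_invariant(neg):
        mid = vol.shape[2] // 2
        sl = (slice(None), slice(None), slice(mid, mid + 1))
        phi2d, res = _solve_block(adm.gamma[sl], adm.electrode[sl], pos[sl],
                                  neg[sl], vol.spacing, potential, method, tol,
                                  gauge_offset)
        phi = np.repeat(phi2d, vol.shape[2], axis=2)
    else:
        phi, res = _solve_block(adm.gamma, adm.electrode, pos, neg,
                                vol.spacing, potential, method, tol, gauge_offset)

    return FieldVolume.like(vol, phi, "potential",
                            meta={"potential_v": float(potential),
                                  "residual": res, "method": method,
                                  "convention": "rms"})


def _z_invariant(arr: np.ndarray) -> bool:
    return bool(np.all(arr == arr[:, :, :1]))


def _solve_block(gamma, electrode, pos, neg, spacing, potential, method, tol,
                 gauge_offset=0.0):
    coefs = _face_admittances(gamma, electrode, spacing)
    unknown = ~electrode
    dvals = np.zeros(gamma.shape, dtype=np.complex128)
    dvals[pos] = gauge_offset + potential / 2.0
    dvals[neg] = gauge_offset - potential / 2.0
    A, b, idx = build_diffusion_system(coefs, unknown, electrode, dvals,
                                       dtype=np.complex128)
    n = A.shape[0]
    if np.linalg.norm(b) == 0:
        x = np.zeros(n, dtype=np.complex128)
        res = 0.0
    else:
        use_direct = method == "direct" or (method == "auto" and n <= _DIRECT_LIMIT)
        if use_direct:
            x = spla.spsolve(A.tocsc(), b)
        else:
            ilu = spla.spilu(A.tocsc(), drop_tol=1e-5, fill_factor=20)
            M = spla.LinearOperator(A.shape, ilu.solve)
            x, info = spla.bicgstab(A, b, rtol=tol / 10, atol=0.0, M=M,
                                    maxiter=2000)
            if info != 0:
                raise RuntimeError(f"iterative EQS solve did not converge (info={info})")
        res = float(np.linalg.norm(A @ x - b) / np.linalg.norm(b))
        if res > tol:
            raise RuntimeError(f"EQS solve residual {res:.2e} exceeds tolerance {tol}")
    phi = np.empty(gamma.shape, dtype=np.complex128)
    phi[unknown] = x
    phi[electrode] = dvals[electrode]
    return phi, res


# ---------------------------------------------------------------------------
# field post-processing
# ---------------------------------------------------------------------------

def _interface_gradient(vals: np.ndarray, labels: np.ndarray,
                        spacing: tuple[float, float, float]) -> list[np.ndarray]:
    """Per-axis gradient: central inside a material, one-sided at interfaces."""
    out = []
    for ax in range(3):
        h = spacing[ax]
        v = np.moveaxis(vals, ax, 0)
        lab = np.moveaxis(labels, ax, 0)
        g = np.diff(v, axis=0) / h
        gl = np.zeros_like(v)
        gr = np.zeros_like(v)
        gl[1:] = g
        gr[:-1] = g
        has_l = np.zeros(v.shape, bool)
        has_r = np.zeros(v.shape, bool)
        has_l[1:] = True
        has_r[:-1] = True
        same = lab[:-1] == lab[1:]
        same_l = np.zeros(v.shape, bool)
        same_r = np.zeros(v.shape, bool)
        same_l[1:] = same
        same_r[:-1] = same
        sl = has_l & same_l
        sr = has_r & same_r
        grad = np.where(
            sl & sr, 0.5 * (gl + gr),
            np.where(sl, gl,
                     np.where(sr, gr,
                              np.where(has_l & has_r, 0.5 * (gl + gr),
                                       np.where(has_l, gl, gr)))))
        out.append(np.moveaxis(grad, 0, ax))
    return out


def compute_e_magnitude(phi: FieldVolume, vol: LabelVolume) -> FieldVolume:
    """|E| = |grad phi| (RMS, V/m)."""
    grads = _interface_gradient(phi.values, vol.labels, vol.spacing)
    e2 = sum(np.abs(g) ** 2 for g in grads)
    return FieldVolume.like(vol, np.sqrt(e2), "e_magnitude", meta=dict(phi.meta))


def compute_sar(phi: FieldVolume, adm: AdmittivityMap, table: MaterialTable,
                vol: LabelVolume) -> FieldVolume:
    """SAR = sigma |E|^2 / rho per voxel (W/kg), zero in air and electrodes."""
    grads = _interface_gradient(phi.values, vol.labels, vol.spacing)
    e2 = sum(np.abs(g) ** 2 for g in grads)
    sigma = adm.gamma.real
    sar = sigma * e2 / adm.rho
    sar[adm.electrode] = 0.0
    sar[vol.labels == int(Tissue.AIR)] = 0.0
    meta = dict(phi.meta)
    meta["sar_convention"] = "sigma*|E_rms|^2/rho"
    return FieldVolume.like(vol, sar, "sar", meta=meta)


def plane_current(phi: FieldVolume, adm: AdmittivityMap, axis: int,
                  index: int) -> complex:
    """Total complex current through the cut plane between ``index`` and
    ``index+1`` along ``axis`` (A)."""
    spacing = adm.vol.spacing
    coefs = _face_admittances(adm.gamma, adm.electrode, spacing)[axis]
    lo, hi = face_slices(axis)
    dphi = phi.values[lo] - phi.values[hi]
    sel = [slice(None)] * 3
    sel[axis] = index
    return complex(np.sum(coefs[tuple(sel)] * dphi[tuple(sel)]))
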