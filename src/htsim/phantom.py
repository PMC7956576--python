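"""Parametric synthetic obese-pelvis voxel phantom.

The phantom stands in for a segmented patient CT of an obese prone pelvis:
an elliptical-cylinder torso with a thick subcutaneous-fat shell over a
muscle bulk, simplified pelvic bone (two lateral iliac/femoral blocks and a
midline sacral block placed cranially of the target), a small visceral-fat
compartment, a spherical midline deep-target tumor sitting just ventral to a
dorsal intergluteal cleft, and the capacitive heating hardware: two 30 cm
disk electrodes (dorsal and ventral), regular boluses (RB) between electrode
and skin, optional conformal overlay boluses (OB) extending laterally beyond
the electrode footprint, and an optional high-salinity bolus filling the
cleft (IGC bolus).

Geometry is emitted as a :class:`~htsim.volumes.LabelVolume`.  Two profiles
exist: full 3D (default 5 mm spacing) and a thin-slab fast mode (three
z-layers through the tumor-center axial plane, default 2 mm) in which all
structures are extruded along z and solvers reduce to 2D.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .volumes import BOLUS_LABELS, LabelVolume, TISSUE_LABELS, Tissue

#: NaCl concentrations (%) with tabulated dielectric data.
TABULATED_CONCENTRATIONS = (0.1, 0.5, 1.0, 5.0)


@dataclasses.dataclass
class PhantomConfig:
    """Geometry and discretization of the synthetic phantom (lengths in m).

    Defaults emulate a BMI-29 pelvis: 0.40 m lateral width, 0.26 m AP
    thickness, 25 mm ventral / 40 mm dorsal subcutaneous fat with buttock
    pads thickened to 65 mm flanking a 55 mm deep intergluteal cleft, and a
    30 mm radius tumor centered on the midline 30 mm dorsal of the torso
    mid-plane (just ventral to the cleft bottom).
    """

    torso_half_width: float = 0.20        # lateral semi-axis (x)
    torso_half_thickness: float = 0.13    # AP semi-axis (y)
    torso_length: float = 0.56            # cranio-caudal extent (z)
    sf_ventral: float = 0.025             # subcutaneous fat thicknesses
    sf_dorsal: float = 0.04
    sf_lateral: float = 0.025
    buttock_half_width: float = 0.08      # buttock pad |x| extent
    buttock_depth: float = 0.065          # pad depth from dorsal apex
    cleft_depth: float = 0.055            # intergluteal cleft wedge depth
    cleft_half_width: float = 0.02        # wedge half-opening at the surface
    tumor_center_y: float = 0.03          # dorsal offset of tumor center
    tumor_center_z: float = 0.0
    tumor_radius: float = 0.03
    electrode_diameter: float = 0.30
    electrode_thickness: float = 0.005
    rb_thickness: float = 0.02            # skin-apex to electrode gap
    ob_thickness: float = 0.010           # conformal overlay-bolus shell
    ob_overhang: float = 0.10             # OB footprint beyond electrode rim
    ob_flank_gap: float = 0.02            # dorsal/ventral pads end |y| > gap
    spacing: float = 0.005
    slab_2d: bool = False
    air_margin: float = 0.010
    roughness_amplitude: float = 0.0      # relative skin-surface perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("slab_2d", "seed", "roughness_amplitude",
                              "tumor_center_y", "tumor_center_z")
        }
        for name, v in lengths.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.roughness_amplitude < 0:
            raise ValueError("roughness_amplitude must be >= 0")
        # tumor sphere strictly inside the muscle compartment (coarse check;
        # the voxelized check runs in build_phantom)
        b_in_dorsal = self.torso_half_thickness - self.sf_dorsal
        if self.tumor_center_y + self.tumor_radius >= b_in_dorsal + self.sf_dorsal:
            raise ValueError("tumor escapes the torso dorsally")
        if self.tumor_radius >= self.torso_half_width - self.sf_lateral:
            raise ValueError("tumor radius exceeds the muscle compartment")

    @classmethod
    def fast_2d(cls, spacing: float = 0.002, **kw) -> "PhantomConfig":
        """Thin-slab profile: a 3-voxel axial slab through the tumor center."""
        return cls(spacing=spacing, slab_2d=True, **kw)

    # -- config file I/O (keys carry explicit units) -----------------------
    _UNITLESS = ("slab_2d", "seed", "roughness_amplitude")

    def to_yaml(self, path: str | Path) -> None:
        out = {}
        for f in dataclasses.fields(self):
            key = f.name if f.name in self._UNITLESS else f"{f.name}_m"
            out[key] = getattr(self, f.name)
        Path(path).write_text(yaml.safe_dump(out, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kw = {}
        for key, v in raw.items():
            name = key[:-2] if key.endswith("_m") else key
            kw[name] = v
        return cls(**kw)


@dataclasses.dataclass
class HeatingSetting:
    """One experimental arm: bolus layout, saline choices, electrode drive.

    The conventional arm uses overlay boluses with 0.5 % NaCl circulating at
    5 degC and regular boluses of 5 % NaCl at 10 degC; without OBs the
    cooled 0.5 % / 5 degC saline circulates in the RBs instead.
    """

    use_overlay_bolus: bool = True
    ob_concentration: float = 0.5
    ob_temperature: float = 5.0
    rb_concentration: float | None = None
    rb_temperature: float | None = None
    use_igc_bolus: bool = False
    electrode_potential: float = 55.0

    def __post_init__(self) -> None:
        if self.rb_concentration is None:
            self.rb_concentration = 5.0 if self.use_overlay_bolus else 0.5
        if self.rb_temperature is None:
            self.rb_temperature = 10.0 if self.use_overlay_bolus else 5.0
        for name, conc in (("ob_concentration", self.ob_concentration),
                           ("rb_concentration", self.rb_concentration)):
            if not any(np.isclose(conc, c) for c in TABULATED_CONCENTRATIONS):
                raise ValueError(
                    f"{name}={conc} is not a tabulated concentration "
                    f"{TABULATED_CONCENTRATIONS}")
        if self.electrode_potential < 0:
            raise ValueError("electrode_potential must be >= 0")
        if not 40.0 <= self.electrode_potential <= 70.0:
            warnings.warn(
                f"electrode potential {self.electrode_potential} V outside the "
                "conventional 40-70 V range", stacklevel=2)

    def key(self) -> tuple:
        """Hashable identity of the arm (used for pipeline caching)."""
        return (self.use_overlay_bolus, self.ob_concentration, self.ob_temperature,
                self.rb_concentration, self.rb_temperature, self.use_igc_bolus,
                self.electrode_potential)


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

def _sym_coords(half_extent: float, h: float) -> np.ndarray:
    """Voxel centers symmetric about 0 covering at least +-half_extent."""
    n = 2 * int(np.ceil(half_extent / h)) + 1
    return (np.arange(n) - (n - 1) / 2.0) * h


def build_phantom(config: PhantomConfig, setting: HeatingSetting) -> LabelVolume:
    """Voxelize the phantom for one heating setting.

    Raises if the tumor sphere is not strictly inside the muscle compartment
    or if overlay and regular bolus regions overlap (they cannot by
    construction; the check guards future geometry edits).
    """
    h = config.spacing
    a = config.torso_half_width
    b = config.torso_half_thickness
    L = config.torso_length
    r_e = config.electrode_diameter / 2.0
    r_ob = r_e + config.ob_overhang
    y_e = b + config.ob_thickness + config.rb_thickness  # electrode inner face

    xs = _sym_coords(a + config.ob_thickness + config.air_margin, h)
    ys = _sym_coords(y_e + config.electrode_thickness + config.air_margin + h, h)
    if config.slab_2d:
        zs = np.array([-h, 0.0, h]) + config.tumor_center_z
    else:
        zs = _sym_coords(L / 2.0 + config.air_margin, h)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    in_z = np.abs(Z) <= L / 2.0 if not config.slab_2d else np.ones_like(Z, bool)

    # torso surface, optionally roughened by smooth azimuthal harmonics
    r2 = (X / a) ** 2 + (Y / b) ** 2
    surface = np.sqrt(r2)
    if config.roughness_amplitude > 0:
        rng = np.random.default_rng(config.seed)
        theta = np.arctan2(Y / b, X / a)
        delta = np.zeros_like(theta)
        for m in range(2, 6):
            cm, sm = rng.normal(0, 1, 2)
            delta += cm * np.cos(m * theta) + sm * np.sin(m * theta)
        delta *= config.roughness_amplitude / 4.0
        surface = surface / (1.0 + delta)
    ellipse = (surface <= 1.0) & in_z

    labels = np.full(X.shape, int(Tissue.AIR), dtype=np.int16)
    labels[ellipse] = int(Tissue.FAT_SUBCUTANEOUS)

    # inner (muscle) compartment: direction-dependent fat thickness via a
    # shifted inner ellipse
    a_in = a - config.sf_lateral
    b_in = b - (config.sf_ventral + config.sf_dorsal) / 2.0
    yc_in = (config.sf_ventral - config.sf_dorsal) / 2.0
    inner = ((X / a_in) ** 2 + ((Y - yc_in) / b_in) ** 2 <= 1.0) & ellipse
    if not config.slab_2d:
        inner &= np.abs(Z) <= L / 2.0 - config.sf_lateral
    labels[inner] = int(Tissue.MUSCLE)

    # buttock fat pads flanking the cleft: smooth (cos^2-windowed) dorsal
    # thickening, avoiding sharp fat corners that would concentrate the field
    extra = np.where(
        np.abs(X) <= config.buttock_half_width,
        (config.buttock_depth - config.sf_dorsal)
        * np.cos(np.pi * X / (2.0 * config.buttock_half_width)) ** 2,
        0.0)
    pad = ellipse & (Y > 0) & (Y >= b - config.sf_dorsal - extra)
    labels[pad] = int(Tissue.FAT_SUBCUTANEOUS)

    # small visceral-fat deposits: paired lateral pockets (the midline path
    # between pubis and cervix is muscle-equivalent viscera)
    visceral = np.zeros_like(ellipse)
    for sx in (-1.0, 1.0):
        visceral |= (((X - sx * 0.30 * a) / (0.125 * a)) ** 2
                     + ((Y + 0.15 * b) / (0.15 * b)) ** 2
                     + ((Z - config.tumor_center_z) / 0.06) ** 2) <= 1.0
    labels[visceral & (labels == int(Tissue.MUSCLE))] = int(Tissue.FAT_OTHER)

    # simplified pelvic bone
    lat = ((np.abs(X) >= 0.45 * a) & (np.abs(X) <= 0.65 * a)
           & (np.abs(Y) <= 0.31 * b)
           & (np.abs(Z - config.tumor_center_z) <= 0.10))
    labels[lat & (labels == int(Tissue.MUSCLE))] = int(Tissue.BONE)
    sacrum = ((np.abs(X) <= 0.03) & (Y >= 0.31 * b) & (Y <= 0.46 * b)
              & (Z - config.tumor_center_z >= 0.06)
              & (Z - config.tumor_center_z <= 0.16))
    labels[sacrum & (labels == int(Tissue.MUSCLE))] = int(Tissue.BONE)

    # intergluteal cleft: dorsal midline wedge, carved from the buttock fat
    y_cleft_bottom = b - config.cleft_depth
    wedge = (ellipse & (Y >= y_cleft_bottom)
             & (np.abs(X) <= config.cleft_half_width
                * (Y - y_cleft_bottom) / config.cleft_depth))
    if not config.slab_2d:
        wedge &= np.abs(Z - config.tumor_center_z) <= L / 2.0
    labels[wedge] = int(Tissue.IGC_BOLUS) if setting.use_igc_bolus else int(Tissue.AIR)

    # deep target tumor (sphere; extruded disk in slab mode)
    d2 = X ** 2 + (Y - config.tumor_center_y) ** 2
    if not config.slab_2d:
        d2 = d2 + (Z - config.tumor_center_z) ** 2
    tumor = d2 <= config.tumor_radius ** 2
    if tumor.any() and not np.all(labels[tumor] == int(Tissue.MUSCLE)):
        bad = sorted({Tissue(int(v)).name for v in np.unique(labels[tumor])
                      if v != int(Tissue.MUSCLE)})
        raise ValueError(f"tumor sphere is not strictly inside muscle; overlaps {bad}")
    labels[tumor] = int(Tissue.TUMOR)

    # -- heating hardware --------------------------------------------------
    if config.slab_2d:
        fp_e = np.abs(X) <= r_e
        fp_ob = np.abs(X) <= r_ob
    else:
        fp2 = X ** 2 + (Z - config.tumor_center_z) ** 2
        fp_e = fp2 <= r_e ** 2
        fp_ob = fp2 <= r_ob ** 2

    # conformal overlay boluses over the (uncarved) torso surface; they bridge
    # the cleft opening rather than dipping into it
    if setting.use_overlay_bolus:
        dist_out = ndimage.distance_transform_edt(~ellipse, sampling=h)
        shell = (~ellipse) & (dist_out <= config.ob_thickness + 1e-9)
        # separate dorsal and ventral pads, leaving the flank equator free
        ob = (shell & fp_ob & (labels == int(Tissue.AIR))
              & (np.abs(Y) > config.ob_flank_gap))
        labels[ob] = int(Tissue.OVERLAY_BOLUS)

    # electrodes: thin disks at the end of the RB stack, dorsal and ventral
    n_e = max(1, int(round(config.electrode_thickness / h)))
    elec = (fp_e & (np.abs(Y) > y_e)
            & (np.abs(Y) <= y_e + n_e * h + 1e-12)
            & (labels == int(Tissue.AIR)))
    labels[elec] = int(Tissue.ELECTRODE)

    # regular boluses: fill between skin (or OB) and the electrode plane
    rb = (fp_e & (np.abs(Y) <= y_e) & (~ellipse)
          & (labels == int(Tissue.AIR)))
    labels[rb] = int(Tissue.REGULAR_BOLUS)

    if setting.use_overlay_bolus:
        overlap = (labels == int(Tissue.REGULAR_BOLUS)) & (labels == int(Tissue.OVERLAY_BOLUS))
        if overlap.any():  # pragma: no cover - impossible by construction
            raise ValueError("overlay and regular bolus regions overlap")

    origin = (float(xs[0]), float(ys[0]), float(zs[0]))
    return LabelVolume(labels=labels, spacing=(h, h, h), origin=origin,
                       slab_2d=config.slab_2d)


# ---------------------------------------------------------------------------
# evaluation regions
# ---------------------------------------------------------------------------

def _footprint(mask3d: np.ndarray) -> np.ndarray:
    """Project a voxel mask onto the (x, z) plane (along the AP axis)."""
    return mask3d.any(axis=1)


def region_masks(vol: LabelVolume, edge_band_width: float = 0.02) -> dict[str, np.ndarray]:
    """Named boolean evaluation masks.

    ``sf_edge`` is the band of subcutaneous-fat voxels within
    ``edge_band_width`` (default 2 cm) of the rim of the active cooling-bolus
    footprint — the OB rim when overlay boluses are present, else the RB rim.
    ``sf_under_electrode`` restricts subcutaneous fat to the electrode-disk
    footprint projection; ``body`` is the union of all tissue labels.
    """
    labels = vol.labels
    ob = labels == int(Tissue.OVERLAY_BOLUS)
    rb = labels == int(Tissue.REGULAR_BOLUS)
    active = ob if ob.any() else rb
    if not active.any():
        raise ValueError("volume contains no cooling-bolus voxels")

    fp = _footprint(active)
    if vol.slab_2d:
        # the slab is a section of an infinitely extruded geometry: the
        # footprint rim exists only in x
        structure = np.zeros((3, 3), bool)
        structure[:, 1] = True
    else:
        structure = ndimage.generate_binary_structure(2, 2)
    rim2d = fp & ~ndimage.binary_erosion(fp, structure=structure)
    rim3d = active & rim2d[:, None, :]

    sf = labels == int(Tissue.FAT_SUBCUTANEOUS)
    if edge_band_width <= 0:
        sf_edge = np.zeros_like(sf)
    else:
        dist = ndimage.distance_transform_edt(~rim3d, sampling=vol.spacing)
        sf_edge = sf & (dist <= edge_band_width + 1e-12)

    fp_e = _footprint(labels == int(Tissue.ELECTRODE))
    body = vol.body_mask()
    tumor = labels == int(Tissue.TUMOR)
    return {
        "tumor": tumor,
        "sf_all": sf,
        "sf_edge": sf_edge,
        "sf_under_electrode": sf & fp_e[:, None, :],
        "body": body,
        "body_outside_tumor": body & ~tumor,
        "body_outside_electrode": body & ~fp_e[:, None, :],
    }


def reference_slices(vol: LabelVolume) -> dict[str, tuple[np.ndarray, ...]]:
    """Index sets for the standard evaluation sections.

    Returns the full axial plane through the tumor center plus coronal lines
    (fixed y, varying x, at the tumor-center axial plane): through the tumor
    center, through the dorsal subcutaneous-fat centroid depth, through the
    buttock-pad depth, and through the ventral subcutaneous-fat centroid.
    Each entry is an ``(i, j, k)`` index triple into the grid.
    """
    tumor = vol.labels == int(Tissue.TUMOR)
    if not tumor.any():
        raise ValueError("phantom has no tumor voxels")
    ci, cj, ck = (int(round(c)) for c in ndimage.center_of_mass(tumor))
    nx, ny, nz = vol.shape

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    axial = (ii.ravel(), jj.ravel(), np.full(ii.size, ck))

    sf = vol.labels == int(Tissue.FAT_SUBCUTANEOUS)
    ys = vol.axis_coords(1)
    dorsal = sf & (ys[None, :, None] > 0)
    ventral = sf & (ys[None, :, None] < 0)

    def line_at(j: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = np.arange(nx)
        return (i, np.full(nx, j), np.full(nx, ck))

    j_dorsal = int(round(ndimage.center_of_mass(dorsal)[1]))
    j_ventral = int(round(ndimage.center_of_mass(ventral)[1]))
    # pad line: midway between the dorsal SF centroid and the dorsal skin apex
    j_top = int(np.where(dorsal.any(axis=(0, 2)))[0].max())
    j_pad = (j_dorsal + j_top) // 2

    return {
        "axial_tumor": axial,
        "tumor_coronal_line": line_at(cj),
        "dorsal_sf_line_e": line_at(j_dorsal),
        "dorsal_sf_line_f": line_at(j_pad),
        "ventral_sf_line_b": line_at(j_ventral),
    }
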