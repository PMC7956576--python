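"""Voxel containers shared by every solver stage.

A :class:`LabelVolume` is an axis-aligned regular grid of integer tissue /
material labels with physical spacing metadata; every field produced by the
electromagnetic and thermal solvers is a :class:`FieldVolume` co-registered
with it.  Conventions: 0-based indices, voxel-center physical coordinates,
right-handed axes with x lateral, y antero-posterior (dorsal = +y) and
z cranio-caudal.  Lengths are metres throughout.
"""

from __future__ import annotations

import dataclasses
import json
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np


class Tissue(IntEnum):
    """Declared label set of the phantom."""

    AIR = 0
    MUSCLE = 1
    FAT_SUBCUTANEOUS = 2
    FAT_OTHER = 3
    BONE = 4
    TUMOR = 5
    REGULAR_BOLUS = 6
    OVERLAY_BOLUS = 7
    IGC_BOLUS = 8
    ELECTRODE = 9


#: Labels that constitute the body (the thermal "tissue" domain minus boluses).
TISSUE_LABELS = (
    Tissue.MUSCLE,
    Tissue.FAT_SUBCUTANEOUS,
    Tissue.FAT_OTHER,
    Tissue.BONE,
    Tissue.TUMOR,
)

BOLUS_LABELS = (Tissue.REGULAR_BOLUS, Tissue.OVERLAY_BOLUS, Tissue.IGC_BOLUS)

LABEL_NAMES = {int(t): t.name.lower() for t in Tissue}


def _as_tuple3(v) -> tuple[float, float, float]:
    if np.isscalar(v):
        return (float(v),) * 3
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError("spacing/origin must be scalar or length-3")
    return t


@dataclasses.dataclass
class LabelVolume:
    """Integer tissue/material label per voxel on a regular 3D grid.

    Parameters
    ----------
    labels:
        ``(nx, ny, nz)`` integer array with values from :class:`Tissue`.
    spacing:
        Voxel edge lengths in metres (scalar or per-axis triple).
    origin:
        Physical coordinate of the center of voxel ``(0, 0, 0)``, metres.
    slab_2d:
        True for the thin-slab fast mode (labels invariant along z, Neumann
        z-faces make the problem effectively two-dimensional).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_names: dict[int, str] = dataclasses.field(
        default_factory=lambda: dict(LABEL_NAMES)
    )
    slab_2d: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        declared = set(int(t) for t in Tissue)
        present = set(np.unique(self.labels).tolist())
        if not present <= declared:
            raise ValueError(f"unknown labels present: {sorted(present - declared)}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel, m^3."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates along ``axis``, metres."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2),
            indexing="ij",
        )

    # -- masks ------------------------------------------------------------
    def mask(self, *tissues: Tissue) -> np.ndarray:
        return np.isin(self.labels, [int(t) for t in tissues])

    def body_mask(self) -> np.ndarray:
        return self.mask(*TISSUE_LABELS)

    # -- I/O --------------------------------------------------------------
    def save_nifti(self, path: str | Path) -> None:
        """Write labels as unsigned-int NIfTI (spacing in mm in the header)."""
        affine = np.diag([s * 1000.0 for s in self.spacing] + [1.0])
        affine[:3, 3] = [o * 1000.0 for o in self.origin]
        img = nib.Nifti1Image(self.labels.astype(np.uint8), affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
        sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
        meta = {"slab_2d": self.slab_2d, "label_names": self.label_names}
        Path(f"{sidecar}.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load_nifti(cls, path: str | Path) -> "LabelVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(affine[i, i]) / 1000.0 for i in range(3))
        origin = tuple(float(affine[i, 3]) / 1000.0 for i in range(3))
        sidecar = Path(str(path)).with_suffix("").with_suffix("")
        slab = False
        names = dict(LABEL_NAMES)
        meta_path = Path(f"{sidecar}.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            slab = bool(meta.get("slab_2d", False))
            names = {int(k): v for k, v in meta.get("label_names", names).items()}
        return cls(
            labels=np.asarray(img.dataobj).astype(np.int16),
            spacing=spacing,
            origin=origin,
            label_names=names,
            slab_2d=slab,
        )


FIELD_KINDS = ("potential", "e_magnitude", "sar", "temperature")


@dataclasses.dataclass
class FieldVolume:
    """Scalar field co-registered with a :class:`LabelVolume`.

    ``values`` may be complex for the electric potential; SAR and temperature
    are real.  ``meta`` records provenance (setting, residuals, conventions).
    """

    values: np.ndarray
    kind: str
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slab_2d: bool = False
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.kind not in FIELD_KINDS:
            raise ValueError(f"kind must be one of {FIELD_KINDS}, got {self.kind!r}")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if self.kind == "sar":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and np.min(finite) < 0:
                raise ValueError("SAR must be non-negative")

    @classmethod
    def like(cls, vol: LabelVolume, values: np.ndarray, kind: str,
             meta: dict | None = None) -> "FieldVolume":
        if np.shape(values) != vol.shape:
            raise ValueError("field shape does not match its LabelVolume")
        return cls(values=np.asarray(values), kind=kind, spacing=vol.spacing,
                   origin=vol.origin, slab_2d=vol.slab_2d, meta=meta or {})

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def save_nifti(self, path: str | Path) -> None:
        """Write as float32 NIfTI plus a JSON sidecar with the metadata."""
        data = self.values
        if np.iscomplexobj(data):
            data = np.abs(data)
        affine = np.diag([s * 1000.0 for s in self.spacing] + [1.0])
        affine[:3, 3] = [o * 1000.0 for o in self.origin]
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
        nib.save(img, str(path))
        sidecar = Path(str(path)).with_suffix("").with_suffix("")
        meta = {"kind": self.kind, "slab_2d": self.slab_2d}
        meta.update({k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, bool, list, dict))})
        Path(f"{sidecar}.json").write_text(json.dumps(meta, indent=1))
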