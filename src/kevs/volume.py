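"""CT volumes, label maps, and binary masks: containers, NIfTI I/O, resampling.

Conventions
-----------
Arrays are indexed ``(x, y, z)`` with ``z`` the slowest-varying cranio-caudal
axis, so ``data[:, :, k]`` is an axial slice.  Voxel indices are 0-based and
address voxel centres; the 4x4 ``affine`` maps voxel indices to world
coordinates in mm (taken from / written to the NIfTI header).  Intensities
are Hounsfield units and are never rescaled on read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume",
    "LabelMap",
    "BinaryMask",
    "DEFAULT_SCHEMA",
    "DEFAULT_ORGAN_LABELS",
    "DEFAULT_VERTEBRA_LABELS",
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "resample_to_spacing",
    "extract_mask",
    "merge_label_maps",
]

#: Unified internal label schema.  External schemas (whole-body segmenters,
#: body-composition annotations) are mapped onto these names on read.
DEFAULT_SCHEMA: dict[str, int] = {
    "abdominal_cavity": 1,
    "thoracic_cavity": 2,
    "subcutaneous_fat": 3,
    "muscle": 4,
    "cutis": 5,
    "vertebra_L1": 6,
    "vertebra_L2": 7,
    "vertebra_L3": 8,
    "vertebra_L4": 9,
    "vertebra_L5": 10,
    "liver": 11,
    "spleen": 12,
    "stomach": 13,
    "pancreas": 14,
    "gallbladder": 15,
    "kidney_left": 16,
    "kidney_right": 17,
    "intestine": 18,
    "bladder": 19,
}

#: Labels counted as "abdominal organs" when building the organ-free cavity.
#: A config list, not hard-coded into the pipeline functions.
DEFAULT_ORGAN_LABELS: tuple[str, ...] = (
    "liver",
    "spleen",
    "stomach",
    "pancreas",
    "gallbladder",
    "kidney_left",
    "kidney_right",
    "intestine",
    "bladder",
)

DEFAULT_VERTEBRA_LABELS: tuple[str, ...] = (
    "vertebra_L1",
    "vertebra_L2",
    "vertebra_L3",
    "vertebra_L4",
    "vertebra_L5",
)


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3D scalar field of Hounsfield units on a regular grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"CTVolume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CTVolume data contains non-finite values")
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag((*self.spacing, 1.0))
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class LabelMap:
    """Integer-valued field aligned voxel-for-voxel with a CTVolume.

    ``schema`` maps label names to nonzero integer codes; 0 is reserved for
    background and every nonzero code occurring in ``data`` must be named.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    schema: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SCHEMA))
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap data must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"LabelMap data must be integer, got {self.data.dtype}")
        if self.data.min() < 0:
            raise ValueError("LabelMap codes must be non-negative")
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag((*self.spacing, 1.0))
        self.affine = np.asarray(self.affine, dtype=float)
        self.schema = dict(self.schema)
        if any(code == 0 for code in self.schema.values()):
            raise ValueError("code 0 is reserved for background")
        present = set(np.unique(self.data).tolist()) - {0}
        named = set(self.schema.values())
        if not present <= named:
            raise ValueError(f"codes {sorted(present - named)} present in data but absent from schema")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def names_present(self) -> list[str]:
        present = set(np.unique(self.data).tolist())
        return [n for n, c in self.schema.items() if c in present]


@dataclass
class BinaryMask:
    """Boolean field with spacing; supports set algebra preserving the grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def _check_companion(self, other: "BinaryMask") -> None:
        if self.data.shape != other.data.shape:
            raise ValueError(f"shape mismatch: {self.data.shape} vs {other.data.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise ValueError(f"spacing mismatch: {self.spacing} vs {other.spacing}")

    def union(self, other: "BinaryMask") -> "BinaryMask":
        self._check_companion(other)
        return BinaryMask(self.data | other.data, self.spacing)

    def intersection(self, other: "BinaryMask") -> "BinaryMask":
        self._check_companion(other)
        return BinaryMask(self.data & other.data, self.spacing)

    def difference(self, other: "BinaryMask") -> "BinaryMask":
        self._check_companion(other)
        return BinaryMask(self.data & ~other.data, self.spacing)

    __or__ = union
    __and__ = intersection
    __sub__ = difference

    def is_subset_of(self, other: "BinaryMask") -> bool:
        self._check_companion(other)
        return bool(np.all(~self.data | other.data))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise ValueError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got {data.ndim}D shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms} in header")
    return data, tuple(float(z) for z in zooms), np.asarray(img.affine, dtype=float)


def read_volume(path) -> CTVolume:
    """Read a CT volume from a NIfTI file; HU values are not modified."""
    data, spacing, affine = _load_nifti(path)
    return CTVolume(np.asarray(data, dtype=np.float64), spacing, affine)


def write_volume(vol: CTVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def _schema_sidecar(path) -> Path:
    p = Path(path)
    name = p.name
    for suff in (".nii.gz", ".nii"):
        if name.endswith(suff):
            name = name[: -len(suff)]
            break
    return p.with_name(name + ".schema.json")


def read_label_map(path, schema: Mapping[str, int] | None = None) -> LabelMap:
    """Read an integer label map.

    The schema is taken from, in order of preference: the ``schema`` argument,
    a ``<stem>.schema.json`` sidecar next to the file, or the package default.
    """
    data, spacing, affine = _load_nifti(path)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: label map contains non-integer values")
    data = np.asarray(np.round(data), dtype=np.int32)
    if schema is None:
        sidecar = _schema_sidecar(path)
        if sidecar.exists():
            schema = {str(k): int(v) for k, v in json.loads(sidecar.read_text()).items()}
        else:
            schema = DEFAULT_SCHEMA
    return LabelMap(data, spacing, schema, affine)


def write_label_map(labels: LabelMap, path) -> None:
    """Write a label map plus its ``<stem>.schema.json`` sidecar."""
    img = nib.Nifti1Image(np.asarray(labels.data, dtype=np.int16), labels.affine)
    img.header.set_zooms(labels.spacing)
    nib.save(img, str(path))
    _schema_sidecar(path).write_text(json.dumps(dict(labels.schema), indent=1))


def read_mask(path) -> BinaryMask:
    data, spacing, _ = _load_nifti(path)
    return BinaryMask(data > 0.5, spacing)


def write_mask(mask: BinaryMask, path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.diag((*mask.spacing, 1.0))
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_spacing(vol, target: Sequence[float], mode: str | None = None):
    """Resample a CTVolume or LabelMap to a new voxel spacing.

    CT volumes are interpolated trilinearly; label maps use nearest-neighbour
    (interpolating categorical codes is meaningless).  The output grid covers
    the same world extent within one voxel and its spacing equals ``target``
    exactly.

    Parameters
    ----------
    vol : CTVolume or LabelMap
    target : three per-axis voxel sizes in mm
    mode : "trilinear" | "nearest" | None
        Override the per-type default interpolation.
    """
    target = _check_spacing(target)
    is_labels = isinstance(vol, LabelMap)
    if mode is None:
        mode = "nearest" if is_labels else "trilinear"
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    order = 0 if mode == "nearest" else 1

    spacing = np.asarray(vol.spacing, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if np.allclose(spacing, tgt):
        out = np.array(vol.data)
        new_affine = vol.affine.copy()
        new_shape = vol.data.shape
    else:
        shape = np.asarray(vol.data.shape)
        new_shape = np.maximum(1, np.rint(shape * spacing / tgt).astype(int))
        # cell-centre sampling: world extent of voxel i spans (i +/- 0.5)*spacing
        axes = [
            (np.arange(n) + 0.5) * t / s - 0.5
            for n, t, s in zip(new_shape, tgt, spacing)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        coords = np.stack([g.ravel() for g in grid])
        out = ndimage.map_coordinates(
            np.asarray(vol.data, dtype=float if order else vol.data.dtype),
            coords,
            order=order,
            mode="nearest",
            prefilter=False,
        ).reshape(tuple(new_shape))
        # voxel->world map of the new grid composed with the old affine
        scale = np.eye(4)
        scale[:3, :3] = np.diag(tgt / spacing)
        scale[:3, 3] = 0.5 * tgt / spacing - 0.5
        new_affine = vol.affine @ scale
    if is_labels:
        return LabelMap(np.asarray(np.round(out), dtype=vol.data.dtype), target, vol.schema, new_affine)
    return CTVolume(np.asarray(out, dtype=float), target, new_affine)


# ---------------------------------------------------------------------------
# Label algebra
# ---------------------------------------------------------------------------

def extract_mask(labels: LabelMap, names: Sequence[str]) -> BinaryMask:
    """Binary mask of voxels whose label is one of ``names`` (empty list -> empty mask)."""
    unknown = [n for n in names if n not in labels.schema]
    if unknown:
        raise KeyError(
            f"unknown label name(s) {unknown}; known labels: {sorted(labels.schema)}"
        )
    codes = [labels.schema[n] for n in names]
    if not codes:
        return BinaryMask(np.zeros(labels.data.shape, dtype=bool), labels.spacing)
    return BinaryMask(np.isin(labels.data, codes), labels.spacing)


def merge_label_maps(
    base_truth: LabelMap,
    auxiliary_pred: LabelMap,
    aux_keep: Sequence[str],
) -> LabelMap:
    """Merge an auxiliary prediction into a ground-truth label map.

    The ground truth wins wherever it is nonzero; elsewhere the auxiliary
    labels restricted to ``aux_keep`` are copied in (remapped into the unified
    output schema).  This is the cross-dataset rule used to graft SAT /
    muscle / cavity predictions onto an organ-annotated reference.
    """
    if base_truth.data.shape != auxiliary_pred.data.shape:
        raise ValueError(
            f"grid mismatch: {base_truth.data.shape} vs {auxiliary_pred.data.shape}"
        )
    if not np.allclose(base_truth.spacing, auxiliary_pred.spacing):
        raise ValueError("spacing mismatch between base and auxiliary label maps")
    unknown = [n for n in aux_keep if n not in auxiliary_pred.schema]
    if unknown:
        raise KeyError(f"aux_keep names {unknown} absent from auxiliary schema")

    out_schema = dict(base_truth.schema)
    next_code = max(out_schema.values(), default=0) + 1
    out = np.array(base_truth.data, dtype=np.int32)
    background = base_truth.data == 0
    for name in aux_keep:
        if name not in out_schema:
            out_schema[name] = next_code
            next_code += 1
        sel = background & (auxiliary_pred.data == auxiliary_pred.schema[name])
        out[sel] = out_schema[name]
    return LabelMap(out, base_truth.spacing, out_schema, base_truth.affine)
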