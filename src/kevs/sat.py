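"""SAT sampling: L3 slice selection, fractional erosion, intensity extraction.

The subcutaneous-fat (SAT) annotation typically includes the cutis (dermis +
epidermis), whose intensities are not adipose, and may include false-positive
voxels outside the body.  Eroding the SAT mask at the L3 level down to a small
fraction of its original area strips these contaminated outer layers before
the intensity sample is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, CTVolume, LabelMap, extract_mask

__all__ = [
    "IntensitySample",
    "select_l3_slice",
    "erode_to_fraction",
    "build_sat_sample",
    "structuring_element",
]


@dataclass
class IntensitySample:
    """An ordered collection of HU values extracted under a mask."""

    values: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError(f"intensity sample needs >= 2 values, got {self.values.size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity sample contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


def structuring_element(kind: str = "cross") -> np.ndarray:
    """2D structuring element: 'cross' (4-connected) or 'square' (8-connected)."""
    if kind == "cross":
        return ndimage.generate_binary_structure(2, 1)
    if kind == "square":
        return np.ones((3, 3), dtype=bool)
    raise ValueError(f"unknown structuring element {kind!r} (use 'cross' or 'square')")


def select_l3_slice(labels: LabelMap, l3_name: str = "vertebra_L3") -> int:
    """Axial index of the L3 level: the median z coordinate of the L3 voxels.

    For an even voxel count the lower of the two middle z values is taken so
    the slice index stays integral.
    """
    mask = extract_mask(labels, [l3_name])
    zs = np.nonzero(mask.data)[2]
    if zs.size == 0:
        raise ValueError(
            f"label {l3_name!r} has no voxels; supply an L3 slice index manually"
        )
    zs = np.sort(zs)
    return int(zs[(zs.size - 1) // 2])


def erode_to_fraction(
    mask2d: np.ndarray,
    fraction: float,
    structure: np.ndarray | str = "cross",
) -> np.ndarray:
    """Iteratively erode a 2D mask until its area is <= ``fraction`` of the original.

    One iteration peels one outer layer (under the chosen element).  Stops at
    the first iterate whose area crosses the target; if erosion would empty the
    mask before the target is reached, the last nonempty iterate is returned
    with a warning.  ``fraction=1`` returns the input unchanged.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if mask2d.ndim != 2:
        raise ValueError(f"expected a 2D mask, got {mask2d.ndim}D")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    area0 = int(mask2d.sum())
    if area0 == 0:
        raise ValueError("cannot erode an empty mask")
    if fraction == 1.0:
        return mask2d.copy()
    if isinstance(structure, str):
        structure = structuring_element(structure)
    target = fraction * area0
    current = mask2d.copy()
    while current.sum() > target:
        nxt = ndimage.binary_erosion(current, structure=structure, border_value=0)
        if not nxt.any():
            warnings.warn(
                f"erosion would empty the mask before reaching {fraction:.0%} of its "
                f"area; returning the last nonempty iterate ({int(current.sum())} px)",
                stacklevel=2,
            )
            break
        current = nxt
    return current


def build_sat_sample(
    ct: CTVolume,
    labels: LabelMap,
    fraction: float = 0.20,
    l3_slice: int | None = None,
    sat_name: str = "subcutaneous_fat",
    structure: str = "cross",
    fit_on_volume: bool = False,
) -> IntensitySample:
    """Extract the HU sample that the adipose KDE is fitted to.

    Takes the SAT mask on the L3 axial slice (median z of the L3 vertebra,
    unless ``l3_slice`` is given), erodes it to ``fraction`` of its area, and
    returns the CT intensities under the eroded mask.  With
    ``fit_on_volume=True`` every nonempty axial SAT slice is eroded the same
    way and the values pooled; on scans with homogeneous SAT this changes the
    downstream segmentation only negligibly.
    """
    if ct.data.shape != labels.data.shape:
        raise ValueError(f"CT/label grid mismatch: {ct.data.shape} vs {labels.data.shape}")
    sat = extract_mask(labels, [sat_name])

    if fit_on_volume:
        values = []
        for z in range(sat.data.shape[2]):
            sl = sat.data[:, :, z]
            if sl.any():
                eroded = erode_to_fraction(sl, fraction, structure)
                values.append(ct.data[:, :, z][eroded])
        if not values:
            raise ValueError(f"label {sat_name!r} is empty; cannot build an intensity sample")
        return IntensitySample(np.concatenate(values), source_tag=f"sat_volume_f{fraction:g}")

    if l3_slice is None:
        l3_slice = select_l3_slice(labels)
    sl = sat.data[:, :, l3_slice]
    if not sl.any():
        raise ValueError(
            f"label {sat_name!r} has no voxels on axial slice {l3_slice}; "
            "try a different slice (l3_slice=...) or fit_on_volume=True"
        )
    eroded = erode_to_fraction(sl, fraction, structure)
    return IntensitySample(
        ct.data[:, :, l3_slice][eroded],
        source_tag=f"sat_z{l3_slice}_f{fraction:g}",
    )
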