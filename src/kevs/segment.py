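"""VAT segmentation: the KDE-refined cavity method and HU-thresholding baselines.

The KDE method ("KEVS") takes the organ-free abdominal cavity, evaluates the
SAT-fitted density at every cavity voxel's HU value, and removes the fixed
fraction of voxels least likely to be adipose — those with the lowest
probability density.  The classical baselines instead keep cavity voxels whose
HU falls inside a fixed range; five published ranges ship as presets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kde import FittedKDE, evaluate_density, fit_kde
from .sat import build_sat_sample
from .volume import (
    DEFAULT_ORGAN_LABELS,
    DEFAULT_VERTEBRA_LABELS,
    BinaryMask,
    CTVolume,
    LabelMap,
    extract_mask,
)

__all__ = [
    "VATPrediction",
    "THRESHOLD_PRESETS",
    "organ_free_cavity",
    "kevs_predict",
    "threshold_predict",
    "vertebral_bounds",
    "restrict_to_bounds",
    "pd_threshold_sweep",
]

#: Published adipose HU windows used as thresholding baselines.
THRESHOLD_PRESETS: tuple[tuple[int, int], ...] = (
    (-190, -30),
    (-195, -45),
    (-200, -10),
    (-200, -20),
    (-250, -50),
)


@dataclass
class VATPrediction:
    """A VAT mask plus the provenance needed to reproduce it."""

    mask: BinaryMask
    method_tag: str
    region_tag: str = "full_cavity"
    pd_percentile: float | None = None
    info: dict = field(default_factory=dict)


def organ_free_cavity(
    labels: LabelMap,
    organ_names: tuple[str, ...] = DEFAULT_ORGAN_LABELS,
    cavity_name: str = "abdominal_cavity",
) -> BinaryMask:
    """Abdominal-cavity mask minus the union of the organ labels.

    Organ names absent from the schema are ignored (the organ list is a
    config list; upstream schemas differ in which organs they carry).
    """
    if cavity_name not in labels.schema:
        raise KeyError(f"label {cavity_name!r} absent from schema")
    cavity = extract_mask(labels, [cavity_name])
    present = [n for n in organ_names if n in labels.schema]
    organs = extract_mask(labels, present)
    out = cavity - organs
    if cavity.voxel_count and not out.voxel_count:
        warnings.warn("organ labels cover the whole abdominal cavity; organ-free cavity is empty",
                      stacklevel=2)
    return out


def _remove_lowest_density(
    cavity: BinaryMask,
    hu: np.ndarray,
    densities: np.ndarray,
    pd_percentile: float,
) -> tuple[np.ndarray, int]:
    """Drop the floor(p*m) lowest-density cavity voxels; return kept mask + count removed.

    Quantised HU produces many density ties; ordering by (density, HU, flat
    voxel index) makes the removal set deterministic and nested across
    percentiles.
    """
    idx = np.flatnonzero(cavity.data.ravel())
    m = idx.size
    k = int(np.floor(pd_percentile * m))
    order = np.lexsort((idx, hu, densities))
    keep = np.zeros(cavity.data.size, dtype=bool)
    keep[idx[order[k:]]] = True
    return keep.reshape(cavity.data.shape), k


def kevs_predict(
    ct: CTVolume,
    labels: LabelMap,
    pd_percentile: float = 0.15,
    *,
    erosion_fraction: float = 0.20,
    l3_slice: int | None = None,
    organ_names: tuple[str, ...] = DEFAULT_ORGAN_LABELS,
    structure: str = "cross",
    fit_on_volume: bool = False,
    scale_by_std: bool = True,
    kde: FittedKDE | None = None,
) -> VATPrediction:
    """Full KDE-refined VAT prediction.

    Pipeline: erode the SAT mask at the L3 level and sample its HU values ->
    fit the Gaussian KDE -> evaluate the density at every organ-free-cavity
    voxel -> remove the ``floor(pd_percentile * m)`` voxels with the lowest
    density.  ``pd_percentile=0`` returns the organ-free cavity unchanged.
    A pre-fitted ``kde`` may be supplied to skip the sampling stage.
    """
    if not (0.0 <= pd_percentile < 1.0):
        raise ValueError(f"pd_percentile must be in [0, 1), got {pd_percentile}")
    if ct.data.shape != labels.data.shape:
        raise ValueError(f"CT/label grid mismatch: {ct.data.shape} vs {labels.data.shape}")

    cavity = organ_free_cavity(labels, organ_names)
    m = cavity.voxel_count
    if m == 0:
        warnings.warn("organ-free cavity is empty; returning an empty VAT prediction",
                      stacklevel=2)
        return VATPrediction(cavity, "kevs", pd_percentile=pd_percentile,
                             info={"m": 0, "removed": 0})

    if kde is None:
        sample = build_sat_sample(
            ct, labels, fraction=erosion_fraction, l3_slice=l3_slice,
            structure=structure, fit_on_volume=fit_on_volume,
        )
        kde = fit_kde(sample, scale_by_std=scale_by_std)

    hu = ct.data[cavity.data]
    if pd_percentile == 0.0:
        return VATPrediction(
            cavity, "kevs", pd_percentile=0.0,
            info={"m": m, "removed": 0, "n": kde.n, "h": kde.h},
        )
    dens = evaluate_density(kde, hu)
    kept, removed = _remove_lowest_density(cavity, hu, dens, pd_percentile)
    return VATPrediction(
        BinaryMask(kept, cavity.spacing),
        "kevs",
        pd_percentile=pd_percentile,
        info={"m": m, "removed": removed, "n": kde.n, "h": kde.h},
    )


def threshold_predict(
    ct: CTVolume,
    region: BinaryMask,
    lo: float,
    hi: float,
    inclusive: bool = True,
    method_tag: str | None = None,
) -> VATPrediction:
    """Fixed-window baseline: region voxels with HU in [lo, hi].

    ``region`` is typically the full abdominal cavity (the classic baseline)
    or the organ-free cavity (the ablation variant).  Bounds are inclusive by
    convention; ``inclusive=False`` gives the open interval.
    """
    if lo >= hi:
        raise ValueError(f"threshold range requires lo < hi, got ({lo}, {hi})")
    if ct.data.shape != region.data.shape:
        raise ValueError("CT/region grid mismatch")
    if inclusive:
        sel = (ct.data >= lo) & (ct.data <= hi)
    else:
        sel = (ct.data > lo) & (ct.data < hi)
    tag = method_tag or f"threshold({lo:g},{hi:g})"
    return VATPrediction(BinaryMask(region.data & sel, region.spacing), tag,
                         info={"lo": lo, "hi": hi})


def vertebral_bounds(
    labels: LabelMap,
    vertebra_names: tuple[str, ...] = DEFAULT_VERTEBRA_LABELS,
) -> tuple[int, int]:
    """Inclusive [min z, max z] spanned by the listed (lumbar) vertebrae."""
    present = [n for n in vertebra_names if n in labels.schema]
    mask = extract_mask(labels, present) if present else None
    if mask is None or not mask.data.any():
        raise ValueError(f"none of the vertebra labels {list(vertebra_names)} are present")
    zs = np.nonzero(mask.data)[2]
    return int(zs.min()), int(zs.max())


def restrict_to_bounds(mask: BinaryMask, bounds: tuple[int, int]) -> BinaryMask:
    """Zero out all axial slices outside the inclusive z interval."""
    lo, hi = bounds
    out = np.zeros_like(mask.data)
    out[:, :, lo : hi + 1] = mask.data[:, :, lo : hi + 1]
    return BinaryMask(out, mask.spacing)


def pd_threshold_sweep(
    ct: CTVolume,
    labels: LabelMap,
    percentiles,
    truth: BinaryMask,
    tau_mm: float = 2.0,
    **kevs_kwargs,
) -> pd.DataFrame:
    """Evaluate the KDE method across removal percentiles in both regions.

    Returns a tidy table with one row per (percentile, region) carrying the
    Dice coefficient, normalised surface distance, precision and recall
    against ``truth``.
    """
    from .metrics import evaluate_prediction  # local import avoids a cycle

    if truth.data.shape != ct.data.shape:
        raise ValueError("truth/CT grid mismatch")
    try:
        bounds = vertebral_bounds(labels)
    except ValueError:
        bounds = None
    rows = []
    for p in percentiles:
        pred = kevs_predict(ct, labels, pd_percentile=p, **kevs_kwargs)
        regions = {"full_cavity": (pred.mask, truth)}
        if bounds is not None:
            regions["vertebral_bounds"] = (
                restrict_to_bounds(pred.mask, bounds),
                restrict_to_bounds(truth, bounds),
            )
        for region, (pm, tm) in regions.items():
            met = evaluate_prediction(pm, tm, tau_mm=tau_mm)
            rows.append({"percentile": p, "region": region, **met})
    return pd.DataFrame(rows)
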