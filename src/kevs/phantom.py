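"""Synthetic abdominal CT phantoms with co-registered labels and VAT truth.

The phantom emulates the tissue layout the segmentation pipeline assumes: an
elliptical body cross-section wrapped in a thin cutis shell, a subcutaneous
fat ring, a muscle band, and an abdominal cavity holding organ blobs, a
labelled lumbar vertebral column (L1–L5), and spatially clumped visceral fat.
SAT and VAT intensities are drawn from one shared adipose HU distribution,
distinct from organ/muscle/bone HU, and global Gaussian noise is added — the
regime in which a scan-specific adipose density model is meaningful.

It is deliberately not an anatomical simulator: no beam hardening, no partial
volume, no patient variability beyond the geometric and intensity parameters
below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import (
    DEFAULT_ORGAN_LABELS,
    DEFAULT_SCHEMA,
    BinaryMask,
    CTVolume,
    LabelMap,
)

__all__ = ["PhantomSpec", "generate_phantom", "degrade_labels", "lowdose_variant"]

_LUMBAR = ("vertebra_L5", "vertebra_L4", "vertebra_L3", "vertebra_L2", "vertebra_L1")


@dataclass
class PhantomSpec:
    """Parameter bundle fully determining one synthetic scan.

    HU distribution defaults are fixture conventions in the usual adult-CT
    ballpark (adipose well inside the classic (-190, -30) window), not claims
    about any dataset.  ``vat_fraction`` is the fraction of the organ-free,
    vertebra-free cavity occupied by visceral fat; its default matches the
    operating point of a 15% low-density removal, i.e. ~15% non-adipose
    residue in the refined cavity.
    """

    shape: tuple[int, int, int] = (112, 112, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    body_radii: tuple[float, float] = (48.0, 40.0)  # in-plane semi-axes, voxels
    body_taper: float = 0.08  # fractional radius reduction at the z extremes
    cutis_thickness: int = 1  # voxels
    sat_thickness: int = 7
    muscle_thickness: int = 3
    organ_count: int = 4
    organ_radius_range: tuple[float, float] = (4.0, 8.0)  # voxels per axis
    vertebra_radius: float = 6.0
    vertebra_y_offset: float = 14.0  # posterior shift of the column, voxels
    lumbar_z: tuple[int, int] = (12, 51)  # inclusive span of L5..L1
    vat_fraction: float = 0.85
    clump_sigma: float = 2.0  # smoothing of the VAT placement field, voxels
    adipose_hu: tuple[float, float] = (-100.0, 20.0)  # mean, sd — shared SAT/VAT
    organ_hu: tuple[float, float] = (40.0, 15.0)
    muscle_hu: tuple[float, float] = (50.0, 15.0)
    bone_hu: tuple[float, float] = (400.0, 100.0)
    cutis_hu: tuple[float, float] = (20.0, 10.0)
    air_hu: float = -1000.0
    noise_sd: float = 10.0
    seed: int = 0
    organ_names: tuple[str, ...] = field(default_factory=lambda: DEFAULT_ORGAN_LABELS[:6])

    def validate(self) -> None:
        nx, ny, nz = self.shape
        rx, ry = self.body_radii
        if rx + 2 > nx / 2 or ry + 2 > ny / 2:
            raise ValueError(
                f"body radii {self.body_radii} do not fit inside grid {self.shape[:2]} "
                "with a one-voxel margin")
        if not (0.0 <= self.vat_fraction <= 1.0):
            raise ValueError(f"vat_fraction must be in [0, 1], got {self.vat_fraction}")
        lo, hi = self.lumbar_z
        if not (0 <= lo <= hi < nz):
            raise ValueError(f"lumbar_z {self.lumbar_z} outside the {nz}-slice grid")
        if not (self.adipose_hu[0] < self.muscle_hu[0] < self.bone_hu[0]):
            raise ValueError(
                "tissue ordering violated: require adipose mean < muscle mean < bone mean")
        if min(self.cutis_thickness, self.sat_thickness, self.muscle_thickness) < 1:
            raise ValueError("ring thicknesses must be >= 1 voxel")
        if self.organ_radius_range[0] > self.organ_radius_range[1]:
            raise ValueError("organ_radius_range must be (min, max)")


def _inplane_structure() -> np.ndarray:
    # 4-connected cross acting only in-plane, so ring thickness is per-slice
    s = np.zeros((3, 3, 1), dtype=bool)
    s[1, :, 0] = True
    s[:, 1, 0] = True
    return s


def _body_mask(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = np.arange(nx)[:, None, None] - cx
    y = np.arange(ny)[None, :, None] - cy
    z = np.arange(nz)[None, None, :]
    zc = (nz - 1) / 2.0
    shrink = 1.0 - spec.body_taper * ((z - zc) / max(zc, 1.0)) ** 2
    rx = spec.body_radii[0] * shrink
    ry = spec.body_radii[1] * shrink
    return (x / rx) ** 2 + (y / ry) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Build one phantom: returns (CTVolume, LabelMap, truth_vat, census).

    Deterministic given ``spec.seed``; the census is recounted from the final
    label map (plus a ``vat_truth`` entry), so it matches the outputs exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    s = _inplane_structure()

    body = _body_mask(spec)
    e1 = ndimage.binary_erosion(body, structure=s, iterations=spec.cutis_thickness)
    e2 = ndimage.binary_erosion(e1, structure=s, iterations=spec.sat_thickness)
    e3 = ndimage.binary_erosion(e2, structure=s, iterations=spec.muscle_thickness)
    cutis = body & ~e1
    sat = e1 & ~e2
    muscle = e2 & ~e3
    cavity_region = e3
    if not cavity_region.any():
        raise ValueError("ring thicknesses leave no cavity: shrink cutis/sat/muscle")

    # lumbar column: a posterior in-plane disk over the lumbar z span,
    # split bottom-to-top into L5..L1
    x = np.arange(nx)[:, None, None] - cx
    y = np.arange(ny)[None, :, None] - (cy + spec.vertebra_y_offset)
    zlo, zhi = spec.lumbar_z
    in_disk = (x**2 + y**2) <= spec.vertebra_radius**2
    zmask = np.zeros((1, 1, nz), dtype=bool)
    zmask[0, 0, zlo : zhi + 1] = True
    vert_all = in_disk & zmask & cavity_region
    if not vert_all.any():
        raise ValueError("vertebral column lies outside the cavity: adjust vertebra_y_offset")
    edges = np.linspace(zlo, zhi + 1, 6).astype(int)
    vert_parts: dict[str, np.ndarray] = {}
    for i, name in enumerate(_LUMBAR):
        band = np.zeros((1, 1, nz), dtype=bool)
        band[0, 0, edges[i] : edges[i + 1]] = True
        vert_parts[name] = vert_all & band

    # organ blobs: axis-aligned ellipsoids clipped to the cavity, avoiding bone
    organ_parts: dict[str, np.ndarray] = {}
    organ_all = np.zeros(spec.shape, dtype=bool)
    xi = np.arange(nx)[:, None, None]
    yi = np.arange(ny)[None, :, None]
    zi = np.arange(nz)[None, None, :]
    rmin, rmax = spec.organ_radius_range
    for i in range(spec.organ_count):
        name = spec.organ_names[i % len(spec.organ_names)]
        ox = rng.uniform(cx - 0.45 * spec.body_radii[0], cx + 0.45 * spec.body_radii[0])
        oy = rng.uniform(cy - 0.55 * spec.body_radii[1], cy)  # anterior of the column
        oz = rng.uniform(zlo + 2, zhi - 2)
        rx, ry_, rz = rng.uniform(rmin, rmax, size=3)
        blob = (((xi - ox) / rx) ** 2 + ((yi - oy) / ry_) ** 2 + ((zi - oz) / rz) ** 2) <= 1.0
        blob &= cavity_region & ~vert_all & ~organ_all
        if blob.any():
            organ_parts[name] = organ_parts.get(name, np.zeros(spec.shape, bool)) | blob
            organ_all |= blob

    remainder = cavity_region & ~vert_all & ~organ_all

    # clumped VAT: top-k voxels of a smoothed random field within the remainder
    m_rem = int(remainder.sum())
    k = int(round(spec.vat_fraction * m_rem))
    vat = np.zeros(spec.shape, dtype=bool)
    if k > 0:
        fieldv = ndimage.gaussian_filter(rng.standard_normal(spec.shape), spec.clump_sigma)
        flat = np.flatnonzero(remainder)
        vals = fieldv.ravel()[flat]
        chosen = flat[np.argpartition(vals, m_rem - k)[m_rem - k:]] if k < m_rem else flat
        vat.ravel()[chosen] = True

    # label map (mutually exclusive); VAT and the non-adipose residue both
    # carry the abdominal_cavity label, as an upstream segmenter would emit
    schema = dict(DEFAULT_SCHEMA)
    lab = np.zeros(spec.shape, dtype=np.int32)
    lab[cutis] = schema["cutis"]
    lab[sat] = schema["subcutaneous_fat"]
    lab[muscle] = schema["muscle"]
    lab[remainder] = schema["abdominal_cavity"]
    for name, part in vert_parts.items():
        lab[part] = schema[name]
    for name, part in organ_parts.items():
        lab[part] = schema[name]

    # intensities: per-tissue normal draws, then global noise
    ct = np.full(spec.shape, spec.air_hu, dtype=float)

    def fill(mask: np.ndarray, mean_sd: tuple[float, float]) -> None:
        cnt = int(mask.sum())
        if cnt:
            ct[mask] = rng.normal(mean_sd[0], mean_sd[1], size=cnt)

    adipose = sat | vat
    fill(adipose, spec.adipose_hu)
    fill(cutis, spec.cutis_hu)
    fill(muscle, spec.muscle_hu)
    fill(vert_all, spec.bone_hu)
    fill(organ_all, spec.organ_hu)
    fill(remainder & ~vat, spec.organ_hu)  # bowel/vessel stand-in
    if spec.noise_sd > 0:
        ct += rng.normal(0.0, spec.noise_sd, size=spec.shape)

    census = {name: int((lab == code).sum()) for name, code in schema.items()
              if (lab == code).any()}
    census["background"] = int((lab == 0).sum())
    census["vat_truth"] = int(vat.sum())

    affine = np.diag((*spec.spacing, 1.0))
    return (
        CTVolume(ct, spec.spacing, affine),
        LabelMap(lab, spec.spacing, schema, affine),
        BinaryMask(vat, spec.spacing),
        census,
    )


def degrade_labels(labels: LabelMap, mode: str, magnitude: int, seed: int = 0) -> LabelMap:
    """Corrupt a label map to emulate imperfect upstream segmentation.

    Modes: ``dilate_muscle`` grows the muscle label into neighbouring cavity
    and SAT voxels (the over-prediction failure mode that starves the cavity);
    ``erode_sat`` shrinks the SAT label, dropped voxels become background;
    ``jitter_boundary`` randomly swaps labels across label boundaries.
    ``magnitude`` counts morphology iterations / jitter passes; 0 is identity.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    out = np.array(labels.data)
    if magnitude == 0:
        return LabelMap(out, labels.spacing, labels.schema, labels.affine)
    structure = ndimage.generate_binary_structure(3, 1)
    sch = labels.schema
    if mode == "dilate_muscle":
        muscle = out == sch["muscle"]
        grown = ndimage.binary_dilation(muscle, structure=structure, iterations=magnitude)
        victims = grown & ~muscle & np.isin(out, [sch["abdominal_cavity"], sch["subcutaneous_fat"]])
        out[victims] = sch["muscle"]
    elif mode == "erode_sat":
        satm = out == sch["subcutaneous_fat"]
        kept = ndimage.binary_erosion(satm, structure=structure, iterations=magnitude)
        out[satm & ~kept] = 0
    elif mode == "jitter_boundary":
        rng = np.random.default_rng(seed)
        for _ in range(magnitude):
            ax = int(rng.integers(0, 3))
            step = int(rng.choice([-1, 1]))
            shifted = np.roll(out, step, axis=ax)
            boundary = shifted != out
            flip = boundary & (rng.random(out.shape) < 0.5)
            out[flip] = shifted[flip]
    else:
        raise ValueError(
            f"unknown degradation mode {mode!r} "
            "(use dilate_muscle | erode_sat | jitter_boundary)")
    return LabelMap(out, labels.spacing, labels.schema, labels.affine)


def lowdose_variant(ct: CTVolume, extra_noise_sd: float, seed: int = 0) -> CTVolume:
    """Add zero-mean Gaussian noise, widening every tissue's HU distribution.

    Emulates a low-dose acquisition, where fixed HU windows clip more of the
    broadened adipose distribution while a scan-specific density fit adapts.
    ``extra_noise_sd=0`` returns an identical copy.
    """
    if extra_noise_sd < 0:
        raise ValueError("extra_noise_sd must be >= 0")
    data = np.array(ct.data)
    if extra_noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, extra_noise_sd, size=data.shape)
    return CTVolume(data, ct.spacing, ct.affine.copy())
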