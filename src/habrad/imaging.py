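"""Volume and mask containers, NIfTI I/O, bias-field correction, resampling.

Volumes are 3-D scalar grids tagged with a contrast (``T1W`` or ``T2W``);
masks are integer label grids on the same voxel lattice.  Orientation is
normalized to nibabel's closest-canonical (RAS) convention on read so that
all downstream voxel indexing is consistent.

The bias-field correction here removes a smooth multiplicative intensity
inhomogeneity by fitting a low-order 3-D polynomial to the log-intensity
inside the mask; it fulfils the same contract as the N4 algorithm commonly
used on clinical MRI (estimate a smooth, strictly positive field with unit
mean over the region of interest and divide it out).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

CONTRASTS = ("T1W", "T2W")


@dataclass
class Volume:
    """A single 3-D scalar image with voxel spacing and world affine."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray = None
    contrast_tag: str = "T1W"
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"Volume must be 3-D, got {self.values.ndim}-D data"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing_mm) + [1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.contrast_tag not in CONTRASTS:
            raise ValueError(f"contrast_tag must be one of {CONTRASTS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class Mask:
    """Integer label grid: 0 = background, positive ids = VOI regions."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray = None
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"Mask must be 3-D, got {self.labels.ndim}-D data")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("Mask labels must be integers")
            self.labels = rounded
        self.labels = self.labels.astype(np.int32)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing_mm) + [1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)
        for rid in self.region_names:
            if not np.any(self.labels == rid):
                raise ValueError(
                    f"declared region {rid} ({self.region_names[rid]}) has no voxels"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def foreground(self) -> np.ndarray:
        """Boolean array of all VOI voxels (any positive label)."""
        return self.labels > 0


def check_aligned(volume: Volume, mask: Mask) -> None:
    """Raise if a mask does not share its volume's grid."""
    if volume.shape != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    if not np.allclose(volume.spacing_mm, mask.spacing_mm):
        raise ValueError(
            f"mask spacing {mask.spacing_mm} does not match volume "
            f"spacing {volume.spacing_mm}"
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_canonical(path):
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(
            f"{path}: expected a 3-D image, file is {len(img.shape)}-D"
        )
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def read_volume(path, contrast_tag: str = "T1W", subject_id: str = "") -> Volume:
    data, spacing, affine = _load_canonical(path)
    return Volume(data, spacing, affine, contrast_tag, subject_id)


def read_mask(path, region_names: dict[int, str] | None = None) -> Mask:
    data, spacing, affine = _load_canonical(path)
    return Mask(data, spacing, affine, region_names or {})


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), volume.affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def write_mask(mask: Mask, path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), mask.affine)
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Bias-field correction
# ---------------------------------------------------------------------------

def _polynomial_design(shape, order: int) -> np.ndarray:
    """Design matrix of 3-D monomials up to total degree ``order``,
    on coordinates scaled to [-1, 1] per axis."""
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    cols = []
    for i, j, k in product(range(order + 1), repeat=3):
        if i + j + k <= order:
            cols.append((xx ** i) * (yy ** j) * (zz ** k))
    return np.stack([c.ravel() for c in cols], axis=1)


def correct_bias_field(volume: Volume, mask: Mask, order: int = 3,
                       method: str = "polynomial") -> tuple[Volume, Volume]:
    """Remove a smooth multiplicative intensity field from ``volume``.

    The default backend fits a polynomial of total degree ``order`` to the
    log-intensity over the mask, exponentiates it into a strictly positive
    field with unit mean over the mask, and divides it out.  With
    ``method="n4"`` the field is instead estimated by the N4 algorithm
    (via SimpleITK) and renormalised to the same unit-mean contract.
    Returns ``(corrected, field)``.

    ``order=0`` is an explicit no-op (field identically 1): with a constant
    log-offset the unit-mean constraint cancels it exactly.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    check_aligned(volume, mask)
    fg = mask.foreground()
    if not np.any(fg):
        raise ValueError("mask is empty")
    if method == "n4":
        return _n4_bias_field(volume, mask, fg)
    if method != "polynomial":
        raise ValueError(f"unknown bias-correction method {method!r}")

    field_vals = np.ones(volume.shape, dtype=np.float64)
    if order > 0:
        vals = volume.values
        inside = vals[fg]
        shift = 0.0
        if np.min(inside) <= 0:
            # log model needs positive intensities; shift up and warn
            shift = -np.min(inside) + 1e-6 * max(1.0, np.ptp(inside))
            warnings.warn(
                "non-positive intensities inside mask; applying shift-then-log "
                "fallback for bias estimation",
                RuntimeWarning,
            )
            logger.warning("bias correction: shift-then-log fallback (shift=%g)", shift)
        log_img = np.log(vals + shift, out=np.full(volume.shape, np.nan),
                         where=(vals + shift) > 0)
        design = _polynomial_design(volume.shape, order)
        fg_flat = fg.ravel()
        coef, *_ = np.linalg.lstsq(design[fg_flat], log_img.ravel()[fg_flat], rcond=None)
        field_vals = np.exp(design @ coef).reshape(volume.shape)
        field_vals /= field_vals[fg].mean()

    corrected = replace(volume, values=volume.values / field_vals)
    field_vol = replace(volume, values=field_vals)
    cv_before = _masked_cv(volume.values, fg)
    cv_after = _masked_cv(corrected.values, fg)
    logger.info("bias correction: CV %0.4f -> %0.4f (order=%d)", cv_before, cv_after, order)
    return corrected, field_vol


def _n4_bias_field(volume: Volume, mask: Mask, fg: np.ndarray
                   ) -> tuple[Volume, Volume]:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(volume.values.astype(np.float32))
    img.SetSpacing(tuple(reversed(volume.spacing_mm)))
    msk = sitk.GetImageFromArray(fg.astype(np.uint8))
    msk.SetSpacing(img.GetSpacing())
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrected_img = corrector.Execute(img, msk)
    log_field = corrector.GetLogBiasFieldAsImage(img)
    field_vals = np.exp(sitk.GetArrayFromImage(log_field)).astype(np.float64)
    field_vals /= field_vals[fg].mean()
    del corrected_img  # recomputed below so the unit-mean contract holds
    corrected = replace(volume, values=volume.values / field_vals)
    return corrected, replace(volume, values=field_vals)


def _masked_cv(values: np.ndarray, fg: np.ndarray) -> float:
    inside = values[fg]
    m = inside.mean()
    return float(inside.std() / abs(m)) if m != 0 else float("inf")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to(obj, target_spacing_mm):
    """Resample a Volume (linear) or Mask (nearest-neighbour) to a new spacing.

    World extent (shape * spacing) is preserved up to voxel rounding; sampling
    positions are voxel centres of the target grid mapped into the source grid.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if len(target) != 3 or any(s <= 0 for s in target):
        raise ValueError("target spacing must be 3 positive reals")

    is_mask = isinstance(obj, Mask)
    data = obj.labels.astype(np.float64) if is_mask else obj.values
    src_spacing = obj.spacing_mm
    if np.allclose(src_spacing, target):
        return obj

    new_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(data.shape, src_spacing, target)
    )
    # target voxel-centre positions expressed in source voxel coordinates
    grids = [
        (np.arange(m) + 0.5) * t / s - 0.5
        for m, t, s in zip(new_shape, target, src_spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    order = 0 if is_mask else 1
    out = ndimage.map_coordinates(data, np.stack(coords), order=order, mode="nearest")

    new_affine = obj.affine.copy()
    scale = np.array(target) / np.array(src_spacing)
    new_affine[:3, :3] = obj.affine[:3, :3] @ np.diag(scale)
    if is_mask:
        return Mask(np.rint(out).astype(np.int32), target, new_affine, obj.region_names)
    return replace(obj, values=out, spacing_mm=target, affine=new_affine)
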