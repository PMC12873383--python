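"""The 19 per-voxel feature maps that drive habitat clustering.

For every VOI voxel, features are evaluated on the cubic neighbourhood of
configurable radius clipped at the VOI boundary (neighbourhoods never reach
into non-VOI tissue), after equal-width discretization over the
neighbourhood's own min-max.  Per contrast the map set is:

* first order: Entropy, MeanAbsoluteDeviation, Median
* GLCM: DifferenceAverage, DifferenceEntropy, DifferenceVariance, Imc1,
  Imc2, InverseVariance, JointEnergy, JointEntropy, SumEntropy
* GLRLM: LongRunEmphasis, RunEntropy, RunVariance
* GLSZM: SizeZoneNonUniformityNormalized, SmallAreaHighGrayLevelEmphasis
* NGTDM: Contrast, Strength

Two contrasts give the 38-dimensional per-voxel vector used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _voxel_kernels as _k
from .imaging import Mask, Volume, check_aligned
from .texture import discretize  # re-exported: shared binning primitive

__all__ = [
    "VoxelFeatureConfig", "VoxelFeatureMap", "FEATURE_NAMES",
    "discretize", "local_first_order", "local_glcm", "local_glrlm",
    "local_glszm", "local_ngtdm", "compute_feature_maps",
    "assemble_voxel_matrix",
]

FIRST_ORDER_NAMES = ("Entropy", "MeanAbsoluteDeviation", "Median")
GLCM_NAMES = (
    "DifferenceAverage", "DifferenceEntropy", "DifferenceVariance",
    "Imc1", "Imc2", "JointEnergy", "JointEntropy", "SumEntropy",
    "InverseVariance",
)
GLRLM_NAMES = ("LongRunEmphasis", "RunEntropy", "RunVariance")
GLSZM_NAMES = ("SizeZoneNonUniformityNormalized",
               "SmallAreaHighGrayLevelEmphasis")
NGTDM_NAMES = ("Contrast", "Strength")

#: the 19 map names, in fixed catalog order
FEATURE_NAMES = FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES + \
    GLSZM_NAMES + NGTDM_NAMES


@dataclass
class VoxelFeatureConfig:
    """Neighbourhood and discretization settings for the voxel maps."""

    neighborhood_radius_voxels: int = 2
    n_gray_levels: int = 16
    glcm_distance: int = 1
    aggregation: str = "mean"  # directions pooled into one matrix

    def __post_init__(self):
        if self.neighborhood_radius_voxels < 1:
            raise ValueError("neighborhood radius must be >= 1")
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")


@dataclass
class VoxelFeatureMap:
    """Named 3-D feature grids for one contrast, NaN outside the VOI."""

    maps: dict[str, np.ndarray]
    contrast_tag: str
    mask: Mask

    def __post_init__(self):
        if len(self.maps) != len(FEATURE_NAMES):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} maps, got {len(self.maps)}"
            )
        fg = self.mask.foreground()
        for name, arr in self.maps.items():
            if not np.all(np.isfinite(arr[fg])):
                raise ValueError(f"map {name} has non-finite VOI values")


def _prep(volume: Volume, mask: Mask):
    check_aligned(volume, mask)
    return np.ascontiguousarray(volume.values, dtype=np.float64), \
        np.ascontiguousarray(mask.foreground())


def local_first_order(volume: Volume, mask: Mask,
                      cfg: VoxelFeatureConfig) -> dict[str, np.ndarray]:
    vals, fg = _prep(volume, mask)
    out = _k.first_order_maps(vals, fg, cfg.neighborhood_radius_voxels,
                              cfg.n_gray_levels)
    return dict(zip(FIRST_ORDER_NAMES, out))


def local_glcm(volume: Volume, mask: Mask,
               cfg: VoxelFeatureConfig) -> dict[str, np.ndarray]:
    vals, fg = _prep(volume, mask)
    out = _k.glcm_maps(vals, fg, cfg.neighborhood_radius_voxels,
                       cfg.n_gray_levels, cfg.glcm_distance)
    return dict(zip(GLCM_NAMES, out))


def local_glrlm(volume: Volume, mask: Mask,
                cfg: VoxelFeatureConfig) -> dict[str, np.ndarray]:
    vals, fg = _prep(volume, mask)
    out = _k.glrlm_maps(vals, fg, cfg.neighborhood_radius_voxels,
                        cfg.n_gray_levels)
    return dict(zip(GLRLM_NAMES, out))


def local_glszm(volume: Volume, mask: Mask,
                cfg: VoxelFeatureConfig) -> dict[str, np.ndarray]:
    vals, fg = _prep(volume, mask)
    out = _k.glszm_maps(vals, fg, cfg.neighborhood_radius_voxels,
                        cfg.n_gray_levels)
    return dict(zip(GLSZM_NAMES, out))


def local_ngtdm(volume: Volume, mask: Mask,
                cfg: VoxelFeatureConfig) -> dict[str, np.ndarray]:
    vals, fg = _prep(volume, mask)
    out = _k.ngtdm_maps(vals, fg, cfg.neighborhood_radius_voxels,
                        cfg.n_gray_levels)
    return dict(zip(NGTDM_NAMES, out))


def compute_feature_maps(volume: Volume, mask: Mask,
                         cfg: VoxelFeatureConfig | None = None
                         ) -> VoxelFeatureMap:
    """All 19 maps of one contrast, in catalog order."""
    cfg = cfg or VoxelFeatureConfig()
    maps: dict[str, np.ndarray] = {}
    maps.update(local_first_order(volume, mask, cfg))
    maps.update(local_glcm(volume, mask, cfg))
    maps.update(local_glrlm(volume, mask, cfg))
    maps.update(local_glszm(volume, mask, cfg))
    maps.update(local_ngtdm(volume, mask, cfg))
    ordered = {name: maps[name] for name in FEATURE_NAMES}
    return VoxelFeatureMap(ordered, volume.contrast_tag, mask)


def assemble_voxel_matrix(t1_maps: VoxelFeatureMap, t2_maps: VoxelFeatureMap,
                          mask: Mask) -> tuple[np.ndarray, np.ndarray]:
    """Stack both contrasts into a (n_voxels, 38) matrix.

    Columns are the 19 T1W maps in catalog order followed by the 19 T2W
    maps; rows follow the lexicographic order of VOI voxel indices.  Returns
    ``(matrix, coords)`` where ``coords`` is the (n_voxels, 3) integer index
    of each row.
    """
    for m in (t1_maps, t2_maps):
        if not np.array_equal(m.mask.labels, mask.labels):
            raise ValueError("feature maps were computed on a different mask")
    if t1_maps.contrast_tag != "T1W" or t2_maps.contrast_tag != "T2W":
        raise ValueError("expected (T1W, T2W) map pair")
    coords = np.argwhere(mask.foreground())
    cols = [t1_maps.maps[n][tuple(coords.T)] for n in FEATURE_NAMES]
    cols += [t2_maps.maps[n][tuple(coords.T)] for n in FEATURE_NAMES]
    return np.stack(cols, axis=1), coords


def matrix_column_names() -> list[str]:
    """The 38 column names of the assembled voxel matrix."""
    return [f"T1W_{n}" for n in FEATURE_NAMES] + \
        [f"T2W_{n}" for n in FEATURE_NAMES]
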