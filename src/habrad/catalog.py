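"""The 1,197-feature radiomic catalog and subjects x features tables.

Per category (whole VOI or one habitat, in one contrast) the catalog pairs
13 image filters — the original image, Laplacian-of-Gaussian at sigma 2, 3,
4 and 5 mm, and the 8 single-level undecimated wavelet subbands LLL..HHH —
with 18 first-order, 22 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM and 5 NGTDM
features, plus 14 shape features computed once on the original image:

    13 x (18 + 22 + 16 + 16 + 14 + 5) + 14 = 1,197

A model with k habitats has 2k + 2 categories (each contrast's whole VOI
plus each contrast's habitats), hence 1,197 x (2k + 2) table columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
import warnings
from scipy import ndimage

from . import texture
from .habitats import HabitatMap
from .imaging import Volume
from .phantom import PhantomSubject

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

FEATURE_CLASSES = {
    "firstorder": texture.FIRST_ORDER_NAMES,
    "glcm": texture.GLCM_NAMES,
    "glrlm": texture.GLRLM_NAMES,
    "glszm": texture.GLSZM_NAMES,
    "gldm": texture.GLDM_NAMES,
    "ngtdm": texture.NGTDM_NAMES,
}
SHAPE_CLASS = ("shape", texture.SHAPE_NAMES)


@dataclass
class ExtractionConfig:
    """Discretization, filter and region-size settings for the catalog."""

    n_bins: int = 32
    log_sigmas_mm: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    wavelet: str = "coif1"
    min_region_voxels: int = 10
    gldm_alpha: int = 0
    glcm_distance: int = 1

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigmas must be positive")

    @property
    def filter_names(self) -> list[str]:
        names = ["original"]
        names += [f"log-sigma-{s:g}mm" for s in self.log_sigmas_mm]
        names += [f"wavelet-{b}" for b in WAVELET_SUBBANDS]
        return names


@dataclass
class FeatureCatalog:
    """Ordered list of (image_filter, feature_class, feature_name) entries."""

    entries: list[tuple[str, str, str]]

    def __len__(self):
        return len(self.entries)

    def count(self, feature_class: str) -> int:
        return sum(1 for e in self.entries if e[1] == feature_class)


def build_catalog(config: ExtractionConfig | None = None) -> FeatureCatalog:
    """Enumerate the 1,197 catalog entries in deterministic order."""
    config = config or ExtractionConfig()
    entries = []
    for filt in config.filter_names:
        for cls, names in FEATURE_CLASSES.items():
            for name in names:
                entries.append((filt, cls, name))
    cls, names = SHAPE_CLASS
    for name in names:
        entries.append(("original", cls, name))
    return FeatureCatalog(entries)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def apply_log_filter(volume: Volume, sigma_mm: float) -> Volume:
    """Laplacian-of-Gaussian response; sigma given in millimetres.

    Sigma is converted to voxels via the spacing per axis; responses keep
    the input grid.  A sigma below half the largest voxel dimension is
    under-resolved and triggers a warning.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    if sigma_mm < max(volume.spacing_mm) / 2:
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is below half a voxel "
            f"({max(volume.spacing_mm)} mm); response will be aliased",
            RuntimeWarning,
        )
    sigma_vox = [sigma_mm / s for s in volume.spacing_mm]
    # truncate=8 keeps the kernel's DC leakage below 1e-13 so flat regions
    # genuinely map to zero response
    out = ndimage.gaussian_laplace(volume.values, sigma=sigma_vox, truncate=8)
    return Volume(out, volume.spacing_mm, volume.affine,
                  volume.contrast_tag, volume.subject_id)


def wavelet_subbands(volume: Volume, wavelet: str = "coif1"
                     ) -> dict[str, Volume]:
    """Single-level undecimated 3-D wavelet decomposition.

    The stationary transform keeps every subband at the input resolution so
    region masks remain aligned.  Keys are LLL..HHH with the letter order
    following the array axes (L = approximation, H = detail).  Odd axis
    lengths are edge-padded to even before the transform and cropped after.
    """
    vals = volume.values
    pads = [(0, n % 2) for n in vals.shape]
    padded = np.pad(vals, pads, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1, norm=False)[0]
    out = {}
    for band in WAVELET_SUBBANDS:
        key = "".join("a" if ch == "L" else "d" for ch in band)
        arr = coeffs[key]
        arr = arr[tuple(slice(0, n) for n in vals.shape)]
        out[band] = Volume(arr, volume.spacing_mm, volume.affine,
                           volume.contrast_tag, volume.subject_id)
    return out


def filtered_stack(volume: Volume, config: ExtractionConfig
                   ) -> dict[str, np.ndarray]:
    """All 13 filter responses of one contrast, keyed by filter name."""
    stack = {"original": volume.values}
    for s in config.log_sigmas_mm:
        stack[f"log-sigma-{s:g}mm"] = apply_log_filter(volume, s).values
    for band, vol in wavelet_subbands(volume, config.wavelet).items():
        stack[f"wavelet-{band}"] = vol.values
    return stack


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------

def _bbox(region: np.ndarray):
    idx = np.argwhere(region)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _texture_block(values_crop, region_crop, config: ExtractionConfig,
                   voxel_volume: float) -> dict[tuple[str, str], float]:
    """First-order + 5 matrix classes for one filter response on one region."""
    region_vals = values_crop[region_crop]
    n_vox = region_vals.size
    out = {}
    fo = texture.first_order_features(region_vals, voxel_volume, config.n_bins)
    for name, v in fo.items():
        out[("firstorder", name)] = v
    levels = np.zeros(region_crop.shape, dtype=np.int64)
    levels[region_crop] = texture.discretize(region_vals, config.n_bins)
    ng = config.n_bins
    out.update({("glcm", k): v for k, v in texture.glcm_features(
        texture.glcm_matrix(levels, ng, config.glcm_distance)).items()})
    out.update({("glrlm", k): v for k, v in texture.glrlm_features(
        texture.glrlm_matrix(levels, ng), n_vox).items()})
    out.update({("glszm", k): v for k, v in texture.glszm_features(
        texture.glszm_matrix(levels, ng), n_vox).items()})
    out.update({("gldm", k): v for k, v in texture.gldm_features(
        texture.gldm_matrix(levels, ng, config.gldm_alpha)).items()})
    out.update({("ngtdm", k): v for k, v in texture.ngtdm_features(
        *texture.ngtdm_table(levels, ng)).items()})
    return out


def extract_region_features(filtered: dict[str, np.ndarray],
                            region: np.ndarray, spacing_mm,
                            catalog: FeatureCatalog,
                            config: ExtractionConfig) -> np.ndarray:
    """The 1,197-vector of one region, in catalog order.

    An empty region yields all-NaN; a region smaller than
    ``config.min_region_voxels`` yields NaN for the texture entries while
    shape descriptors are still computed.
    """
    n_entries = len(catalog)
    out = np.full(n_entries, np.nan)
    region = np.asarray(region, dtype=bool)
    n_vox = int(region.sum())
    if n_vox == 0:
        return out
    box = _bbox(region)
    region_crop = region[box]
    voxel_volume = float(np.prod(spacing_mm))
    texture_ok = n_vox >= config.min_region_voxels

    values: dict[tuple[str, str, str], float] = {}
    if texture_ok:
        for filt, arr in filtered.items():
            block = _texture_block(arr[box], region_crop, config, voxel_volume)
            for (cls, name), v in block.items():
                values[(filt, cls, name)] = v
    shp = texture.shape_features(region_crop, spacing_mm)
    for name, v in shp.items():
        values[("original", "shape", name)] = v

    for i, entry in enumerate(catalog.entries):
        if entry in values:
            out[i] = values[entry]
    return out


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects x features matrix with missing-value mask and schema."""

    values: pd.DataFrame
    missing: pd.DataFrame
    schema: list[dict] = field(default_factory=list)

    @property
    def n_categories(self) -> int:
        return len({s["category"] for s in self.schema})

    def write(self, csv_path, schema_path=None) -> None:
        self.values.to_csv(csv_path)
        if schema_path is not None:
            Path(schema_path).write_text(json.dumps(self.schema, indent=1))


def category_names(k: int) -> list[str]:
    cats = ["T1W", "T2W"]
    cats += [f"T1_H{j}" for j in range(1, k + 1)]
    cats += [f"T2_H{j}" for j in range(1, k + 1)]
    return cats


def column_name(filt: str, cls: str, name: str, category: str) -> str:
    return f"{filt}_{cls}_{name}_{category}"


def build_feature_table(subjects: list[PhantomSubject],
                        habitat_maps: dict[str, HabitatMap],
                        catalog: FeatureCatalog,
                        config: ExtractionConfig | None = None
                        ) -> FeatureTable:
    """Extract the full per-subject table over all 2k + 2 categories.

    Missing values (empty habitats, regions below the texture size floor)
    are NaN in ``values`` and True in ``missing``; they are never silently
    zeroed.
    """
    config = config or ExtractionConfig()
    ks = {m.k for m in habitat_maps.values()}
    if len(ks) != 1:
        raise ValueError(f"inconsistent k across subjects: {sorted(ks)}")
    k = ks.pop()
    cats = category_names(k)
    columns = [column_name(*entry, cat) for cat in cats
               for entry in catalog.entries]
    rows = []
    for subj in subjects:
        hmap = habitat_maps[subj.subject_id]
        fg = subj.voi_mask.foreground()
        stacks = {"T1": filtered_stack(subj.t1w, config),
                  "T2": filtered_stack(subj.t2w, config)}
        spacing = subj.voi_mask.spacing_mm
        vec = []
        for cat in cats:
            contrast = cat[:2]
            if cat.endswith("W"):
                region = fg
            else:
                j = int(cat.split("_H")[1])
                region = hmap.labels == j
            vec.append(extract_region_features(stacks[contrast], region,
                                               spacing, catalog, config))
        rows.append(np.concatenate(vec))
    values = pd.DataFrame(rows, index=[s.subject_id for s in subjects],
                          columns=columns)
    schema = [{"column": column_name(*entry, cat), "image_filter": entry[0],
               "feature_class": entry[1], "feature_name": entry[2],
               "category": cat}
              for cat in cats for entry in catalog.entries]
    return FeatureTable(values, values.isna(), schema)
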