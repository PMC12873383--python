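"""Synthetic two-class phantom cohorts with planted habitat structure.

Each phantom subject mimics a pair of co-registered T1W/T2W brain volumes in
which two bilateral deep-gray structures (a caudate-like and a putamen-like
pair of ellipsoids) have been delineated.  Inside each structure, ``k_true``
spatially contiguous habitats are planted as the Voronoi cells of random
seed voxels; each habitat is filled with a Gaussian random field of
prescribed mean, standard deviation and correlation length per contrast.

Disease-class subjects receive a per-habitat class effect that raises the
intensity range and RMS (standard-deviation scaling), shifts the mean, and
adds a sparse positive "speckle" tail that increases kurtosis and skewness —
the direction of the group differences reported for the diseased basal
ganglia (greater variability, heavier and more asymmetric intensity tails).

Magnitude-MRI noise is Rician; a smooth multiplicative bias field of
controllable peak-to-trough amplitude is applied last.  Everything is
deterministic given ``PhantomSpec.seed``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import Mask, Volume, read_mask, read_volume, write_mask, write_volume

REGION_NAMES = {1: "caudate", 2: "putamen"}


@dataclass
class HabitatTexture:
    """Gaussian-random-field parameters of one habitat in one contrast."""

    mean: float
    std: float
    corr_mm: float = 2.0


@dataclass
class ClassEffect:
    """Per-habitat shift applied to disease-class subjects.

    ``std_scale`` multiplies the fluctuation amplitude (raises range and RMS),
    ``mean_shift`` is additive, and ``tail_boost`` sets the amplitude (in
    habitat-std units) of a sparse exponential speckle component that raises
    kurtosis and skewness.
    """

    mean_shift: float = 0.0
    std_scale: float = 1.0
    tail_boost: float = 0.0
    tail_fraction: float = 0.05


def default_habitat_params(k_true: int) -> dict[str, list[HabitatTexture]]:
    """Habitat textures spread over a plausible deep-gray intensity range.

    Habitats differ jointly in mean level (ascending in T1W, descending in
    T2W, as iron-rich versus iron-poor tissue would) and in texture
    correlation length (a geometric ladder from fine to coarse grain), so
    that both the intensity-driven and the structure-driven voxel features
    carry habitat identity.
    """
    if k_true == 1:
        corrs = [1.0]
    else:
        corrs = list(np.geomspace(0.5, 2.5, k_true))
    t1 = [
        HabitatTexture(mean=100.0 + 8.0 * h, std=3.0, corr_mm=corrs[h])
        for h in range(k_true)
    ]
    t2 = [
        HabitatTexture(mean=100.0 + 8.0 * (k_true - 1 - h), std=3.0,
                       corr_mm=corrs[h])
        for h in range(k_true)
    ]
    return {"T1W": t1, "T2W": t2}


def default_class_effect(k_true: int) -> list[ClassEffect]:
    """Moderate disease effect concentrated in the higher-index habitats."""
    effects = []
    for h in range(k_true):
        strength = (h + 1) / k_true
        effects.append(
            ClassEffect(
                mean_shift=6.0 * strength,
                std_scale=1.0 + 0.8 * strength,
                tail_boost=1.5 * strength,
            )
        )
    return effects


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom cohort."""

    n_per_class: int = 30
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    k_true: int = 2
    habitat_params: dict[str, list[HabitatTexture]] | None = None
    class_effect: list[ClassEffect] | None = None
    noise_sigma: float = 1.0
    bias_amplitude: float = 0.15
    background_mean: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.habitat_params is None:
            self.habitat_params = default_habitat_params(self.k_true)
        if self.class_effect is None:
            self.class_effect = default_class_effect(self.k_true)
        for contrast in ("T1W", "T2W"):
            if len(self.habitat_params[contrast]) != self.k_true:
                raise ValueError(
                    f"habitat_params[{contrast}] must have exactly k_true="
                    f"{self.k_true} entries"
                )
        if len(self.class_effect) != self.k_true:
            raise ValueError("class_effect must have exactly k_true entries")
        if min(self.grid_shape) < 10:
            raise ValueError(
                f"grid {self.grid_shape} too small to fit bilateral VOIs "
                "(need every dimension >= 10)"
            )


@dataclass
class PhantomTruth:
    """Planted ground truth for one subject."""

    habitat_label_volume: np.ndarray
    class_label: int
    bias_field: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class PhantomSubject:
    subject_id: str
    t1w: Volume
    t2w: Volume
    voi_mask: Mask
    truth: PhantomTruth


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center_frac, radii_frac) -> np.ndarray:
    idx = np.indices(shape).astype(np.float64)
    out = np.zeros(idx.shape[1:])
    for ax in range(3):
        c = center_frac[ax] * (shape[ax] - 1)
        r = max(1.0, radii_frac[ax] * shape[ax])
        out += ((idx[ax] - c) / r) ** 2
    return out <= 1.0


def make_voi_mask(grid_shape, spacing_mm) -> Mask:
    """Two bilateral ellipsoid pairs: caudate-like (label 1), putamen-like (2)."""
    labels = np.zeros(grid_shape, dtype=np.int32)
    # caudate-like: smaller, medial, anterior
    for x in (0.35, 0.65):
        labels[_ellipsoid(grid_shape, (x, 0.32, 0.5), (0.1, 0.14, 0.2))] = 1
    # putamen-like: larger, lateral, posterior
    for x in (0.16, 0.84):
        blob = _ellipsoid(grid_shape, (x, 0.62, 0.5), (0.12, 0.18, 0.26))
        labels[blob & (labels == 0)] = 2
    for rid in REGION_NAMES:
        if not np.any(labels == rid):
            raise ValueError(
                f"grid {grid_shape} too small to fit VOI region "
                f"{REGION_NAMES[rid]}"
            )
    return Mask(labels, spacing_mm, region_names=dict(REGION_NAMES))


def plant_habitats(mask: Mask, k_true: int, rng: np.random.Generator) -> np.ndarray:
    """Voronoi partition of every connected VOI blob into ``k_true`` habitats.

    Habitat j is the union of the j-th Voronoi cell over all blobs, so every
    habitat label is present in (and contiguous within) each structure.
    """
    labels = np.zeros(mask.shape, dtype=np.int32)
    spacing = np.asarray(mask.spacing_mm)
    blobs, n_blobs = ndimage.label(mask.foreground())
    for b in range(1, n_blobs + 1):
        coords = np.argwhere(blobs == b)
        if len(coords) < k_true:
            raise ValueError(
                f"VOI blob of {len(coords)} voxels cannot hold {k_true} habitats"
            )
        seed_idx = rng.choice(len(coords), size=k_true, replace=False)
        seeds = coords[seed_idx].astype(np.float64) * spacing
        pts = coords.astype(np.float64) * spacing
        d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1) + 1
        labels[tuple(coords.T)] = assign
    return labels


# ---------------------------------------------------------------------------
# texture, noise, bias
# ---------------------------------------------------------------------------

def _gaussian_random_field(shape, spacing_mm, corr_mm, rng) -> np.ndarray:
    """Zero-mean, unit-variance field with the given correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = [max(corr_mm / s, 1e-6) for s in spacing_mm]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field with given peak-to-trough amplitude, mean 1."""
    if amplitude == 0:
        return np.ones(shape)
    axes = [np.linspace(-1, 1, n) for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    coef = rng.standard_normal(9)
    f = (coef[0] * xx + coef[1] * yy + coef[2] * zz
         + coef[3] * xx * yy + coef[4] * xx * zz + coef[5] * yy * zz
         + coef[6] * xx ** 2 + coef[7] * yy ** 2 + coef[8] * zz ** 2)
    ptp = np.ptp(f)
    if ptp == 0:
        return np.ones(shape)
    f = f * (amplitude / ptp)
    f = f - f.mean() + 1.0
    return f


def _rician(values, sigma, rng) -> np.ndarray:
    if sigma == 0:
        return np.abs(values)
    n1 = rng.normal(0.0, sigma, values.shape)
    n2 = rng.normal(0.0, sigma, values.shape)
    return np.sqrt((values + n1) ** 2 + n2 ** 2)


def _render_contrast(spec: PhantomSpec, contrast: str, habitat_labels, diseased,
                     rng) -> tuple[np.ndarray, np.ndarray]:
    vals = np.full(spec.grid_shape, spec.background_mean, dtype=np.float64)
    params = spec.habitat_params[contrast]
    for h in range(spec.k_true):
        p = params[h]
        sel = habitat_labels == h + 1
        if not np.any(sel):
            continue
        fluct = _gaussian_random_field(spec.grid_shape, spec.spacing_mm,
                                       p.corr_mm, rng)
        mean, std = p.mean, p.std
        if diseased:
            eff = spec.class_effect[h]
            mean = mean + eff.mean_shift
            std = std * eff.std_scale
            vals[sel] = mean + std * fluct[sel]
            if eff.tail_boost > 0:
                spikes = rng.random(spec.grid_shape) < eff.tail_fraction
                amp = eff.tail_boost * p.std
                vals[sel & spikes] += amp * rng.exponential(
                    1.0, int((sel & spikes).sum())
                )
        else:
            vals[sel] = mean + std * fluct[sel]
    bias = _bias_field(spec.grid_shape, spec.bias_amplitude, rng)
    vals = _rician(vals * bias, spec.noise_sigma, rng)
    return vals, bias


# ---------------------------------------------------------------------------
# cohort generation and I/O
# ---------------------------------------------------------------------------

def generate_cohort(spec: PhantomSpec) -> list[PhantomSubject]:
    """Deterministically generate ``2 * n_per_class`` phantom subjects.

    Subjects ``C###`` are the control class (label 0), ``P###`` the disease
    class (label 1).
    """
    root = np.random.SeedSequence(spec.seed)
    mask = make_voi_mask(spec.grid_shape, spec.spacing_mm)
    subjects = []
    child_seeds = root.spawn(2 * spec.n_per_class)
    order = [(0, i) for i in range(spec.n_per_class)] + \
            [(1, i) for i in range(spec.n_per_class)]
    for (cls, i), ss in zip(order, child_seeds):
        rng = np.random.Generator(np.random.PCG64(ss))
        habitat_labels = plant_habitats(mask, spec.k_true, rng)
        sid = f"{'P' if cls else 'C'}{i:03d}"
        volumes = {}
        bias = {}
        for contrast in ("T1W", "T2W"):
            vals, b = _render_contrast(spec, contrast, habitat_labels,
                                       diseased=bool(cls), rng=rng)
            volumes[contrast] = Volume(vals, spec.spacing_mm,
                                       contrast_tag=contrast, subject_id=sid)
            bias[contrast] = b
        truth = PhantomTruth(habitat_labels, cls, bias)
        subjects.append(PhantomSubject(sid, volumes["T1W"], volumes["T2W"],
                                       Mask(mask.labels.copy(), spec.spacing_mm,
                                            region_names=dict(REGION_NAMES)),
                                       truth))
    return subjects


MANIFEST_COLUMNS = ["subject_id", "class", "t1_path", "t2_path", "mask_path"]


def write_cohort(cohort: list[PhantomSubject], directory,
                 cohort_labels: dict[str, str] | None = None) -> Path:
    """Write NIfTI volumes, masks and a CSV manifest; return manifest path.

    ``cohort_labels`` optionally maps subject_id to a cohort name (e.g.
    train / validation), added as an extra manifest column.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    columns = list(MANIFEST_COLUMNS)
    if cohort_labels is not None:
        columns.append("cohort")
    rows = []
    for subj in cohort:
        t1 = directory / f"{subj.subject_id}_t1w.nii.gz"
        t2 = directory / f"{subj.subject_id}_t2w.nii.gz"
        mk = directory / f"{subj.subject_id}_mask.nii.gz"
        write_volume(subj.t1w, t1)
        write_volume(subj.t2w, t2)
        write_mask(subj.voi_mask, mk)
        row = [subj.subject_id, str(subj.truth.class_label),
               t1.name, t2.name, mk.name]
        if cohort_labels is not None:
            row.append(cohort_labels.get(subj.subject_id, ""))
        rows.append(row)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        writer.writerows(rows)
    return manifest


def read_cohort(manifest_path) -> list[PhantomSubject]:
    """Load a written cohort back; truth carries only the class label."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    subjects = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["subject_id"]
            t1 = read_volume(base / row["t1_path"], "T1W", sid)
            t2 = read_volume(base / row["t2_path"], "T2W", sid)
            mask = read_mask(base / row["mask_path"], dict(REGION_NAMES))
            truth = PhantomTruth(np.zeros(mask.shape, dtype=np.int32),
                                 int(row["class"]))
            subjects.append(PhantomSubject(sid, t1, t2, mask, truth))
    return subjects
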