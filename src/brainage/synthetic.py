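"""Synthetic VBM-like tissue-density cohorts.

Real inputs for brain-age modelling are voxel-based-morphometry (VBM)
outputs: smooth, nonnegative grey-matter (GM) and white-matter (WM)
density maps on a common stereotactic grid, zero outside the brain.
This module generates phantom cohorts with the same contract so the
whole downstream pipeline (preprocessing, CNN training, evaluation,
confound decomposition, saliency) is testable without any MRI download:

* a toy labelled atlas of disjoint ellipsoidal ROIs inside an
  ellipsoidal brain mask (stand-in for an anatomical parcellation),
* per-subject phenotypes (age, sex, site, diagnosis flag, dimensional
  symptom score, total brain volume),
* two-channel (GM, WM) density volumes in which selected ROIs change
  density linearly with age, with additive site and sex shifts,
  voxel noise, and mask-restricted Gaussian smoothing.

The ``site_age_confounding`` dial in :class:`CohortConfig` controls how
strongly site membership tracks age: 0 makes them independent, 1 makes
site a deterministic function of the age quantile.  This is the lever
used to emulate cohorts whose acquisition sites differ in age
composition, the mechanism behind confounded brain-age models.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomAtlas",
    "SubjectRecord",
    "AgeDistribution",
    "CohortConfig",
    "TissueVolume",
    "fwhm_to_sigma",
    "make_atlas",
    "sample_cohort",
    "render_volume",
    "render_cohort",
    "records_to_frame",
    "frame_to_records",
    "save_cohort",
    "load_cohort",
    "save_atlas",
    "load_atlas",
]

GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma -> FWHM


# ---------------------------------------------------------------------------
# types


@dataclass
class PhantomAtlas:
    """Labelled parcellation phantom: integer ROI labels inside a brain mask.

    ``label_grid`` holds 0 for background / unlabelled brain tissue and a
    positive ROI id elsewhere; ``brain_mask`` is a superset of all labelled
    voxels (ROIs plus unlabelled brain tissue).
    """

    label_grid: np.ndarray
    roi_ids: list[int]
    roi_names: list[str]
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        labels = np.unique(self.label_grid)
        labels = labels[labels != 0]
        if not set(labels.tolist()) <= set(self.roi_ids):
            raise ValueError("label_grid contains ids not listed in roi_ids")
        if np.any(self.label_grid[~self.brain_mask] != 0):
            raise ValueError("labelled voxels found outside the brain mask")
        if len(self.roi_ids) < 3:
            raise ValueError("an atlas needs at least 3 ROIs")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_grid.shape

    def roi_mask(self, roi_id: int) -> np.ndarray:
        return self.label_grid == roi_id

    def roi_voxel_counts(self) -> dict[int, int]:
        return {int(r): int(np.sum(self.label_grid == r)) for r in self.roi_ids}


@dataclass
class SubjectRecord:
    """Phenotypes and confounders for one subject."""

    subject_id: str
    age: float
    sex: int  # 0 = female, 1 = male
    site: int
    diagnosis: int  # 0 = typically developing, 1 = diagnosed
    symptom_score: float  # dimensional psychopathology, >= 0
    total_brain_volume: float  # mask-integrated tissue density x voxel volume


@dataclass
class AgeDistribution:
    """Cohort age distribution: ``uniform`` on [low, high] or a normal
    truncated to [low, high]."""

    kind: str = "uniform"  # "uniform" | "truncnorm"
    low: float = 8.0
    high: float = 18.0
    mean: float | None = None
    sd: float | None = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.high <= self.low:
            raise ValueError(
                f"degenerate age range [{self.low}, {self.high}]: low must be < high"
            )
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        if self.kind == "truncnorm":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError("truncnorm ages need mean and positive sd")
            out = np.empty(n)
            filled = 0
            while filled < n:
                draw = rng.normal(self.mean, self.sd, size=2 * (n - filled))
                keep = draw[(draw >= self.low) & (draw <= self.high)][: n - filled]
                out[filled : filled + keep.size] = keep
                filled += keep.size
            return out
        raise ValueError(f"unknown age distribution kind {self.kind!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


@dataclass
class CohortConfig:
    """Generative settings for one phantom cohort ("dataset").

    ``roi_age_slopes`` are GM density changes per year for each ROI id
    (units: density/yr, signed); WM slopes default to their negation,
    mimicking opposing GM/WM maturation trends.  ``site_offsets`` are
    additive density shifts per acquisition site; ``sex_effect`` is an
    additive shift applied to male subjects.  All density effects act
    before clipping to [0, 1] and before smoothing.
    """

    name: str = "cohort"
    n_subjects: int = 160
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    age_distribution: AgeDistribution = field(default_factory=AgeDistribution)
    n_sites: int = 2
    roi_age_slopes: dict[int, float] = field(
        default_factory=lambda: {1: -0.012, 2: 0.010, 3: -0.008}
    )
    site_offsets: Sequence[float] = (0.0, 0.02)
    site_age_confounding: float = 0.0
    sex_effect: float = 0.015
    noise_sd: float = 0.02
    smoothing_fwhm: float = 2.0
    voxel_size: float = 1.0
    seed: int = 0
    # baselines: unlabelled brain tissue and per-ROI start densities
    gm_baseline: float = 0.45
    wm_baseline: float = 0.40
    roi_gm_baseline: float = 0.55
    roi_wm_baseline: float = 0.45
    wm_age_slopes: dict[int, float] | None = None  # default: negated GM slopes
    female_fraction: float = 0.5
    diagnosis_prevalence: float = 0.3
    symptom_mean: float = 20.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be >= 0")
        if not 0.0 <= self.site_age_confounding <= 1.0:
            raise ValueError("site_age_confounding must lie in [0, 1]")
        if len(self.site_offsets) < self.n_sites:
            raise ValueError("need one site_offset per site")

    def wm_slopes(self) -> dict[int, float]:
        if self.wm_age_slopes is not None:
            return dict(self.wm_age_slopes)
        return {r: -s for r, s in self.roi_age_slopes.items()}

    @property
    def age_ref(self) -> float:
        """Reference age for the linear ROI trends (cohort age midpoint)."""
        return self.age_distribution.midpoint


@dataclass
class TissueVolume:
    """Two-channel (GM, WM) density volume for one subject."""

    data: np.ndarray  # (2, D, H, W), nonnegative, zero outside the brain
    voxel_size: float
    subject_id: str

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[0] != 2:
            raise ValueError("TissueVolume data must have shape (2, D, H, W)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("TissueVolume contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]


# ---------------------------------------------------------------------------
# helpers


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Gaussian sigma in voxels for a smoothing kernel given as FWHM in mm.

    sigma = FWHM / (2 sqrt(2 ln 2)) / voxel_size.
    """
    if fwhm_mm <= 0 or voxel_size_mm <= 0:
        raise ValueError("fwhm_mm and voxel_size_mm must both be positive")
    return fwhm_mm / GAUSS_FWHM_FACTOR / voxel_size_mm


def _ellipsoid_mask(
    shape: Sequence[int], center: Sequence[float], semi_axes: Sequence[float]
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(tuple(shape), dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_atlas(
    grid_shape: Sequence[int], n_rois: int, seed: int, max_tries: int = 500
) -> PhantomAtlas:
    """Place ``n_rois`` disjoint ellipsoidal ROIs inside a central brain mask.

    Deterministic given ``seed``.  Raises ``RuntimeError`` when an ROI cannot
    be placed without overlap after ``max_tries`` attempts.
    """
    if n_rois < 3:
        raise ValueError("n_rois must be >= 3")
    shape = tuple(int(s) for s in grid_shape)
    rng = np.random.default_rng(seed)

    center = [(s - 1) / 2.0 for s in shape]
    brain_axes = [0.44 * s for s in shape]
    brain_mask = _ellipsoid_mask(shape, center, brain_axes)

    label_grid = np.zeros(shape, dtype=np.int16)
    min_ax = min(shape)
    for roi in range(1, n_rois + 1):
        placed = False
        for _ in range(max_tries):
            semi = rng.uniform(0.09 * min_ax, 0.16 * min_ax, size=3)
            semi = np.maximum(semi, 1.2)
            c = [rng.uniform(a, s - 1 - a) for s, a in zip(shape, semi)]
            mask = _ellipsoid_mask(shape, c, semi)
            if not mask.any():
                continue
            if np.any(mask & ~brain_mask):
                continue  # must lie fully inside the brain
            if np.any(label_grid[mask] != 0):
                continue  # must not overlap earlier ROIs
            label_grid[mask] = roi
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place ROI {roi} of {n_rois} in grid {shape} "
                f"after {max_tries} attempts; enlarge the grid or reduce n_rois"
            )
    roi_ids = list(range(1, n_rois + 1))
    names = [f"roi_{i:02d}" for i in roi_ids]
    return PhantomAtlas(label_grid, roi_ids, names, brain_mask)


# ---------------------------------------------------------------------------
# cohort sampling


def sample_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw phenotypes for one cohort.

    Site assignment implements the confound dial: each subject's age
    quantile maps to a "block" site; with probability
    ``site_age_confounding`` the subject is assigned its block site,
    otherwise a uniformly random site.  At 0 site is independent of age,
    at 1 it is a deterministic function of the age quantile.

    ``total_brain_volume`` is provisional here (a sex-and-noise-dependent
    placeholder) and is recomputed from the rendered image by
    :func:`render_volume` so that record and volume stay consistent.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ages = config.age_distribution.sample(n, rng)
    sexes = (rng.uniform(size=n) >= config.female_fraction).astype(int)

    # block site from the within-cohort age rank
    order = np.argsort(ages, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    block_site = (ranks * config.n_sites) // n
    random_site = rng.integers(0, config.n_sites, size=n)
    use_block = rng.uniform(size=n) < config.site_age_confounding
    sites = np.where(use_block, block_site, random_site)

    diagnosis = (rng.uniform(size=n) < config.diagnosis_prevalence).astype(int)
    symptoms = rng.exponential(scale=config.symptom_mean, size=n)

    # provisional TBV: sex shift + individual variation (overwritten on render)
    voxvol = config.voxel_size**3
    base_vol = 0.4 * float(np.prod(config.grid_shape)) * voxvol
    tbv = base_vol * (1.0 + 0.05 * sexes + rng.normal(0.0, 0.02, size=n))

    return [
        SubjectRecord(
            subject_id=f"{config.name}_s{i:04d}",
            age=float(ages[i]),
            sex=int(sexes[i]),
            site=int(sites[i]),
            diagnosis=int(diagnosis[i]),
            symptom_score=float(symptoms[i]),
            total_brain_volume=float(tbv[i]),
        )
        for i in range(n)
    ]


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            age=float(row.age),
            sex=int(row.sex),
            site=int(row.site),
            diagnosis=int(row.diagnosis),
            symptom_score=float(row.symptom_score),
            total_brain_volume=float(row.total_brain_volume),
        )
        for row in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# volume rendering


def _masked_smooth(channel: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing restricted to the mask.

    Normalising by the smoothed mask keeps in-mask values a convex
    combination of in-mask inputs, so [0, 1] bounds and the
    zero-outside-mask invariant survive smoothing exactly.
    """
    if sigma <= 0:
        return channel * mask
    sm_num = ndimage.gaussian_filter(channel * mask, sigma=sigma)
    sm_den = ndimage.gaussian_filter(mask.astype(float), sigma=sigma)
    out = np.zeros_like(channel)
    inside = mask
    out[inside] = sm_num[inside] / np.maximum(sm_den[inside], 1e-12)
    return out


def render_volume(
    record: SubjectRecord,
    atlas: PhantomAtlas,
    config: CohortConfig,
    rng: np.random.Generator,
) -> TissueVolume:
    """Render one subject's two-channel density phantom.

    Inside ROI r each channel takes
    ``clip(baseline_r + slope_r * (age - age_ref) + site_offset +
    sex_effect * male + noise, 0, 1)``; unlabelled brain tissue uses the
    channel baseline with the same site/sex/noise terms; the result is
    Gaussian-smoothed inside the brain mask and re-zeroed outside.
    ``record.total_brain_volume`` is updated in place to the
    mask-integrated mean tissue density times voxel volume.
    """
    if atlas.shape != tuple(config.grid_shape):
        raise ValueError(
            f"atlas grid {atlas.shape} does not match config grid {tuple(config.grid_shape)}"
        )
    d_age = record.age - config.age_ref
    site_off = float(config.site_offsets[record.site])
    sex_off = config.sex_effect * record.sex
    sigma = (
        fwhm_to_sigma(config.smoothing_fwhm, config.voxel_size)
        if config.smoothing_fwhm > 0
        else 0.0
    )

    channels = []
    for base, roi_base, slopes in (
        (config.gm_baseline, config.roi_gm_baseline, config.roi_age_slopes),
        (config.wm_baseline, config.roi_wm_baseline, config.wm_slopes()),
    ):
        vol = np.full(atlas.shape, base, dtype=np.float64)
        for roi_id in atlas.roi_ids:
            roi_mask = atlas.label_grid == roi_id
            slope = slopes.get(roi_id, 0.0)
            vol[roi_mask] = roi_base + slope * d_age
        vol += site_off + sex_off
        if config.noise_sd > 0:
            vol += rng.normal(0.0, config.noise_sd, size=atlas.shape)
        np.clip(vol, 0.0, 1.0, out=vol)
        vol = _masked_smooth(vol, atlas.brain_mask, sigma)
        vol[~atlas.brain_mask] = 0.0
        channels.append(vol)

    data = np.stack(channels).astype(np.float32)
    voxvol = config.voxel_size**3
    record.total_brain_volume = float(
        data.mean(axis=0)[atlas.brain_mask].sum() * voxvol
    )
    return TissueVolume(data=data, voxel_size=config.voxel_size, subject_id=record.subject_id)


def render_cohort(
    records: Sequence[SubjectRecord], atlas: PhantomAtlas, config: CohortConfig
) -> np.ndarray:
    """Render every subject; returns an (n, 2, D, H, W) float32 array.

    Each subject gets an independent child random stream spawned from the
    cohort seed, so cohorts are reproducible under subject reordering.
    """
    streams = np.random.SeedSequence(config.seed).spawn(len(records))
    out = np.empty((len(records), 2, *atlas.shape), dtype=np.float32)
    for i, (rec, ss) in enumerate(zip(records, streams)):
        out[i] = render_volume(rec, atlas, config, np.random.default_rng(ss)).data
    return out


# ---------------------------------------------------------------------------
# disk IO (NIfTI volumes, CSV phenotypes, NIfTI+TSV atlas)

PHENOTYPE_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "site",
    "diagnosis",
    "symptom_score",
    "total_brain_volume",
]


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def save_atlas(atlas: PhantomAtlas, path: Path | str, voxel_size: float = 1.0) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(atlas.label_grid.astype(np.int16), _affine(voxel_size)),
        path / "atlas_labels.nii.gz",
    )
    nib.save(
        nib.Nifti1Image(atlas.brain_mask.astype(np.uint8), _affine(voxel_size)),
        path / "atlas_brain_mask.nii.gz",
    )
    pd.DataFrame({"roi_id": atlas.roi_ids, "roi_name": atlas.roi_names}).to_csv(
        path / "atlas_lookup.tsv", sep="\t", index=False
    )


def load_atlas(path: Path | str) -> PhantomAtlas:
    path = Path(path)
    labels = np.asarray(
        nib.load(path / "atlas_labels.nii.gz").get_fdata(), dtype=np.int16
    )
    mask = np.asarray(
        nib.load(path / "atlas_brain_mask.nii.gz").get_fdata(), dtype=bool
    )
    lut = pd.read_csv(path / "atlas_lookup.tsv", sep="\t")
    return PhantomAtlas(labels, lut.roi_id.tolist(), lut.roi_name.tolist(), mask)


def save_cohort(
    volumes: np.ndarray,
    records: Sequence[SubjectRecord],
    config: CohortConfig,
    path: Path | str,
    per_channel: bool = False,
) -> None:
    """Write a cohort to disk: NIfTI volumes, phenotype CSV, manifest CSV.

    ``per_channel=False`` (default) writes one 4D NIfTI per subject with
    GM/WM in the 4th dimension; ``per_channel=True`` writes one 3D file
    per subject per channel.  The manifest maps subject_id to file paths.
    """
    path = Path(path)
    (path / "volumes").mkdir(parents=True, exist_ok=True)
    aff = _affine(config.voxel_size)
    manifest = []
    for vol, rec in zip(volumes, records):
        if per_channel:
            paths = {}
            for ci, ch in enumerate(("gm", "wm")):
                fn = f"{rec.subject_id}_{ch}.nii.gz"
                nib.save(nib.Nifti1Image(vol[ci].astype(np.float32), aff),
                         path / "volumes" / fn)
                paths[f"{ch}_path"] = f"volumes/{fn}"
            manifest.append({"subject_id": rec.subject_id, **paths})
        else:
            fn = f"{rec.subject_id}.nii.gz"
            img = nib.Nifti1Image(np.moveaxis(vol, 0, -1).astype(np.float32), aff)
            nib.save(img, path / "volumes" / fn)
            manifest.append({"subject_id": rec.subject_id,
                             "volume_path": f"volumes/{fn}"})
    pd.DataFrame(manifest).to_csv(path / "manifest.csv", index=False)
    records_to_frame(records)[PHENOTYPE_COLUMNS].to_csv(
        path / "phenotypes.csv", index=False
    )
    (path / "cohort_config.json").write_text(
        json.dumps(
            {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(config).items()
                    if k != "age_distribution"
                },
                "age_distribution": dataclasses.asdict(config.age_distribution),
            },
            indent=2,
            default=str,
        )
    )


def load_cohort(path: Path | str) -> tuple[np.ndarray, list[SubjectRecord]]:
    path = Path(path)
    frame = pd.read_csv(path / "phenotypes.csv")
    records = frame_to_records(frame)
    manifest = pd.read_csv(path / "manifest.csv").set_index("subject_id")
    vols = []
    for rec in records:
        row = manifest.loc[rec.subject_id]
        if "volume_path" in manifest.columns:
            img = nib.load(path / row.volume_path)
            vols.append(
                np.moveaxis(np.asarray(img.get_fdata(), dtype=np.float32), -1, 0)
            )
        else:
            chans = [
                np.asarray(nib.load(path / row[f"{ch}_path"]).get_fdata(),
                           dtype=np.float32)
                for ch in ("gm", "wm")
            ]
            vols.append(np.stack(chans))
    return np.stack(vols), records
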