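"""SmoothGrad attention maps and atlas ROI ranking.

SmoothGrad averages absolute input gradients over noise-perturbed copies
of each input: map = mean_i |d output / d input|(x + eps_i), with
eps_i ~ N(0, sigma^2) and sigma = noise_fraction * (max(x) - min(x))
computed per input volume.  Defaults follow the original method's
recommendation: 20% noise, 50 samples.  GM/WM channels are reduced to a
single spatial map by their mean (per-channel maps are available).

Aggregation follows the study protocol: per-subject maps are averaged
within each cross-validation fold, each fold mean is max-normalized to
1, and fold maps are averaged into one study map.  Intersecting a map
with a labelled atlas yields a ranked ROI table; the ROI score is the
mean attention per in-ROI voxel (a sum would rank large ROIs above
small high-attention ones such as brainstem nuclei).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import PhantomAtlas

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothGradConfig",
    "AttentionMap",
    "smoothgrad",
    "gradient_check",
    "aggregate_attention",
    "roi_rank",
    "roi_overlap",
    "save_attention_map",
]


@dataclass
class SmoothGradConfig:
    n_samples: int = 50
    noise_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")


@dataclass
class AttentionMap:
    """Nonnegative voxel importances on the model-input lattice."""

    data: np.ndarray  # 3D spatial map (channels already reduced)
    provenance: dict

    def __post_init__(self) -> None:
        if np.any(self.data < 0) or not np.all(np.isfinite(self.data)):
            raise ValueError("attention maps must be nonnegative and finite")


def smoothgrad(model, volume: np.ndarray, config: SmoothGradConfig,
               reduce_channels: bool = True) -> AttentionMap:
    """SmoothGrad saliency for one input volume (channels, D, H, W).

    With ``noise_fraction=0, n_samples=1`` this is exactly the absolute
    vanilla gradient at the input.
    """
    x = np.asarray(volume, dtype=np.float32)
    if x.size == 0:
        raise ValueError("zero-size input")
    if x.ndim != 4:
        raise ValueError("expected a (channels, D, H, W) volume")
    rng = np.random.default_rng(config.seed)
    sigma = config.noise_fraction * float(x.max() - x.min())
    acc = np.zeros_like(x, dtype=np.float64)
    chunk = 16  # noisy replicas per backprop batch
    done = 0
    while done < config.n_samples:
        m = min(chunk, config.n_samples - done)
        batch = np.repeat(x[None], m, axis=0)
        if sigma > 0:
            batch = batch + rng.normal(0.0, sigma, size=batch.shape).astype(np.float32)
        grads = model.input_gradient(batch)
        acc += np.abs(grads).sum(axis=0)
        done += m
    acc /= config.n_samples
    data = acc.mean(axis=0) if reduce_channels else acc
    return AttentionMap(
        data=data,
        provenance={
            "n_samples": config.n_samples,
            "noise_fraction": config.noise_fraction,
            "seed": config.seed,
        },
    )


def gradient_check(model, volume: np.ndarray, n_probe_voxels: int = 20,
                   seed: int = 0, step: float = 1e-3) -> float:
    """Worst relative deviation between the analytic input gradient and
    central finite differences at randomly probed voxels.

    Serves as the independent oracle for the saliency gradient engine.
    Probes that straddle a non-differentiable kink (ReLU / max-pool
    boundaries, detected by disagreeing one-sided differences) are
    skipped: there the finite-difference oracle itself is invalid, not
    the gradient.
    """
    if step <= 0 or step < 1e-12:
        raise ValueError("finite-difference step underflow")
    x = np.asarray(volume, dtype=np.float64)
    analytic = model.input_gradient(x[None])[0]
    rng = np.random.default_rng(seed)
    flat_idx = rng.choice(x.size, size=min(n_probe_voxels, x.size), replace=False)
    worst = 0.0
    scale = max(float(np.abs(analytic).max()), 1e-8)
    f0 = float(model.predict(x[None])[0])
    for fi in flat_idx:
        idx = np.unravel_index(fi, x.shape)
        xp = x.copy()
        xp[idx] += step
        xm = x.copy()
        xm[idx] -= step
        fp = float(model.predict(xp[None])[0])
        fm = float(model.predict(xm[None])[0])
        fd_fwd = (fp - f0) / step
        fd_bwd = (f0 - fm) / step
        if abs(fd_fwd - fd_bwd) > 2e-3 * scale:
            continue  # kink inside the probe interval
        fd = (fp - fm) / (2 * step)
        dev = abs(fd - float(analytic[idx])) / scale
        worst = max(worst, dev)
    return worst


def aggregate_attention(maps: Sequence[AttentionMap], level: str) -> AttentionMap:
    """Aggregate maps: ``level='fold'`` -> voxelwise mean of per-subject maps;
    ``level='study'`` -> max-normalize each fold map to 1, then voxelwise
    mean across folds.  All-zero maps skip normalization with a warning."""
    if len(maps) == 0:
        raise ValueError("no attention maps to aggregate")
    arrays = [np.asarray(m.data, dtype=np.float64) for m in maps]
    if any(a.shape != arrays[0].shape for a in arrays):
        raise ValueError("attention maps must share one lattice")
    if level == "fold":
        agg = np.mean(arrays, axis=0)
    elif level == "study":
        normed = []
        for a in arrays:
            peak = a.max()
            if peak <= 0:
                logger.warning("all-zero fold map: normalization skipped")
                normed.append(a)
            else:
                normed.append(a / peak)
        agg = np.mean(normed, axis=0)
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    return AttentionMap(data=agg, provenance={"level": level, "n_maps": len(maps)})


def roi_rank(map_: AttentionMap, atlas: PhantomAtlas, top_k: int | None = None
             ) -> pd.DataFrame:
    """Ranked ROI table: score = mean attention per in-ROI voxel.

    Sorted descending; ties broken by ascending roi_id.  ROIs with zero
    voxels on the lattice are excluded with a warning.  ``top_k`` flags
    the leading rows in a boolean column.
    """
    data = np.asarray(map_.data)
    if data.shape != atlas.shape:
        raise ValueError(
            f"map lattice {data.shape} does not match atlas {atlas.shape}"
        )
    rows = []
    for roi_id, name in zip(atlas.roi_ids, atlas.roi_names):
        mask = atlas.label_grid == roi_id
        n_vox = int(mask.sum())
        if n_vox == 0:
            logger.warning("ROI %d (%s) has no voxels on this lattice", roi_id, name)
            continue
        rows.append({"roi_id": roi_id, "roi_name": name,
                     "score": float(data[mask].mean()), "n_voxels": n_vox})
    table = pd.DataFrame(rows).sort_values(
        ["score", "roi_id"], ascending=[False, True], kind="stable"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    if top_k is not None:
        if top_k > len(table):
            raise ValueError(f"top_k={top_k} exceeds table length {len(table)}")
        table["top_k"] = table["rank"] <= top_k
    return table.reset_index(drop=True)


def roi_overlap(table_a: pd.DataFrame, table_b: pd.DataFrame, k: int) -> int:
    """Size of the intersection of the two top-k ROI id sets."""
    if k > len(table_a) or k > len(table_b):
        raise ValueError(f"k={k} exceeds a table length")
    top_a = set(table_a.nsmallest(k, "rank").roi_id)
    top_b = set(table_b.nsmallest(k, "rank").roi_id)
    return len(top_a & top_b)


def save_attention_map(map_: AttentionMap, path: Path | str,
                       voxel_size: float = 1.0) -> None:
    aff = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(map_.data.astype(np.float32), aff), str(path))
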