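"""Bring tissue-density volumes to the model input geometry.

VBM outputs arrive on an odd-sized stereotactic grid (e.g. 121x145x121);
pooling CNNs want each axis divisible by 2^n_blocks (e.g. 128^3).  The
only geometric change allowed here is center padding/trimming that
touches background voxels exclusively: cropping any in-brain voxel is an
error, never a silent loss.  Convention for odd differences: the smaller
share goes to the low-index side, the larger to the high side (145 -> 128
trims 8 low / 9 high).  Axes are 0-based (x, y, z) in NIfTI array order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PrepConfig", "pad_trim", "pad_trim_array", "stack_channels", "split_channels"]


@dataclass
class PrepConfig:
    target_shape: tuple[int, int, int] = (128, 128, 128)
    channels: tuple[str, str] = ("gm", "wm")
    enforce_mask_zero: bool = True

    def validate_for_blocks(self, n_blocks: int) -> None:
        div = 2**n_blocks
        for ax, t in enumerate(self.target_shape):
            if t % div:
                raise ValueError(
                    f"target axis {ax} size {t} not divisible by 2^{n_blocks}"
                )


def _axis_plan(size: int, target: int) -> tuple[slice, tuple[int, int]]:
    """Crop slice and pad widths bringing one axis from ``size`` to ``target``."""
    if size > target:
        cut = size - target
        lo = cut // 2
        return slice(lo, lo + target), (0, 0)
    pad = target - size
    return slice(0, size), (pad // 2, pad - pad // 2)


def pad_trim_array(
    data: np.ndarray, target_shape: tuple[int, int, int]
) -> np.ndarray:
    """Center pad/trim the trailing three axes of ``data`` to ``target_shape``.

    Raises ``ValueError`` if any trimmed voxel is nonzero (brain content
    would be cropped).
    """
    spatial = data.shape[-3:]
    slices: list[slice] = []
    pads: list[tuple[int, int]] = []
    for size, target in zip(spatial, target_shape):
        sl, pad = _axis_plan(size, target)
        slices.append(sl)
        pads.append(pad)

    lead = data.ndim - 3
    full_slices = (slice(None),) * lead + tuple(slices)
    cropped = data[full_slices]
    if np.count_nonzero(data) != np.count_nonzero(cropped):
        raise ValueError(
            "pad_trim would crop nonzero (brain) voxels: the brain bounding box "
            f"does not fit target_shape {tuple(target_shape)}"
        )
    full_pads = [(0, 0)] * lead + pads
    return np.pad(cropped, full_pads, mode="constant", constant_values=0)


def pad_trim(volume, target_shape: tuple[int, int, int]):
    """Pad/trim a :class:`~brainage.synthetic.TissueVolume` (or bare array).

    Every in-brain voxel value is preserved; padding fills with 0.
    """
    from .synthetic import TissueVolume

    if isinstance(volume, TissueVolume):
        return TissueVolume(
            data=pad_trim_array(volume.data, target_shape),
            voxel_size=volume.voxel_size,
            subject_id=volume.subject_id,
        )
    return pad_trim_array(np.asarray(volume), target_shape)


def stack_channels(gm: np.ndarray, wm: np.ndarray) -> np.ndarray:
    """Stack single-channel GM and WM grids into the model's (2, D, H, W) input."""
    gm = np.asarray(gm)
    wm = np.asarray(wm)
    if gm.shape != wm.shape:
        raise ValueError(f"GM grid {gm.shape} and WM grid {wm.shape} differ")
    return np.stack([gm, wm], axis=0)


def split_channels(stacked: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`stack_channels`."""
    if stacked.shape[0] != 2:
        raise ValueError("expected a two-channel (2, D, H, W) array")
    return stacked[0], stacked[1]
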