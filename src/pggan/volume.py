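"""Volumes and the standard preprocessing chain.

A :class:`Volume` is a registered 3D structural scan (or a model prediction)
on a common voxel grid.  The preprocessing path applied to every scan before
it reaches the network is: central crop -> integer-factor downsampling by
local mean -> per-volume min-max normalization to [0, 1] rescaled to [-1, 1].
Evaluation maps the signed representation back to [0, 1] (``to_unit``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "central_crop",
    "downsample",
    "normalize_signed",
    "to_unit",
    "load_volume",
    "save_volume",
    "preprocess",
]

#: Allowed intensity-range tags.
RANGE_TAGS = ("raw", "unit", "signed")


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid with voxel size and an intensity-range tag.

    Parameters
    ----------
    data
        3D float array, finite everywhere.
    voxel_size
        Physical voxel edge length per axis, in mm.
    intensity_range
        One of ``raw`` (unconstrained), ``unit`` ([0, 1]) or ``signed``
        ([-1, 1]).  The tag is validated against the actual data range.
    session
        Acquisition label, e.g. ``"bl"``, ``"1y"``, ``"4y"``.
    subject_id
        Owning subject identifier.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_range: str = "raw"
    session: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")
        if self.intensity_range not in RANGE_TAGS:
            raise ValueError(f"unknown intensity range tag {self.intensity_range!r}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        eps = 1e-9
        if self.intensity_range == "unit":
            if self.data.min() < -eps or self.data.max() > 1 + eps:
                raise ValueError("tag 'unit' but data outside [0, 1]")
        elif self.intensity_range == "signed":
            if self.data.min() < -1 - eps or self.data.max() > 1 + eps:
                raise ValueError("tag 'signed' but data outside [-1, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, **changes) -> "Volume":
        """Copy of this volume with new data (and optional field changes)."""
        kwargs = dict(
            voxel_size=self.voxel_size,
            intensity_range=self.intensity_range,
            session=self.session,
            subject_id=self.subject_id,
        )
        kwargs.update(changes)
        return Volume(data=data, **kwargs)


def central_crop(v: Volume, target_shape: tuple[int, int, int]) -> Volume:
    """Crop ``v`` to ``target_shape`` about the grid centre.

    The crop window is centred on each axis; when source minus target is odd
    the extra voxel is removed from the high-index side (ties break toward the
    lower index).  Windows are half-open in 0-based voxel coordinates.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3:
        raise ValueError("target_shape must have 3 entries")
    for src, tgt in zip(v.shape, target_shape):
        if tgt > src:
            raise ValueError(f"crop target {target_shape} exceeds source {v.shape}")
        if tgt <= 0:
            raise ValueError("crop target must be positive")
    starts = [(src - tgt) // 2 for src, tgt in zip(v.shape, target_shape)]
    sl = tuple(slice(s, s + t) for s, t in zip(starts, target_shape))
    return v.with_data(v.data[sl])


def downsample(v: Volume, factor: int) -> Volume:
    """Downsample by an integer factor using local-mean aggregation.

    Each axis shrinks to ``ceil(size / factor)``; a ragged trailing block is
    averaged over the voxels it actually contains.  Voxel size is multiplied
    by the factor.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    if factor == 1:
        return v.with_data(v.data.copy())
    data = v.data
    out_shape = tuple(-(-s // factor) for s in data.shape)
    out = np.zeros(out_shape)
    counts = np.zeros(out_shape)
    for i in range(factor):
        for j in range(factor):
            for k in range(factor):
                block = data[i::factor, j::factor, k::factor]
                out[: block.shape[0], : block.shape[1], : block.shape[2]] += block
                counts[: block.shape[0], : block.shape[1], : block.shape[2]] += 1
    out /= counts
    return v.with_data(
        out, voxel_size=tuple(s * factor for s in v.voxel_size)
    )


def normalize_signed(v: Volume) -> Volume:
    """Min-max normalize to [0, 1], then rescale affinely to [-1, 1].

    Raises on a constant volume (zero dynamic range).
    """
    lo, hi = float(v.data.min()), float(v.data.max())
    if hi == lo:
        raise ValueError("cannot normalize a constant volume (zero dynamic range)")
    unit = (v.data - lo) / (hi - lo)
    return v.with_data(unit * 2.0 - 1.0, intensity_range="signed")


def to_unit(v: Volume) -> Volume:
    """Affine map of a signed [-1, 1] volume onto [0, 1] (evaluation range)."""
    if v.intensity_range != "signed":
        raise ValueError(f"to_unit expects a 'signed' volume, got {v.intensity_range!r}")
    return v.with_data((v.data + 1.0) / 2.0, intensity_range="unit")


def preprocess(
    v: Volume,
    crop_shape: tuple[int, int, int] | None = None,
    downsample_factor: int = 1,
    normalize: bool = True,
) -> Volume:
    """Standard chain: central crop, mean downsample, signed normalization."""
    out = v
    if crop_shape is not None:
        out = central_crop(out, crop_shape)
    out = downsample(out, downsample_factor)
    if normalize:
        out = normalize_signed(out)
    return out


def save_volume(v: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a diagonal affine from the voxel size."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(v.voxel_size) + [1.0])
    img = nib.Nifti1Image(v.data.astype(np.float32), affine)
    nib.save(img, str(path))
    return path


def load_volume(
    path: str | Path,
    intensity_range: str = "raw",
    session: str = "",
    subject_id: str = "",
) -> Volume:
    """Read a NIfTI-1 volume; voxel size is taken from the affine diagonal."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    return Volume(
        data=data,
        voxel_size=tuple(float(z) for z in zooms),
        intensity_range=intensity_range,
        session=session,
        subject_id=subject_id,
    )
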