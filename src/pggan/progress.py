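"""Group-level spatiotemporal priors ("progress maps").

A *residual map* for an interval is the voxel-wise mean of (follow-up minus
baseline) over the training-split subjects only — test and validation
subjects never contribute, so the prior generalizes to unseen individuals.
An *edge map* is the 3D Sobel gradient magnitude of a residual map,
emphasizing the boundaries of change; it is min-max scaled to [0, 1] before
entering the network, while residual maps keep their native signed units
(the sign encodes atrophy direction).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cohort import SubjectRecord
from .volume import Volume, load_volume, save_volume

__all__ = ["ProgressMap", "build_residual_map", "build_edge_map", "map_bank",
           "save_map_bank", "load_map_bank"]


@dataclasses.dataclass
class ProgressMap:
    """A group-level 3D prior for one inter-scan interval.

    ``kind`` is ``"residual"`` (signed mean intensity change) or ``"edge"``
    (nonnegative Sobel gradient magnitude of the residual, scaled to [0, 1]).
    ``provenance`` records the training subjects averaged; it must never
    intersect validation/test subjects.
    """

    data: np.ndarray
    interval: str
    kind: str
    n_subjects: int
    provenance: list[str]
    scaling: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("progress map must be 3D")
        if self.kind not in ("residual", "edge"):
            raise ValueError(f"unknown progress map kind {self.kind!r}")
        if self.kind == "edge" and self.data.min() < 0:
            raise ValueError("edge map must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def _training_residuals(cohort: list[SubjectRecord], interval: str):
    pairs = []
    for subj in cohort:
        if subj.split != "train":
            continue
        if interval not in subj.followups:
            continue
        pairs.append((subj.subject_id, subj.followups[interval].data - subj.baseline.data))
    return pairs


def build_residual_map(cohort: list[SubjectRecord], interval: str) -> ProgressMap:
    """Average (follow-up − baseline) over training subjects at ``interval``.

    Only ``split == "train"`` subjects enter the average, by construction.
    """
    pairs = _training_residuals(cohort, interval)
    if not pairs:
        raise ValueError(
            f"no training subject has a follow-up at interval {interval!r}"
        )
    shapes = {r.shape for _, r in pairs}
    if len(shapes) != 1:
        raise ValueError(f"residuals are not on a common grid: {shapes}")
    stack = np.stack([r for _, r in pairs])
    return ProgressMap(
        data=stack.mean(axis=0),
        interval=interval,
        kind="residual",
        n_subjects=len(pairs),
        provenance=[sid for sid, _ in pairs],
        scaling="native",
    )


def sobel_magnitude(data: np.ndarray) -> np.ndarray:
    """3D Sobel gradient magnitude with replicate-edge boundary handling.

    Per axis: derivative stencil [-1, 0, +1] along the gradient axis with
    [1, 2, 1] smoothing along both orthogonal axes; Euclidean magnitude over
    the three axis responses.
    """
    grads = [ndimage.sobel(data, axis=ax, mode="nearest") for ax in range(3)]
    return np.sqrt(sum(g * g for g in grads))


def build_edge_map(residual: ProgressMap) -> ProgressMap:
    """Sobel gradient magnitude of a residual map, min-max scaled to [0, 1]."""
    if residual.kind != "residual":
        raise ValueError("edge maps are built from residual maps only")
    mag = sobel_magnitude(residual.data)
    peak = mag.max()
    scaling = "native"
    if peak > 0:
        mag = mag / peak
        scaling = "minmax_unit"
    return ProgressMap(
        data=mag,
        interval=residual.interval,
        kind="edge",
        n_subjects=residual.n_subjects,
        provenance=list(residual.provenance),
        scaling=scaling,
    )


def map_bank(
    cohort: list[SubjectRecord],
    intervals: list[str],
    kinds: list[str] = ("residual", "edge"),
) -> dict[tuple[str, str], ProgressMap]:
    """Build one progress map per (interval, kind) pair from the train split."""
    bank: dict[tuple[str, str], ProgressMap] = {}
    for interval in intervals:
        residual = build_residual_map(cohort, interval)
        if "residual" in kinds:
            bank[(interval, "residual")] = residual
        if "edge" in kinds:
            bank[(interval, "edge")] = build_edge_map(residual)
    for kind in kinds:
        if kind not in ("residual", "edge"):
            raise ValueError(f"unknown map kind {kind!r}")
    return bank


def assert_no_leakage(
    bank: dict[tuple[str, str], ProgressMap], cohort: list[SubjectRecord]
) -> None:
    """Fail loudly if any progress map was built from a held-out subject."""
    held_out = {s.subject_id for s in cohort if s.split in ("validation", "test")}
    for key, pmap in bank.items():
        overlap = held_out & set(pmap.provenance)
        if overlap:
            raise RuntimeError(
                f"progress map {key} was built from held-out subjects {sorted(overlap)}"
            )


def save_map_bank(bank: dict[tuple[str, str], ProgressMap], out_dir: str | Path) -> Path:
    """Serialize a bank as NIfTI volumes with JSON provenance sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (interval, kind), pmap in bank.items():
        stem = f"progress_{interval}_{kind}"
        save_volume(Volume(data=pmap.data), out_dir / f"{stem}.nii.gz")
        sidecar = {
            "interval": pmap.interval,
            "kind": pmap.kind,
            "n_subjects": pmap.n_subjects,
            "provenance": pmap.provenance,
            "scaling": pmap.scaling,
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def load_map_bank(in_dir: str | Path) -> dict[tuple[str, str], ProgressMap]:
    in_dir = Path(in_dir)
    bank = {}
    for sidecar in sorted(in_dir.glob("progress_*.json")):
        meta = json.loads(sidecar.read_text())
        vol = load_volume(sidecar.with_suffix("").with_suffix(".nii.gz"))
        bank[(meta["interval"], meta["kind"])] = ProgressMap(
            data=vol.data,
            interval=meta["interval"],
            kind=meta["kind"],
            n_subjects=meta["n_subjects"],
            provenance=meta["provenance"],
            scaling=meta["scaling"],
        )
    return bank
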