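"""Synthetic longitudinal-atrophy cohorts and cohort bookkeeping.

The generator emulates the structure of a longitudinal ageing/dementia MRI
study: every subject has a co-registered baseline scan and one follow-up per
inter-scan interval, with a *group-level* structural change (ventricle
enlargement plus cortical-shell intensity decrease) whose magnitude grows
with the interval length, per-subject heterogeneity in the change rate, and
additive acquisition noise.

The phantom is a pair of concentric smooth ellipsoids: a bright "tissue"
shell surrounding a darker "ventricle" cavity on a zero background.  Because
the image is an analytic function of the ventricle scale and shell
amplitude, the exact group change field for any interval is available in
closed form — which makes progress-map construction testable against an
oracle.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import Volume, load_volume, save_volume

__all__ = [
    "PhantomParams",
    "SubjectRecord",
    "generate_cohort",
    "group_change_field",
    "split_cohort",
    "write_cohort",
    "read_cohort",
]

SPLITS = ("train", "validation", "test")

# Canonical phantom geometry/appearance, in units of the grid half-extent.
_TISSUE_RADII = (0.80, 0.85, 0.78)
_VENTRICLE_RADII = (0.28, 0.33, 0.26)
_EDGE_WIDTH = 0.08
_TISSUE_AMPLITUDE = 0.80
_VENTRICLE_AMPLITUDE = 0.10


@dataclasses.dataclass(frozen=True)
class PhantomParams:
    """Configuration of a synthetic longitudinal cohort.

    Parameters
    ----------
    grid_shape
        Voxel grid, every axis divisible by 16 (four stride-2 stages).
    n_subjects
        Cohort size.
    intervals
        Mapping from interval label (e.g. ``"1y"``) to interval length in
        years.
    ventricle_growth_rate
        Fractional ventricle radius increase per year (>= 0).
    cortical_thinning_rate
        Tissue-shell intensity decrease per year, in intensity units (>= 0).
    subject_heterogeneity_sd
        Log-scale s.d. of the per-subject multiplicative factor applied to
        both rates (log-normal, median 1).
    noise_sd
        Additive Gaussian noise s.d. applied to every scan before clipping.
    seed
        Seed for all randomness; identical params + seed give a bit-identical
        cohort.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_subjects: int = 40
    intervals: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"1y": 1.0, "4y": 4.0}
    )
    ventricle_growth_rate: float = 0.05
    cortical_thinning_rate: float = 0.02
    subject_heterogeneity_sd: float = 0.2
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if any(int(s) % 16 != 0 for s in self.grid_shape):
            raise ValueError(
                f"grid_shape {self.grid_shape} must be divisible by 16 on every axis"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not self.intervals:
            raise ValueError("at least one follow-up interval is required")
        for label, years in self.intervals.items():
            if years <= 0:
                raise ValueError(f"interval {label!r} must have positive length")
        if self.ventricle_growth_rate < 0 or self.cortical_thinning_rate < 0:
            raise ValueError("change rates must be nonnegative")
        if self.subject_heterogeneity_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


@dataclasses.dataclass
class SubjectRecord:
    """One subject's longitudinal scans plus attributes and split label."""

    subject_id: str
    baseline: Volume
    followups: dict[str, Volume]
    age_at_baseline: float
    sex: int  # 0 / 1
    split: str = "train"

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")
        shapes = {self.baseline.shape} | {v.shape for v in self.followups.values()}
        if len(shapes) != 1:
            raise ValueError(f"all volumes of a subject must share one grid: {shapes}")


def _ellipsoid_rho(shape: tuple[int, int, int], radii_frac, scale: float = 1.0):
    """Normalized elliptical radius field (1 on the ellipsoid surface)."""
    axes = [np.arange(s, dtype=np.float64) - (s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    rho2 = np.zeros(shape)
    for g, s, rf in zip(grids, shape, radii_frac):
        radius = rf * scale * (s / 2.0)
        rho2 += (g / radius) ** 2
    return np.sqrt(rho2)


def _soft_inside(rho: np.ndarray) -> np.ndarray:
    """Smooth indicator ~1 inside the unit ellipsoid, ~0 outside."""
    return 1.0 / (1.0 + np.exp((rho - 1.0) / _EDGE_WIDTH))


def phantom_image(
    shape: tuple[int, int, int],
    ventricle_scale: float = 1.0,
    tissue_amplitude: float = _TISSUE_AMPLITUDE,
) -> np.ndarray:
    """Noise-free phantom: bright tissue shell around a dark ventricle cavity."""
    inside_t = _soft_inside(_ellipsoid_rho(shape, _TISSUE_RADII))
    inside_v = _soft_inside(_ellipsoid_rho(shape, _VENTRICLE_RADII, ventricle_scale))
    tissue_amplitude = max(tissue_amplitude, 0.0)
    return tissue_amplitude * inside_t * (1.0 - inside_v) + _VENTRICLE_AMPLITUDE * inside_t * inside_v


def _changed_image(params: PhantomParams, years: float, factor: float) -> np.ndarray:
    scale = 1.0 + params.ventricle_growth_rate * years * factor
    amp = _TISSUE_AMPLITUDE - params.cortical_thinning_rate * years * factor
    return phantom_image(params.grid_shape, ventricle_scale=scale, tissue_amplitude=amp)


def group_change_field(params: PhantomParams, interval: str) -> np.ndarray:
    """Closed-form group-level change field (follow-up minus baseline).

    This is the deterministic change applied at heterogeneity factor 1,
    before noise and clipping — the oracle the empirical mean residual over
    subjects converges to.
    """
    years = params.intervals[interval]
    return _changed_image(params, years, 1.0) - phantom_image(params.grid_shape)


def generate_cohort(
    params: PhantomParams,
) -> tuple[list[SubjectRecord], dict[str, np.ndarray]]:
    """Generate a seeded synthetic cohort.

    Returns the subject list and the analytic group change field per
    interval (for oracle tests; the fields are *not* derived from the
    sampled subjects).
    """
    rng = np.random.default_rng(params.seed)
    baseline_clean = phantom_image(params.grid_shape)
    subjects: list[SubjectRecord] = []
    for i in range(params.n_subjects):
        sid = f"sub-{i:04d}"
        if params.subject_heterogeneity_sd > 0:
            factor = float(rng.lognormal(0.0, params.subject_heterogeneity_sd))
        else:
            factor = 1.0
        age = float(np.clip(rng.normal(71.3, 7.2), 55.0, 90.0))
        sex = int(rng.integers(0, 2))

        def _finish(clean: np.ndarray, session: str) -> Volume:
            data = clean
            if params.noise_sd > 0:
                data = data + rng.normal(0.0, params.noise_sd, size=clean.shape)
            data = np.clip(data, 0.0, 1.0)
            return Volume(data=data, intensity_range="unit", session=session, subject_id=sid)

        baseline = _finish(baseline_clean, "bl")
        followups = {
            label: _finish(_changed_image(params, years, factor), label)
            for label, years in params.intervals.items()
        }
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                baseline=baseline,
                followups=followups,
                age_at_baseline=age,
                sex=sex,
            )
        )
    fields = {label: group_change_field(params, label) for label in params.intervals}
    return subjects, fields


def split_cohort(
    cohort: list[SubjectRecord], ratios: tuple[int, int, int], seed: int
) -> list[SubjectRecord]:
    """Randomly assign train/validation/test labels in the given proportions.

    Counts follow the ratio proportions (largest-remainder rounding), so a
    cohort whose size equals the ratio sum — e.g. 210 subjects at 170:20:20 —
    gets exactly those counts.  Assignment is a seeded permutation; the
    subject records are relabelled in place and the cohort is returned.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    ratios = tuple(int(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be three nonnegative integers")
    if ratios[0] == 0:
        raise ValueError("train ratio must be positive (progress maps need training subjects)")
    total = sum(ratios)
    n = len(cohort)
    exact = [n * r / total for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    remainders = [e - c for e, c in zip(exact, counts)]
    for idx in sorted(range(3), key=lambda i: (-remainders[i], i)):
        if sum(counts) == n:
            break
        counts[idx] += 1
    while sum(counts) < n:  # residual ties: give to train
        counts[0] += 1
    perm = np.random.default_rng(seed).permutation(n)
    labels = np.empty(n, dtype=object)
    start = 0
    for label, c in zip(SPLITS, counts):
        labels[perm[start : start + c]] = label
        start += c
    for subj, label in zip(cohort, labels):
        subj.split = str(label)
    return cohort


def write_cohort(
    cohort: list[SubjectRecord],
    out_dir: str | Path,
    intervals: dict[str, float],
) -> Path:
    """Write one NIfTI per subject-session plus a CSV manifest.

    The manifest schema (subject_id, session, interval_years, age, sex,
    split, path) is also the ingestion contract for real, pre-registered
    data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort:
        sessions = {"bl": (0.0, subj.baseline)}
        for label, vol in subj.followups.items():
            sessions[label] = (float(intervals[label]), vol)
        for session, (years, vol) in sessions.items():
            rel = f"{subj.subject_id}_{session}.nii.gz"
            save_volume(vol, out_dir / rel)
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "session": session,
                    "interval_years": years,
                    "age": subj.age_at_baseline,
                    "sex": subj.sex,
                    "split": subj.split,
                    "path": rel,
                }
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> tuple[list[SubjectRecord], dict[str, float]]:
    """Read a cohort written by :func:`write_cohort` (or real data matching it)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    subjects = []
    intervals: dict[str, float] = {}
    for sid, group in df.groupby("subject_id", sort=True):
        baseline = None
        followups = {}
        age = float(group["age"].iloc[0])
        sex = int(group["sex"].iloc[0])
        split = str(group["split"].iloc[0])
        for _, row in group.iterrows():
            vol = load_volume(
                base / row["path"],
                intensity_range="unit",
                session=row["session"],
                subject_id=str(sid),
            )
            if row["session"] == "bl":
                baseline = vol
            else:
                followups[row["session"]] = vol
                intervals[row["session"]] = float(row["interval_years"])
        if baseline is None:
            raise ValueError(f"subject {sid} has no baseline session in manifest")
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                baseline=baseline,
                followups=followups,
                age_at_baseline=age,
                sex=sex,
                split=split,
            )
        )
    return subjects, intervals
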