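"""Image-quality metrics, error maps, aggregation and paired significance.

PSNR, NRMSE and SSIM follow the standard definitions

    PSNR  = 10 log10( A * MAX^2 / ||truth - pred||_2^2 )   [dB]
    NRMSE = ||truth - pred||_2 / ||denominator||_2
    SSIM  = mean over sliding windows of
            (2 mu_x mu_y + C1)(2 cov_xy + C2) /
            ((mu_x^2 + mu_y^2 + C1)(var_x + var_y + C2))

computed on the [0, 1] intensity representation with MAX = 1.  PSNR is
invariant to the consistent affine choice of range; the SSIM stabilizers
C1 = (0.01 MAX)^2, C2 = (0.03 MAX)^2 depend on it, so the convention is
fixed here.  The SSIM window is a 7^3 uniform (unweighted) box with sample
covariance normalization, matching the common volumetric default of
reference implementations.

The NRMSE denominator defaults to the ground-truth norm (the reference-API
convention); ``denominator="prediction"`` normalizes by the predicted
image's norm instead.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .cohort import SubjectRecord
from .progress import ProgressMap, assert_no_leakage
from .training import Checkpoint, task_intervals
from .volume import Volume, to_unit

__all__ = [
    "psnr",
    "nrmse",
    "ssim",
    "error_map",
    "slice_view",
    "paired_compare",
    "evaluate_task",
    "MetricsReport",
]

logger = logging.getLogger("pggan")

SSIM_WINDOW = 7
K1, K2 = 0.01, 0.03


def _data(v) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)


def psnr(pred, truth, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical volumes."""
    p, t = _data(pred), _data(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    err = np.sum((t - p) ** 2)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(p.size * max_value**2 / err))


def nrmse(pred, truth, denominator: str = "truth") -> float:
    """Euclidean-normalized RMSE: ||truth - pred|| / ||reference||."""
    p, t = _data(pred), _data(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if denominator == "truth":
        ref = t
    elif denominator == "prediction":
        ref = p
    else:
        raise ValueError("denominator must be 'truth' or 'prediction'")
    denom = np.sqrt(np.sum(ref**2))
    if denom == 0:
        raise ValueError("zero-norm NRMSE denominator")
    return float(np.sqrt(np.sum((t - p) ** 2)) / denom)


def ssim(pred, truth, data_range: float = 1.0, window: int = SSIM_WINDOW) -> float:
    """Mean structural similarity over sliding uniform 3D windows."""
    p, t = _data(pred), _data(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if any(window > s for s in p.shape):
        raise ValueError(f"window {window} exceeds volume shape {p.shape}")
    n_win = window**p.ndim
    cov_norm = n_win / (n_win - 1)  # sample covariance

    def f(a):
        return ndimage.uniform_filter(a, size=window)

    ux, uy = f(p), f(t)
    uxx, uyy, uxy = f(p * p), f(t * t), f(p * t)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    c1 = (K1 * data_range) ** 2
    c2 = (K2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    pad = (window - 1) // 2
    core = s[tuple(slice(pad, dim - pad) for dim in s.shape)]
    return float(core.mean())


def error_map(pred: Volume, truth: Volume) -> Volume:
    """Signed voxel-wise difference, prediction minus ground truth."""
    p, t = _data(pred), _data(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    base = pred if isinstance(pred, Volume) else Volume(data=p)
    return base.with_data(p - t, intensity_range="raw", session="error")


_VIEWS = {"sagittal": 0, "coronal": 1, "axial": 2}


def slice_view(data: np.ndarray, view: str, index: int) -> np.ndarray:
    """Extract one 2D slice along the sagittal/coronal/axial axis."""
    if view not in _VIEWS:
        raise ValueError(f"view must be one of {sorted(_VIEWS)}")
    return np.take(np.asarray(data), index, axis=_VIEWS[view])


def save_error_slices(err: Volume, out_path, indices=None) -> None:
    """Render signed error slices (blue over-, red under-prediction) to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if indices is None:
        indices = {v: err.shape[ax] // 2 for v, ax in _VIEWS.items()}
    lim = max(float(np.abs(err.data).max()), 1e-12)
    fig, axes = plt.subplots(1, len(indices), figsize=(4 * len(indices), 4))
    axes = np.atleast_1d(axes)
    for ax, (view, idx) in zip(axes, indices.items()):
        ax.imshow(slice_view(err.data, view, idx).T, cmap="bwr_r",
                  vmin=-lim, vmax=lim, origin="lower")
        ax.set_title(f"{view} slice {idx}")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


METRIC_COLUMNS = ("nrmse", "ssim", "psnr_db")


def paired_compare(model_a_rows: pd.DataFrame, model_b_rows: pd.DataFrame,
                   alpha: float = 0.05) -> dict[str, dict]:
    """Two-sided paired t-test per metric over matched subject rows.

    Rows are aligned on (subject_id, interval); mismatching subject sets are
    an error.  Degenerate difference vectors are flagged: all-zero
    differences give p = 1 ('identical'); a nonzero constant difference has
    zero variance ('exact_difference', t undefined).
    """
    keys = ["subject_id", "interval"]
    a = model_a_rows.sort_values(keys).reset_index(drop=True)
    b = model_b_rows.sort_values(keys).reset_index(drop=True)
    if len(a) != len(b) or not (a[keys].values == b[keys].values).all():
        raise ValueError("paired comparison requires identical subject/interval sets")
    if len(a) < 2:
        raise ValueError("paired t-test needs at least 2 matched rows")
    out = {}
    for metric in METRIC_COLUMNS:
        diff = a[metric].to_numpy() - b[metric].to_numpy()
        if np.allclose(diff, 0.0):
            out[metric] = {"t": 0.0, "p": 1.0, "significant": False, "flag": "identical"}
        elif np.isclose(diff.std(ddof=1), 0.0):
            out[metric] = {
                "t": float("nan"),
                "p": float("nan"),
                "significant": True,
                "flag": "exact_difference",
            }
        else:
            t, p = stats.ttest_rel(a[metric], b[metric])
            out[metric] = {
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
                "flag": "",
            }
    return out


@dataclasses.dataclass
class MetricsReport:
    """Per-subject and aggregate NRMSE/SSIM/PSNR for one evaluated model."""

    per_subject: pd.DataFrame
    aggregate: pd.DataFrame
    comparisons: list[dict] = dataclasses.field(default_factory=list)
    constants: dict = dataclasses.field(
        default_factory=lambda: {
            "max_value": 1.0,
            "C1": (K1 * 1.0) ** 2,
            "C2": (K2 * 1.0) ** 2,
            "ssim_window": SSIM_WINDOW,
        }
    )

    def save(self, out_dir) -> None:
        from pathlib import Path
        import json

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_subject.to_csv(out_dir / "per_subject.csv", index=False)
        self.aggregate.to_csv(out_dir / "aggregate.csv", index=False)
        payload = {"constants": self.constants, "comparisons": self.comparisons}
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2, default=float))


def _aggregate(per_subject: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for metric in METRIC_COLUMNS:
        values = per_subject[metric].replace([np.inf, -np.inf], np.nan)
        dropped = int(values.isna().sum())
        if dropped:
            logger.warning("%d non-finite %s values excluded from aggregate", dropped, metric)
        rows.append(
            {
                "metric": metric,
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if values.notna().sum() > 1 else 0.0,
                "n": int(values.notna().sum()),
            }
        )
    return pd.DataFrame(rows)


def predictions_for_task(
    checkpoint: Checkpoint,
    cohort: list[SubjectRecord],
    maps: dict[tuple[str, str], ProgressMap],
    task: str,
    split: str = "test",
):
    """Yield (subject, interval, predicted Volume, truth Volume) over a split."""
    from .model import predict_volume

    labels = task_intervals(task, checkpoint.intervals)
    gen = checkpoint.build_generator()
    spec = checkpoint.spec
    map_kind = checkpoint.train_config.map_kind
    if spec.needs_map:
        assert_no_leakage(
            {k: v for k, v in maps.items() if k in [(lb, map_kind) for lb in labels]},
            cohort,
        )
    for subj in cohort:
        if subj.split != split:
            continue
        for label in labels:
            if label not in subj.followups:
                logger.warning(
                    "subject %s has no %s follow-up; skipped", subj.subject_id, label
                )
                continue
            pmap = maps[(label, map_kind)] if spec.needs_map else None
            attrs = None
            if spec.needs_attrs:
                attrs = checkpoint.scaled_attrs(
                    subj.age_at_baseline + checkpoint.intervals[label], subj.sex
                )
            pred = predict_volume(gen, subj.baseline, pmap, attrs)
            yield subj, label, pred, subj.followups[label]


def evaluate_task(
    checkpoint: Checkpoint,
    cohort: list[SubjectRecord],
    maps: dict[tuple[str, str], ProgressMap],
    task: str,
    split: str = "test",
    nrmse_denominator: str = "truth",
    out_dir=None,
) -> MetricsReport:
    """Per-subject metrics over the evaluation split for each task interval.

    Predictions and ground truth are mapped from the signed training range
    to [0, 1] before metric computation (MAX = 1).  The multi-term task
    pools rows from both intervals.
    """
    rows = []
    for subj, label, pred, truth in predictions_for_task(
        checkpoint, cohort, maps, task, split
    ):
        pred_u, truth_u = to_unit(pred), to_unit(truth)
        rows.append(
            {
                "subject_id": subj.subject_id,
                "interval": label,
                "nrmse": nrmse(pred_u, truth_u, denominator=nrmse_denominator),
                "ssim": ssim(pred_u, truth_u),
                "psnr_db": psnr(pred_u, truth_u, max_value=1.0),
            }
        )
    if not rows:
        raise ValueError(f"no evaluable subjects in split {split!r}")
    per_subject = pd.DataFrame(rows)
    report = MetricsReport(per_subject=per_subject, aggregate=_aggregate(per_subject))
    if out_dir is not None:
        report.save(out_dir)
    return report
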