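"""Config-driven orchestration of the three prediction-task families.

A plan names tasks (near-term, long-term, multi-term prediction), model
variants (unconditioned GAN, attribute-conditioned mi-GAN / FiLM-GAN,
progress-map-guided GANs with image-level concatenation or feature-level
fusion of residual or edge maps) and seeds.  For every (task, variant,
seed) cell the pipeline generates (or loads) the cohort, splits it, builds
progress maps from the training split only, trains, evaluates on the test
split, and files all artifacts under a run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import PhantomParams, generate_cohort, read_cohort, split_cohort
from .evaluation import evaluate_task, paired_compare
from .model import GeneratorSpec
from .progress import assert_no_leakage, map_bank, save_map_bank
from .training import LossConfig, TrainConfig, prepare_cohort, task_intervals, train

__all__ = ["ExperimentPlan", "VARIANTS", "run_experiment", "run_cell"]

logger = logging.getLogger("pggan")

#: variant name -> (fusion_mode, map_kind or None)
VARIANTS: dict[str, tuple[str, str | None]] = {
    "gan_baseline": ("none", None),
    "mi_gan": ("attr_concat", None),
    "film_gan": ("attr_film", None),
    "pg_image_concat_residual": ("image_concat", "residual"),
    "pg_ffm_residual": ("ffm", "residual"),
    "pg_image_concat_edge": ("image_concat", "edge"),
    "pg_ffm_edge": ("ffm", "edge"),
    "pg_ffm_parallel_residual": ("ffm_parallel", "residual"),
    "pg_ffm_cascade_residual": ("ffm_cascade", "residual"),
    "pg_mffm_residual": ("mffm", "residual"),
}

TABLE_TASKS = ("near_term", "long_term", "multi_term")


@dataclasses.dataclass
class ExperimentPlan:
    """What to run and under which desk-scale conditions."""

    tasks: tuple[str, ...] = ("near_term",)
    variants: tuple[str, ...] = ("gan_baseline", "pg_ffm_residual")
    seeds: tuple[int, ...] = (0, 1, 2)
    phantom: PhantomParams = dataclasses.field(default_factory=PhantomParams)
    manifest: str | None = None
    split_ratios: tuple[int, int, int] = (170, 20, 20)
    base_channels: int = 8
    batch_size: int = 2
    max_epochs: int = 10
    patience: int = 10
    alpha: float = 60.0

    def __post_init__(self) -> None:
        if not self.tasks or not self.variants or not self.seeds:
            raise ValueError("plan needs at least one task, variant and seed")
        for t in self.tasks:
            if t not in TABLE_TASKS:
                raise ValueError(f"unknown task {t!r}")
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant {v!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentPlan":
        raw = yaml.safe_load(Path(path).read_text())
        phantom = raw.pop("phantom", None)
        plan = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if phantom is not None:
            if "grid_shape" in phantom:
                phantom["grid_shape"] = tuple(phantom["grid_shape"])
            plan.phantom = PhantomParams(**phantom)
        return plan

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["phantom"] = dataclasses.asdict(self.phantom)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def _cohort_for_seed(plan: ExperimentPlan, seed: int):
    if plan.manifest is not None:
        cohort, intervals = read_cohort(plan.manifest)
    else:
        params = dataclasses.replace(plan.phantom, seed=seed)
        cohort, _ = generate_cohort(params)
        intervals = dict(params.intervals)
        split_cohort(cohort, plan.split_ratios, seed=seed + 1)
    return prepare_cohort(cohort), intervals


def run_cell(
    plan: ExperimentPlan,
    task: str,
    variant: str,
    seed: int,
    cohort,
    intervals,
    bank,
    out_dir: Path | None = None,
):
    """Train and evaluate one (task, variant, seed) cell."""
    fusion_mode, map_kind = VARIANTS[variant]
    spec = GeneratorSpec(fusion_mode=fusion_mode, base_channels=plan.base_channels)
    tcfg = TrainConfig(
        batch_size=plan.batch_size,
        max_epochs=plan.max_epochs,
        patience=plan.patience,
        seed=seed,
        task=task,
        fusion_mode=fusion_mode,
        map_kind=map_kind or "residual",
    )
    lcfg = LossConfig(alpha=plan.alpha)
    ckpt_dir = out_dir / "checkpoint" if out_dir is not None else None
    checkpoint = train(cohort, intervals, bank, spec, tcfg, lcfg, out_dir=ckpt_dir)
    assert_no_leakage(bank, cohort)
    report = evaluate_task(
        checkpoint, cohort, bank, task,
        out_dir=out_dir / "report" if out_dir is not None else None,
    )
    return checkpoint, report


def run_experiment(plan: ExperimentPlan, out_dir: str | Path) -> pd.DataFrame:
    """Run every (task, variant, seed) cell of the plan.

    Returns the long-format results table (one row per cell per metric
    aggregate) and writes per-task tables shaped like the comparison tables
    (rows = variants, columns = metric mean ± sd, paired-test flags against
    the non-progress-map variants), plus a JSON with every cell.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan.to_yaml(out_dir / "plan.yaml")

    cell_rows = []
    per_subject_store: dict[tuple[str, str, int], pd.DataFrame] = {}
    for seed in plan.seeds:
        cohort, intervals = _cohort_for_seed(plan, seed)
        needed = sorted(
            {lb for task in plan.tasks for lb in task_intervals(task, intervals)}
        )
        bank = map_bank(cohort, needed, kinds=("residual", "edge"))
        save_map_bank(bank, out_dir / f"seed{seed}" / "maps")
        for task in plan.tasks:
            for variant in plan.variants:
                cell_dir = out_dir / f"seed{seed}" / task / variant
                try:
                    _, report = run_cell(
                        plan, task, variant, seed, cohort, intervals, bank, cell_dir
                    )
                except Exception:  # noqa: BLE001 - other cells proceed
                    logger.error(
                        "cell (%s, %s, seed %d) failed:\n%s",
                        task, variant, seed, traceback.format_exc(),
                    )
                    continue
                per_subject_store[(task, variant, seed)] = report.per_subject
                for _, arow in report.aggregate.iterrows():
                    cell_rows.append(
                        {
                            "task": task,
                            "variant": variant,
                            "seed": seed,
                            "metric": arow["metric"],
                            "mean": arow["mean"],
                            "sd": arow["sd"],
                            "n": arow["n"],
                        }
                    )
    results = pd.DataFrame(cell_rows)
    results.to_csv(out_dir / "cells.csv", index=False)

    tables_dir = out_dir / "tables"
    tables_dir.mkdir(exist_ok=True)
    comparisons = _comparisons(plan, per_subject_store)
    for task in plan.tasks:
        table = _task_table(results[results["task"] == task], plan)
        table.to_csv(tables_dir / f"{task}.csv", index=False)
    (out_dir / "comparisons.json").write_text(
        json.dumps(comparisons, indent=2, default=float)
    )
    return results


def standard_benchmark(
    seeds: tuple[int, ...] = (0, 1, 2),
    out_dir: str | Path = "benchmark_run",
    variants: tuple[str, ...] = ("gan_baseline", "pg_ffm_residual"),
    task: str = "near_term",
    max_epochs: int = 20,
) -> dict[str, dict[str, float]]:
    """The standard desk-scale benchmark: 40 synthetic subjects on a 32^3
    grid with the default change rates and noise, reduced channel widths,
    one run per seed per variant.

    Returns ``{variant: {metric: median over seeds of the test-split mean}}``.
    """
    plan = ExperimentPlan(
        tasks=(task,),
        variants=tuple(variants),
        seeds=tuple(int(s) for s in seeds),
        max_epochs=max_epochs,
    )
    results = run_experiment(plan, out_dir)
    out: dict[str, dict[str, float]] = {}
    for variant in variants:
        sub = results[(results["task"] == task) & (results["variant"] == variant)]
        out[variant] = {
            metric: float(sub[sub["metric"] == metric]["mean"].median())
            for metric in ("nrmse", "ssim", "psnr_db")
        }
    return out


def _task_table(task_results: pd.DataFrame, plan: ExperimentPlan) -> pd.DataFrame:
    rows = []
    for variant in plan.variants:
        sub = task_results[task_results["variant"] == variant]
        if sub.empty:
            continue
        row = {"variant": variant}
        for metric in ("nrmse", "ssim", "psnr_db"):
            m = sub[sub["metric"] == metric]
            row[f"{metric}_median_over_seeds"] = float(m["mean"].median())
            row[f"{metric}_mean"] = float(m["mean"].mean())
            row[f"{metric}_sd"] = float(m["sd"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _comparisons(plan, store) -> list[dict]:
    """Paired tests between every progress-map variant and every other one."""
    out = []
    pg = [v for v in plan.variants if v.startswith("pg_")]
    non_pg = [v for v in plan.variants if not v.startswith("pg_")]
    for task in plan.tasks:
        for seed in plan.seeds:
            for a in pg:
                for b in non_pg:
                    ka, kb = (task, a, seed), (task, b, seed)
                    if ka not in store or kb not in store:
                        continue
                    try:
                        res = paired_compare(store[ka], store[kb])
                    except ValueError as exc:
                        res = {"error": str(exc)}
                    out.append(
                        {"task": task, "seed": seed, "model_a": a, "model_b": b,
                         "tests": res}
                    )
    return out
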