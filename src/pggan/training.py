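"""Adversarial + L1 joint optimization of generator and discriminator.

The generator G(baseline, map) is trained against an unconditional
discriminator D with the log-loss

    L_adv(G, D) = E[log D(real)] + E[log(1 - D(G(baseline, map)))]

plus a weighted L1 reconstruction term, L_total = L_adv + alpha * L1 with
alpha = 60 by default.  D ascends L_adv; G descends its term (the literal
log(1 - D) form by default; a non-saturating -log D switch is available
because the literal form can stall when D saturates).  Both networks use
Adam with first-moment decay 0.5 and learning rate 1e-4.

Early stopping monitors the generator total loss on the validation split
and stops after ``patience`` consecutive non-improving epochs; the returned
checkpoint holds the weights of the best validation epoch.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .cohort import SubjectRecord
from .model import Discriminator, Generator, GeneratorSpec
from .nn import Tensor
from .progress import ProgressMap
from .volume import normalize_signed

__all__ = [
    "LossConfig",
    "TrainConfig",
    "adversarial_loss",
    "l1_loss",
    "total_generator_loss",
    "early_stop_epoch",
    "task_intervals",
    "prepare_cohort",
    "train",
    "Checkpoint",
]

TASKS = ("near_term", "long_term", "multi_term")
_EPS = 1e-7


@dataclasses.dataclass(frozen=True)
class LossConfig:
    """alpha weights the L1 term in L_total = L_adv + alpha * L1."""

    alpha: float = 60.0
    non_saturating: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    learning_rate_g: float = 1e-4
    learning_rate_d: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    batch_size: int = 4
    patience: int = 10
    max_epochs: int = 30
    seed: int = 0
    task: str = "near_term"
    fusion_mode: str = "ffm"
    map_kind: str = "residual"

    def __post_init__(self) -> None:
        if self.learning_rate_g <= 0 or self.learning_rate_d <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("batch size, epochs and patience must be positive")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")


def adversarial_loss(d_real: Tensor, d_fake: Tensor) -> Tensor:
    """Mean log D(real) + mean log(1 - D(fake)); probabilities clamped."""
    if d_real.data.size == 0 or d_fake.data.size == 0:
        raise ValueError("adversarial loss needs nonempty probability batches")
    real = d_real.clip(_EPS, 1.0 - _EPS)
    fake = d_fake.clip(_EPS, 1.0 - _EPS)
    return real.log().mean() + (1.0 - fake).log().mean()


def l1_loss(pred: Tensor, truth: Tensor) -> Tensor:
    """Mean absolute voxel difference."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return (truth - pred).abs().mean()


def total_generator_loss(adv_term, l1_term, cfg: LossConfig):
    """L_total = L_adv + alpha * L1 (works on scalars or graph tensors)."""
    return adv_term + cfg.alpha * l1_term


def early_stop_epoch(val_losses: list[float], patience: int) -> int | None:
    """Index (0-based) of the epoch where training stops, else None.

    Training stops at the epoch where the count of consecutive epochs
    without improvement over the best validation loss reaches ``patience``.
    """
    best = np.inf
    counter = 0
    for i, loss in enumerate(val_losses):
        if loss < best:
            best = loss
            counter = 0
        else:
            counter += 1
            if counter >= patience:
                return i
    return None


def task_intervals(task: str, intervals: dict[str, float]) -> list[str]:
    """Interval labels a task trains on: shortest, longest, or all."""
    if not intervals:
        raise ValueError("no intervals available")
    ordered = sorted(intervals, key=lambda k: intervals[k])
    if task == "near_term":
        return [ordered[0]]
    if task == "long_term":
        return [ordered[-1]]
    if task == "multi_term":
        return ordered
    raise ValueError(f"unknown task {task!r}")


def prepare_cohort(cohort: list[SubjectRecord]) -> list[SubjectRecord]:
    """Signed-normalize every volume of every subject (new records)."""
    out = []
    for subj in cohort:
        out.append(
            SubjectRecord(
                subject_id=subj.subject_id,
                baseline=normalize_signed(subj.baseline),
                followups={k: normalize_signed(v) for k, v in subj.followups.items()},
                age_at_baseline=subj.age_at_baseline,
                sex=subj.sex,
                split=subj.split,
            )
        )
    return out


@dataclasses.dataclass
class Checkpoint:
    """Best-validation weights plus everything needed to rebuild the models."""

    spec: GeneratorSpec
    train_config: TrainConfig
    loss_config: LossConfig
    gen_state: dict[str, np.ndarray]
    disc_state: dict[str, np.ndarray]
    history: pd.DataFrame
    best_epoch: int
    intervals: dict[str, float]
    attr_scaling: tuple[float, float]
    input_shape: tuple[int, int, int]
    optimizer_state: dict | None = None
    rng_state: dict | None = None

    def build_generator(self) -> Generator:
        gen = Generator(self.spec, np.random.default_rng(0))
        nn.load_state_dict(gen, self.gen_state)
        gen.eval()
        return gen

    def scaled_attrs(self, target_age: float, sex: int) -> np.ndarray:
        lo, hi = self.attr_scaling
        a = 0.5 if hi == lo else (target_age - lo) / (hi - lo)
        return np.asarray([a, float(sex)], dtype=np.float32)

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "generator.npz", **self.gen_state)
        np.savez(out_dir / "discriminator.npz", **self.disc_state)
        self.history.to_csv(out_dir / "history.csv", index=False)
        meta = {
            "spec": dataclasses.asdict(self.spec),
            "train_config": dataclasses.asdict(self.train_config),
            "loss_config": dataclasses.asdict(self.loss_config),
            "best_epoch": self.best_epoch,
            "intervals": self.intervals,
            "attr_scaling": list(self.attr_scaling),
            "input_shape": list(self.input_shape),
        }
        (out_dir / "checkpoint.json").write_text(json.dumps(meta, indent=2))
        if self.rng_state is not None:
            (out_dir / "rng_state.json").write_text(json.dumps(self.rng_state))
        return out_dir

    @classmethod
    def load(cls, out_dir: str | Path) -> "Checkpoint":
        out_dir = Path(out_dir)
        meta = json.loads((out_dir / "checkpoint.json").read_text())
        with np.load(out_dir / "generator.npz") as z:
            gen_state = {k: z[k] for k in z.files}
        with np.load(out_dir / "discriminator.npz") as z:
            disc_state = {k: z[k] for k in z.files}
        return cls(
            spec=GeneratorSpec(**meta["spec"]),
            train_config=TrainConfig(**meta["train_config"]),
            loss_config=LossConfig(**meta["loss_config"]),
            gen_state=gen_state,
            disc_state=disc_state,
            history=pd.read_csv(out_dir / "history.csv"),
            best_epoch=meta["best_epoch"],
            intervals={k: float(v) for k, v in meta["intervals"].items()},
            attr_scaling=tuple(meta["attr_scaling"]),
            input_shape=tuple(meta["input_shape"]),
        )


def _examples(cohort, split, labels):
    out = []
    for subj in cohort:
        if subj.split != split:
            continue
        for label in labels:
            if label in subj.followups:
                out.append((subj, label))
    return out


def _batch_arrays(examples, bank_key, maps, needs_map, needs_attrs, intervals, scaling):
    xs, ys, ms, ats = [], [], [], []
    for subj, label in examples:
        xs.append(subj.baseline.data[None])
        ys.append(subj.followups[label].data[None])
        if needs_map:
            ms.append(maps[bank_key(label)].data[None])
        if needs_attrs:
            lo, hi = scaling
            age = subj.age_at_baseline + intervals[label]
            a = 0.5 if hi == lo else (age - lo) / (hi - lo)
            ats.append([a, float(subj.sex)])
    x = Tensor(np.asarray(xs, dtype=np.float32))
    y = Tensor(np.asarray(ys, dtype=np.float32))
    m = Tensor(np.asarray(ms, dtype=np.float32)) if needs_map else None
    a = Tensor(np.asarray(ats, dtype=np.float32)) if needs_attrs else None
    return x, y, m, a


def train(
    cohort: list[SubjectRecord],
    intervals: dict[str, float],
    maps: dict[tuple[str, str], ProgressMap],
    spec: GeneratorSpec,
    tcfg: TrainConfig,
    lcfg: LossConfig,
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> Checkpoint:
    """Alternating D/G minibatch training with early stopping.

    ``cohort`` must already be split and signed-normalized; ``maps`` must
    contain a ``(interval, map_kind)`` entry for every interval the task
    requires (each multi-term example is paired with its own interval's
    map).  Fully deterministic under ``tcfg.seed``.
    """
    labels = task_intervals(tcfg.task, intervals)
    needs_map, needs_attrs = spec.needs_map, spec.needs_attrs
    if needs_map:
        for label in labels:
            if (label, tcfg.map_kind) not in maps:
                raise ValueError(
                    f"task {tcfg.task!r} needs the ({label}, {tcfg.map_kind}) progress map"
                )
    train_ex = _examples(cohort, "train", labels)
    val_ex = _examples(cohort, "validation", labels)
    if not train_ex:
        raise ValueError("training split is empty")
    if not val_ex:
        raise ValueError("validation split is empty")

    target_ages = [s.age_at_baseline + intervals[lb] for s, lb in train_ex]
    scaling = (float(min(target_ages)), float(max(target_ages)))

    input_shape = train_ex[0][0].baseline.shape
    rng = np.random.default_rng(tcfg.seed)
    gen = Generator(spec, np.random.default_rng(rng.integers(2**31)))
    disc = Discriminator(
        input_shape,
        np.random.default_rng(rng.integers(2**31)),
        base_channels=max(1, spec.base_channels // 2),
    )
    opt_g = nn.Adam(gen.parameters(), lr=tcfg.learning_rate_g,
                    beta1=tcfg.adam_beta1, beta2=tcfg.adam_beta2)
    opt_d = nn.Adam(disc.parameters(), lr=tcfg.learning_rate_d,
                    beta1=tcfg.adam_beta1, beta2=tcfg.adam_beta2)

    def key(label):
        return (label, tcfg.map_kind)

    history_rows = []
    best_val = np.inf
    best_epoch = -1
    best_gen = nn.state_dict(gen)
    best_disc = nn.state_dict(disc)
    bad_epochs = 0

    epoch_iter = range(tcfg.max_epochs)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        epoch_iter = tqdm(epoch_iter, desc="epochs")

    for epoch in epoch_iter:
        gen.train()
        disc.train()
        order = rng.permutation(len(train_ex))
        d_losses, g_losses = [], []
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            batch = [train_ex[i] for i in idx]
            x, y, m, a = _batch_arrays(
                batch, key, maps, needs_map, needs_attrs, intervals, scaling
            )
            # --- discriminator ascends L_adv
            fake_detached = Tensor(gen(x, m, a).data)
            d_loss = -adversarial_loss(disc(y), disc(fake_detached))
            disc.zero_grad()
            d_loss.backward()
            opt_d.step()
            # --- generator descends its adversarial term + alpha * L1
            fake = gen(x, m, a)
            d_fake = disc(fake).clip(_EPS, 1.0 - _EPS)
            if lcfg.non_saturating:
                adv_g = -(d_fake.log().mean())
            else:
                adv_g = (1.0 - d_fake).log().mean()
            g_loss = total_generator_loss(adv_g, l1_loss(fake, y), lcfg)
            gen.zero_grad()
            disc.zero_grad()
            g_loss.backward()
            opt_g.step()
            d_losses.append(float(d_loss.data))
            g_losses.append(float(g_loss.data))

        val_loss = _validation_loss(gen, disc, val_ex, key, maps, needs_map,
                                    needs_attrs, intervals, scaling, lcfg,
                                    tcfg.batch_size)
        history_rows.append(
            {
                "epoch": epoch,
                "d_loss": float(np.mean(d_losses)),
                "g_loss": float(np.mean(g_losses)),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_gen = nn.state_dict(gen)
            best_disc = nn.state_dict(disc)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= tcfg.patience:
                break

    checkpoint = Checkpoint(
        spec=spec,
        train_config=tcfg,
        loss_config=lcfg,
        gen_state=best_gen,
        disc_state=best_disc,
        history=pd.DataFrame(history_rows),
        best_epoch=best_epoch,
        intervals={k: float(intervals[k]) for k in labels},
        attr_scaling=scaling,
        input_shape=tuple(input_shape),
        optimizer_state={"g": opt_g.state(), "d": opt_d.state()},
        rng_state=rng.bit_generator.state,
    )
    if out_dir is not None:
        checkpoint.save(out_dir)
    return checkpoint


def _validation_loss(gen, disc, val_ex, key, maps, needs_map, needs_attrs,
                     intervals, scaling, lcfg, batch_size) -> float:
    """Generator total loss (adv term + alpha * L1) on the validation split."""
    gen.eval()
    disc.eval()
    losses, weights = [], []
    for start in range(0, len(val_ex), batch_size):
        batch = val_ex[start : start + batch_size]
        x, y, m, a = _batch_arrays(
            batch, key, maps, needs_map, needs_attrs, intervals, scaling
        )
        fake = gen(x, m, a)
        d_fake = disc(fake).clip(_EPS, 1.0 - _EPS)
        if lcfg.non_saturating:
            adv_g = -(d_fake.log().mean())
        else:
            adv_g = (1.0 - d_fake).log().mean()
        loss = total_generator_loss(adv_g, l1_loss(fake, y), lcfg)
        losses.append(float(loss.data))
        weights.append(len(batch))
    return float(np.average(losses, weights=weights))
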