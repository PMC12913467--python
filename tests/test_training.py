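"""Loss arithmetic, early stopping, and training-loop contracts."""

import numpy as np
import pytest

import pggan.training as training_mod
from pggan.cohort import PhantomParams, generate_cohort, split_cohort
from pggan.model import GeneratorSpec
from pggan.nn import Tensor
from pggan.progress import map_bank
from pggan.training import (
    Checkpoint,
    LossConfig,
    TrainConfig,
    adversarial_loss,
    early_stop_epoch,
    l1_loss,
    prepare_cohort,
    task_intervals,
    total_generator_loss,
    train,
)


def t(values):
    return Tensor(np.asarray(values, dtype=np.float64))


class TestLosses:
    def test_adversarial_closed_form_at_half(self):
        loss = adversarial_loss(t([0.5]), t([0.5]))
        assert np.isclose(float(loss.data), -2 * np.log(2))

    def test_adversarial_supremum_at_perfect_discrimination(self):
        loss = adversarial_loss(t([1.0 - 1e-12]), t([1e-12]))
        assert abs(float(loss.data)) < 1e-4

    def test_adversarial_hand_arithmetic(self):
        loss = adversarial_loss(t([0.8, 0.6]), t([0.3, 0.1]))
        expected = np.mean([np.log(0.8), np.log(0.6)]) + np.mean(
            [np.log(0.7), np.log(0.9)]
        )
        assert np.isclose(float(loss.data), expected)

    def test_adversarial_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            adversarial_loss(t([]), t([0.5]))

    def test_l1_cases(self):
        a = t(np.zeros((2, 2)))
        assert float(l1_loss(a, a).data) == 0.0
        assert np.isclose(float(l1_loss(t(np.zeros(4) + 0.1), t(np.zeros(4))).data), 0.1)
        assert np.isclose(float(l1_loss(t([0.0, 1.0]), t([0.5, 0.5])).data), 0.5)

    def test_l1_shape_mismatch(self):
        with pytest.raises(ValueError):
            l1_loss(t(np.zeros(3)), t(np.zeros(4)))

    def test_total_loss_weighting(self):
        cfg = LossConfig(alpha=60.0)
        assert np.isclose(total_generator_loss(0.7, 0.1, cfg), 6.7)
        assert total_generator_loss(0.7, 0.1, LossConfig(alpha=0.0)) == 0.7
        assert total_generator_loss(0.7, 0.0, cfg) == 0.7

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(alpha=-1.0)


class TestEarlyStopping:
    def test_stops_after_exact_patience(self):
        # one improving epoch, then 11 non-improving: stop when the counter
        # reaches 10, i.e. at index 10
        losses = [1.0] + [1.5] * 11
        assert early_stop_epoch(losses, patience=10) == 10

    def test_counter_resets_on_improvement(self):
        losses = [1.0, 1.2, 1.2, 0.9, 1.1, 1.1]
        assert early_stop_epoch(losses, patience=3) is None
        losses = [1.0, 1.2, 1.2, 0.9, 1.1, 1.1, 1.1]
        assert early_stop_epoch(losses, patience=3) == 6

    def test_strict_improvement_required(self):
        assert early_stop_epoch([1.0, 1.0, 1.0], patience=2) == 2


class TestTaskIntervals:
    def test_task_selection(self):
        intervals = {"1y": 1.0, "4y": 4.0}
        assert task_intervals("near_term", intervals) == ["1y"]
        assert task_intervals("long_term", intervals) == ["4y"]
        assert task_intervals("multi_term", intervals) == ["1y", "4y"]


def _tiny_setup(seed=0, n=6, task="near_term", fusion="ffm"):
    params = PhantomParams(grid_shape=(16, 16, 16), n_subjects=n, seed=seed)
    cohort, _ = generate_cohort(params)
    split_cohort(cohort, (n - 2, 1, 1), seed=seed)
    cohort = prepare_cohort(cohort)
    bank = map_bank(cohort, ["1y", "4y"])
    spec = GeneratorSpec(fusion_mode=fusion, base_channels=2)
    tcfg = TrainConfig(batch_size=2, max_epochs=2, seed=seed, task=task)
    return params, cohort, bank, spec, tcfg


class TestTrainLoop:
    def test_smoke_run_emits_checkpoint_and_log(self, tmp_path):
        params, cohort, bank, spec, tcfg = _tiny_setup()
        ckpt = train(cohort, params.intervals, bank, spec, tcfg, LossConfig(),
                     out_dir=tmp_path / "run")
        assert len(ckpt.history) == 2
        assert set(ckpt.history.columns) == {"epoch", "d_loss", "g_loss", "val_loss"}
        assert (tmp_path / "run" / "history.csv").exists()
        assert (tmp_path / "run" / "generator.npz").exists()

    def test_seeded_determinism(self):
        params, cohort, bank, spec, tcfg = _tiny_setup()
        c1 = train(cohort, params.intervals, bank, spec, tcfg, LossConfig())
        c2 = train(cohort, params.intervals, bank, spec, tcfg, LossConfig())
        assert c1.history.equals(c2.history)
        for key in c1.gen_state:
            assert np.array_equal(c1.gen_state[key], c2.gen_state[key])

    def test_patience_stops_training(self, monkeypatch):
        """An injected non-improving validation sequence stops the loop when
        the counter reaches the configured patience."""
        params, cohort, bank, spec, _ = _tiny_setup()
        injected = iter([1.0] + [2.0] * 20)
        monkeypatch.setattr(
            training_mod, "_validation_loss", lambda *a, **k: next(injected)
        )
        tcfg = TrainConfig(batch_size=2, max_epochs=30, patience=10, seed=0,
                           task="near_term")
        ckpt = train(cohort, params.intervals, bank, spec, tcfg, LossConfig())
        assert len(ckpt.history) == 11  # epoch 0 improves, epochs 1..10 do not
        assert ckpt.best_epoch == 0

    def test_best_checkpoint_is_validation_minimum(self, trained_setup):
        _, _, _, ckpt = trained_setup
        assert ckpt.best_epoch == int(ckpt.history["val_loss"].idxmin())

    def test_l1_descends_under_large_alpha(self):
        """One optimization step with a dominant L1 weight reduces the
        reconstruction error on a fixed batch."""
        from pggan import nn
        from pggan.model import Generator

        params, cohort, bank, spec, _ = _tiny_setup()
        gen = Generator(spec, np.random.default_rng(0))
        subj = [s for s in cohort if s.split == "train"][:2]
        x = Tensor(np.stack([s.baseline.data[None] for s in subj]).astype(np.float32))
        y = Tensor(np.stack([s.followups["1y"].data[None] for s in subj]).astype(np.float32))
        m = Tensor(np.repeat(bank[("1y", "residual")].data[None, None], 2, axis=0
                             ).astype(np.float32))
        opt = nn.Adam(gen.parameters(), lr=1e-3, beta1=0.5)
        before = float(l1_loss(gen(x, m), y).data)
        for _ in range(3):
            loss = l1_loss(gen(x, m), y)
            gen.zero_grad()
            loss.backward()
            opt.step()
        after = float(l1_loss(gen(x, m), y).data)
        assert after < before

    def test_missing_map_for_task_rejected(self):
        params, cohort, bank, spec, _ = _tiny_setup()
        bank.pop(("4y", "residual"))
        bank.pop(("4y", "edge"))
        tcfg = TrainConfig(batch_size=2, max_epochs=1, seed=0, task="multi_term")
        with pytest.raises(ValueError):
            train(cohort, params.intervals, bank, spec, tcfg, LossConfig())

    def test_empty_validation_split_rejected(self):
        params, cohort, bank, spec, tcfg = _tiny_setup()
        for s in cohort:
            if s.split == "validation":
                s.split = "train"
        with pytest.raises(ValueError):
            train(cohort, params.intervals, bank, spec, tcfg, LossConfig())


class TestMultiTerm:
    def test_single_weight_set_serves_both_intervals(self, trained_setup):
        from pggan.evaluation import evaluate_task

        params, cohort, bank, ckpt = trained_setup
        assert set(ckpt.intervals) == {"1y", "4y"}
        report = evaluate_task(ckpt, cohort, bank, "multi_term")
        assert set(report.per_subject["interval"]) == {"1y", "4y"}

    def test_checkpoint_round_trip(self, tmp_path, trained_setup):
        _, _, _, ckpt = trained_setup
        ckpt.save(tmp_path / "ck")
        back = Checkpoint.load(tmp_path / "ck")
        assert back.spec == ckpt.spec
        assert back.best_epoch == ckpt.best_epoch
        for key in ckpt.gen_state:
            assert np.array_equal(back.gen_state[key], ckpt.gen_state[key])
        gen = back.build_generator()
        x = Tensor(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))
        m = Tensor(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))
        assert gen(x, m).shape == x.shape
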