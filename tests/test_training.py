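"""Two-stage training protocol: freezing, scheduling, reproducibility, CV."""

import numpy as np
import pytest

import dsanet.training as training
from dsanet.data_io import SliceRecord
from dsanet.network import ModelConfig, build_model
from dsanet.synthetic import PhantomSpec, generate_cohort
from dsanet.training import (
    StageConfig,
    calibrate_batchnorm,
    cross_validate,
    fold_summary,
    records_to_arrays,
    train_two_stage,
)


def _tiny_data(n=16, size=16, seed=0):
    spec = PhantomSpec(image_size=2 * size)
    records = generate_cohort(n // 2, 2, 0.5, spec, seed=seed)
    return records_to_arrays(records[:n], size)


def _tiny_model(size=16, seed=0):
    return build_model(ModelConfig.smoke(size), seed=seed)


def test_stage_defaults_follow_protocol():
    s1, s2 = StageConfig.stage1(), StageConfig.stage2()
    assert s1.epoch_range == (1, 25) and s2.epoch_range == (26, 50)
    assert s1.backbone_frozen and not s2.backbone_frozen
    assert s2.learning_rate / s1.learning_rate == pytest.approx(0.1)
    assert (s1.early_stop_patience, s2.early_stop_patience) == (7, 10)
    assert (s1.lr_reduce_patience, s2.lr_reduce_patience) == (3, 7)
    assert s1.lr_reduce_factor == s2.lr_reduce_factor == 0.5


def test_stage_config_validation():
    with pytest.raises(ValueError, match="learning_rate"):
        StageConfig((1, 2), True, 0.0, 3)
    with pytest.raises(ValueError, match="patiences"):
        StageConfig((1, 2), True, 0.1, 0)
    with pytest.raises(ValueError, match="lr_reduce_factor"):
        StageConfig((1, 2), True, 0.1, 3, lr_reduce_factor=1.0)


def test_stage1_leaves_backbone_bit_identical():
    model = _tiny_model()
    x, y = _tiny_data()
    before = {k: v.copy() for k, v in model.backbone.get_weights().items()}
    head_before = {k: v.copy() for k, v in model.conv_s1.get_weights().items()}
    s1 = StageConfig.stage1(epoch_range=(1, 2))
    s2 = StageConfig.stage2(epoch_range=(3, 2))  # empty stage 2
    train_two_stage(model, (x, y), (x, y), s1, s2, batch_size=8, seed=0)
    after = model.backbone.get_weights()
    assert all(np.array_equal(before[k], after[k]) for k in before)  # frozen
    head_after = model.conv_s1.get_weights()
    assert any(not np.array_equal(head_before[k], head_after[k]) for k in head_before)  # trained


def test_stage2_updates_backbone():
    model = _tiny_model(seed=1)
    x, y = _tiny_data(seed=1)
    before = {k: v.copy() for k, v in model.backbone.get_weights().items()}
    s1 = StageConfig.stage1(epoch_range=(1, 1))
    s2 = StageConfig.stage2(epoch_range=(2, 3))
    train_two_stage(model, (x, y), (x, y), s1, s2, batch_size=8, seed=1)
    after = model.backbone.get_weights()
    conv_keys = [k for k in before if "kernel" in k]
    assert any(not np.array_equal(before[k], after[k]) for k in conv_keys)


def test_plateau_halving_and_early_stop_schedule(monkeypatch):
    # scripted validation metrics: epoch 1 improves, then a permanent plateau
    scripted = iter([0.9] + [0.5] * 30)

    def fake_evaluate(model, x, y, batch_size):
        auc = next(scripted)
        return 0.7, 0.5, auc, None

    monkeypatch.setattr(training, "_evaluate", fake_evaluate)
    model = _tiny_model(seed=2)
    x, y = _tiny_data(n=8, seed=2)
    s1 = StageConfig.stage1()  # patience 7, plateau patience 3, factor 0.5
    s2 = StageConfig.stage2(epoch_range=(26, 25))  # empty
    _, history = train_two_stage(model, (x, y), (x, y), s1, s2, batch_size=8, seed=2)
    rows = [r for r in history.rows if r["stage"] == 1]
    # early stopping fires after exactly 7 non-improving epochs (epochs 2-8)
    assert [r["epoch"] for r in rows] == list(range(1, 9))
    assert history.stopping["stage1"]["reason"] == "early_stop"
    # lr halves after epochs 4 and 7 (3 plateaued epochs each time)
    assert history.lr_trace(stage=1) == pytest.approx([1e-3] * 4 + [5e-4] * 3 + [2.5e-4])


def test_lr_trace_non_increasing_within_stage():
    model = _tiny_model(seed=3)
    x, y = _tiny_data(seed=3)
    s1 = StageConfig.stage1(epoch_range=(1, 4), lr_reduce_patience=1)
    s2 = StageConfig.stage2(epoch_range=(5, 7), lr_reduce_patience=1)
    _, history = train_two_stage(model, (x, y), (x, y), s1, s2, batch_size=8, seed=3)
    for stage in (1, 2):
        trace = history.lr_trace(stage=stage)
        assert all(a >= b for a, b in zip(trace, trace[1:]))
    assert history.stage_boundary == max(r["epoch"] for r in history.rows if r["stage"] == 1)


def test_training_is_reproducible_for_fixed_seed():
    runs = []
    for _ in range(2):
        model = _tiny_model(seed=4)
        x, y = _tiny_data(seed=4)
        calibrate_batchnorm(model, x)
        s1 = StageConfig.stage1(epoch_range=(1, 2))
        s2 = StageConfig.stage2(epoch_range=(3, 4))
        _, history = train_two_stage(model, (x, y), (x, y), s1, s2, batch_size=8, seed=4)
        runs.append(history.to_dataframe())
    assert np.allclose(runs[0]["val_auc"], runs[1]["val_auc"])
    assert np.allclose(runs[0]["train_loss"], runs[1]["train_loss"])


def test_validation_needs_both_classes():
    model = _tiny_model(seed=5)
    x, y = _tiny_data(seed=5)
    with pytest.raises(ValueError, match="both classes"):
        train_two_stage(model, (x, y), (x, np.ones_like(y)), batch_size=8, seed=5)


def test_calibration_touches_only_moving_statistics():
    model = _tiny_model(seed=6)
    x, _ = _tiny_data(seed=6)
    before = model.get_weights()
    calibrate_batchnorm(model, x)
    after = model.get_weights()
    for k in before:
        if "moving" in k:
            continue
        assert np.array_equal(before[k], after[k]), k
    assert any("moving" in k and not np.array_equal(before[k], after[k]) for k in before)


# -- cross-validation ------------------------------------------------------


def test_fold_summary_matches_hand_arithmetic():
    stats = fold_summary([0.9, 0.95, 0.92, 0.94, 0.93])
    assert stats["mean"] == pytest.approx(0.928)
    assert stats["sd"] == pytest.approx(0.019235, abs=1e-6)  # sample sd, ddof=1


def _cheap_records(n=25):
    return [
        SliceRecord(patient_id=f"PAT_{i % 5:04d}", pixels=np.zeros((2, 2)), label=i % 2, metadata={"idx": i})
        for i in range(n)
    ]


def test_cross_validate_partitions_exactly():
    records = _cheap_records(25)
    seen = []

    def stub(train_recs, val_recs, fold_seed):
        seen.append({r.metadata["idx"] for r in val_recs})
        assert {r.metadata["idx"] for r in train_recs}.isdisjoint(seen[-1])
        return {"accuracy": 0.9, "macro_f1": 0.9, "auc": 0.95}

    result = cross_validate(records, k=5, seed=0, train_eval_fn=stub)
    sizes = [len(s) for s in seen]
    assert max(sizes) - min(sizes) <= 1
    assert set().union(*seen) == set(range(25))
    assert sum(sizes) == 25
    assert result["summary"]["accuracy"]["mean"] == pytest.approx(0.9)


def test_cross_validate_grouped_folds_respect_patients():
    records = _cheap_records(30)
    for r in records:  # one label per patient for grouped stratification
        r.label = int(r.patient_id[-1]) % 2

    def stub(train_recs, val_recs, fold_seed):
        assert {r.patient_id for r in train_recs}.isdisjoint({r.patient_id for r in val_recs})
        return {"accuracy": 1.0, "macro_f1": 1.0, "auc": 1.0}

    cross_validate(records, k=2, seed=0, train_eval_fn=stub, group_by_patient=True)


def test_cross_validate_k_validation():
    records = _cheap_records(6)
    with pytest.raises(ValueError, match="k="):
        cross_validate(records, k=5, seed=0, train_eval_fn=lambda *a, **k: {})
    with pytest.raises(ValueError, match="k must be"):
        cross_validate(records, k=1, seed=0, train_eval_fn=lambda *a, **k: {})
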