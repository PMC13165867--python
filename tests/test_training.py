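"""Training loop, fold construction, and experiment runners (desk scale)."""

from __future__ import annotations

import numpy as np
import pytest

import imau_seg as I
from imau_seg.training import (
    ablation_deltas,
    pairwise_differences,
    run_architectural_ablation,
    run_controlled_comparison,
    run_preprocessing_ablation,
)

TINY_TRAIN = I.TrainConfig(batch_size=4, epochs=2, seed=0, max_steps_override=3)


# -- folds ---------------------------------------------------------------

def test_folds_partition_dataset_evenly(small_dataset):
    dataset = I.generate_dataset(100, I.SceneConfig(image_size=(64, 64), seed=4))
    folds = I.make_folds(dataset, k=5, seed=1)
    ids = [i for f in folds.folds for i in f]
    assert sorted(ids) == sorted(s.sample_id for s in dataset)
    assert all(len(f) == 20 for f in folds.folds)


def test_folds_deterministic_and_disjoint(small_dataset):
    a = I.make_folds(small_dataset, k=3, seed=9)
    b = I.make_folds(small_dataset, k=3, seed=9)
    assert a.folds == b.folds
    train, test = a.split(1)
    assert not set(train) & set(test)
    assert sorted(train + test) == sorted(s.sample_id for s in small_dataset)


def test_folds_stratify_by_area_quartile():
    dataset = I.generate_dataset(80, I.SceneConfig(image_size=(64, 64), seed=6))
    folds = I.make_folds(dataset, k=4, seed=0)
    areas = {s.sample_id: s.mask.mean() for s in dataset}
    qs = np.quantile(list(areas.values()), [0.25, 0.5, 0.75])
    label = {i: int(np.searchsorted(qs, a, side="right")) for i, a in areas.items()}
    global_counts = np.bincount([label[i] for i in areas], minlength=4) / len(dataset)
    for fold in folds.folds:
        counts = np.bincount([label[i] for i in fold], minlength=4)
        expected = global_counts * len(fold)
        assert np.abs(counts - expected).max() <= 1.0 + 1e-9


def test_folds_reject_too_small_dataset(small_dataset):
    with pytest.raises(ValueError, match="folds"):
        I.make_folds(small_dataset[:3], k=5)


# -- training loop -------------------------------------------------------

def test_training_improves_train_dice_on_tiny_fixture(small_dataset, tiny_spec):
    model = I.build_model(tiny_spec, seed=0)
    cfg = I.TrainConfig(batch_size=4, epochs=8, seed=0, max_steps_override=30,
                        convergence_patience=1000)
    hist = I.train(model, small_dataset[:8], small_dataset[:8], cfg)
    assert hist.train_dice[-1] > hist.train_dice[0]
    assert hist.n_epochs == len(hist.val_loss)
    assert np.isfinite(hist.train_loss).all()


def test_training_is_reproducible_for_fixed_seeds(small_dataset, tiny_spec):
    def run():
        model = I.build_model(tiny_spec, seed=2)
        return I.train(model, small_dataset[:6], small_dataset[6:8], TINY_TRAIN)

    h1, h2 = run(), run()
    assert h1.train_loss == h2.train_loss
    assert h1.val_loss == h2.val_loss


def test_training_rejects_empty_sets(tiny_spec, small_dataset):
    model = I.build_model(tiny_spec, seed=0)
    with pytest.raises(ValueError, match="non-empty"):
        I.train(model, [], small_dataset[:2], TINY_TRAIN)


def test_train_config_invariants():
    with pytest.raises(ValueError):
        I.TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        I.TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        I.TrainConfig(loss="bce")


# -- cross-validation ----------------------------------------------------

def test_run_cv_contract(small_dataset, tiny_spec):
    summary = I.run_cv(tiny_spec, small_dataset, TINY_TRAIN, k=2)
    assert summary.n_folds == 2
    for r in summary.fold_reports:
        assert 0.0 <= r.dice <= 1.0 and 0.0 <= r.iou <= 1.0
    assert summary.mean["dice"] == pytest.approx(
        np.mean([r.dice for r in summary.fold_reports])
    )


# -- experiment runners --------------------------------------------------

def test_architectural_ablation_table_shape_and_baseline_delta(
    small_dataset, tiny_spec
):
    table = run_architectural_ablation(small_dataset, TINY_TRAIN,
                                       base_spec=tiny_spec, k=2)
    assert len(table) == 4
    assert set(table["variant"]) == set(I.architectures.VARIANTS)
    base_row = table[table["variant"] == "inceptionv3_unet"].iloc[0]
    assert base_row["delta_dice"] == 0.0
    assert "delta_iou" in table.columns


def test_controlled_comparison_provenance_and_pairwise_columns(
    small_dataset, tiny_spec
):
    table = run_controlled_comparison(small_dataset, TINY_TRAIN,
                                      base_spec=tiny_spec, k=2)
    assert table["batch_size"].nunique() == 1
    assert table["epochs"].nunique() == 1
    assert table["learning_rate"].nunique() == 1
    dice = dict(zip(table["variant"], table["dice"]))
    for other in I.architectures.VARIANTS:
        col = f"dice_minus_{other}"
        assert col in table.columns
        for _, row in table.iterrows():
            assert row[col] == pytest.approx(dice[row["variant"]] - dice[other])


def test_preprocessing_ablation_rows_and_toggles(small_dataset):
    cfg = I.TrainConfig(batch_size=4, epochs=1, seed=0, max_steps_override=2)
    # 64x64 inputs keep the four training runs quick; the ASPP variant has
    # no pooling-kernel floor, so it tolerates the tiny bottleneck grid
    from imau_seg.preprocess import PreprocessConfig

    spec = I.ArchitectureSpec(
        variant="aspp_unet", width_multiplier=0.0625, input_size=(64, 64, 3)
    )
    table = run_preprocessing_ablation(
        small_dataset[:8], spec, cfg,
        preprocess_base=PreprocessConfig(target_size=(64, 64)),
    )
    assert list(table["configuration"]) == [
        "No Preprocessing", "CLAHE Only", "CLAHE + Denoising", "Full Preprocessing",
    ]
    toggles = table[["enable_clahe", "enable_denoise", "enable_mask_refine"]]
    assert toggles.drop_duplicates().shape[0] == 4  # rows differ only in toggles
    assert table.loc[0, "delta_dice"] == 0.0


# -- delta arithmetic ----------------------------------------------------

def test_ablation_deltas_and_pairwise_differences():
    scores = {"a": 0.90, "b": 0.92, "c": 0.95}
    deltas = ablation_deltas(scores, "a")
    assert deltas["a"] == 0.0
    assert deltas["c"] == pytest.approx(0.05)
    pw = pairwise_differences(scores)
    assert pw["c_minus_b"] == pytest.approx(0.03)
    assert pw["b_minus_c"] == pytest.approx(-0.03)
    with pytest.raises(KeyError):
        ablation_deltas(scores, "missing")
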