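"""Seeded training loop, stratified cross-validation, and experiment runners.

Training follows the family's shared recipe — Adam on the soft Dice loss —
with per-variant batch/epoch budgets supplied through :class:`TrainConfig`.
``max_steps_override`` and ``ArchitectureSpec.width_multiplier`` together
form the desk-scale mode in which every experiment runner completes on a
single CPU; with ``width_multiplier=1.0`` and no step cap the runners use
the full published budgets.

Stratification uses the only per-sample scalar a binary segmentation task
offers: the foreground-area fraction, discretized into quartiles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import metrics as M
from .architectures import ArchitectureSpec, Model, build_model, VARIANTS
from .nn import Adam, Tensor
from .nn.ops import dice_loss as dice_loss_op
from .preprocess import (
    ABLATION_CONFIGS,
    PreprocessConfig,
    _ablation_configs,
    run_pipeline,
)
from .stats import CVSummary, aggregate_folds
from .synthetic import ImageSample

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "FoldAssignment",
    "make_folds",
    "train",
    "evaluate",
    "mean_report",
    "run_cv",
    "run_architectural_ablation",
    "run_controlled_comparison",
    "run_preprocessing_ablation",
    "ablation_deltas",
    "pairwise_differences",
]

BASELINE_VARIANT = "inceptionv3_unet"


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 50
    learning_rate: float = 1e-3
    loss: str = "dice"
    seed: int = 0
    max_steps_override: int | None = None
    convergence_patience: int = 10
    convergence_min_delta: float = 1e-4
    stop_at_train_dice: float | None = None
    dice_smooth: float = 1.0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss != "dice":
            raise ValueError(f"unsupported loss {self.loss!r}; only 'dice'")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    converged_epoch: int | None = None
    steps: int = 0
    stop_reason: str = "epochs"

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "train_loss": self.train_loss,
                "train_dice": self.train_dice,
                "val_loss": self.val_loss,
                "val_dice": self.val_dice,
            }
        )


@dataclass
class FoldAssignment:
    folds: list[list[str]]

    @property
    def k(self) -> int:
        return len(self.folds)

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """(train ids, test ids) for one held-out fold."""
        test = list(self.folds[fold])
        train = [i for j, f in enumerate(self.folds) if j != fold for i in f]
        assert not set(train) & set(test), "fold leakage"
        return train, test


def _area_quartiles(dataset: list[ImageSample]) -> np.ndarray:
    areas = np.array([s.mask.mean() for s in dataset])
    # quartile labels; ties collapse bins gracefully
    qs = np.quantile(areas, [0.25, 0.5, 0.75])
    return np.searchsorted(qs, areas, side="right")


def make_folds(dataset: list[ImageSample], k: int = 5, seed: int = 0) -> FoldAssignment:
    """k folds stratified by foreground-area quartile, sizes within 1."""
    if len(dataset) < k:
        raise ValueError(f"dataset of {len(dataset)} samples cannot form {k} folds")
    labels = _area_quartiles(dataset)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    ids = [s.sample_id for s in dataset]
    folds = [
        [ids[i] for i in test_idx]
        for _, test_idx in skf.split(np.zeros(len(dataset)), labels)
    ]
    return FoldAssignment(folds)


def _stack(samples: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples]).astype(np.float32)
    y = np.stack([s.mask for s in samples]).astype(np.float32)[..., None]
    return x, y


def _hard_dice(probs: np.ndarray, truth: np.ndarray) -> float:
    """Mean per-sample Dice of thresholded predictions (NHW1 arrays)."""
    pred = probs > M.BINARIZE_THRESHOLD
    t = truth > 0.5
    axes = tuple(range(1, pred.ndim))
    inter = (pred & t).sum(axis=axes)
    denom = pred.sum(axis=axes) + t.sum(axis=axes)
    with np.errstate(invalid="ignore"):
        d = np.where(denom > 0, 2.0 * inter / np.maximum(denom, 1), 1.0)
    return float(d.mean())


def _predict_batched(model: Model, x: np.ndarray, batch: int = 8) -> np.ndarray:
    return np.concatenate(
        [model.predict(x[i : i + batch]) for i in range(0, len(x), batch)]
    )


def train(
    model: Model,
    train_set: list[ImageSample],
    val_set: list[ImageSample],
    cfg: TrainConfig,
) -> TrainHistory:
    """Adam + Dice-loss training with patience-based convergence stopping.

    Raises ``RuntimeError`` naming the epoch/step if the loss goes
    non-finite.  Fully seeded: shuffling comes from ``cfg.seed`` and the
    model carries its own init seed.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(list(model.net.parameters()), lr=cfg.learning_rate)
    x, y = _stack(train_set)
    xv, yv = _stack(val_set)
    hist = TrainHistory()
    best_val = math.inf
    since_improved = 0
    done = False
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(x))
        losses, dices = [], []
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            out = model.forward(Tensor(x[idx]))
            loss = dice_loss_op(out, y[idx], cfg.dice_smooth)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, step {hist.steps + 1}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            dices.append(_hard_dice(out.data, y[idx]))
            hist.steps += 1
            if (
                cfg.max_steps_override is not None
                and hist.steps >= cfg.max_steps_override
            ):
                hist.stop_reason = "max_steps"
                done = True
                break
        vprobs = _predict_batched(model, xv)[..., None]
        vloss = float(
            np.mean([M.dice_loss(p, t, cfg.dice_smooth) for p, t in zip(vprobs, yv)])
        )
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_dice.append(float(np.mean(dices)))
        hist.val_loss.append(vloss)
        hist.val_dice.append(_hard_dice(vprobs, yv))
        if (
            cfg.stop_at_train_dice is not None
            and hist.train_dice[-1] >= cfg.stop_at_train_dice
        ):
            hist.stop_reason = "target_train_dice"
            done = True
        if vloss < best_val - cfg.convergence_min_delta:
            best_val = vloss
            since_improved = 0
        else:
            since_improved += 1
            if since_improved >= cfg.convergence_patience:
                hist.converged_epoch = epoch + 1
                hist.stop_reason = "plateau"
                done = True
        if done:
            break
    return hist


def evaluate(model: Model, samples: list[ImageSample]) -> list[M.MetricReport]:
    x, _ = _stack(samples)
    probs = _predict_batched(model, x)
    return [
        M.evaluate_pair(p, s.mask, sample_id=s.sample_id)
        for p, s in zip(probs, samples)
    ]


def mean_report(reports: list[M.MetricReport]) -> M.MetricReport:
    """Per-metric NaN-aware mean across per-image rows."""
    out = M.MetricReport()
    for name in out.metric_names():
        vals = np.array([getattr(r, name) for r in reports], np.float64)
        vals = vals[~np.isnan(vals)]
        setattr(out, name, float(vals.mean()) if vals.size else math.nan)
    return out


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence((seed, fold)).generate_state(1)[0] % 2**31)


def run_cv(
    spec: ArchitectureSpec,
    dataset: list[ImageSample],
    cfg: TrainConfig,
    k: int = 5,
    val_fraction: float = 0.15,
) -> CVSummary:
    """Train k models on k-1 folds each; per-fold metrics on the held-out fold.

    A seeded slice of each training split serves as the convergence-
    monitoring set, so the held-out fold is never seen during training.
    """
    assignment = make_folds(dataset, k=k, seed=cfg.seed)
    by_id = {s.sample_id: s for s in dataset}
    fold_reports: list[M.MetricReport] = []
    for fold in range(k):
        train_ids, test_ids = assignment.split(fold)
        assert not set(train_ids) & set(test_ids), "train/test leakage"
        rng = np.random.default_rng(_fold_seed(cfg.seed, fold))
        train_ids = list(train_ids)
        rng.shuffle(train_ids)
        n_val = max(1, int(round(val_fraction * len(train_ids))))
        val_ids, fit_ids = train_ids[:n_val], train_ids[n_val:]
        if not fit_ids:
            fit_ids, val_ids = train_ids, train_ids
        model = build_model(spec, seed=_fold_seed(cfg.seed, fold))
        train(
            model,
            [by_id[i] for i in fit_ids],
            [by_id[i] for i in val_ids],
            replace(cfg, seed=_fold_seed(cfg.seed, fold)),
        )
        fold_reports.append(mean_report(evaluate(model, [by_id[i] for i in test_ids])))
    return aggregate_folds(fold_reports)


# ---------------------------------------------------------------------------
# delta arithmetic shared by the experiment runners and the report fixtures
# ---------------------------------------------------------------------------

def ablation_deltas(scores: dict[str, float], baseline: str) -> dict[str, float]:
    """Per-variant score minus the baseline's score (baseline delta is 0)."""
    if baseline not in scores:
        raise KeyError(f"baseline {baseline!r} missing from scores")
    return {name: s - scores[baseline] for name, s in scores.items()}


def pairwise_differences(scores: dict[str, float]) -> dict[str, float]:
    """All ordered pairwise differences, keyed 'a_minus_b'."""
    return {
        f"{a}_minus_{b}": scores[a] - scores[b]
        for a, b in itertools.permutations(scores, 2)
    }


def _summary_row(name: str, summary: CVSummary) -> dict:
    row: dict = {"variant": name}
    for metric in ("dice", "iou", "precision", "recall", "mae"):
        row[metric] = summary.mean[metric]
        row[f"{metric}_std"] = summary.std[metric]
    return row


def run_architectural_ablation(
    dataset: list[ImageSample],
    cfg: TrainConfig,
    base_spec: ArchitectureSpec | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """Cross-validate the four variants under identical settings.

    Output: one row per variant with mean±std metrics and Dice/IoU deltas
    against the plain-encoder baseline.
    """
    base_spec = base_spec or ArchitectureSpec()
    summaries = {
        v: run_cv(replace(base_spec, variant=v), dataset, cfg, k=k) for v in VARIANTS
    }
    rows = [_summary_row(v, s) for v, s in summaries.items()]
    table = pd.DataFrame(rows)
    for metric in ("dice", "iou"):
        deltas = ablation_deltas(
            dict(zip(table["variant"], table[metric])), BASELINE_VARIANT
        )
        table[f"delta_{metric}"] = table["variant"].map(deltas)
    return table


def run_controlled_comparison(
    dataset: list[ImageSample],
    cfg: TrainConfig | None = None,
    base_spec: ArchitectureSpec | None = None,
    k: int = 2,
) -> pd.DataFrame:
    """Re-train all four variants under one shared TrainConfig.

    Provenance columns record the (identical) batch size, epochs and
    learning rate per row; pairwise Dice differences are appended as
    ``dice_minus_<variant>`` columns.
    """
    cfg = cfg or TrainConfig()
    base_spec = base_spec or ArchitectureSpec()
    summaries = {
        v: run_cv(replace(base_spec, variant=v), dataset, cfg, k=k) for v in VARIANTS
    }
    rows = []
    for v, s in summaries.items():
        row = _summary_row(v, s)
        row.update(
            batch_size=cfg.batch_size, epochs=cfg.epochs,
            learning_rate=cfg.learning_rate,
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    dice_by = dict(zip(table["variant"], table["dice"]))
    for other in VARIANTS:
        table[f"dice_minus_{other}"] = table["variant"].map(
            {v: dice_by[v] - dice_by[other] for v in VARIANTS}
        )
    return table


def run_preprocessing_ablation(
    dataset: list[ImageSample],
    spec: ArchitectureSpec | None = None,
    cfg: TrainConfig | None = None,
    preprocess_base: PreprocessConfig | None = None,
    val_fraction: float = 0.3,
) -> pd.DataFrame:
    """Train one model per preprocessing configuration (none .. full pipeline).

    Each row records the stage toggles it was produced with and the
    held-out Dice/IoU, plus Dice deltas against the no-preprocessing row.
    """
    spec = spec or ArchitectureSpec()
    cfg = cfg or TrainConfig()
    configs = (
        ABLATION_CONFIGS
        if preprocess_base is None
        else _ablation_configs(preprocess_base)
    )
    rows = []
    for label, pcfg in configs.items():
        processed = [run_pipeline(s, pcfg) for s in dataset]
        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(len(processed))
        n_val = max(1, int(round(val_fraction * len(processed))))
        val = [processed[i] for i in order[:n_val]]
        fit = [processed[i] for i in order[n_val:]] or val
        model = build_model(spec, seed=cfg.seed)
        train(model, fit, val, cfg)
        report = mean_report(evaluate(model, val))
        rows.append(
            {
                "configuration": label,
                "dice": report.dice,
                "iou": report.iou,
                "enable_clahe": pcfg.enable_clahe,
                "enable_denoise": pcfg.enable_denoise,
                "enable_mask_refine": pcfg.enable_mask_refine,
            }
        )
    table = pd.DataFrame(rows)
    deltas = ablation_deltas(
        dict(zip(table["configuration"], table["dice"])), "No Preprocessing"
    )
    table["delta_dice"] = table["configuration"].map(deltas)
    return table
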