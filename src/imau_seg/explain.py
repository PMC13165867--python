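"""Perturbation-based importance maps for segmentation models.

The image is divided into a regular grid; each cell in turn is replaced by
a constant baseline value and the model re-run.  A cell's importance is
the drop in Dice (against the ground-truth mask) that occluding it causes.
The procedure is deterministic and model-agnostic — any object with a
``predict(image) -> probability map`` method works.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metrics as M
from .synthetic import ImageSample

__all__ = ["ImportanceMap", "occlusion_importance", "organ_background_means"]


@dataclass
class ImportanceMap:
    grid_rows: int
    grid_cols: int
    values: np.ndarray  # (grid_rows, grid_cols) Dice drop per occluded cell

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid_rows, self.grid_cols):
            raise ValueError("importance values do not match the grid shape")
        if not np.isfinite(self.values).all():
            raise ValueError("importance values must be finite")

    def cell_slices(self, image_shape: tuple[int, int]):
        """Yield (row, col, y-slice, x-slice) for every grid cell."""
        h, w = image_shape
        ys = np.linspace(0, h, self.grid_rows + 1).astype(int)
        xs = np.linspace(0, w, self.grid_cols + 1).astype(int)
        for r in range(self.grid_rows):
            for c in range(self.grid_cols):
                yield r, c, slice(ys[r], ys[r + 1]), slice(xs[c], xs[c + 1])


def _dice_of(prob: np.ndarray, truth: np.ndarray) -> float:
    pred = (prob > M.BINARIZE_THRESHOLD).astype(np.uint8)
    return M.dice(M.confusion_counts(pred, truth))


def occlusion_importance(
    model,
    sample: ImageSample,
    grid: tuple[int, int] = (8, 8),
    baseline_value: float = 0.0,
) -> ImportanceMap:
    """Dice drop caused by occluding each grid cell with ``baseline_value``."""
    rows, cols = grid
    h, w = sample.mask.shape
    if rows > h or cols > w:
        raise ValueError(f"grid {grid} larger than image {h}x{w}")
    base_prob = model.predict(sample.image)
    base_dice = _dice_of(base_prob, sample.mask)
    values = np.zeros((rows, cols), np.float64)
    out = ImportanceMap(rows, cols, values)
    for r, c, ys, xs in out.cell_slices((h, w)):
        perturbed = sample.image.copy()
        perturbed[ys, xs, :] = baseline_value
        values[r, c] = base_dice - _dice_of(model.predict(perturbed), sample.mask)
    return out


def organ_background_means(
    imp: ImportanceMap, mask: np.ndarray
) -> tuple[float, float]:
    """Mean importance over organ-overlapping cells vs pure-background cells."""
    organ_vals, bg_vals = [], []
    for r, c, ys, xs in imp.cell_slices(mask.shape):
        (organ_vals if mask[ys, xs].any() else bg_vals).append(imp.values[r, c])
    organ = float(np.mean(organ_vals)) if organ_vals else float("nan")
    bg = float(np.mean(bg_vals)) if bg_vals else float("nan")
    return organ, bg
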