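"""Dataset readers/writers and split handling.

On-disk layout mirrors common PNG segmentation datasets::

    root/
      images/<sample_id>.png     8-bit RGB
      masks/<sample_id>.png      8-bit grayscale 0/255 (or a color-coded map)
      manifest.csv               sample_id, area_fraction, n_occluders (optional)

Masks are stored 0/255 for visual inspectability and interpreted as {0,1}.
Color-coded multi-class masks (e.g. a liver class painted with one RGB
value) are binarized by exact match against ``mask_rgb_value``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DatasetError
from .synthetic import ImageSample

__all__ = [
    "save_dataset",
    "load_dataset",
    "split_dataset",
    "write_provenance",
]


def save_dataset(samples: list[ImageSample], root) -> Path:
    """Write PNG pairs plus a manifest; returns the root path."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        iio.imwrite(
            root / "images" / f"{s.sample_id}.png",
            (np.clip(s.image, 0, 1) * 255).round().astype(np.uint8),
        )
        iio.imwrite(
            root / "masks" / f"{s.sample_id}.png",
            (s.mask.astype(np.uint8) * 255),
        )
        rows.append({"sample_id": s.sample_id, "area_fraction": float(s.mask.mean())})
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    return root


def _read_mask(path: Path, mask_rgb_value) -> np.ndarray:
    raw = iio.imread(path)
    if raw.ndim == 3 and mask_rgb_value is not None:
        target = np.asarray(mask_rgb_value, raw.dtype)
        return np.all(raw[..., :3] == target, axis=-1).astype(np.uint8)
    if raw.ndim == 3:
        raw = raw[..., :3].mean(axis=-1)
    return (raw.astype(np.float64) / 255.0 > 0.5).astype(np.uint8)


def load_dataset(root, mask_rgb_value: tuple[int, int, int] | None = None) -> list[ImageSample]:
    """Load image/mask PNG pairs; raises DatasetError on orphans or emptiness."""
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise DatasetError(f"{root} must contain images/ and masks/ subdirectories")
    images = {p.stem: p for p in sorted(img_dir.glob("*.png"))}
    masks = {p.stem: p for p in sorted(mask_dir.glob("*.png"))}
    if not images:
        raise DatasetError(f"no PNG images found under {img_dir}")
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise DatasetError(f"unpaired image/mask ids: {orphans}")
    samples = []
    for sid, path in images.items():
        try:
            image = iio.imread(path).astype(np.float32) / 255.0
            mask = _read_mask(masks[sid], mask_rgb_value)
        except OSError as exc:
            raise DatasetError(f"unreadable file for sample {sid!r}: {exc}") from exc
        if image.ndim == 2:
            image = np.stack([image] * 3, axis=-1)
        samples.append(ImageSample(image[..., :3], mask, sid).validate())
    return samples


def split_dataset(
    dataset: list[ImageSample],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
):
    """Seeded disjoint train/val/test split; rounding remainder goes to train."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    n = len(dataset)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    order = np.random.default_rng(seed).permutation(n)
    train_idx = order[: n - n_val - n_test]
    val_idx = order[n - n_val - n_test : n - n_test]
    test_idx = order[n - n_test :]
    pick = lambda idx: [dataset[i] for i in idx]  # noqa: E731
    return pick(train_idx), pick(val_idx), pick(test_idx)


def write_provenance(path, **info) -> None:
    """JSON provenance block (seeds, configs, version) for a run directory."""
    from . import __version__

    payload = {"package_version": __version__, **info}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
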