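"""Shared fixtures.

The expensive desk-scale overfit run (a narrow fused-bottleneck model
driven to high train Dice on a handful of synthetic scenes) is session-
scoped because both the learning check and the explainability check use
the same trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

import imau_seg as I

OVERFIT_SEED = 11
OVERFIT_N = 8
OVERFIT_MAX_STEPS = 200


# 160x160 is the smallest grid on which the deepest encoder tap (1/32
# resolution) still accommodates the 5x5 pooling kernel of the MCP block.
DESK_SIZE = 160


@pytest.fixture(scope="session")
def small_dataset() -> list[I.ImageSample]:
    """Twelve desk-scale synthetic scenes for fast harness tests."""
    return I.generate_dataset(
        12, I.SceneConfig(image_size=(DESK_SIZE, DESK_SIZE), seed=2)
    )


@pytest.fixture(scope="session")
def tiny_spec() -> I.ArchitectureSpec:
    return I.ArchitectureSpec(
        variant="imau_net",
        width_multiplier=0.0625,
        input_size=(DESK_SIZE, DESK_SIZE, 3),
    )


@pytest.fixture(scope="session")
def overfit_fixture():
    """Width-0.125 fused-bottleneck model overfit on 8 synthetic 256x256 scenes.

    Returns (model, samples, history).  Training stops early once the
    train Dice target is comfortably exceeded, always within the step cap.
    """
    scenes = I.generate_dataset(OVERFIT_N, I.SceneConfig(seed=OVERFIT_SEED))
    samples = [
        I.run_pipeline(s, I.PreprocessConfig(enable_denoise=False)) for s in scenes
    ]
    spec = I.ArchitectureSpec(variant="imau_net", width_multiplier=0.125)
    model = I.build_model(spec, seed=0)
    cfg = I.TrainConfig(
        batch_size=4,
        epochs=200,
        seed=0,
        max_steps_override=OVERFIT_MAX_STEPS,
        stop_at_train_dice=0.93,
        convergence_patience=10_000,
    )
    history = I.train(model, samples, samples, cfg)
    return model, samples, history


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
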