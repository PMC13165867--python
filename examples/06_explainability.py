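"""Occlusion-importance maps: which image regions drive the segmentation.

Each cell of a grid is painted over with a baseline value and the model is
re-run; the importance of the cell is the Dice the perturbation costs.
Here a quickly-trained narrow model shows the expected pattern: cells over
the organ matter, pure-background cells do not.
"""

import numpy as np

from imau_seg import (
    ArchitectureSpec, SceneConfig, TrainConfig, build_model, generate_dataset,
    occlusion_importance, organ_background_means, train,
)

data = generate_dataset(6, SceneConfig(image_size=(160, 160), seed=3))
spec = ArchitectureSpec(variant="imau_net", width_multiplier=0.125,
                        input_size=(160, 160, 3))
model = build_model(spec, seed=0)
cfg = TrainConfig(batch_size=4, epochs=200, seed=0, max_steps_override=250,
                  stop_at_train_dice=0.85, convergence_patience=1000)
history = train(model, data, data, cfg)
print(f"trained {history.steps} steps, train Dice {history.train_dice[-1]:.3f}\n")

sample = data[0]
imp = occlusion_importance(model, sample, grid=(8, 8), baseline_value=0.0)
organ, background = organ_background_means(imp, sample.mask)
print("importance map (Dice drop per occluded cell, x1000):")
for row in imp.values:
    print("  " + " ".join(f"{1000 * v:6.1f}" for v in row))
print(f"\nmean importance over organ cells:      {organ:.4f}")
print(f"mean importance over background cells: {background:.4f}")
# Organ cells should dominate: occluding them removes the evidence the
# model segments from, while background cells barely move the prediction.
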