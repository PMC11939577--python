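"""Canonical experiment profiles.

``study_train_config`` carries the full clinical-study protocol: 224x224 input,
ViT-Small/16 encoder with the [256, 128, 64, 32] decoder (23 M parameters),
Adam at 1e-4, batch 16, 40 epochs, 5-fold cross-validation.

``desk_train_config`` is the scaled-down phantom profile used by the test
suite and worked examples so a full train/evaluate cycle fits on one CPU:
96x96 input (6x6 token grid, four decoder stages), a proportionally narrower
decoder [128, 64, 32, 16], 5 epochs — optimizer, learning rate, batch size,
loss and fold count unchanged.  ``desk_phantom_spec`` shrinks the phantom
geometry to match (pleural depth 16 so up to four reverberations fit).
"""

from __future__ import annotations

import dataclasses

from .model import ModelConfig
from .pipeline import TrainConfig
from .synthetic import PhantomSpec

__all__ = ["study_train_config", "desk_train_config", "desk_phantom_spec",
           "DESK_DATASET_KWARGS"]

# count strata for desk-scale phantom datasets: up to 4 reverberations fit
# below a 16-px pleura in 96 px; high B-counts leave no room for an A-band
DESK_DATASET_KWARGS = {"a_max": 4, "b_max": 3, "b_max_mixed": 2}


def study_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(seed=seed)


def desk_train_config(seed: int = 0, epochs: int = 5) -> TrainConfig:
    return TrainConfig(
        epochs=epochs,
        seed=seed,
        model=ModelConfig(image_size=96, decoder_channels=[128, 64, 32, 16],
                          seed=seed),
    )


def desk_phantom_spec(seed: int = 0) -> PhantomSpec:
    return dataclasses.replace(
        PhantomSpec(), height=96, width=96, pleural_depth=16,
        a_thickness=4, b_thickness=5, blur_sigma=1.0, seed=seed)
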