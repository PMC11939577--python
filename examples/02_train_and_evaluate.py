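"""Train the desk-scale network on phantoms and evaluate one fold.

Uses the desk profile (96x96 input, full-depth ViT-Small/16 encoder,
[128, 64, 32, 16] decoder, Adam 1e-4, batch 16, 5 epochs) on a 100-phantom
dataset, training the first of five folds.  Takes a few minutes on one CPU.
For the full study-scale run (200 phantoms, all folds) see README
"Reproducing the results".

Run:  python examples/02_train_and_evaluate.py
"""

import tempfile
import time
from pathlib import Path

from lusseg import (DESK_DATASET_KWARGS, desk_phantom_spec, desk_train_config,
                    generate_dataset, kfold_split, load_dataset, train_fold)
from lusseg.model import count_trainable_parameters

cfg = desk_train_config(seed=1)
print(f"model: {cfg.model.image_size}px input, "
      f"{count_trainable_parameters(cfg.model):,} trainable parameters")

with tempfile.TemporaryDirectory() as tmp:
    data_dir = Path(tmp) / "phantoms"
    generate_dataset(100, data_dir, seed=11, spec=desk_phantom_spec(),
                     **DESK_DATASET_KWARGS)
    items = load_dataset(data_dir, cfg)
    folds = kfold_split(items, cfg.folds, cfg.seed)
    val_items = folds[0]
    train_items = [it for fold in folds[1:] for it in fold]
    print(f"training on {len(train_items)} phantoms, "
          f"validating on {len(val_items)}")

    t0 = time.time()
    result = train_fold(train_items, val_items, cfg, out_dir=Path(tmp) / "run")
    print(f"trained {cfg.epochs} epochs in {time.time() - t0:.0f}s")
    print("epoch losses:", [round(v, 3) for v in result.loss_history])
    agg = result.aggregate
    print(f"validation Dice {agg['dice_mean']:.3f}, "
          f"IoU {agg['iou_mean']:.3f}, "
          f"Hausdorff {agg['hausdorff_mean']:.2f}px")
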