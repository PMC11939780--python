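"""Train a small model end to end on synthetic data and evaluate it.

Uses a reduced problem (48 images at 32x32, eighth width, 6 epochs) so
the script finishes in about a minute on one CPU; the full desk-scale
benchmark is run by ``scripts/acceptance.py``.
"""

from dfdrnet.data_synth import SynthConfig, generate_dataset
from dfdrnet.far import DfdrConfig
from dfdrnet.metrics import evaluate_dataset
from dfdrnet.network import NetworkConfig, build_model
from dfdrnet.train import TrainConfig, train

data = generate_dataset(SynthConfig(image_size=32, seed=0), 48)
tr, va, te = data[:32], data[32:40], data[40:]

model = build_model(NetworkConfig(input_size=32, width_multiplier=0.125,
                                  dfdr=DfdrConfig(attention_downsample=2), seed=0))
cfg = TrainConfig(epochs=6, patch_size=32, seed=0)
_, log = train(model, tr, va, cfg)

print("train loss per epoch:", " ".join(f"{v:.3f}" for v in log.train_loss))
print("val loss per epoch  :", " ".join(f"{v:.3f}" for v in log.val_loss))
print(f"checkpointed epoch  : {log.selected_epoch} (lowest validation loss)")

mean, _ = evaluate_dataset(model, te)
print(f"held-out ({mean.n_images} images): dice {mean.dice:.3f}  iou {mean.iou:.3f}  "
      f"sensitivity {mean.sensitivity:.3f}  specificity {mean.specificity:.3f}")
# Dice is the headline overlap score; sensitivity counts recovered lesion
# pixels, specificity counts correctly rejected background.
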