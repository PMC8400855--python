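"""Train a small segmentation network on synthetic scenes and grade it
with the dice distribution report.

Uses a scaled-down configuration (64x64 scenes, 8 base features, a few
epochs) so the example runs in about a minute on a laptop CPU.
"""

import numpy as np

import dermcad as dc

scenes = dc.generate_scenes(n=60, malignant_fraction=0.5, seed=3, canvas_side=64)
train, val = dc.split_dataset(scenes, n_train=48, seed=3)

cfg = dc.SegNetConfig(base_features=8)          # valid mode: input 106 -> output 64
tc = dc.TrainConfig(epochs=4, batch_size=8)
model, history = dc.train_segmenter(train, val, cfg, tc, seed=3)

print("epoch  train_loss  val_loss  val_pixel_acc")
for i in range(len(history)):
    print(f"{i + 1:>5}  {history.train_loss[i]:>10.4f}  "
          f"{history.val_loss[i]:>8.4f}  {history.val_acc[i]:>13.3f}")

report = dc.segmentation_report(model, val)
baseline = np.mean([dc.dice_coefficient(np.ones_like(s.mask), s.mask) for s in val])
print(f"\nvalidation mean dice: {report.mean:.1f}%  "
      f"(all-foreground baseline: {baseline:.1f}%)")
print("dice bins  >=90 / 80-90 / 70-80 / <70 :",
      " / ".join(f"{b:.2f}" for b in report.bins))
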