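"""Run the full two-stage diagnosis on held-out synthetic scenes.

Trains both stages briefly, then for each test image: mirror-pad,
segment, extract the lesion by zeroing the background, and classify the
extracted lesion as malignant or benign.  The classifier is trained on
lesions extracted with the *predicted* masks so its inputs match what
it will see at diagnosis time.
"""

import dermcad as dc
from dermcad.preprocess import normalize_image, pad_symmetric

scenes = dc.generate_scenes(n=80, malignant_fraction=0.5, seed=5, canvas_side=64)
train, val = dc.split_dataset(scenes, n_train=64, seed=5)

seg, _ = dc.train_segmenter(train, val, dc.SegNetConfig(base_features=8),
                            dc.TrainConfig(epochs=4, batch_size=8), seed=5)


def predicted_lesion(scene):
    padded = pad_symmetric(normalize_image(scene.image), 21)
    return dc.extract_lesion(scene.image, dc.predict_mask(seg, padded))


clf_items = [(predicted_lesion(s), s.label) for s in train]
val_items = [(predicted_lesion(s), s.label) for s in val]
clf, hist = dc.train_classifier(clf_items, val_items,
                                dc.ClassifierConfig(kernels_per_layer=8),
                                dc.TrainConfig(epochs=20, batch_size=16), seed=5)
print(f"classifier validation accuracy: {hist.val_acc[-1]:.2f}")

print(f"\n{'truth':<10} {'predicted':<10} {'P(malignant)':>12} {'dice %':>7}")
correct = 0
for s in val[:8]:
    result = dc.run_cad(s.image, seg, clf, ground_truth=s.mask)
    correct += result.label == s.label
    print(f"{s.label:<10} {result.label:<10} {result.probability:>12.3f} "
          f"{result.dice:>7.1f}")
print(f"\n{correct}/8 test scenes classified correctly; dice grades the "
      "predicted mask against the exact generator mask.")
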