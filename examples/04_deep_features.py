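"""Train the compact convnet on synthetic lesions and extract features.

The penultimate dense layer's activations are the "deep features" that
the selection stage consumes; a k-nearest-neighbour classifier on them
shows how separable the two classes are.
"""

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from dermao.features import (
    CNNSpec, PreprocessConfig, TrainConfig, extract_features, preprocess, train_cnn,
)
from dermao.synthetic import SyntheticImageSpec, gen_image_arrays

raw, labels, _ = gen_image_arrays(40, SyntheticImageSpec(image_size=(64, 64), seed=0))
pp = PreprocessConfig(target_size=(32, 32))
images = np.stack([preprocess(im, pp) for im in raw])

train = np.r_[0:30, 40:70]   # 30 per class for training
test = np.r_[30:40, 70:80]   # 10 per class held out

spec = CNNSpec(conv_blocks=((8, 3, 1), (16, 3, 1), (32, 3, 1)), feature_dim=64)
model, history = train_cnn(
    images[train], labels[train], spec, TrainConfig(epochs=10, batch_size=20, seed=0)
)
print("train loss per epoch:", [round(l, 3) for l in history["train_loss"]])
print("val loss per epoch:  ", [round(l, 3) for l in history["val_loss"]])

feats = extract_features(model, images)
print(f"feature matrix: {feats.shape} (rows follow input order)")
clf = KNeighborsClassifier(5).fit(feats[train], labels[train])
print(f"held-out 5-NN accuracy on the features: {clf.score(feats[test], labels[test]):.2f}"
      " (well above 0.5 means the features separate benign from malignant)")
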