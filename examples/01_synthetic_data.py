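"""Generate synthetic inputs: a labeled feature table and lesion images.

The feature generator plants a known informative subset (class-shifted
Gaussian columns) among pure-noise columns; the image generator draws
elliptical lesions on textured skin, with malignant lesions made more
asymmetric, more irregular, and darker.
"""

import numpy as np

from dermao.synthetic import (
    SyntheticFeatureSpec,
    SyntheticImageSpec,
    gen_feature_dataset,
    gen_image_arrays,
)

spec = SyntheticFeatureSpec(
    n_samples=200, n_features=20, n_informative=4, effect_size=1.5, seed=0
)
X, y, informative = gen_feature_dataset(spec)
shifts = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
print(f"feature table: {X.shape[0]} samples x {X.shape[1]} features, "
      f"{int(y.sum())} malignant")
print(f"planted informative columns: {sorted(informative)}")
print(f"their class-mean shifts: {np.round(shifts[sorted(informative)], 2)} "
      "(should sit near the requested effect size of 1.5)")

img_spec = SyntheticImageSpec(image_size=(64, 64), seed=0)
images, labels, masks = gen_image_arrays(5, img_spec)
areas = masks.sum(axis=(1, 2))
print(f"\nimages: {images.shape[0]} RGB {images.shape[1]}x{images.shape[2]}, "
      f"lesion areas {areas.min()}-{areas.max()} px "
      "(each mask marks exactly the lesion pixels)")
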