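"""Seeded synthetic data: two-class feature tables and lesion-like images.

Real dermoscopic collections (ISIC, PH2) cannot ship with a test suite,
so every downstream stage here is exercised on generated data with known
ground truth.  Two generators are provided:

* :func:`gen_feature_dataset` — a two-class Gaussian feature matrix in
  which a known subset of columns carries a class-conditional mean shift
  (the standardized shift is Cohen's d) and the rest are pure noise.
  This stands in for a CNN feature table whose informative subset a
  feature selector should recover.
* :func:`gen_lesion_image` / :func:`gen_image_dataset` — lesion-like RGB
  images: an elliptical lesion with a sinusoidally perturbed border on a
  textured skin background, plus a binary ground-truth mask.  Malignant
  lesions get extra eccentricity (asymmetry), border irregularity and a
  color shift — a cartoon of the ABCD dermoscopy criteria — and optional
  Gaussian blur and speckle noise emulate common acquisition artifacts.

All generators are pure functions of (spec, seed): the same seed yields
bit-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SyntheticFeatureSpec",
    "SyntheticImageSpec",
    "gen_feature_dataset",
    "gen_lesion_image",
    "gen_image_arrays",
    "gen_image_dataset",
    "write_feature_csv",
    "read_feature_csv",
    "BENIGN",
    "MALIGNANT",
]

BENIGN = "benign"
MALIGNANT = "malignant"  # positive class, label 1


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Parameters of the two-class Gaussian feature generator.

    ``effect_size`` is the standardized mean shift (Cohen's d) applied to
    each informative column in the malignant class only; ``noise_sd`` is
    the common within-class standard deviation of every column.
    """

    n_samples: int = 400
    n_features: int = 50
    n_informative: int = 8
    effect_size: float = 1.5
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must not exceed n_features")
        if self.n_informative < 0 or self.n_features < 1:
            raise ValueError("feature counts must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie strictly in (0, 1)")


def gen_feature_dataset(
    spec: SyntheticFeatureSpec,
) -> tuple[np.ndarray, np.ndarray, frozenset[int]]:
    """Generate (features, labels, informative_index_set).

    Benign rows are N(0, noise_sd^2) in every column; malignant rows are
    shifted by ``effect_size * noise_sd`` in the informative columns.
    The informative column indices are drawn without replacement from
    the seeded stream and returned as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_samples, spec.n_features, spec.n_informative

    n_pos = int(round(spec.class_balance * n))
    n_pos = min(max(n_pos, 1), n - 1)
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1

    informative = np.sort(rng.choice(d, size=k, replace=False)) if k else np.array([], int)
    X = rng.normal(0.0, spec.noise_sd, size=(n, d))
    if k:
        X[np.ix_(labels == 1, informative)] += spec.effect_size * spec.noise_sd
    return X, labels, frozenset(int(i) for i in informative)


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of the lesion-image generator.

    Radii are fractions of min(H, W).  ``asymmetry_delta`` lowers the
    malignant minor/major axis ratio (more eccentric), and
    ``border_irregularity`` is the relative amplitude of the sinusoidal
    radial perturbation applied to malignant borders.  ``color_shift``
    is an RGB offset (unit scale) applied to the malignant lesion tone.
    """

    image_size: tuple[int, int] = (128, 128)
    lesion_radius_range: tuple[float, float] = (0.20, 0.32)
    asymmetry_delta: float = 0.25
    border_irregularity: float = 0.12
    color_shift: tuple[float, float, float] = (-0.10, -0.08, -0.02)
    blur_sigma: float = 1.0
    speckle_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValueError("image_size must be at least 16x16")
        lo, hi = self.lesion_radius_range
        if not (0.0 < lo <= hi):
            raise ValueError("lesion_radius_range must be positive and ordered")
        # worst-case radius (with irregularity and center jitter) must fit
        if hi * (1.0 + self.border_irregularity) + 0.08 > 0.5:
            raise ValueError("lesion_radius_range too large: lesion may leave frame")
        for name, v in (
            ("asymmetry_delta", self.asymmetry_delta),
            ("border_irregularity", self.border_irregularity),
            ("speckle_rate", self.speckle_rate),
        ):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


_SKIN_TONE = np.array([0.86, 0.66, 0.56])
_LESION_TONE = np.array([0.55, 0.38, 0.30])


def _lesion_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    angle: float,
    irregularity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize a filled ellipse whose border radius is modulated by a
    small sum of sinusoids (the irregularity model)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - center[1]
    dy = yy - center[0]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (dx * ca + dy * sa) / a
    v = (-dx * sa + dy * ca) / b
    rho = np.hypot(u, v)
    if irregularity > 0:
        theta = np.arctan2(v, u)
        harmonics = rng.integers(3, 8, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        amps = rng.dirichlet(np.ones(3)) * irregularity
        pert = sum(
            amp * np.sin(k * theta + ph) for amp, k, ph in zip(amps, harmonics, phases)
        )
        return rho <= 1.0 + pert
    return rho <= 1.0


def gen_lesion_image(
    class_label: str,
    spec: SyntheticImageSpec,
    rng: np.random.Generator,
    with_geometry: bool = False,
):
    """Generate one (H, W, 3) uint8 image and its (H, W) binary mask.

    Benign lesions are near-circular ellipses with clean borders;
    malignant lesions add the spec's asymmetry, border irregularity and
    color shift.  Blur and speckle are applied to the image after
    composition, never to the mask.
    """
    if class_label not in (BENIGN, MALIGNANT):
        raise ValueError(f"class_label must be '{BENIGN}' or '{MALIGNANT}'")
    malignant = class_label == MALIGNANT
    h, w = spec.image_size
    m = min(h, w)

    # geometry
    r_frac = rng.uniform(*spec.lesion_radius_range)
    a = r_frac * m
    ratio = rng.uniform(0.85, 1.0)
    if malignant:
        ratio = max(ratio - spec.asymmetry_delta, 0.3)
    b = a * ratio
    angle = rng.uniform(0, np.pi)
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    irregularity = spec.border_irregularity if malignant else 0.0
    mask = _lesion_mask((h, w), (cy, cx), a, b, angle, irregularity, rng)

    # skin background with smooth texture
    img = np.empty((h, w, 3))
    base = _SKIN_TONE + rng.uniform(-0.04, 0.04, size=3)
    texture = gaussian_filter(rng.normal(0, 1, size=(h, w)), sigma=m / 16)
    tex_std = texture.std()
    if tex_std > 0:
        texture = texture / tex_std * 0.03
    for c in range(3):
        img[:, :, c] = base[c] + texture

    # lesion fill, mildly shaded toward the center
    tone = _LESION_TONE + rng.uniform(-0.03, 0.03, size=3)
    if malignant:
        tone = tone + np.asarray(spec.color_shift)
    yy, xx = np.mgrid[0:h, 0:w]
    radial = np.hypot((yy - cy) / max(a, 1e-9), (xx - cx) / max(b, 1e-9))
    shade = 1.0 - 0.15 * np.clip(1.0 - radial, 0, 1)
    for c in range(3):
        img[:, :, c] = np.where(mask, tone[c] * shade, img[:, :, c])

    if spec.blur_sigma > 0:
        for c in range(3):
            img[:, :, c] = gaussian_filter(img[:, :, c], sigma=spec.blur_sigma)
    if spec.speckle_rate > 0:
        n_spots = rng.binomial(h * w, spec.speckle_rate)
        ys = rng.integers(0, h, size=n_spots)
        xs = rng.integers(0, w, size=n_spots)
        img[ys, xs] = rng.uniform(0, 1, size=(n_spots, 3))

    img8 = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
    if with_geometry:
        geometry = {"center": (cy, cx), "a": a, "b": b, "angle": angle}
        return img8, mask.astype(np.uint8), geometry
    return img8, mask.astype(np.uint8)


def gen_image_arrays(
    n_per_class: int, spec: SyntheticImageSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate a balanced in-memory batch: (images, labels, masks).

    Labels are 0 = benign, 1 = malignant; rows are benign first, then
    malignant, each block internally seed-ordered.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed)
    images, masks, labels = [], [], []
    for cls, lab in ((BENIGN, 0), (MALIGNANT, 1)):
        for _ in range(n_per_class):
            img, mask = gen_lesion_image(cls, spec, rng)
            images.append(img)
            masks.append(mask)
            labels.append(lab)
    return np.stack(images), np.asarray(labels), np.stack(masks)


def gen_image_dataset(
    n_per_class: int, spec: SyntheticImageSpec, out_dir
) -> pd.DataFrame:
    """Write a labeled image set to disk and return the manifest.

    Emits ``<cls>_<i>.png`` 8-bit RGB images, ``<cls>_<i>_mask.png``
    single-channel {0, 255} masks, and ``manifest.csv`` with columns
    (path, mask_path, label).  Paths in the manifest are relative to
    ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, labels, masks = gen_image_arrays(n_per_class, spec)
    rows = []
    counters = {0: 0, 1: 0}
    for img, lab, mask in zip(images, labels, masks):
        cls = MALIGNANT if lab == 1 else BENIGN
        i = counters[lab]
        counters[lab] += 1
        img_name = f"{cls}_{i:04d}.png"
        mask_name = f"{cls}_{i:04d}_mask.png"
        Image.fromarray(img).save(out / img_name)
        Image.fromarray(mask * 255).save(out / mask_name)
        rows.append({"path": img_name, "mask_path": mask_name, "label": cls})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def manifest_hash(manifest: pd.DataFrame) -> str:
    """Stable content hash of a manifest (order-sensitive)."""
    return hashlib.sha256(manifest.to_csv(index=False).encode()).hexdigest()


def write_feature_csv(path, features: np.ndarray, labels: np.ndarray) -> None:
    """Write a feature table as CSV: f0..f{D-1} columns plus `label`."""
    df = pd.DataFrame(features, columns=[f"f{j}" for j in range(features.shape[1])])
    df["label"] = labels
    df.to_csv(path, index=False)


def read_feature_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a feature table CSV (last column `label`) -> (X, y)."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("feature table must have a `label` column")
    y = df["label"].to_numpy()
    X = df.drop(columns="label").to_numpy(dtype=float)
    return X, y
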