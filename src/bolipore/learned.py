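"""Trainable pore segmenter: a neural pixel classifier over a multiscale
filter bank.

Each pixel is described by a small bank of Gaussian, difference-of-Gaussian,
gradient and local-variance features and classified pore / non-pore by a
single-hidden-layer perceptron trained with minibatch SGD (scikit-learn's
``MLPClassifier`` via ``partial_fit``, one shuffled pass per epoch).  The
probability map is thresholded at 0.5 — ties go to background — and then
fed through the same post-processing chain as the classical route, so the
two segmenters are directly comparable.

Training is deterministic for a fixed seed and single-threaded BLAS; no GPU
is involved.
"""
from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, sobel

from .core import PoreLabelMap, SEMImage
from .segmentation import SegConfig, detect_test_mask, postprocess_binary

__all__ = ["PoreModel", "train_pore_model", "segment_pores_learned", "pixel_features"]

_FEATURE_NAMES = (
    "intensity",
    "gauss1",
    "gauss2",
    "gauss4",
    "dog12",
    "dog24",
    "sobel1",
    "localstd2",
    "flat16",
)


def pixel_features(image: SEMImage) -> np.ndarray:
    """Per-pixel multiscale feature stack, shape (rows, cols, n_features).

    Scales are expressed in pixels of the image as given; a model therefore
    records the pixel size it was trained at and warns when applied at a
    different calibration.
    """
    arr = image.astype_float()
    scale = 65535.0 if image.pixels.dtype == np.uint16 else 255.0
    a = arr / scale
    g1 = gaussian(a, 1.0, preserve_range=True)
    g2 = gaussian(a, 2.0, preserve_range=True)
    g4 = gaussian(a, 4.0, preserve_range=True)
    g16 = gaussian(a, 16.0, preserve_range=True)
    local_var = np.clip(gaussian(a**2, 2.0, preserve_range=True) - g2**2, 0.0, None)
    feats = [a, g1, g2, g4, g1 - g2, g2 - g4, sobel(g1), np.sqrt(local_var), a - g16]
    return np.stack(feats, axis=-1)


@dataclass
class PoreModel:
    """A trained pixel classifier plus its training manifest."""

    classifier: object | None
    scaler_mean: np.ndarray | None
    scaler_std: np.ndarray | None
    pixel_size: float
    manifest: dict = field(default_factory=dict)

    @property
    def trained(self) -> bool:
        return self.classifier is not None and self.manifest.get("epochs", 0) > 0

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "PoreModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, PoreModel):
            raise TypeError("file does not contain a PoreModel")
        return model


def _sample_training_pixels(
    feats: np.ndarray,
    truth: np.ndarray,
    rng: np.random.Generator,
    per_class: int = 1500,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced random pixel sample from one image (pore vs non-pore)."""
    pore_idx = np.flatnonzero(truth.ravel())
    bg_idx = np.flatnonzero(~truth.ravel())
    n_pore = min(per_class, pore_idx.size)
    n_bg = min(per_class, bg_idx.size)
    sel = np.concatenate(
        [
            rng.choice(pore_idx, size=n_pore, replace=False) if n_pore else pore_idx,
            rng.choice(bg_idx, size=n_bg, replace=False) if n_bg else bg_idx,
        ]
    )
    X = feats.reshape(-1, feats.shape[-1])[sel]
    y = truth.ravel()[sel].astype(np.int64)
    return X, y


def train_pore_model(
    pairs: "list[tuple[SEMImage, PoreLabelMap]]",
    epochs: int = 10,
    seed: int = 0,
    hidden: int = 16,
) -> PoreModel:
    """Train the pixel classifier on (image, pore label map) pairs.

    Fewer than 8 training images is allowed (useful for overfitting sanity
    checks) but triggers a warning; ``epochs=0`` returns an untrained model
    with a warning.  All images must share shape-compatible rasters and one
    pixel size.
    """
    from sklearn.neural_network import MLPClassifier

    if len(pairs) < 1:
        raise ValueError("need at least one training pair")
    if len(pairs) < 8:
        warnings.warn(
            f"only {len(pairs)} training pairs; the classifier may not generalize",
            stacklevel=2,
        )
    sizes = {img.pixel_size for img, _ in pairs}
    if len(sizes) > 1:
        raise ValueError(f"training images mix pixel sizes: {sorted(sizes)}")
    for img, lm in pairs:
        if img.pixels.shape != lm.labels.shape:
            raise ValueError("image and label rasters have mismatched shapes")
    pixel_size = sizes.pop()
    manifest = {
        "image_ids": [img.id for img, _ in pairs],
        "epochs": int(epochs),
        "seed": int(seed),
        "pixel_size": pixel_size,
        "n_pairs": len(pairs),
        "features": list(_FEATURE_NAMES),
        "loss_curve": [],
    }
    if epochs == 0:
        warnings.warn("epochs=0: returning an untrained model", stacklevel=2)
        return PoreModel(None, None, None, pixel_size, manifest)

    rng = np.random.default_rng(seed)
    Xs, ys = [], []
    for img, lm in pairs:
        feats = pixel_features(img)
        X, y = _sample_training_pixels(feats, lm.labels > 0, rng)
        Xs.append(X)
        ys.append(y)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs_ = (X - mean) / std

    clf = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        batch_size=min(512, len(y)),
        learning_rate_init=1e-2,
        random_state=seed,
        max_iter=1,  # epochs are driven explicitly below
        warm_start=False,
    )
    from sklearn.metrics import log_loss

    order = np.arange(len(y))
    for ep in range(epochs):
        rng.shuffle(order)
        clf.partial_fit(Xs_[order], y[order], classes=np.array([0, 1]))
        p = clf.predict_proba(Xs_)[:, 1]
        manifest["loss_curve"].append(float(log_loss(y, p, labels=[0, 1])))
    return PoreModel(clf, mean, std, pixel_size, manifest)


def segment_pores_learned(
    image: SEMImage, model: PoreModel, config: SegConfig | None = None
) -> PoreLabelMap:
    """Apply the trained classifier and the shared post-processing chain.

    An untrained model warns and returns an empty labelling.  The 0.5
    probability threshold is fixed; ties go to background.
    """
    config = config or SegConfig()
    config.validate()
    if not model.trained:
        warnings.warn("model is untrained; returning an empty segmentation", stacklevel=2)
        return PoreLabelMap(
            np.zeros(image.pixels.shape, dtype=np.int32), provenance="learned"
        )
    if not np.isclose(model.pixel_size, image.pixel_size, rtol=1e-3):
        warnings.warn(
            f"model trained at {model.pixel_size} µm/px applied at "
            f"{image.pixel_size} µm/px; features are scale-sensitive",
            stacklevel=2,
        )
    feats = pixel_features(image)
    X = (feats.reshape(-1, feats.shape[-1]) - model.scaler_mean) / model.scaler_std
    prob = model.classifier.predict_proba(X)[:, 1].reshape(image.pixels.shape)
    binary = prob > 0.5
    try:
        mask = detect_test_mask(image)
        if config.mask_erosion_px > 0:
            mask = ndi.binary_erosion(mask, iterations=config.mask_erosion_px)
        binary &= mask
    except Exception:
        pass  # blank frames and the like: fall back to the raw prediction
    return postprocess_binary(binary, image.pixel_size, config, provenance="learned")
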