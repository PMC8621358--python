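"""Texture-energy features and the shallow pixel classifier.

The segmentation core follows a classical texture-energy recipe:

1. the RGB image is converted to gray and (by default) reduced to the
   approximation (LL) subband of a level-1 Haar wavelet transform,
   normalized so constants are preserved (a 2 x 2 block average);
2. nine 3 x 3 Laws masks — the outer products of the vectors
   L3 = (1, 2, 1) (level), E3 = (-1, 0, 1) (edge) and S3 = (-1, 2, -1)
   (spot) — are convolved with the (sub)image, giving response grids F;
3. each response is turned into a texture-energy map
   E(i, j) = mean |F| over the (2n+1) x (2n+1) macro-window centered at
   (i, j) — high where the neighborhood is busy (spike grain), low on
   smooth leaves and flat background;
4. the per-pixel energy vectors, optionally augmented with the raw
   R, G, B channels scaled to [0, 1], feed a single-hidden-layer neural
   network with logistic activations that outputs a per-pixel spike
   probability.

Channel order of the Laws responses is fixed:
L3L3, L3E3, L3S3, E3L3, E3E3, E3S3, S3L3, S3E3, S3S3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pywt
from scipy import ndimage
from skimage.color import rgb2gray
from sklearn.neural_network import MLPClassifier

from .io_formats import BinaryMask, ImageRecord

__all__ = [
    "LAWS_VECTORS",
    "LAWS_CHANNEL_NAMES",
    "laws_masks",
    "haar_ll",
    "laws_convolve",
    "texture_energy",
    "FeatureConfig",
    "PixelFeatureStack",
    "assemble_pixel_features",
    "TrainConfig",
    "ShallowAnnModel",
    "train_pixel_classifier",
    "predict_segmentation",
]

LAWS_VECTORS: dict[str, np.ndarray] = {
    "L3": np.array([1.0, 2.0, 1.0]),
    "E3": np.array([-1.0, 0.0, 1.0]),
    "S3": np.array([-1.0, 2.0, -1.0]),
}

_ORDER = ("L3", "E3", "S3")
LAWS_CHANNEL_NAMES: tuple[str, ...] = tuple(f"{a}{b}" for a in _ORDER for b in _ORDER)


def laws_masks() -> dict[str, np.ndarray]:
    """The nine 3 x 3 Laws kernels as outer products of L3/E3/S3."""
    return {f"{a}{b}": np.outer(LAWS_VECTORS[a], LAWS_VECTORS[b]) for a in _ORDER for b in _ORDER}


def haar_ll(image_gray: np.ndarray) -> np.ndarray:
    """Level-1 Haar approximation (LL) subband at half resolution.

    Normalized to the averaging convention — a constant image maps to the
    same constant, i.e. LL is the 2 x 2 block average. Odd dimensions are
    padded by edge replication first.
    """
    arr = np.asarray(image_gray, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D intensity grid")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    pad_r = arr.shape[0] % 2
    pad_c = arr.shape[1] % 2
    if pad_r or pad_c:
        arr = np.pad(arr, ((0, pad_r), (0, pad_c)), mode="edge")
    ll, _ = pywt.dwt2(arr, "haar", mode="periodization")
    return ll / 2.0


def laws_convolve(image: np.ndarray, masks: Optional[dict[str, np.ndarray]] = None) -> np.ndarray:
    """Convolve an intensity grid with the nine Laws masks.

    Returns an (H, W, 9) array in the fixed channel order; borders use
    edge replication. Each response is the sliding inner product of the
    mask with the 3 x 3 neighborhood (the usual imaging convention), so
    an impulse reproduces the point-reflected kernel; the sign flip
    relative to strict convolution is irrelevant once |F| is taken.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite pixels")
    if masks is None:
        masks = laws_masks()
    out = np.empty(arr.shape + (9,), dtype=float)
    for k, name in enumerate(LAWS_CHANNEL_NAMES):
        out[:, :, k] = ndimage.correlate(arr, masks[name], mode="nearest")
    return out


def texture_energy(responses: np.ndarray, n: int = 7) -> np.ndarray:
    """Macro-window texture energy: mean of |F| over (2n+1) x (2n+1) windows.

    Accepts a single response grid (H, W) or a stack (H, W, K); borders
    use edge replication. The output is non-negative everywhere.
    """
    arr = np.asarray(responses, dtype=float)
    if n < 1:
        raise ValueError("macro-window half-size n must be >= 1")
    h, w = arr.shape[:2]
    if 2 * n + 1 > min(h, w):
        raise ValueError(f"macro-window size {2 * n + 1} exceeds image extent {min(h, w)}")
    absarr = np.abs(arr)
    if arr.ndim == 2:
        return ndimage.uniform_filter(absarr, size=2 * n + 1, mode="nearest")
    out = np.empty_like(absarr)
    for k in range(arr.shape[2]):
        out[:, :, k] = ndimage.uniform_filter(absarr[:, :, k], size=2 * n + 1, mode="nearest")
    return out


@dataclass
class FeatureConfig:
    """Feature-assembly options.

    use_dwt:
        compute Laws energies on the Haar LL subband (half resolution) and
        upsample back by nearest neighbor; halves compute and suppresses
        single-pixel noise at the cost of some boundary resolution.
    n:
        macro-window half-size; 7 gives the 15 x 15 energy window.
    include_color:
        append the raw R, G, B channels scaled to [0, 1].
    """

    use_dwt: bool = True
    n: int = 7
    include_color: bool = True


@dataclass
class PixelFeatureStack:
    """Per-pixel feature vectors, shape (H, W, K), with channel provenance."""

    features: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        if self.features.ndim != 3:
            raise ValueError("features must be (H, W, K)")
        if self.features.shape[2] != len(self.provenance):
            raise ValueError("provenance length must match feature count")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain NaN/Inf")

    @property
    def n_features(self) -> int:
        return int(self.features.shape[2])


def assemble_pixel_features(image: ImageRecord, config: FeatureConfig = FeatureConfig()) -> PixelFeatureStack:
    """Grayscale -> (Haar LL) -> Laws responses -> energies (-> upsample) (+ color)."""
    gray = rgb2gray(image.pixels)  # float in [0, 1]
    h, w = gray.shape
    if config.use_dwt:
        base = haar_ll(gray)
    else:
        base = gray
    energies = texture_energy(laws_convolve(base), n=config.n)
    if config.use_dwt:
        energies = np.repeat(np.repeat(energies, 2, axis=0), 2, axis=1)[:h, :w]
    names = [f"energy_{name}" for name in LAWS_CHANNEL_NAMES]
    if config.include_color:
        color = image.pixels.astype(float) / 255.0
        energies = np.concatenate([energies, color], axis=2)
        names += ["R", "G", "B"]
    return PixelFeatureStack(features=energies, provenance=names)


@dataclass
class TrainConfig:
    hidden: int = 10
    epochs: int = 300
    lr: float = 1e-3
    sample_per_class: int = 20000
    seed: int = 0


@dataclass
class ShallowAnnModel:
    """A trained single-hidden-layer pixel classifier.

    Weights are stored explicitly (input -> hidden -> 1 output, logistic
    activations) together with the training-set standardization, so the
    model is a small portable JSON file and prediction does not depend on
    the training backend.
    """

    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    w_hidden: np.ndarray       # (K, h)
    b_hidden: np.ndarray       # (h,)
    w_out: np.ndarray          # (h,)
    b_out: float
    threshold: float = 0.5
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Spike probability for an (N, K) feature matrix."""
        x = (np.asarray(features, dtype=float) - self.scaler_mean) / self.scaler_sd
        hidden = _logistic(x @ self.w_hidden + self.b_hidden)
        return _logistic(hidden @ self.w_out + self.b_out)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
            "threshold": self.threshold,
            "feature_config": self.feature_config.__dict__,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ShallowAnnModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_names=payload["feature_names"],
            scaler_mean=np.array(payload["scaler_mean"]),
            scaler_sd=np.array(payload["scaler_sd"]),
            w_hidden=np.array(payload["w_hidden"]),
            b_hidden=np.array(payload["b_hidden"]),
            w_out=np.array(payload["w_out"]),
            b_out=float(payload["b_out"]),
            threshold=float(payload["threshold"]),
            feature_config=FeatureConfig(**payload["feature_config"]),
            metadata=payload.get("metadata", {}),
        )


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _balanced_sample(stacks: Sequence[PixelFeatureStack], masks: Sequence[BinaryMask],
                     sample_per_class: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    spike_feats, bg_feats = [], []
    for stack, mask in zip(stacks, masks):
        if stack.features.shape[:2] != mask.labels.shape:
            raise ValueError("feature stack and mask shapes differ")
        flat = stack.features.reshape(-1, stack.n_features)
        lab = mask.labels.reshape(-1).astype(bool)
        spike_feats.append(flat[lab])
        bg_feats.append(flat[~lab])
    spike = np.concatenate(spike_feats)
    background = np.concatenate(bg_feats)
    if len(spike) == 0 or len(background) == 0:
        raise ValueError("training data must contain both spike and background pixels")
    n = min(sample_per_class, len(spike), len(background))
    si = rng.choice(len(spike), size=n, replace=False)
    bi = rng.choice(len(background), size=n, replace=False)
    x = np.concatenate([spike[si], background[bi]])
    y = np.concatenate([np.ones(n), np.zeros(n)])
    return x, y


def train_pixel_classifier(stacks: Sequence[PixelFeatureStack], masks: Sequence[BinaryMask],
                           config: TrainConfig = TrainConfig(),
                           feature_config: FeatureConfig = FeatureConfig()) -> ShallowAnnModel:
    """Train the shallow classifier on balanced, standardized pixel samples.

    ``sample_per_class`` spike pixels and the same number of background
    pixels are drawn (seeded, without replacement) across all images;
    features are standardized by the training mean/sd, which is stored in
    the model. Training is reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    x, y = _balanced_sample(stacks, masks, config.sample_per_class, rng)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd < 1e-12] = 1.0
    xs = (x - mean) / sd

    net = MLPClassifier(
        hidden_layer_sizes=(config.hidden,),
        activation="logistic",
        solver="adam",
        learning_rate_init=config.lr,
        max_iter=config.epochs,
        random_state=int(rng.integers(0, 2**31 - 1)),
        tol=1e-6,
        n_iter_no_change=25,
    )
    import warnings as _warnings
    with _warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        _warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(xs, y)

    return ShallowAnnModel(
        feature_names=list(stacks[0].provenance),
        scaler_mean=mean,
        scaler_sd=sd,
        w_hidden=np.asarray(net.coefs_[0]),
        b_hidden=np.asarray(net.intercepts_[0]),
        w_out=np.asarray(net.coefs_[1]).ravel(),
        b_out=float(np.asarray(net.intercepts_[1]).ravel()[0]),
        threshold=0.5,
        feature_config=feature_config,
        metadata={
            "seed": config.seed,
            "epochs_run": int(net.n_iter_),
            "hidden": config.hidden,
            "loss_curve": [float(v) for v in net.loss_curve_],
            "n_train": int(len(y)),
        },
    )


def predict_segmentation(model: ShallowAnnModel, image: ImageRecord) -> tuple[np.ndarray, BinaryMask]:
    """Per-pixel spike probability and the thresholded binary mask."""
    stack = assemble_pixel_features(image, model.feature_config)
    if stack.provenance != model.feature_names:
        raise ValueError(
            f"feature mismatch: model expects {model.feature_names}, got {stack.provenance}"
        )
    flat = stack.features.reshape(-1, stack.n_features)
    proba = model.predict_proba(flat).reshape(stack.features.shape[:2])
    return proba, BinaryMask((proba >= model.threshold).astype(np.uint8))
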