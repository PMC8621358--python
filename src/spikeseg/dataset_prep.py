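"""Dataset preparation: splitting, frame extraction, balancing, augmentation.

A *frame* is a fixed-size square tile (default 256 x 256) cut from an
image and its mask by a non-overlapping tiling; frames are the unit at
which spike vs. background balance is restored before training a
segmentation model, since spikes occupy only a small fraction of a
greenhouse image. Right/bottom edges are padded to a multiple of the
frame size — pixels with the median border color (the uniform chamber
background), masks with 0 — so stitching the frames back and cropping
the padding reconstructs the originals exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .io_formats import BinaryMask, ImageRecord

__all__ = [
    "Frame",
    "SplitResult",
    "AugmentParams",
    "split_dataset",
    "extract_frames",
    "stitch_frames",
    "balance_frames",
    "augment_pair",
    "FRAME_THRESHOLD",
]

# A frame counts as a spike frame when at least this fraction of its
# pixels is spike: one stray pixel should not label a frame positive.
FRAME_THRESHOLD = 0.005


@dataclass
class Frame:
    """One S x S tile of an image/mask pair."""

    pixels: np.ndarray          # (S, S, 3) uint8
    mask_crop: np.ndarray       # (S, S) uint8 in {0, 1}
    origin: tuple[int, int]     # (row, col) of the top-left corner in the parent
    is_spike_frame: bool

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def spike_fraction(self) -> float:
        return float(self.mask_crop.mean())


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list


def split_dataset(ids: Sequence, ratio: float, seed: int) -> SplitResult:
    """Seeded random train/test partition with |train| = round(ratio * N).

    Rounding is round-half-up, so 292 ids at ratio 0.8 give 234 train and
    58 test. Order within each part follows the shuffled order.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 ids to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    n_train = int(math.floor(ratio * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)  # both parts non-empty
    order = np.random.default_rng(seed).permutation(n)
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train:]]
    return SplitResult(train_ids=train, test_ids=test)


def _median_border_color(pixels: np.ndarray) -> np.ndarray:
    border = np.concatenate([
        pixels[0, :, :], pixels[-1, :, :], pixels[:, 0, :], pixels[:, -1, :]
    ])
    return np.median(border, axis=0)


def extract_frames(image: ImageRecord, mask: BinaryMask, size: int = 256,
                   frame_threshold: float = FRAME_THRESHOLD) -> list[Frame]:
    """Tile an image/mask pair into non-overlapping ``size`` x ``size`` frames.

    Yields ``ceil(H/size) * ceil(W/size)`` frames in row-major order.
    """
    if size < 16:
        raise ValueError("frame size must be >= 16")
    if mask.labels.shape != image.pixels.shape[:2]:
        raise ValueError("mask shape must match image shape")
    h, w = image.height, image.width
    ph = (size - h % size) % size
    pw = (size - w % size) % size
    fill = np.round(_median_border_color(image.pixels)).astype(np.uint8)
    pixels = np.pad(image.pixels, ((0, ph), (0, pw), (0, 0)), mode="constant")
    if ph or pw:
        pixels[h:, :, :] = fill
        pixels[:, w:, :] = fill
    labels = np.pad(mask.labels, ((0, ph), (0, pw)), mode="constant")

    frames = []
    for r in range(0, h + ph, size):
        for c in range(0, w + pw, size):
            mc = labels[r:r + size, c:c + size]
            frames.append(Frame(
                pixels=pixels[r:r + size, c:c + size].copy(),
                mask_crop=mc.copy(),
                origin=(r, c),
                is_spike_frame=bool(mc.mean() >= frame_threshold),
            ))
    return frames


def stitch_frames(frames: Sequence[Frame], height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Reassemble frames into (pixels, mask) arrays, cropping the padding."""
    if not frames:
        raise ValueError("no frames to stitch")
    size = frames[0].size
    max_r = max(f.origin[0] for f in frames) + size
    max_c = max(f.origin[1] for f in frames) + size
    pixels = np.zeros((max_r, max_c, 3), dtype=np.uint8)
    labels = np.zeros((max_r, max_c), dtype=np.uint8)
    for f in frames:
        r, c = f.origin
        pixels[r:r + size, c:c + size] = f.pixels
        labels[r:r + size, c:c + size] = f.mask_crop
    return pixels[:height, :width], labels[:height, :width]


def _is_pure_background(frame: Frame, std_threshold: float) -> bool:
    return (not frame.is_spike_frame
            and float(frame.pixels.std(axis=(0, 1)).max()) < std_threshold)


def balance_frames(frames: Sequence[Frame], ratio: float = 1.0, seed: int = 0,
                   pure_background_std: float = 8.0) -> list[Frame]:
    """Rebalance spike vs. background frames to ``ratio`` (spike : background).

    All spike frames are kept. Background frames that are pure chamber
    background (near-constant color, per-channel std below
    ``pure_background_std``) are dropped first; the remaining background
    frames are subsampled without replacement to ``round(n_spike /
    ratio)``. Background frames are never upsampled: if too few remain,
    all are kept and a warning is issued.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    spike = [f for f in frames if f.is_spike_frame]
    background = [f for f in frames if not f.is_spike_frame]
    if not spike:
        warnings.warn("no spike frames present; returning empty list", stacklevel=2)
        return []
    background = [f for f in background if not _is_pure_background(f, pure_background_std)]
    n_target = int(round(len(spike) / ratio))
    if len(background) <= n_target:
        if len(background) < n_target:
            warnings.warn(
                f"only {len(background)} background frames available for a target of {n_target}; keeping all",
                stacklevel=2,
            )
        chosen = background
    else:
        idx = np.random.default_rng(seed).choice(len(background), size=n_target, replace=False)
        chosen = [background[i] for i in sorted(idx)]
    return spike + chosen


@dataclass
class AugmentParams:
    """Augmentation ranges: rotation in degrees, brightness as a multiplier."""

    rotation_range: tuple[float, float] = (-30.0, 30.0)
    hflip: bool = True
    brightness_range: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if self.rotation_range[0] > self.rotation_range[1]:
            raise ValueError("rotation_range must be (low, high)")
        if self.brightness_range[0] <= 0:
            raise ValueError("brightness factors must be > 0")
        if self.brightness_range[0] > self.brightness_range[1]:
            raise ValueError("brightness_range must be (low, high)")


def augment_pair(image: ImageRecord, mask: BinaryMask,
                 params: AugmentParams = AugmentParams(),
                 seed: int = 0) -> tuple[ImageRecord, BinaryMask]:
    """Apply one random rotation / horizontal-flip / brightness draw to a pair.

    The rotation is applied identically to image (bilinear) and mask
    (nearest-neighbor, so labels stay in {0, 1}); corners exposed by the
    rotation are filled with the median border color, matching the
    uniform chamber background. Brightness multiplies all channels by a
    single factor with clipping to [0, 255] and leaves the mask untouched.
    """
    if mask.labels.shape != image.pixels.shape[:2]:
        raise ValueError("mask shape must match image shape")
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(*params.rotation_range))
    flip = bool(params.hflip and rng.random() < 0.5)
    factor = float(rng.uniform(*params.brightness_range))

    pixels = image.pixels.astype(float)
    labels = mask.labels
    if angle != 0.0:
        fill = _median_border_color(image.pixels)
        channels = [
            _sk_rotate(pixels[:, :, k], angle, resize=False, order=1,
                       mode="constant", cval=float(fill[k]), preserve_range=True)
            for k in range(3)
        ]
        pixels = np.stack(channels, axis=2)
        labels = _sk_rotate(labels.astype(float), angle, resize=False, order=0,
                            mode="constant", cval=0.0, preserve_range=True)
        labels = (labels > 0.5).astype(np.uint8)
    if flip:
        pixels = pixels[:, ::-1, :]
        labels = labels[:, ::-1]
    pixels = np.clip(pixels * factor, 0, 255)

    out_image = ImageRecord(pixels=np.round(pixels).astype(np.uint8), id=image.id,
                            view=image.view, phenotype=image.phenotype)
    return out_image, BinaryMask(np.ascontiguousarray(labels))
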