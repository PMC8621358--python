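"""Synthetic greenhouse scenes with exact ground truth.

Emulates the statistical structure of side-view greenhouse phenotyping
images: a uniform blue photo-chamber background, a green (or senescent
yellow) canopy of curved leaf strokes and thin stems, and textured
elliptical spikes with awns. Two color regimes are supported:

* ``GSGC`` — green spike, green canopy: spike and leaf hues overlap, so
  color alone cannot separate them; texture is the discriminating cue.
* ``YSYC`` — yellow spike, yellow canopy: the same difficulty for
  senescent plants.

Spikes fall into three visibility categories:

* ``top`` — prominently visible in the upper quartile, free of leaves;
* ``inner`` — embedded in the leaf mass (>= 30% of the ellipse overlaps
  leaf strokes lying behind the spike);
* ``occluded_emergent`` — partially hidden: >= 40% of the ellipse area is
  erased by an occluding leaf. The bounding box still covers the full
  spike (a partially hidden spike is one annotated object), while the
  mask keeps only the visible pixels.

Rendering is stylized, not photorealistic: what matters downstream is
that spikes are compact, textured, and color-confusable with leaves,
while leaves and stems are smooth, elongated structures — the regime the
texture/vesselness pipeline is designed for. Everything is drawn with an
integer-seeded generator, so a fixed seed gives byte-identical scenes.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import binary_dilation
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage.morphology import disk

from .io_formats import BinaryMask, BoxAnnotation, ImageRecord, write_boxes, write_image, write_mask

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "PlacementError",
    "generate_scene",
    "generate_dataset",
    "inject_linear_artifacts",
]

CATEGORIES = ("top", "inner", "occluded_emergent")

# Category proportions follow the observed composition of greenhouse test
# images: 80 top, 45 inner, 27 occluded/emergent spikes out of 152.
DEFAULT_CATEGORY_MIX = (0.53, 0.30, 0.17)


class PlacementError(RuntimeError):
    """Raised when spikes cannot be placed without overlap."""


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    The default canvas is 512 x 595 (width x height), the 2560 x 2976
    acquisition format scaled by ~1/5 so test suites stay fast; spike and
    leaf dimensions scale with the canvas, so full-size scenes are one
    config change away. ``noise_sd`` is additive Gaussian sensor noise in
    8-bit intensity units.
    """

    height: int = 595
    width: int = 512
    phenotype: str = "GSGC"
    n_spikes: int = 3
    category_mix: tuple[float, float, float] = DEFAULT_CATEGORY_MIX
    n_leaves: int = 12
    n_stems: int = 4
    background_rgb: tuple[int, int, int] = (30, 60, 150)
    noise_sd: float = 3.0
    draw_pot: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("canvas must be at least 32x32")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")
        if self.phenotype not in ("GSGC", "YSYC"):
            raise ValueError("phenotype must be 'GSGC' or 'YSYC'")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("category_mix", "background_rgb"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data))


@dataclass
class SceneTruth:
    """A rendered scene together with its exact ground truth.

    ``leaf_mask`` and ``stem_segments`` expose the rendered distractor
    geometry (leaf-stroke pixels; straight stem end-point pairs). They are
    auxiliary outputs used to construct controlled false-positive probes
    for the line-suppression filter, not part of the annotation contract.
    """

    image: ImageRecord
    boxes: list[BoxAnnotation]
    mask: BinaryMask
    leaf_mask: BinaryMask
    stem_segments: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)


def _hsv_rgb(h: float, s: float, v: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb(h % 1.0, float(np.clip(s, 0, 1)), float(np.clip(v, 0, 1)))) * 255.0


def _palette(phenotype: str, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Spike/leaf/stem colors; spike and leaf hue ranges overlap >= 50%."""
    if phenotype == "GSGC":
        leaf = _hsv_rgb(rng.uniform(0.28, 0.38), rng.uniform(0.55, 0.80), rng.uniform(0.35, 0.60))
        spike = _hsv_rgb(rng.uniform(0.26, 0.36), rng.uniform(0.45, 0.70), rng.uniform(0.55, 0.80))
        stem = _hsv_rgb(rng.uniform(0.28, 0.36), rng.uniform(0.50, 0.75), rng.uniform(0.30, 0.50))
    else:
        leaf = _hsv_rgb(rng.uniform(0.11, 0.16), rng.uniform(0.60, 0.85), rng.uniform(0.50, 0.70))
        spike = _hsv_rgb(rng.uniform(0.10, 0.15), rng.uniform(0.55, 0.80), rng.uniform(0.65, 0.90))
        stem = _hsv_rgb(rng.uniform(0.11, 0.15), rng.uniform(0.55, 0.80), rng.uniform(0.40, 0.60))
    return {"leaf": leaf, "spike": spike, "stem": stem}


def _stamp_stroke(canvas: np.ndarray, stroke_mask: np.ndarray, points: np.ndarray,
                  width: float, color: np.ndarray, rng: np.random.Generator,
                  shade: float = 0.12) -> None:
    """Paint a smooth stroke by stamping disks along sampled path points."""
    h, w = stroke_mask.shape
    radius = max(1, int(round(width / 2.0)))
    n = len(points)
    for i, (r, c) in enumerate(points):
        ri, ci = int(round(r)), int(round(c))
        if ri < -radius or ci < -radius or ri >= h + radius or ci >= w + radius:
            continue
        rr, cc = skdraw.disk((ri, ci), radius, shape=(h, w))
        # gentle along-stroke shading so leaves are smooth but not flat
        factor = 1.0 + shade * np.sin(2.0 * np.pi * i / max(n - 1, 1))
        canvas[rr, cc] = np.clip(color * factor, 0, 255)
        stroke_mask[rr, cc] = True


def _bezier_points(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, n: int = 140) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def _draw_leaf(canvas: np.ndarray, leaf_mask: np.ndarray, rng: np.random.Generator,
               color: np.ndarray, origin: np.ndarray, unit: float) -> None:
    h, w = leaf_mask.shape
    span = rng.uniform(0.18, 0.42) * w * rng.choice([-1.0, 1.0])
    rise = rng.uniform(-0.28, 0.10) * h
    p0 = origin
    p2 = origin + np.array([rise, span])
    mid = 0.5 * (p0 + p2)
    direction = p2 - p0
    norm = np.hypot(*direction) + 1e-9
    perp = np.array([-direction[1], direction[0]]) / norm
    p1 = mid + perp * rng.uniform(-0.25, 0.25) * norm
    width = unit * rng.uniform(4.0, 8.0)
    jitter = color * rng.uniform(0.9, 1.1)
    _stamp_stroke(canvas, leaf_mask, _bezier_points(p0, p1, p2), width, jitter, rng)


def _spike_pixels(center: tuple[float, float], a: float, b: float, theta: float,
                  shape: tuple[int, int], rng: np.random.Generator,
                  unit: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pixel coordinates of the spike body (ellipse) and its awns.

    Returns (ellipse_rr, ellipse_cc, awn_rr, awn_cc). ``theta`` is the
    tilt of the major axis from vertical, in radians.
    """
    r0, c0 = center
    err, ecc = skdraw.ellipse(r0, c0, b, a, shape=shape, rotation=theta)
    # awns: short thin segments fanning out from the upper tip
    tip = np.array([r0 - b * np.cos(theta), c0 + b * np.sin(theta)])
    awn_r, awn_c = [], []
    for _ in range(rng.integers(6, 11)):
        ang = theta + rng.uniform(-0.45, 0.45)
        length = unit * rng.uniform(8.0, 16.0)
        end = tip + np.array([-length * np.cos(ang), length * np.sin(ang)])
        rr, cc = skdraw.line(int(round(tip[0])), int(round(tip[1])), int(round(end[0])), int(round(end[1])))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        awn_r.append(rr[keep])
        awn_c.append(cc[keep])
    return err, ecc, np.concatenate(awn_r), np.concatenate(awn_c)


def _render_spike(canvas: np.ndarray, rr: np.ndarray, cc: np.ndarray,
                  center: tuple[float, float], theta: float, color: np.ndarray,
                  rng: np.random.Generator, unit: float) -> None:
    """Fill spike pixels with a striped + speckled texture.

    Stripes run across the spike axis with a ~4 px period (spikelet rows);
    speckle adds grain. Both modulate brightness, keeping the hue in the
    canopy's range so color alone does not give the spike away.
    """
    t = (rr - center[0]) * (-np.cos(theta)) + (cc - center[1]) * np.sin(theta)
    stripes = 30.0 * np.sin(2.0 * np.pi * t / (4.0 * unit))
    speckle = rng.normal(0.0, 25.0, size=rr.shape)
    values = color[None, :] + (stripes + speckle)[:, None]
    canvas[rr, cc] = np.clip(values, 0, 255)


def generate_scene(config: SceneConfig) -> SceneTruth:
    """Render one scene; deterministic for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    unit = h / 595.0  # geometry scales with the canvas

    canvas = np.clip(
        np.array(config.background_rgb, dtype=float)[None, None, :]
        + rng.normal(0.0, config.noise_sd, size=(h, w, 3)),
        0, 255,
    )
    palette = _palette(config.phenotype, rng)
    leaf_mask = np.zeros((h, w), dtype=bool)
    stem_mask = np.zeros((h, w), dtype=bool)

    if config.draw_pot:
        pot_top = int(h * 0.93)
        rr, cc = skdraw.rectangle((pot_top, int(w * 0.35)), (h - 1, int(w * 0.65)), shape=(h, w))
        canvas[rr, cc] = np.array([95.0, 60.0, 35.0]) + rng.normal(0, 3, size=(*rr.shape, 3))
    else:
        pot_top = h - 1

    # stems: thin, nearly vertical, straight — classic elongated distractors
    stem_segments: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for _ in range(config.n_stems):
        c_base = int(rng.uniform(0.30, 0.70) * w)
        top_r = int(rng.uniform(0.18, 0.45) * h)
        tilt = rng.uniform(-0.08, 0.08)
        c_top = int(np.clip(c_base + tilt * (pot_top - top_r), 2, w - 3))
        pts = np.stack([np.linspace(pot_top - 1, top_r, 200), np.linspace(c_base, c_top, 200)], axis=1)
        _stamp_stroke(canvas, stem_mask, pts, 3.0 * unit, palette["stem"], rng, shade=0.05)
        stem_segments.append(((pot_top - 1, c_base), (top_r, c_top)))

    leaf_origins_r = rng.uniform(0.35, 0.90, size=config.n_leaves) * h
    leaf_origins_c = rng.uniform(0.25, 0.75, size=config.n_leaves) * w
    for orr, occ in zip(leaf_origins_r, leaf_origins_c):
        _draw_leaf(canvas, leaf_mask, rng, palette["leaf"], np.array([orr, occ]), unit)

    # spikes
    categories = [CATEGORIES[i] for i in rng.choice(3, size=config.n_spikes, p=np.asarray(config.category_mix))]
    mask = np.zeros((h, w), dtype=bool)
    boxes: list[BoxAnnotation] = []
    occupied = np.zeros((h, w), dtype=bool)

    for category in categories:
        placed = False
        for _ in range(1000):
            a = unit * rng.uniform(7.0, 11.0)   # semi-minor (half-width)
            b = a * rng.uniform(2.4, 3.3)       # semi-major (half-length)
            theta = rng.uniform(-0.45, 0.45)
            margin = b + 16.0 * unit
            if category == "top":
                r0 = rng.uniform(margin, max(margin + 1, 0.25 * h - a))
            elif category == "inner":
                r0 = rng.uniform(max(margin, 0.32 * h), 0.78 * h)
            else:
                r0 = rng.uniform(max(margin, 0.18 * h), 0.62 * h)
            c0 = rng.uniform(margin, w - margin)
            err, ecc, arr_, acc_ = _spike_pixels((r0, c0), a, b, theta, (h, w), rng, unit)
            if err.size == 0:
                continue
            if occupied[err, ecc].any() or occupied[arr_, acc_].any():
                continue
            leaf_overlap = leaf_mask[err, ecc].mean()
            if category == "top" and leaf_overlap > 0.0:
                continue
            if category == "inner" and leaf_overlap < 0.30:
                # guarantee embedding: draw a backing leaf through the spike
                # center along its axis, then the spike on top of it
                backing = np.stack(
                    [np.linspace(r0 + b * np.cos(theta), r0 - b * np.cos(theta), 80),
                     np.linspace(c0 - b * np.sin(theta), c0 + b * np.sin(theta), 80)], axis=1)
                _stamp_stroke(canvas, leaf_mask, backing, max(3.0, 0.9 * a), palette["leaf"], rng)
                leaf_overlap = leaf_mask[err, ecc].mean()
                if leaf_overlap < 0.30:
                    continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a {category!r} spike after 1000 attempts (n_spikes={config.n_spikes})"
            )

        _render_spike(canvas, err, ecc, (r0, c0), theta, palette["spike"], rng, unit)
        awn_color = np.clip(palette["spike"] * 1.15, 0, 255)
        canvas[arr_, acc_] = awn_color + rng.normal(0, 8, size=(arr_.size, 3))

        all_r = np.concatenate([err, arr_])
        all_c = np.concatenate([ecc, acc_])
        box = BoxAnnotation(
            xmin=float(all_c.min()), ymin=float(all_r.min()),
            xmax=float(all_c.max() + 1), ymax=float(all_r.max() + 1),
            category=category,
        )

        spike_px = np.zeros((h, w), dtype=bool)
        spike_px[all_r, all_c] = True

        if category == "occluded_emergent":
            # erase the lower portion of the spike under an occluding leaf
            t = (all_r - r0) * np.cos(theta) - (all_c - c0) * np.sin(theta)  # + towards the base
            frac = rng.uniform(0.40, 0.55)
            t_ell = (err - r0) * np.cos(theta) - (ecc - c0) * np.sin(theta)
            cutoff = np.quantile(t_ell, 1.0 - frac)
            erase = t >= cutoff
            er_r, er_c = all_r[erase], all_c[erase]
            spike_px[er_r, er_c] = False
            paint = np.zeros((h, w), dtype=bool)
            paint[er_r, er_c] = True
            paint = binary_dilation(paint, structure=disk(2)) & ~spike_px
            pr, pc = np.nonzero(paint)
            canvas[pr, pc] = np.clip(palette["leaf"] * 0.95 + rng.normal(0, 4, size=(pr.size, 3)), 0, 255)
            leaf_mask |= paint

        mask |= spike_px
        occupied |= binary_dilation(spike_px, structure=disk(max(3, int(round(4 * unit)))))
        boxes.append(box)

    canvas = np.clip(canvas + rng.normal(0.0, config.noise_sd * 0.5, size=canvas.shape), 0, 255)

    image = ImageRecord(pixels=canvas.astype(np.uint8), id=f"scene_{config.seed}",
                        view="side", phenotype=config.phenotype)
    return SceneTruth(
        image=image,
        boxes=boxes,
        mask=BinaryMask(mask.astype(np.uint8)),
        leaf_mask=BinaryMask(leaf_mask.astype(np.uint8)),
        stem_segments=stem_segments,
    )


def generate_dataset(config: SceneConfig, n_images: int, out_dir: str | Path,
                     seed: int, overwrite: bool = False) -> pd.DataFrame:
    """Write ``n_images`` scenes (PNG image, VOC XML boxes, mask PNG) plus a manifest CSV.

    Per-image seeds are derived deterministically from ``seed``; the
    ``seed`` field of ``config`` is ignored.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty; pass overwrite=True to replace")
    for sub in ("images", "boxes", "masks"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    image_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_images)
    rows = []
    for i, s in enumerate(image_seeds):
        truth = generate_scene(replace(config, seed=int(s)))
        image_id = f"scene_{i:04d}"
        truth.image.id = image_id
        write_image(truth.image, out_dir / "images" / f"{image_id}.png")
        write_boxes(truth.boxes, out_dir / "boxes" / f"{image_id}.xml", "voc_xml",
                    image_size=(config.height, config.width))
        write_mask(truth.mask, out_dir / "masks" / f"{image_id}.png", encoding="0255")
        counts = {c: sum(1 for b in truth.boxes if b.category == c) for c in CATEGORIES}
        rows.append({
            "id": image_id, "phenotype": config.phenotype, "n_spikes": len(truth.boxes),
            "n_top": counts["top"], "n_inner": counts["inner"],
            "n_occluded_emergent": counts["occluded_emergent"], "seed": int(s),
        })
    manifest = pd.DataFrame(
        rows, columns=["id", "phenotype", "n_spikes", "n_top", "n_inner", "n_occluded_emergent", "seed"]
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def inject_linear_artifacts(truth: SceneTruth, n_artifacts: int = 4, seed: int = 0,
                            width: int = 2, min_length: float = 60.0,
                            avoid: Optional[BinaryMask] = None) -> BinaryMask:
    """Thin elongated false-positive components traced along rendered stems.

    Emulates the characteristic failure mode of per-pixel texture
    classifiers — misclassified stem/leaf-edge pixels forming long thin
    components — at controlled, known positions. Artifacts keep a 3 px
    clearance from the true spike mask (and from ``avoid``, typically the
    prediction they will be unioned with) so they form separate
    components rather than fusing with spike regions; pieces whose major
    axis falls below ``min_length`` after trimming are dropped. Returns
    the artifact pixel mask; union it with a prediction to obtain a
    corrupted mask with a known false-positive set.
    """
    rng = np.random.default_rng(seed)
    h, w = truth.mask.labels.shape
    keep_out = truth.mask.labels.astype(bool)
    if avoid is not None:
        keep_out = keep_out | avoid.labels.astype(bool)
    forbidden = binary_dilation(keep_out, structure=disk(3))
    fp = np.zeros((h, w), dtype=bool)
    if not truth.stem_segments:
        return BinaryMask(fp.astype(np.uint8))
    for _ in range(n_artifacts):
        (r0, c0), (r1, c1) = truth.stem_segments[rng.integers(len(truth.stem_segments))]
        t0, t1 = sorted(rng.uniform(0.0, 1.0, size=2))
        if t1 - t0 < 0.45:
            t1 = min(1.0, t0 + 0.45)
        n = 240
        rr = np.linspace(r0 + t0 * (r1 - r0), r0 + t1 * (r1 - r0), n)
        cc = np.linspace(c0 + t0 * (c1 - c0), c0 + t1 * (c1 - c0), n)
        seg = np.zeros((h, w), dtype=bool)
        radius = max(1, width // 2)
        for r, c in zip(rr, cc):
            dr, dc = skdraw.disk((round(r), round(c)), radius, shape=(h, w))
            seg[dr, dc] = True
        fp |= seg & ~forbidden
    labeled = skmeasure.label(fp, connectivity=2)
    for region in skmeasure.regionprops(labeled):
        if region.axis_major_length < min_length:
            fp[labeled == region.label] = False
    return BinaryMask(fp.astype(np.uint8))
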