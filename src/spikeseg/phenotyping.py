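"""Per-spike trait extraction: a fixed registry of 70 descriptors.

Each segmented spike region yields 12 shape, 32 color and 26 texture
descriptors. The registry (name, family, units) is versioned and fixed
in order, so trait tables from different runs are column-compatible.

Families
--------
shape (12)
    area, perimeter, bounding-box width/height, aspect ratio, extent,
    solidity, eccentricity, major/minor axis lengths, orientation and
    compactness 4*pi*A/P^2 (1 for an ideal disk).
color (32)
    mean / sd / min / max of R, G, B and of hue, saturation, value (24),
    plus an 8-bin normalized hue histogram. Hue mean and sd are circular
    (computed on the hue angle) to avoid the 0/360 wrap artifact; hue
    min/max are plain order statistics on [0, 1) and are only meaningful
    for regions away from the wrap point.
texture (26)
    mean and sd of the nine Laws texture-energy channels inside the
    region (18), plus gray-level co-occurrence contrast, homogeneity,
    energy and correlation at the two unit offsets 0 deg and 90 deg (8),
    computed on the region's bounding-box crop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure as skmeasure
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import graycomatrix, graycoprops

from .io_formats import BinaryMask, ImageRecord
from .texture_ann import LAWS_CHANNEL_NAMES, laws_convolve, texture_energy

__all__ = [
    "TraitRegistryEntry",
    "TRAIT_REGISTRY",
    "SpikeRegion",
    "extract_regions",
    "compute_traits",
]

REGISTRY_VERSION = "1.0"

_GLCM_STATS = ("contrast", "homogeneity", "energy", "correlation")
_GLCM_OFFSETS = ("0deg", "90deg")


@dataclass(frozen=True)
class TraitRegistryEntry:
    name: str
    family: str   # shape | color | texture
    units: str


def _build_registry() -> tuple[TraitRegistryEntry, ...]:
    entries: list[TraitRegistryEntry] = []
    shape = [
        ("area", "px^2"), ("perimeter", "px"), ("bbox_width", "px"), ("bbox_height", "px"),
        ("aspect_ratio", "ratio"), ("extent", "ratio"), ("solidity", "ratio"),
        ("eccentricity", "ratio"), ("major_axis_length", "px"), ("minor_axis_length", "px"),
        ("orientation", "rad"), ("compactness", "ratio"),
    ]
    entries += [TraitRegistryEntry(n, "shape", u) for n, u in shape]
    for channel in ("R", "G", "B", "hue", "saturation", "value"):
        unit = "intensity" if channel in ("R", "G", "B") else "ratio"
        for stat in ("mean", "sd", "min", "max"):
            entries.append(TraitRegistryEntry(f"{channel}_{stat}", "color", unit))
    entries += [TraitRegistryEntry(f"hue_hist_bin{i}", "color", "fraction") for i in range(8)]
    for name in LAWS_CHANNEL_NAMES:
        entries.append(TraitRegistryEntry(f"laws_{name}_mean", "texture", "energy"))
    for name in LAWS_CHANNEL_NAMES:
        entries.append(TraitRegistryEntry(f"laws_{name}_sd", "texture", "energy"))
    for stat in _GLCM_STATS:
        for off in _GLCM_OFFSETS:
            entries.append(TraitRegistryEntry(f"glcm_{stat}_{off}", "texture", "ratio"))
    assert len(entries) == 70
    return tuple(entries)


TRAIT_REGISTRY: tuple[TraitRegistryEntry, ...] = _build_registry()


@dataclass
class SpikeRegion:
    """One 8-connected component of a segmentation mask."""

    region_id: int
    coords: np.ndarray              # (N, 2) row/col pixel coordinates
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    centroid: tuple[float, float]
    _props: object = None

    @property
    def area(self) -> int:
        return int(len(self.coords))


def extract_regions(mask: BinaryMask, min_area: int = 1) -> list[SpikeRegion]:
    """8-connected components with area >= ``min_area``, ordered row-major by centroid."""
    labeled = skmeasure.label(mask.labels, connectivity=2)
    regions = []
    for props in skmeasure.regionprops(labeled):
        if props.area < min_area:
            continue
        regions.append(SpikeRegion(
            region_id=0, coords=props.coords, bbox=tuple(props.bbox),
            centroid=tuple(props.centroid), _props=props,
        ))
    regions.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    for i, region in enumerate(regions):
        region.region_id = i
    return regions


def _circular_hue_stats(hue: np.ndarray) -> tuple[float, float]:
    angles = hue * 2.0 * np.pi
    c, s = np.cos(angles).mean(), np.sin(angles).mean()
    mean = (np.arctan2(s, c) / (2.0 * np.pi)) % 1.0
    r = min(np.hypot(c, s), 1.0)
    sd = np.sqrt(max(-2.0 * np.log(r), 0.0)) / (2.0 * np.pi) if r > 1e-12 else 0.5
    return float(mean), float(sd)


def _shape_traits(region: SpikeRegion) -> dict[str, float]:
    props = region._props
    minr, minc, maxr, maxc = region.bbox
    bw, bh = maxc - minc, maxr - minr
    perim = float(props.perimeter)
    area = float(props.area)
    # a degenerate (zero-perimeter) region is a single pixel: maximally compact
    compactness = 4.0 * np.pi * area / (perim ** 2) if perim > 0 else 1.0
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    return {
        "area": area,
        "perimeter": float(perim),
        "bbox_width": float(bw),
        "bbox_height": float(bh),
        "aspect_ratio": float(major / minor) if minor > 0 else float(max(bw, bh)) / max(min(bw, bh), 1),
        "extent": float(props.extent),
        "solidity": float(props.solidity),
        "eccentricity": float(props.eccentricity),
        "major_axis_length": major,
        "minor_axis_length": minor,
        "orientation": float(props.orientation),
        "compactness": float(compactness),
    }


def _color_traits(rgb: np.ndarray, hsv: np.ndarray, coords: np.ndarray) -> dict[str, float]:
    rr, cc = coords[:, 0], coords[:, 1]
    out: dict[str, float] = {}
    samples = {
        "R": rgb[rr, cc, 0].astype(float),
        "G": rgb[rr, cc, 1].astype(float),
        "B": rgb[rr, cc, 2].astype(float),
        "hue": hsv[rr, cc, 0],
        "saturation": hsv[rr, cc, 1],
        "value": hsv[rr, cc, 2],
    }
    for channel, values in samples.items():
        if channel == "hue":
            mean, sd = _circular_hue_stats(values)
        else:
            mean, sd = float(values.mean()), float(values.std())
        out[f"{channel}_mean"] = mean
        out[f"{channel}_sd"] = sd
        out[f"{channel}_min"] = float(values.min())
        out[f"{channel}_max"] = float(values.max())
    hist, _ = np.histogram(samples["hue"], bins=8, range=(0.0, 1.0))
    hist = hist / max(hist.sum(), 1)
    for i in range(8):
        out[f"hue_hist_bin{i}"] = float(hist[i])
    return out


def _texture_traits(gray_u8: np.ndarray, energy: np.ndarray, region: SpikeRegion) -> dict[str, float]:
    rr, cc = region.coords[:, 0], region.coords[:, 1]
    out: dict[str, float] = {}
    degenerate = region.area < 4
    for k, name in enumerate(LAWS_CHANNEL_NAMES):
        values = energy[rr, cc, k]
        out[f"laws_{name}_mean"] = float(values.mean())
        out[f"laws_{name}_sd"] = 0.0 if degenerate else float(values.std())
    minr, minc, maxr, maxc = region.bbox
    crop = gray_u8[minr:maxr, minc:maxc]
    if degenerate or crop.shape[0] < 2 or crop.shape[1] < 2:
        # too small for co-occurrence statistics; fall back to flat values
        fallback = {"contrast": 0.0, "homogeneity": 1.0, "energy": 1.0, "correlation": 0.0}
        for stat in _GLCM_STATS:
            for off in _GLCM_OFFSETS:
                out[f"glcm_{stat}_{off}"] = fallback[stat]
        return out
    quantized = (crop.astype(int) * 32 // 256).astype(np.uint8)
    glcm = graycomatrix(quantized, distances=[1], angles=[0.0, np.pi / 2.0],
                        levels=32, symmetric=True, normed=True)
    for stat in _GLCM_STATS:
        values = graycoprops(glcm, stat)[0]
        for a, off in enumerate(_GLCM_OFFSETS):
            out[f"glcm_{stat}_{off}"] = float(values[a])
    return out


def compute_traits(image: ImageRecord, regions: Sequence[SpikeRegion],
                   energy_window_n: int = 2) -> pd.DataFrame:
    """Trait table: one row per region, columns fixed by ``TRAIT_REGISTRY``.

    ``energy_window_n`` is the macro-window half-size for the Laws energy
    channels; 2 (a 5 x 5 window) keeps the texture statistics local to
    the region.
    """
    columns = ["region_id", "image_id"] + [e.name for e in TRAIT_REGISTRY]
    if not regions:
        return pd.DataFrame(columns=columns)
    gray = rgb2gray(image.pixels)
    gray_u8 = (gray * 255).astype(np.uint8)
    n = energy_window_n
    if 2 * n + 1 > min(gray.shape):
        n = max(1, (min(gray.shape) - 1) // 2)
    energy = texture_energy(laws_convolve(gray), n=n)
    hsv = rgb2hsv(image.pixels)

    rows = []
    for region in regions:
        row: dict[str, object] = {"region_id": region.region_id, "image_id": image.id}
        row.update(_shape_traits(region))
        row.update(_color_traits(image.pixels, hsv, region.coords))
        row.update(_texture_traits(gray_u8, energy, region))
        rows.append(row)
    table = pd.DataFrame(rows, columns=columns)
    table.attrs["registry_version"] = REGISTRY_VERSION
    return table
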