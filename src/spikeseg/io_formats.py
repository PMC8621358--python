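"""Images, bounding-box annotations and binary masks on disk.

Internal conventions
--------------------
* Boxes are 0-based, half-open: ``width = xmax - xmin``. On disk, VOC XML
  keeps its native 1-based inclusive convention (as written by LabelImg),
  so a VOC box ``(xmin, ymin, xmax, ymax)`` maps to the internal box
  ``(xmin - 1, ymin - 1, xmax, ymax)`` and back.
* YOLO dialects store normalized ``(class, cx, cy, w, h)`` and therefore
  need the image size to recover pixel coordinates; round-trips are exact
  up to +/- 1 pixel from rounding.
* Masks are per-pixel ``{0, 1}`` with 1 = spike. Files using the common
  0/255 encoding are accepted: any value > 0 reads as 1.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "ImageRecord",
    "BoxAnnotation",
    "BinaryMask",
    "read_image",
    "write_image",
    "read_boxes",
    "write_boxes",
    "read_mask",
    "write_mask",
]

VIEWS = ("side", "top", "unknown")
PHENOTYPES = ("GSGC", "YSYC", "unknown")


@dataclass
class ImageRecord:
    """An 8-bit RGB raster with optional acquisition metadata.

    ``view`` tags the camera direction (side/top) and ``phenotype`` the
    color regime: GSGC (green spike, green canopy) or YSYC (yellow spike,
    yellow canopy), the two regimes in which spike and canopy share a
    color fingerprint.
    """

    pixels: np.ndarray
    id: str = ""
    view: str = "unknown"
    phenotype: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"phenotype must be one of {PHENOTYPES}")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class BoxAnnotation:
    """Axis-aligned spike box, 0-based half-open pixel coordinates.

    ``confidence`` is a detector score in [0, 1]; ground-truth boxes leave
    it ``None``. ``category`` optionally tags the spike visibility class
    (top / inner / occluded_emergent).
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    label: str = "spike"
    confidence: Optional[float] = None
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"degenerate box ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )
        if self.xmin < 0 or self.ymin < 0:
            raise ValueError("box coordinates must be non-negative")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))


@dataclass
class BinaryMask:
    """Per-pixel labels, 1 = spike, 0 = background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        values = np.unique(self.labels)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0, 1}}, found {values}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def height(self) -> int:
        return int(self.labels.shape[0])

    @property
    def width(self) -> int:
        return int(self.labels.shape[1])

    @property
    def spike_pixel_count(self) -> int:
        return int(self.labels.sum())


# ---------------------------------------------------------------------------
# images


def read_image(path: str | Path) -> ImageRecord:
    """Load a PNG/JPEG image; grayscale inputs are promoted to 3 channels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as img:
            img = img.convert("RGB")
            pixels = np.asarray(img, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise ValueError(f"cannot decode image file {path}: {exc}") from exc
    return ImageRecord(pixels=pixels, id=path.stem)


def write_image(record: ImageRecord, path: str | Path) -> None:
    Image.fromarray(record.pixels, mode="RGB").save(Path(path))


# ---------------------------------------------------------------------------
# boxes

DIALECTS = ("voc_xml", "yolo_txt", "yolo_json")


def _require_image_size(dialect: str, image_size: Optional[tuple[int, int]]) -> tuple[int, int]:
    if image_size is None:
        raise ValueError(f"dialect {dialect!r} stores normalized coordinates; image_size=(height, width) is required")
    h, w = image_size
    if h < 1 or w < 1:
        raise ValueError("image_size must be positive")
    return int(h), int(w)


def _clamp_box(xmin: float, ymin: float, xmax: float, ymax: float,
               image_size: Optional[tuple[int, int]], origin: str) -> tuple[float, float, float, float]:
    clamped = (max(xmin, 0.0), max(ymin, 0.0), xmax, ymax)
    if image_size is not None:
        h, w = image_size
        clamped = (clamped[0], clamped[1], min(clamped[2], float(w)), min(clamped[3], float(h)))
    if clamped != (xmin, ymin, xmax, ymax):
        warnings.warn(f"box {(xmin, ymin, xmax, ymax)} from {origin} exceeds image bounds; clamped", stacklevel=3)
    return clamped


def _parse_voc_xml(path: Path, image_size: Optional[tuple[int, int]]) -> list[BoxAnnotation]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML {path}: {exc}") from exc
    if image_size is None:
        size = root.find("size")
        if size is not None:
            image_size = (int(size.findtext("height")), int(size.findtext("width")))
    boxes = []
    for obj in root.iter("object"):
        name = obj.findtext("name", default="spike")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"object without bndbox in {path}")
        # VOC on disk is 1-based inclusive; internal is 0-based half-open.
        xmin = float(bnd.findtext("xmin")) - 1.0
        ymin = float(bnd.findtext("ymin")) - 1.0
        xmax = float(bnd.findtext("xmax"))
        ymax = float(bnd.findtext("ymax"))
        conf_text = obj.findtext("confidence")
        conf = float(conf_text) if conf_text is not None else None
        xmin, ymin, xmax, ymax = _clamp_box(xmin, ymin, xmax, ymax, image_size, str(path))
        boxes.append(BoxAnnotation(xmin, ymin, xmax, ymax, label=name, confidence=conf))
    return boxes


def _yolo_to_internal(cx: float, cy: float, w: float, h: float,
                      image_size: tuple[int, int]) -> tuple[float, float, float, float]:
    ih, iw = image_size
    xmin = round((cx - w / 2.0) * iw)
    xmax = round((cx + w / 2.0) * iw)
    ymin = round((cy - h / 2.0) * ih)
    ymax = round((cy + h / 2.0) * ih)
    return float(xmin), float(ymin), float(xmax), float(ymax)


def _parse_yolo_txt(path: Path, image_size: tuple[int, int]) -> list[BoxAnnotation]:
    boxes = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"malformed YOLO line {lineno} in {path}: {line!r}")
        try:
            cx, cy, w, h = map(float, parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else None
        except ValueError as exc:
            raise ValueError(f"malformed YOLO line {lineno} in {path}: {line!r}") from exc
        xmin, ymin, xmax, ymax = _yolo_to_internal(cx, cy, w, h, image_size)
        xmin, ymin, xmax, ymax = _clamp_box(xmin, ymin, xmax, ymax, image_size, str(path))
        boxes.append(BoxAnnotation(xmin, ymin, xmax, ymax, confidence=conf))
    return boxes


def _parse_yolo_json(path: Path, image_size: tuple[int, int]) -> list[BoxAnnotation]:
    try:
        objects = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed YOLO JSON {path}: {exc}") from exc
    if not isinstance(objects, list):
        raise ValueError(f"YOLO JSON {path} must contain a list of objects")
    boxes = []
    for obj in objects:
        xmin, ymin, xmax, ymax = _yolo_to_internal(
            float(obj["cx"]), float(obj["cy"]), float(obj["w"]), float(obj["h"]), image_size
        )
        xmin, ymin, xmax, ymax = _clamp_box(xmin, ymin, xmax, ymax, image_size, str(path))
        boxes.append(
            BoxAnnotation(
                xmin, ymin, xmax, ymax,
                label=str(obj.get("label", "spike")),
                confidence=(float(obj["confidence"]) if "confidence" in obj else None),
            )
        )
    return boxes


def read_boxes(path: str | Path, dialect: str,
               image_size: Optional[tuple[int, int]] = None) -> list[BoxAnnotation]:
    """Read box annotations, converting to the internal 0-based half-open convention.

    Parameters
    ----------
    dialect:
        ``voc_xml`` (LabelImg's 1-based inclusive XML), ``yolo_txt``
        (``class cx cy w h`` normalized lines) or ``yolo_json``.
    image_size:
        ``(height, width)``; required for the YOLO dialects, optional for
        VOC (used only for bounds clamping).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "voc_xml":
        return _parse_voc_xml(path, image_size)
    if dialect == "yolo_txt":
        return _parse_yolo_txt(path, _require_image_size(dialect, image_size))
    if dialect == "yolo_json":
        return _parse_yolo_json(path, _require_image_size(dialect, image_size))
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _internal_to_yolo(box: BoxAnnotation, image_size: tuple[int, int]) -> tuple[float, float, float, float]:
    ih, iw = image_size
    cx = (box.xmin + box.xmax) / 2.0 / iw
    cy = (box.ymin + box.ymax) / 2.0 / ih
    return cx, cy, box.width / iw, box.height / ih


def write_boxes(boxes: Sequence[BoxAnnotation], path: str | Path, dialect: str,
                image_size: Optional[tuple[int, int]] = None) -> None:
    """Write boxes in the named dialect (inverse of :func:`read_boxes`)."""
    path = Path(path)
    if dialect == "voc_xml":
        root = ET.Element("annotation")
        ET.SubElement(root, "filename").text = path.stem
        if image_size is not None:
            size = ET.SubElement(root, "size")
            ET.SubElement(size, "width").text = str(int(image_size[1]))
            ET.SubElement(size, "height").text = str(int(image_size[0]))
            ET.SubElement(size, "depth").text = "3"
        for box in boxes:
            obj = ET.SubElement(root, "object")
            ET.SubElement(obj, "name").text = box.label
            if box.confidence is not None:
                ET.SubElement(obj, "confidence").text = repr(box.confidence)
            bnd = ET.SubElement(obj, "bndbox")
            ET.SubElement(bnd, "xmin").text = str(int(round(box.xmin)) + 1)
            ET.SubElement(bnd, "ymin").text = str(int(round(box.ymin)) + 1)
            ET.SubElement(bnd, "xmax").text = str(int(round(box.xmax)))
            ET.SubElement(bnd, "ymax").text = str(int(round(box.ymax)))
        tree = ET.ElementTree(root)
        ET.indent(tree)
        tree.write(path, encoding="unicode")
    elif dialect == "yolo_txt":
        ih, iw = _require_image_size(dialect, image_size)
        lines = []
        for box in boxes:
            cx, cy, w, h = _internal_to_yolo(box, (ih, iw))
            fields = f"0 {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
            if box.confidence is not None:
                fields += f" {box.confidence:.6f}"
            lines.append(fields)
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif dialect == "yolo_json":
        ih, iw = _require_image_size(dialect, image_size)
        objects = []
        for box in boxes:
            cx, cy, w, h = _internal_to_yolo(box, (ih, iw))
            obj = {"label": box.label, "cx": cx, "cy": cy, "w": w, "h": h}
            if box.confidence is not None:
                obj["confidence"] = box.confidence
            objects.append(obj)
        path.write_text(json.dumps(objects, indent=1) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


# ---------------------------------------------------------------------------
# masks


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask image; any pixel value > 0 maps to 1 (accepts 0/1 and 0/255)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as img:
            arr = np.asarray(img)
    except (UnidentifiedImageError, OSError) as exc:
        raise ValueError(f"cannot decode mask file {path}: {exc}") from exc
    if arr.ndim == 3:
        warnings.warn(f"mask file {path} is multi-channel; binarizing by any-channel > 0", stacklevel=2)
        arr = arr.max(axis=2)
    return BinaryMask(labels=(arr > 0).astype(np.uint8))


def write_mask(mask: BinaryMask, path: str | Path, encoding: str = "0255") -> None:
    """Write a mask as grayscale PNG, spike pixels stored as 1 or 255."""
    if encoding == "01":
        out = mask.labels
    elif encoding == "0255":
        out = mask.labels * np.uint8(255)
    else:
        raise ValueError(f"unknown encoding {encoding!r}; expected '01' or '0255'")
    Image.fromarray(out, mode="L").save(Path(path))
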