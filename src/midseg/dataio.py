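"""Annotation parsing, mask rasterization and dataset statistics.

Polygon annotations follow the VGG Image Annotator (VIA) version-2
project-export JSON dialect: a mapping of image keys to records whose
``regions`` hold polygon ``shape_attributes`` (``all_points_x`` /
``all_points_y``) and a class label in ``region_attributes``.

Rasterization is pinned to painter's order (later regions overwrite
earlier ones) with an even-odd fill sampled at pixel centers: pixel
(row r, col c) is inside when the point (c + 0.5, r + 0.5) lies inside
the polygon by the crossing-number rule with half-open edge spans.

Dataset statistics mirror the exploratory analysis a segmentation corpus
ships with: object occurrences per class, the distribution of the number
of distinct (non-background) classes per image, and the small/medium/
large object-size bands — small below 5% of the image area, medium from
5% to 20%, large above 20%, measured by mask pixel count by default or
by bounding-box area on request.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from PIL import Image

__all__ = ["AnnotationSet", "Region", "DatasetStats", "parse_via", "write_via",
           "rasterize", "size_category", "dataset_stats", "load_label_map",
           "save_label_map", "save_mask_png", "load_mask_png",
           "CAMERFOOD10_CLASSES", "SIZE_SMALL_MAX", "SIZE_MEDIUM_MAX"]

# the ten food classes of the study's corpus; background is id 0
CAMERFOOD10_CLASSES = [
    "White rice",
    "Fried plantain",
    "Puff-puff",
    "Koki",
    "Tomato soup",
    "Waterfufu",
    "Taro",
    "Bobolo",
    "Yellow soup",
    "Beans",
]

SIZE_SMALL_MAX = 0.05  # below this relative size: small
SIZE_MEDIUM_MAX = 0.20  # up to this: medium; above: large


def default_label_map():
    """Class-name -> integer id map, background = 0."""
    m = {"background": 0}
    for i, name in enumerate(CAMERFOOD10_CLASSES, start=1):
        m[name] = i
    return m


@dataclass
class Region:
    """One annotated polygon: ordered vertices (x, y) plus a class id."""

    polygon: np.ndarray  # (V, 2) float, pixel coordinates
    class_id: int
    class_name: str = ""

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be a (V, 2) vertex array")
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")


@dataclass
class AnnotationSet:
    """All polygon regions of one image."""

    image_id: str
    width: int
    height: int
    regions: list = field(default_factory=list)

    def clipped(self):
        """Copy with every vertex clipped into [0, W] x [0, H]."""
        out = AnnotationSet(self.image_id, self.width, self.height, [])
        for r in self.regions:
            poly = np.clip(r.polygon, [0, 0], [self.width, self.height])
            out.regions.append(Region(poly, r.class_id, r.class_name))
        return out


class ViaParseError(ValueError):
    """Malformed VIA document; the message names the offending path."""


def parse_via(document, label_map, strict=False):
    """Parse a VIA-2 project export into AnnotationSets.

    ``document`` is a dict, JSON string, or path.  Returns
    ``(annotation_sets, warnings)`` where warnings counts skipped
    non-polygon regions and unknown class labels.  With ``strict=True``
    unknown labels raise instead.
    """
    if isinstance(document, (str, bytes)) and not str(document).lstrip().startswith("{"):
        with open(document) as fh:
            document = fh.read()
    if isinstance(document, (str, bytes)):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as e:
            raise ViaParseError(f"invalid JSON at line {e.lineno}, column {e.colno}: {e.msg}")
    if not isinstance(document, dict):
        raise ViaParseError("top level must be an object mapping image keys to records")

    img_meta = document.get("_via_img_metadata", document)
    sets, warnings = [], {"non_polygon": 0, "unknown_class": 0, "skipped_labels": []}
    for key, rec in img_meta.items():
        if key.startswith("_via"):
            continue
        if not isinstance(rec, dict) or "regions" not in rec:
            raise ViaParseError(f"image record {key!r} has no 'regions' list")
        fa = rec.get("file_attributes", {}) or {}
        width = int(fa.get("width", 0)) or None
        height = int(fa.get("height", 0)) or None
        ann = AnnotationSet(
            image_id=rec.get("filename", key),
            width=width or 0,
            height=height or 0,
        )
        regions = rec["regions"]
        if isinstance(regions, dict):  # older VIA-2 exports use a dict
            regions = [regions[k] for k in sorted(regions)]
        for ri, region in enumerate(regions):
            sa = region.get("shape_attributes", {})
            if sa.get("name") != "polygon":
                warnings["non_polygon"] += 1
                continue
            try:
                xs = sa["all_points_x"]
                ys = sa["all_points_y"]
            except KeyError as e:
                raise ViaParseError(f"region {ri} of {key!r} lacks {e.args[0]}")
            ra = region.get("region_attributes", {}) or {}
            label = ra.get("class", ra.get("label", next(iter(ra.values()), None)))
            if label not in label_map:
                if strict:
                    raise ViaParseError(f"unknown class label {label!r} in {key!r}")
                warnings["unknown_class"] += 1
                warnings["skipped_labels"].append(label)
                continue
            poly = np.column_stack([xs, ys]).astype(float)
            if len(poly) < 3:
                warnings["non_polygon"] += 1
                continue
            ann.regions.append(Region(poly, label_map[label], str(label)))
        if ann.width and ann.height:
            ann = ann.clipped()
        sets.append(ann)
    return sets, warnings


def write_via(annotation_sets, path=None):
    """Serialize AnnotationSets back to a VIA-2 project-export document."""
    doc = {}
    for ann in annotation_sets:
        regions = []
        for r in ann.regions:
            regions.append(
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [float(v) for v in r.polygon[:, 0]],
                        "all_points_y": [float(v) for v in r.polygon[:, 1]],
                    },
                    "region_attributes": {"class": r.class_name},
                }
            )
        doc[ann.image_id] = {
            "filename": ann.image_id,
            "size": -1,
            "regions": regions,
            "file_attributes": {"width": ann.width, "height": ann.height},
        }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    return doc


# ---------------------------------------------------------------------------
# rasterization


def _fill_polygon(mask, poly, value):
    """Paint ``value`` where pixel centers fall inside ``poly`` (even-odd).

    Vectorized crossing-number scan: for every polygon edge spanning a
    scanline's y-center (half-open [y1, y2)), the x of the intersection
    is compared against pixel-center x; an odd crossing count is inside.
    Returns the number of painted pixels.
    """
    h, w = mask.shape
    ys = np.arange(h) + 0.5
    xs = np.arange(w) + 0.5
    x1 = poly[:, 0]
    y1 = poly[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    # edges crossing each scanline (half-open span avoids double-counting
    # vertices); (E, H) boolean
    cross = ((y1[:, None] <= ys) & (ys < y2[:, None])) | (
        (y2[:, None] <= ys) & (ys < y1[:, None])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ys[None, :] - y1[:, None]) / (y2 - y1)[:, None]
        xint = x1[:, None] + t * (x2 - x1)[:, None]
    inside = np.zeros((h, w), dtype=bool)
    for r in range(h):
        xe = xint[cross[:, r], r]
        if xe.size == 0:
            continue
        # crossing count to the right of each pixel center
        parity = (xs[None, :] < xe[:, None]).sum(axis=0) % 2
        inside[r] = parity.astype(bool)
    mask[inside] = value
    return int(inside.sum())


def rasterize(ann, num_classes, size=None, report_degenerate=False):
    """Rasterize an AnnotationSet to an integer LabelMask (H x W).

    Later regions overwrite earlier ones on overlap (painter's order).
    Regions whose class id exceeds ``num_classes`` raise; regions that
    cover no pixel center are counted and reported when
    ``report_degenerate`` is set.
    """
    if size is not None:
        h, w = size
    else:
        h, w = ann.height, ann.width
    if h <= 0 or w <= 0:
        raise ValueError(f"invalid mask size {h}x{w}")
    mask = np.zeros((h, w), dtype=np.int32)
    degenerate = 0
    for r in ann.regions:
        if not 0 <= r.class_id < num_classes:
            raise ValueError(
                f"class id {r.class_id} out of range [0, {num_classes}) "
                f"in image {ann.image_id!r}"
            )
        painted = _fill_polygon(mask, r.polygon, r.class_id)
        if painted == 0:
            degenerate += 1
    if report_degenerate:
        return mask, degenerate
    return mask


# ---------------------------------------------------------------------------
# size bands and statistics


def size_category(object_pixels, image_pixels):
    """Classify an object's relative size r into small/medium/large.

    r < 5% -> small; 5% <= r <= 20% -> medium; r > 20% -> large.
    """
    if image_pixels <= 0:
        raise ValueError("image_pixels must be positive")
    if object_pixels > image_pixels:
        raise ValueError(
            f"object ({object_pixels} px) larger than image ({image_pixels} px)"
        )
    r = object_pixels / image_pixels
    if r < SIZE_SMALL_MAX:
        return "small"
    if r <= SIZE_MEDIUM_MAX:
        return "medium"
    return "large"


@dataclass
class DatasetStats:
    """Occurrences, classes-per-image histogram and size-band proportions."""

    occurrences: dict  # class id -> region count
    classes_per_image: dict  # n distinct classes -> fraction of images
    classes_per_image_counts: dict  # n -> image count
    size_categories: dict  # band -> fraction of objects
    size_category_counts: dict  # band -> object count
    per_class_sizes: dict  # class id -> {band: count}
    n_images: int
    n_objects: int

    def table(self):
        """Classes-per-image layout mirroring the corpus summary table."""
        order = [1, 2, 3, 4]
        header = ["One Class", "Two Classes", "Three Classes", "Four Classes"]
        vals = [100.0 * self.classes_per_image.get(n, 0.0) for n in order]
        head = "\t".join(f"{h}" for h in header)
        row = "\t".join(f"{v:.2f}%" for v in vals)
        return f"{head}\n{row}"

    def to_dict(self):
        return {
            "occurrences": {str(k): v for k, v in self.occurrences.items()},
            "classes_per_image": {str(k): v for k, v in self.classes_per_image.items()},
            "size_categories": dict(self.size_categories),
            "per_class_sizes": {
                str(k): dict(v) for k, v in self.per_class_sizes.items()
            },
            "n_images": self.n_images,
            "n_objects": self.n_objects,
        }


def dataset_stats(annotations, num_classes=None, size=None, mode="mask"):
    """Compute corpus statistics from a list of AnnotationSets.

    Occurrences count regions per class.  Classes-per-image counts
    distinct non-background classes (background is not taken into
    account).  Object sizes use per-region painted pixels under painter's
    order (``mode='mask'``) or bounding-box area (``mode='bbox'``).
    """
    if not annotations:
        raise ValueError("need at least one annotated image")
    if num_classes is None:
        num_classes = 1 + max(
            (r.class_id for a in annotations for r in a.regions), default=1
        )
    occurrences: dict = {}
    cpi_counts: dict = {}
    band_counts = {"small": 0, "medium": 0, "large": 0}
    per_class: dict = {}
    n_objects = 0
    for ann in annotations:
        h, w = size if size is not None else (ann.height, ann.width)
        image_px = h * w
        distinct = set()
        # painter's order pixel counts: paint region indices, then tally
        idx_mask = np.full((h, w), -1, dtype=np.int32)
        for ri, r in enumerate(ann.regions):
            _fill_polygon(idx_mask, r.polygon, ri)
        for ri, r in enumerate(ann.regions):
            n_objects += 1
            occurrences[r.class_id] = occurrences.get(r.class_id, 0) + 1
            if r.class_id != 0:
                distinct.add(r.class_id)
            if mode == "bbox":
                mins = r.polygon.min(axis=0)
                maxs = r.polygon.max(axis=0)
                obj_px = float((maxs[0] - mins[0]) * (maxs[1] - mins[1]))
                obj_px = min(obj_px, image_px)
            else:
                obj_px = int((idx_mask == ri).sum())
            band = size_category(obj_px, image_px)
            band_counts[band] += 1
            per_class.setdefault(r.class_id, {"small": 0, "medium": 0, "large": 0})
            per_class[r.class_id][band] += 1
        n = len(distinct)
        cpi_counts[n] = cpi_counts.get(n, 0) + 1
    n_images = len(annotations)
    cpi = {k: v / n_images for k, v in sorted(cpi_counts.items())}
    bands = {
        k: (v / n_objects if n_objects else 0.0) for k, v in band_counts.items()
    }
    return DatasetStats(
        occurrences=dict(sorted(occurrences.items())),
        classes_per_image=cpi,
        classes_per_image_counts=dict(sorted(cpi_counts.items())),
        size_categories=bands,
        size_category_counts=band_counts,
        per_class_sizes=dict(sorted(per_class.items())),
        n_images=n_images,
        n_objects=n_objects,
    )


# ---------------------------------------------------------------------------
# label maps and indexed-PNG masks

# a fixed, well-separated palette: background black, then saturated hues
_PALETTE = [
    (0, 0, 0), (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (170, 110, 40), (128, 128, 128), (255, 250, 200),
    (0, 0, 128), (128, 0, 0), (0, 128, 128),
]


def class_color(class_id):
    return _PALETTE[class_id % len(_PALETTE)]


def save_label_map(label_map, path):
    with open(path, "w") as fh:
        yaml.safe_dump({"labels": label_map}, fh, sort_keys=False)


def load_label_map(path):
    with open(path) as fh:
        data = yaml.safe_load(fh)
    m = data["labels"] if isinstance(data, dict) and "labels" in data else data
    return {str(k): int(v) for k, v in m.items()}


def save_mask_png(mask, path):
    """Write an integer label mask as an indexed (palette) PNG."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("mask values must fit in a palette PNG (0..255)")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = []
    for i in range(256):
        palette.extend(class_color(i) if i < len(_PALETTE) else (0, 0, 0))
    img.putpalette(palette)
    img.save(path, format="PNG")


def load_mask_png(path):
    img = Image.open(path)
    if img.mode != "P":
        img = img.convert("P")
    return np.asarray(img, dtype=np.int32)


def overlay_mask(image, mask, alpha=0.5):
    """Alpha-blend class colors over an RGB image (uint8 HxWx3)."""
    image = np.asarray(image).astype(np.float32)
    out = image.copy()
    mask = np.asarray(mask)
    for cid in np.unique(mask):
        if cid == 0:
            continue
        color = np.array(class_color(int(cid)), dtype=np.float32)
        sel = mask == cid
        out[sel] = (1 - alpha) * out[sel] + alpha * color
    return out.astype(np.uint8)
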