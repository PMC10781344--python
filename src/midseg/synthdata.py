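"""Seeded synthetic food-scene generator.

Emits small RGB scenes that structurally mimic a plated-food segmentation
corpus: each image holds 1-4 food objects drawn as smooth blob polygons
(radial perturbations of an ellipse, so outlines are food-plausible and
never rasterize to slivers), each with a distinctive per-class color
(optionally noise-textured), over a neutral background.  The generator
returns pixel-exact label masks, the matching VIA-2 polygon document and
a bookkeeping record of every region's class and painted pixel count, so
parsing, rasterization, statistics and training are all testable with no
external download.

Defaults follow the study corpus: 10 food classes + background, a
classes-per-image distribution matching the training split (76.65% /
22.09% / 1.16% / 0.10% for one/two/three/four classes) and object-size
band targets of 16.09% small, 43.95% medium, 39.96% large.

Everything is driven by one integer seed; the same seed reproduces the
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import (AnnotationSet, Region, default_label_map, rasterize,
                     save_mask_png, save_label_map, write_via,
                     SIZE_SMALL_MAX, SIZE_MEDIUM_MAX)

__all__ = ["SynthConfig", "SynthDataset", "generate", "write_dataset",
           "GenerationError"]

# classes-per-image probabilities of the corpus training split
DEFAULT_CLASSES_PER_IMAGE = (0.7665, 0.2209, 0.0116, 0.0010)
# small/medium/large object-size band targets of the training split
DEFAULT_SIZE_BANDS = (0.1609, 0.4395, 0.3996)

# distinct, well-separated mean colors per class id (background = dark gray)
_CLASS_COLORS = np.array(
    [
        (40, 40, 40),      # background
        (235, 235, 235),   # white rice: near-white
        (250, 200, 60),    # fried plantain: golden
        (200, 140, 60),    # puff-puff: brown
        (120, 80, 40),     # koki: dark brown
        (220, 60, 40),     # tomato soup: red
        (240, 240, 190),   # waterfufu: pale
        (150, 120, 200),   # taro: violet
        (90, 60, 20),      # bobolo: deep brown
        (215, 220, 20),    # yellow soup
        (160, 40, 60),     # beans: maroon
        (60, 160, 220),    # extra hues if n_classes > 10
        (60, 200, 120),
        (250, 120, 180),
    ],
    dtype=np.float32,
)


class GenerationError(RuntimeError):
    """Raised when the requested scene composition cannot be placed."""


@dataclass
class SynthConfig:
    n_images: int = 8
    image_size: tuple = (128, 128)
    n_classes: int = 10  # food classes; background adds one more id
    classes_per_image_distribution: tuple = DEFAULT_CLASSES_PER_IMAGE
    size_band_targets: tuple = DEFAULT_SIZE_BANDS
    texture: str = "noise"  # 'flat' or 'noise'
    noise_level: float = 12.0  # per-pixel RGB noise std (0..255 scale)
    seed: int = 0
    max_attempts: int = 240  # placement retries per object before giving up

    def validate(self):
        if self.n_classes < 1:
            raise ValueError("need at least one food class")
        for name, vec in (
            ("classes_per_image_distribution", self.classes_per_image_distribution),
            ("size_band_targets", self.size_band_targets),
        ):
            arr = np.asarray(vec, dtype=float)
            if arr.min() < 0 or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if self.texture not in ("flat", "noise"):
            raise ValueError("texture must be 'flat' or 'noise'")
        return self


@dataclass
class SynthDataset:
    """Images + annotations + masks + ground-truth bookkeeping."""

    images: list  # uint8 (H, W, 3) arrays
    annotations: list  # AnnotationSet per image
    masks: list  # int32 (H, W) label masks
    truth: list  # per image: list of dicts (class_id, pixels, band, ...)
    config: SynthConfig
    label_map: dict


def _blob_polygon(rng, cx, cy, rx, ry, n_vertices=24, roughness=0.25):
    """Smooth closed blob: an ellipse with low-frequency radial wobble."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    wobble = np.ones_like(theta)
    for harmonic in (2, 3, 5):
        wobble += (roughness / harmonic) * (
            rng.normal() * np.cos(harmonic * theta)
            + rng.normal() * np.sin(harmonic * theta)
        )
    wobble = np.clip(wobble, 0.55, 1.45)
    phase = rng.uniform(0, 2 * np.pi)
    xs = cx + rx * wobble * np.cos(theta + phase)
    ys = cy + ry * wobble * np.sin(theta + phase)
    return np.column_stack([xs, ys])


def _sample_band(rng, targets):
    return int(rng.choice(3, p=np.asarray(targets, dtype=float)))


def _band_ratio_range(band):
    # feasible relative-size windows inside each band (large capped so a
    # few objects still fit in one image)
    return [
        (0.012, SIZE_SMALL_MAX * 0.9),
        (SIZE_SMALL_MAX * 1.15, SIZE_MEDIUM_MAX * 0.92),
        (SIZE_MEDIUM_MAX * 1.1, 0.34),
    ][band]


def _band_of(pixels, image_pixels):
    r = pixels / image_pixels
    if r < SIZE_SMALL_MAX:
        return 0
    if r <= SIZE_MEDIUM_MAX:
        return 1
    return 2


def generate(config):
    """Generate a dataset per the config; deterministic for a given seed.

    Every image draws its class count from the configured distribution,
    samples a size band per object from the band targets and places
    non-overlapping blobs until each object's *painted* pixel count falls
    in its intended band (so corpus statistics recover the targets).
    Raises GenerationError when a composition cannot be placed within the
    retry budget.
    """
    config = config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    image_px = h * w
    label_map = default_label_map()
    # extend or trim to n_classes food classes
    names = list(label_map)[1 : config.n_classes + 1]
    while len(names) < config.n_classes:
        names.append(f"class_{len(names) + 1}")
    label_map = {"background": 0}
    for i, n in enumerate(names, start=1):
        label_map[n] = i

    from .dataio import _fill_polygon

    def try_build_image(idx, n_obj, bands):
        """One attempt at composing an image; None when placement fails.

        Objects are placed strictly non-overlapping so every region's
        bookkeeping pixel count stays exact under painter's order.  The
        object count and the size bands are decided by the caller and
        held fixed across retries, so the classes-per-image and size-band
        distributions stay unbiased; larger objects are placed first to
        make packing reliable.
        """
        class_ids = rng.choice(config.n_classes, size=min(n_obj, config.n_classes),
                               replace=False) + 1
        ann = AnnotationSet(image_id=f"synth_{idx:05d}.png", width=w, height=h)
        mask = np.zeros((h, w), dtype=np.int32)
        records = []
        for cid, band in zip(class_ids, sorted(bands, reverse=True)):
            for attempt in range(config.max_attempts):
                lo, hi = _band_ratio_range(band)
                ratio = rng.uniform(lo, hi)
                area = ratio * image_px
                aspect = rng.uniform(0.7, 1.4)
                rx = np.sqrt(area / np.pi * aspect)
                ry = np.sqrt(area / np.pi / aspect)
                if 2 * rx > 0.95 * w or 2 * ry > 0.95 * h:
                    continue
                # early attempts keep blobs interior; later ones may hang
                # off the border (clipped), which lets several big objects
                # share one image — the painted-pixel band check below
                # still guarantees the intended size band
                margin = 1.05 if attempt < config.max_attempts // 2 else 0.25
                if rx * margin * 2 > w or ry * margin * 2 > h:
                    continue
                cx = rng.uniform(rx * margin, w - rx * margin)
                cy = rng.uniform(ry * margin, h - ry * margin)
                poly = _blob_polygon(rng, cx, cy, rx, ry)
                poly = np.clip(poly, [0.0, 0.0], [float(w), float(h)])
                trial = mask.copy()
                painted = _fill_polygon(trial, poly, int(cid))
                if painted == 0:
                    continue
                if int(((mask != 0) & (trial == cid)).sum()):
                    continue  # overlaps an earlier object
                if _band_of(painted, image_px) != band:
                    continue
                mask = trial
                ann.regions.append(Region(poly, int(cid), names[cid - 1]))
                records.append(
                    {
                        "class_id": int(cid),
                        "class_name": names[cid - 1],
                        "pixels": painted,
                        "band": ["small", "medium", "large"][band],
                    }
                )
                break
            else:
                return None
        return ann, mask, records

    images, annotations, masks, truth = [], [], [], []
    cpi_probs = np.asarray(config.classes_per_image_distribution, dtype=float)
    for idx in range(config.n_images):
        built = None
        n_obj = int(rng.choice(len(cpi_probs), p=cpi_probs)) + 1
        n_placed = min(n_obj, config.n_classes)
        # at most two large objects fit one image without overlap (three
        # would exceed ~60% of the area); re-draw infeasible band vectors
        for _ in range(20):
            bands = [_sample_band(rng, config.size_band_targets) for _ in range(n_placed)]
            if sum(b == 2 for b in bands) <= 2:
                break
        else:
            raise GenerationError(
                f"could not draw a feasible size-band combination for "
                f"{n_placed} objects within the retry budget; the size "
                "targets are infeasible (too many large objects per image)"
            )
        for _ in range(8):  # whole-image retries with fresh positions
            built = try_build_image(idx, n_obj, bands)
            if built is not None:
                break
        if built is None:
            raise GenerationError(
                f"could not compose image {idx} within the retry budget; "
                "the class-count / size-band targets may be infeasible "
                f"for image size {h}x{w}"
            )
        ann, mask, records = built
        # render
        img = np.empty((h, w, 3), dtype=np.float32)
        img[...] = _CLASS_COLORS[0]
        for cid in np.unique(mask):
            if cid == 0:
                continue
            img[mask == cid] = _CLASS_COLORS[int(cid) % len(_CLASS_COLORS)]
        if config.texture == "noise":
            img += rng.normal(0.0, config.noise_level, img.shape)
        images.append(np.clip(img, 0, 255).astype(np.uint8))
        annotations.append(ann)
        masks.append(mask)
        truth.append(records)

    return SynthDataset(images, annotations, masks, truth, config, label_map)


def write_dataset(dataset, root):
    """Write a dataset directory: images/, masks/, annotations.json,
    labelmap.yaml and truth.json."""
    import json
    import os

    from PIL import Image

    os.makedirs(os.path.join(root, "images"), exist_ok=True)
    os.makedirs(os.path.join(root, "masks"), exist_ok=True)
    for img, ann, mask in zip(dataset.images, dataset.annotations, dataset.masks):
        Image.fromarray(img).save(os.path.join(root, "images", ann.image_id))
        save_mask_png(mask, os.path.join(root, "masks", ann.image_id))
    write_via(dataset.annotations, os.path.join(root, "annotations.json"))
    save_label_map(dataset.label_map, os.path.join(root, "labelmap.yaml"))
    with open(os.path.join(root, "truth.json"), "w") as fh:
        json.dump(
            [
                {"image": ann.image_id, "regions": recs}
                for ann, recs in zip(dataset.annotations, dataset.truth)
            ],
            fh,
            indent=1,
        )
    return root
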