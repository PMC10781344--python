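"""Training, evaluation and prediction for the segmentation network.

The training recipe follows the study configuration: Adam with an initial
learning rate of 1e-4, categorical cross-entropy over softmaxed logits,
and a reduce-on-plateau schedule monitoring validation loss (patience 25,
factor 0.8, floor 1e-7), for 250 epochs at 512x512 by default.  Runs are
exactly reproducible from (config, seed) on CPU.

A compact fixed-step driver (``train_steps``) supports overfit-sanity
experiments at desk scale: a handful of synthetic images, a few hundred
optimizer steps, training mIoU evaluated with batch statistics.
"""

from __future__ import annotations

import csv
import json
import os
import platform
from dataclasses import dataclass, asdict

import numpy as np

from . import _engine as eng
from ._engine import Adam, Tensor, set_training, softmax_cross_entropy
from .backbone import preprocess_images
from .metrics import (ConfusionMatrix, accumulate, logits_to_mask, mean_iou,
                      mean_pixel_accuracy, metrics_report)
from .network import MidDeepLabV3Plus, NetworkConfig

__all__ = ["TrainConfig", "PlateauScheduler", "train", "train_steps",
           "evaluate", "predict_mask", "load_dataset_dir"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 250
    batch_size: int = 4
    input_size: tuple = (512, 512)
    patience: int = 25
    factor: float = 0.8
    min_lr: float = 1e-7
    seed: int = 0
    checkpoint_path: str = "checkpoint.npz"
    history_path: str = "history.csv"

    def validate(self):
        if not 0.0 < self.factor < 1.0:
            raise ValueError("plateau factor must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        return self


class PlateauScheduler:
    """Reduce-on-plateau: multiply lr by ``factor`` after ``patience``
    epochs without improvement of the monitored loss."""

    def __init__(self, optimizer, patience=25, factor=0.8, min_lr=1e-7):
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.wait = 0
        self.reductions = 0

    def step(self, monitored_loss):
        """Record one epoch's monitored loss; returns the current lr."""
        if monitored_loss < self.best - 1e-12:
            self.best = monitored_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                new_lr = max(self.optimizer.lr * self.factor, self.min_lr)
                if new_lr < self.optimizer.lr:
                    self.reductions += 1
                self.optimizer.lr = new_lr
                self.wait = 0
        return self.optimizer.lr


def load_dataset_dir(root, num_classes, input_size=None):
    """Load (images, masks) from a dataset directory.

    Accepts either pre-rendered ``masks/`` indexed PNGs or a VIA
    ``annotations.json`` + ``labelmap.yaml`` pair (rasterized on load).
    Validates emptiness, mask/image size agreement and label range
    before any training starts.
    """
    from PIL import Image

    from .dataio import load_label_map, load_mask_png, parse_via, rasterize

    img_dir = os.path.join(root, "images")
    if not os.path.isdir(img_dir):
        raise FileNotFoundError(f"no images/ directory under {root}")
    names = sorted(f for f in os.listdir(img_dir) if f.lower().endswith((".png", ".jpg", ".jpeg")))
    if not names:
        raise ValueError(f"dataset at {root} contains no images")

    mask_dir = os.path.join(root, "masks")
    ann_path = os.path.join(root, "annotations.json")
    anns = None
    if not os.path.isdir(mask_dir):
        if not os.path.exists(ann_path):
            raise FileNotFoundError(f"{root} has neither masks/ nor annotations.json")
        label_map = load_label_map(os.path.join(root, "labelmap.yaml"))
        sets, _ = parse_via(ann_path, label_map)
        anns = {a.image_id: a for a in sets}

    images, masks = [], []
    for name in names:
        img = np.asarray(Image.open(os.path.join(img_dir, name)).convert("RGB"))
        if anns is None:
            mask = load_mask_png(os.path.join(mask_dir, name))
        else:
            if name not in anns:
                raise ValueError(f"no annotation for image {name}")
            a = anns[name]
            mask = rasterize(a, num_classes, size=(img.shape[0], img.shape[1]))
        if mask.shape != img.shape[:2]:
            raise ValueError(
                f"mask/image size mismatch for {name}: {mask.shape} vs {img.shape[:2]}"
            )
        if mask.max() >= num_classes:
            raise ValueError(
                f"mask {name} holds class id {int(mask.max())} >= num_classes={num_classes}"
            )
        if input_size is not None and img.shape[:2] != tuple(input_size):
            raise ValueError(
                f"image {name} is {img.shape[:2]}, expected {tuple(input_size)}"
            )
        images.append(img)
        masks.append(mask)
    return np.stack(images), np.stack(masks)


def _epoch_pass(model, images, masks, batch_size, optimizer=None, rng=None):
    """One pass over the data; trains when an optimizer is given.

    Returns (mean loss, mIoU, mPA) accumulated over the pass.
    """
    n = len(images)
    order = np.arange(n) if rng is None else rng.permutation(n)
    cm = ConfusionMatrix(model.config.num_classes)
    losses = []
    training = optimizer is not None
    set_training(model, training)
    for start in range(0, n, batch_size):
        sel = order[start : start + batch_size]
        batch = preprocess_images(images[sel])
        labels = masks[sel]
        if training:
            logits = model(Tensor(batch))
            loss = softmax_cross_entropy(logits, labels)
            loss.backward()
            optimizer.step()
            model.zero_grad()
        else:
            with eng.no_grad():
                logits = model(Tensor(batch))
                loss = softmax_cross_entropy(logits, labels)
        losses.append(float(loss.data))
        accumulate(logits_to_mask(logits.data), labels, cm)
    return float(np.mean(losses)), mean_iou(cm), mean_pixel_accuracy(cm)


def train(net_config, train_config, dataset_dir, val_dir=None, verbose=True):
    """Full training run; returns (model, history list of dict rows).

    The learning rate drops only after ``patience`` epochs without
    validation-loss improvement, by exactly ``factor``; the best
    checkpoint (validation loss) is kept at ``checkpoint_path``.
    """
    net_config = (net_config or NetworkConfig()).validate()
    tc = (train_config or TrainConfig()).validate()
    images, masks = load_dataset_dir(dataset_dir, net_config.num_classes,
                                     input_size=tc.input_size)
    if val_dir is not None:
        val_images, val_masks = load_dataset_dir(val_dir, net_config.num_classes,
                                                 input_size=tc.input_size)
    else:
        val_images, val_masks = images, masks

    rng = np.random.default_rng(tc.seed)
    model = MidDeepLabV3Plus(net_config)
    optimizer = Adam(model.parameters(), lr=tc.learning_rate)
    sched = PlateauScheduler(optimizer, tc.patience, tc.factor, tc.min_lr)

    run_log = {
        "network_config": net_config.to_dict(),
        "train_config": asdict(tc),
        "seed": tc.seed,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    if verbose:
        print(json.dumps(run_log, indent=2, default=str))

    history = []
    best_val = np.inf
    for epoch in range(1, tc.epochs + 1):
        tr_loss, tr_miou, tr_mpa = _epoch_pass(
            model, images, masks, tc.batch_size, optimizer=optimizer, rng=rng
        )
        val_loss, val_miou, val_mpa = _epoch_pass(
            model, val_images, val_masks, tc.batch_size
        )
        lr_now = sched.step(val_loss)
        row = {
            "epoch": epoch, "lr": lr_now,
            "train_loss": tr_loss, "train_miou": tr_miou, "train_mpa": tr_mpa,
            "val_loss": val_loss, "val_miou": val_miou, "val_mpa": val_mpa,
        }
        history.append(row)
        if verbose:
            print(
                f"epoch {epoch:4d}  loss {tr_loss:.4f}  mIoU {tr_miou:.4f}  "
                f"val_loss {val_loss:.4f}  val_mIoU {val_miou:.4f}  lr {lr_now:.2e}"
            )
        if val_loss < best_val:
            best_val = val_loss
            model.save(tc.checkpoint_path)
    if tc.history_path:
        with open(tc.history_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0]))
            writer.writeheader()
            writer.writerows(history)
    return model, history


def train_steps(model, images, masks, steps=300, lr=1e-3, batch_size=4, seed=0,
                log_every=0):
    """Fixed-step overfit driver on in-memory arrays.

    Runs ``steps`` Adam updates over shuffled mini-batches, then reports
    the training mIoU of the final model computed with batch statistics
    (the regime the updates themselves saw).  Returns (final_miou,
    loss_history).
    """
    images = np.asarray(images)
    masks = np.asarray(masks)
    rng = np.random.default_rng(seed)
    optimizer = Adam(model.parameters(), lr=lr)
    batch = preprocess_images(images)
    n = len(images)
    losses = []
    set_training(model, True)
    for step in range(steps):
        sel = rng.choice(n, size=min(batch_size, n), replace=False)
        logits = model(Tensor(batch[sel]))
        loss = softmax_cross_entropy(logits, masks[sel])
        loss.backward()
        optimizer.step()
        model.zero_grad()
        losses.append(float(loss.data))
        if log_every and (step + 1) % log_every == 0:
            print(f"step {step + 1:4d}  loss {losses[-1]:.4f}")
    # training mIoU: one batch-statistics pass over the full training set
    cm = ConfusionMatrix(model.config.num_classes)
    set_training(model, True)
    with eng.no_grad():
        logits = model(Tensor(batch))
    accumulate(logits_to_mask(logits.data), masks, cm)
    set_training(model, False)
    return mean_iou(cm), losses


def evaluate(model, images, masks, batch_size=2, class_names=None,
             ignore_background=False):
    """Stream the confusion matrix over a dataset; returns the report."""
    images = np.asarray(images)
    masks = np.asarray(masks)
    cm = ConfusionMatrix(model.config.num_classes)
    set_training(model, False)
    losses = []
    for start in range(0, len(images), batch_size):
        batch = preprocess_images(images[start : start + batch_size])
        with eng.no_grad():
            logits = model(Tensor(batch))
            losses.append(
                float(softmax_cross_entropy(logits, masks[start : start + batch_size]).data)
            )
        accumulate(logits_to_mask(logits.data), masks[start : start + batch_size], cm)
    report = metrics_report(cm, class_names=class_names,
                            ignore_background=ignore_background)
    report["loss"] = float(np.mean(losses))
    return report


def predict_mask(model, image):
    """Predict the label mask of a single RGB image."""
    arr = np.asarray(image)
    if arr.ndim != 3:
        raise ValueError("expected one (H, W, 3) image")
    return model.predict(arr[None])[0]
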