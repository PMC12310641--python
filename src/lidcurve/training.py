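"""Training loop, augmentation, compound loss and mask inference.

The loss is, per enabled head, binary cross-entropy plus soft-Dice
(1 - 2*sum(p*t)/(sum(p)+sum(t))), summed over heads.  Augmentation
applies one identical spatial transform (random crop resized back,
horizontal/vertical flips) to the image and both masks; masks stay
binary (nearest-neighbour resampling).  Inference thresholds the
probability maps, keeps the largest 4-connected component and fills
interior holes, since the measurement stage requires one simply
connected region per class.
"""
from __future__ import annotations

import copy
import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .network import AtDUNet, NetConfig, build_network
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.modules import Adam
from . import synth

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 2
    learning_rate: float = 1e-3
    seed: int = 0
    augment_crop: bool = True
    augment_hflip: bool = True
    augment_vflip: bool = True
    crop_fraction: float = 0.85
    threshold: float = 0.5

    def validate(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if not (0.5 < self.crop_fraction <= 1.0):
            raise ValueError("crop_fraction must lie in (0.5, 1]")


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

def augment_pair(image: np.ndarray, masks: tuple[np.ndarray, np.ndarray],
                 rng: np.random.Generator, tc: TrainConfig
                 ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """One identical random spatial transform for image and both masks."""
    fissure, cornea = masks
    if image.shape[:2] != fissure.shape or fissure.shape != cornea.shape:
        raise ValueError("image and masks must share spatial size")
    h, w = fissure.shape
    if tc.augment_crop and tc.crop_fraction < 1.0:
        ch = max(int(round(h * tc.crop_fraction)), 1)
        cw = max(int(round(w * tc.crop_fraction)), 1)
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        image = image[r0:r0 + ch, c0:c0 + cw]
        fissure = fissure[r0:r0 + ch, c0:c0 + cw]
        cornea = cornea[r0:r0 + ch, c0:c0 + cw]
        image = resize(image, (h, w), order=1, preserve_range=True,
                       anti_aliasing=False).astype(image.dtype)
        fissure = resize(fissure.astype(np.uint8), (h, w), order=0,
                         preserve_range=True).astype(bool)
        cornea = resize(cornea.astype(np.uint8), (h, w), order=0,
                        preserve_range=True).astype(bool)
    if tc.augment_hflip and rng.random() < 0.5:
        image = image[:, ::-1].copy()
        fissure = fissure[:, ::-1].copy()
        cornea = cornea[:, ::-1].copy()
    if tc.augment_vflip and rng.random() < 0.5:
        image = image[::-1].copy()
        fissure = fissure[::-1].copy()
        cornea = cornea[::-1].copy()
    return image, (fissure, cornea)


# ---------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------

_EPS = 1e-6


def _bce_dice(pred: Tensor, target: np.ndarray) -> Tensor:
    t = Tensor(target.astype(np.float32))
    p = ag.clamp(pred, _EPS, 1.0 - _EPS)
    bce = -ag.tmean(t * ag.log(p) + (1.0 - t) * ag.log(1.0 - p))
    inter = ag.tsum(p * t)
    soft_dice = (2.0 * inter + _EPS) * 1.0
    denom = ag.tsum(p) + ag.tsum(t) + _EPS
    # soft dice as product with reciprocal of the (scalar) denominator
    dice = mul_scalar_div(soft_dice, denom)
    return bce + (1.0 - dice)


def mul_scalar_div(num: Tensor, den: Tensor) -> Tensor:
    """num / den for scalar tensors, with gradients to both."""
    data = num.data / den.data

    def backward(g):
        if num.requires_grad:
            num._accum(g / den.data)
        if den.requires_grad:
            den._accum(-g * num.data / den.data ** 2)

    return ag._make(data, (num, den), backward)


def compound_loss(pred_pair: dict[str, Tensor],
                  target_pair: dict[str, np.ndarray]) -> Tensor:
    """Sum over enabled heads of BCE + (1 - soft Dice)."""
    if set(pred_pair) != set(target_pair):
        raise ValueError("prediction and target heads differ")
    total = None
    for head in sorted(pred_pair):
        if pred_pair[head].shape != target_pair[head].shape:
            raise ValueError(f"shape mismatch for head {head!r}")
        term = _bce_dice(pred_pair[head], target_pair[head])
        total = term if total is None else total + term
    return total


# ---------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------

def prepare_sample(image: np.ndarray, fissure: np.ndarray, cornea: np.ndarray,
                   size: tuple[int, int]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resize to the network input size: image bilinear, masks nearest."""
    h, w = size
    img = resize(image, (h, w), order=1, preserve_range=True,
                 anti_aliasing=True).astype(np.float32) / 255.0
    fis = resize(fissure.astype(np.uint8), (h, w), order=0,
                 preserve_range=True).astype(bool)
    cor = resize(cornea.astype(np.uint8), (h, w), order=0,
                 preserve_range=True).astype(bool)
    return img, fis, cor


def load_split(manifest: dict, split: str, size: tuple[int, int]) -> list[dict]:
    out = []
    for sid in manifest[split]:
        img, fis, cor, _ = synth.load_sample(manifest, sid)
        img, fis, cor = prepare_sample(img, fis, cor, size)
        out.append({"id": sid, "image": img, "fissure": fis, "cornea": cor})
    return out


# ---------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------

def _dice_np(pred: np.ndarray, true: np.ndarray) -> float:
    inter = np.count_nonzero(pred & true)
    s = np.count_nonzero(pred) + np.count_nonzero(true)
    return 1.0 if s == 0 else 2.0 * inter / s


def _iou_np(pred: np.ndarray, true: np.ndarray) -> float:
    inter = np.count_nonzero(pred & true)
    union = np.count_nonzero(pred | true)
    return 1.0 if union == 0 else inter / union


def evaluate(net: AtDUNet, samples: list[dict], threshold: float = 0.5
             ) -> dict[str, float]:
    """Mean IoU/Dice per head over raw thresholded probability maps."""
    heads = tuple(net.cfg.heads_enabled)
    acc = {f"{h}_{k}": [] for h in heads for k in ("iou", "dice")}
    with ag.no_grad():
        for s in samples:
            x = Tensor(s["image"].transpose(2, 0, 1)[None])
            out = net.forward(x)
            for h in heads:
                pred = out[h].data[0, 0] >= threshold
                acc[f"{h}_iou"].append(_iou_np(pred, s[h]))
                acc[f"{h}_dice"].append(_dice_np(pred, s[h]))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def fit_network(net: AtDUNet, manifest: dict, tc: TrainConfig,
                preloaded: dict[str, dict] | None = None
                ) -> tuple[AtDUNet, list[dict]]:
    """Seeded training loop; returns the net restored to the best-Dice
    epoch's weights and a per-epoch log.

    ``preloaded`` optionally maps sample ids to already-prepared samples
    (dicts with "image"/"fissure"/"cornea" at the network input size),
    bypassing the manifest file round trip.
    """
    tc.validate()
    if not manifest["train"] or not manifest["test"]:
        raise ValueError("manifest must contain a nonempty train and test split")
    size = net.cfg.input_size
    if preloaded is None:
        train = load_split(manifest, "train", size)
        test = load_split(manifest, "test", size)
    else:
        train = [preloaded[sid] for sid in manifest["train"]]
        test = [preloaded[sid] for sid in manifest["test"]]
    heads = tuple(net.cfg.heads_enabled)
    rng = np.random.default_rng(tc.seed)
    opt = Adam(net.parameters(), lr=tc.learning_rate)

    log: list[dict] = []
    best_dice, best_state = -1.0, None
    for epoch in range(tc.epochs):
        order = rng.permutation(len(train))
        losses = []
        for start in range(0, len(order), tc.batch_size):
            batch = [train[i] for i in order[start:start + tc.batch_size]]
            imgs, targets = [], {h: [] for h in heads}
            for s in batch:
                img, (fis, cor) = augment_pair(s["image"], (s["fissure"], s["cornea"]),
                                               rng, tc)
                imgs.append(img.transpose(2, 0, 1))
                pair = {"fissure": fis, "cornea": cor}
                for h in heads:
                    targets[h].append(pair[h][None])
            x = Tensor(np.stack(imgs))
            out = net.forward(x)
            loss = compound_loss(out, {h: np.stack(targets[h]) for h in heads})
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        scores = evaluate(net, test, tc.threshold)
        mean_dice = float(np.mean([scores[f"{h}_dice"] for h in heads]))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "test_mean_dice": mean_dice, **scores}
        log.append(entry)
        if mean_dice > best_dice:
            best_dice = mean_dice
            best_state = net.state_dict()
    if best_state is not None:
        net.load_state_dict(best_state)
    return net, log


# ---------------------------------------------------------------------
# inference post-processing
# ---------------------------------------------------------------------

def clean_mask(binary: np.ndarray) -> np.ndarray:
    """Largest 4-connected component with interior holes filled; the empty
    mask passes through as the all-background sentinel."""
    binary = np.asarray(binary, bool)
    if not binary.any():
        return binary
    labels, ncomp = ndimage.label(binary, structure=_CROSS)
    if ncomp > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, ncomp + 1))
        binary = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(binary)


def infer_masks(net: AtDUNet, image: np.ndarray, threshold: float = 0.5
                ) -> dict[str, np.ndarray]:
    """Probability maps -> clean binary masks per enabled head.

    An all-background prediction is returned as an empty mask with a
    warning; downstream measurement refuses empty masks.
    """
    x = image.astype(np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    with ag.no_grad():
        out = net.forward(Tensor(x.transpose(2, 0, 1)[None]))
    result = {}
    for head, prob in out.items():
        mask = clean_mask(prob.data[0, 0] >= threshold)
        if not mask.any():
            warnings.warn(f"empty {head} mask predicted", RuntimeWarning)
        result[head] = mask
    return result


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(net: AtDUNet, path: str | Path,
                    log: list[dict] | None = None) -> None:
    payload = {"config": net.cfg.to_dict(), "state": net.state_dict(),
               "log": log or []}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path: str | Path) -> tuple[AtDUNet, list[dict]]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cfg = NetConfig.from_dict(payload["config"])
    net = build_network(cfg)
    net.load_state_dict(payload["state"])
    return net, payload["log"]
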