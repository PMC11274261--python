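"""Offline, class-ratio-correcting data augmentation.

The raw cohort is imbalanced (~1:8 difficult to non-difficult).  Each
positive subject is expanded to ``pos_multiplier`` samples (the original plus
multiplier - 1 transformed copies) and each negative to ``neg_multiplier``
samples, giving 400 positive / 800 negative samples (a 1:2 ratio) at the
default 16/4 multipliers on a 25/200 cohort.

One composite transform is drawn per record per copy: horizontal flip,
brightness/contrast/saturation jitter and a rotation in [-15, +15] degrees
are drawn ONCE per view group (frontal, lateral) and applied to every view in
the group — the network stacks views channel-wise, so independently rotated
views would destroy the cross-view correspondence the consistency loss relies
on (``share_within_group=False`` restores fully independent draws).  Random
erasing (a rectangle refilled with uniform noise) is drawn per image.
Augmented samples carry ids ``<orig>__augK`` and remember their source
subject so cross-validation can keep all copies of a subject on one side of
the split.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

from .data_io import _load_pixels, save_manifest
from .types import CohortManifest, MultiViewRecord, ViewRole


@dataclass
class AugmentPolicy:
    pos_multiplier: int = 16
    neg_multiplier: int = 4
    hflip_prob: float = 0.5
    jitter_range: float = 0.2          # +-20% brightness/contrast/saturation
    rotation_range: float = 15.0       # degrees, symmetric
    erase_area: tuple[float, float] = (0.02, 0.2)
    erase_prob: float = 0.5
    share_within_group: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.pos_multiplier < 1 or self.neg_multiplier < 1:
            raise ValueError("multipliers must be >= 1")
        if not (0.0 <= self.hflip_prob <= 1.0 and 0.0 <= self.erase_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be non-negative (symmetric)")


# ---------------------------------------------------------------------------
# single-image transforms on H x W x 3 float arrays in [0, 1]
# ---------------------------------------------------------------------------

def _color_jitter(img, brightness, contrast, saturation):
    img = img * brightness
    gray = img.mean(axis=2, keepdims=True)
    img = (img - gray.mean()) * contrast + gray.mean()
    img = gray + (img - gray) * saturation
    return img


def _rotate(img, angle):
    if angle == 0.0:
        return img
    return ndimage.rotate(img, angle, axes=(1, 0), reshape=False, order=1, mode="nearest")


def _erase(img, rng, area_range):
    h, w = img.shape[:2]
    for _ in range(10):
        frac = rng.uniform(*area_range)
        aspect = np.exp(rng.uniform(np.log(0.3), np.log(1 / 0.3)))
        eh = int(round(np.sqrt(frac * h * w * aspect)))
        ew = int(round(np.sqrt(frac * h * w / aspect)))
        if 0 < eh <= h and 0 < ew <= w:
            y0 = rng.integers(0, h - eh + 1)
            x0 = rng.integers(0, w - ew + 1)
            img = img.copy()
            img[y0:y0 + eh, x0:x0 + ew] = rng.random((eh, ew, 1))
            return img
    return img


@dataclass
class _GroupDraw:
    flip: bool
    angle: float
    brightness: float
    contrast: float
    saturation: float


def _draw(policy: AugmentPolicy, rng: np.random.Generator) -> _GroupDraw:
    lo, hi = 1.0 - policy.jitter_range, 1.0 + policy.jitter_range
    return _GroupDraw(
        flip=bool(rng.random() < policy.hflip_prob),
        angle=float(rng.uniform(-policy.rotation_range, policy.rotation_range)),
        brightness=float(rng.uniform(lo, hi)),
        contrast=float(rng.uniform(lo, hi)),
        saturation=float(rng.uniform(lo, hi)),
    )


def random_transform(images: dict[ViewRole, np.ndarray], policy: AugmentPolicy,
                     rng: np.random.Generator) -> dict[ViewRole, np.ndarray]:
    """Apply one sampled composite transform to a record's five views."""
    draws: dict[ViewRole, _GroupDraw] = {}
    if policy.share_within_group:
        front = _draw(policy, rng)
        side = _draw(policy, rng)
        for r in ViewRole.frontal():
            draws[r] = front
        for r in ViewRole.lateral():
            draws[r] = side
    else:
        for r in ViewRole.ordered():
            draws[r] = _draw(policy, rng)
    out = {}
    for role in ViewRole.ordered():
        img = _load_pixels(images[role])
        d = draws[role]
        if d.flip:
            img = img[:, ::-1]
        img = _color_jitter(img, d.brightness, d.contrast, d.saturation)
        img = _rotate(img, d.angle)
        if policy.erase_prob > 0 and rng.random() < policy.erase_prob:
            img = _erase(img, rng, policy.erase_area)
        out[role] = np.clip(img, 0.0, 1.0).astype(np.float32)
    return out


def _identity_policy(policy: AugmentPolicy) -> bool:
    return (policy.hflip_prob == 0 and policy.jitter_range == 0
            and policy.rotation_range == 0 and policy.erase_prob == 0)


def augment_offline(manifest: CohortManifest, policy: AugmentPolicy,
                    out_dir: str | None = None) -> CohortManifest:
    """Expand a cohort by the class multipliers.

    With ``out_dir`` the transformed images are written as PNGs and a
    manifest CSV is saved there; otherwise images stay in memory as arrays.
    Deterministic under ``policy.seed``.
    """
    root = np.random.SeedSequence(policy.seed)
    streams = root.spawn(len(manifest.records))
    new_records: list[MultiViewRecord] = []
    img_dir = None
    if out_dir is not None:
        img_dir = os.path.join(out_dir, "images")
        os.makedirs(img_dir, exist_ok=True)
    for rec, stream in zip(manifest.records, streams):
        rng = np.random.default_rng(stream)
        mult = policy.pos_multiplier if rec.label == 1 else policy.neg_multiplier
        new_records.append(rec)
        for k in range(1, mult):
            sid = f"{rec.subject_id}__aug{k}"
            imgs = random_transform(rec.images, policy, rng)
            if img_dir is not None:
                paths = {}
                for role, img in imgs.items():
                    fpath = os.path.join(img_dir, f"{sid}_{role.value}.png")
                    Image.fromarray((img * 255).round().astype(np.uint8)).save(fpath)
                    paths[role] = fpath
                images: dict = paths
            else:
                images = dict(imgs)
            new_records.append(MultiViewRecord(
                subject_id=sid, label=rec.label, images=images,
                crop_boxes=dict(rec.crop_boxes) if rec.crop_boxes else None,
                source_id=rec.subject_id))
    out = CohortManifest(records=new_records, provenance="augmented")
    if out_dir is not None:
        try:
            save_manifest(out, os.path.join(out_dir, "manifest.csv"))
        except ValueError:
            pass  # source records may be in-memory arrays; skip the CSV
    return out
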