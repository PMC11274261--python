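"""Synthetic multi-view face-phantom cohorts.

Clinical difficult-airway photographs cannot be shared, so this module
generates geometrically controlled stand-ins with the statistical structure
the network and its losses assume.  Each subject is a latent parameter vector
(mouth opening, thyromental distance, neck extension, facial height/width
ratio) rendered consistently into the five standard views:

* frontal views show the face ellipse, eyes and nose; the open-mouth and
  tongue-protruding views render a dark mouth aperture whose height is
  proportional to the latent mouth opening (the tongue view adds a tongue
  blob);
* lateral views show a profile with a dark chin-to-thyroid segment whose
  length is proportional to the thyromental distance, pitched by the neck
  extension angle (the chin-lift view adds a fixed extension increment).

Class signal: difficult subjects have smaller mouth opening, shorter
thyromental distance, smaller neck extension and a larger facial ratio, each
shifted by ``class_separation`` pooled standard deviations.  By construction
the mouth aperture is visible only frontally and the thyromental segment only
laterally (complementary information), while all five views of a subject are
driven by one latent vector (consistent information).  Per-view pixel jitter
and seeded Gaussian background texture provide nuisance variation.  Pixel
realism is deliberately out of scope; geometric control is what makes oracle
tests possible.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .types import CohortManifest, MultiViewRecord, ViewRole

# latent feature means/SDs (lengths as fractions of image size, angle in deg);
# the sign of the class shift follows clinical direction: difficult airways
# have smaller mouth opening / thyromental distance / neck extension and a
# larger facial ratio.
_FEATURES = {
    "mouth_opening": (0.20, 0.04, -1.0),
    "thyromental_distance": (0.26, 0.05, -1.0),
    "neck_extension": (25.0, 6.0, -1.0),
    "facial_ratio": (1.30, 0.08, +1.0),
}


@dataclass
class PhantomParams:
    mouth_opening: float
    thyromental_distance: float
    neck_extension: float
    facial_ratio: float
    skin_tone: float
    per_view_jitter: tuple[tuple[float, float, float], ...]  # (dx, dy, rot deg) x5

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _FEATURES}
        d["skin_tone"] = self.skin_tone
        return d


@dataclass
class CohortSpec:
    n_pos: int = 25
    n_neg: int = 200
    seed: int = 0
    class_separation: float = 1.5
    noise_sd: float = 0.05
    image_size: int = 224
    jitter_px: float = 2.0     # SD of per-view translation at 224 px scale
    jitter_deg: float = 2.0    # SD of per-view rotation

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")


def sample_subject(label: int, spec: CohortSpec, rng: np.random.Generator) -> PhantomParams:
    """Draw latent phantom geometry from the class-conditional Gaussians."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    values = {}
    for name, (mean, sd, direction) in _FEATURES.items():
        mu = mean + direction * spec.class_separation * sd if label == 1 else mean
        v = rng.normal(mu, sd)
        values[name] = max(v, 1e-3) if name != "facial_ratio" else max(v, 0.5)
    skin = rng.uniform(0.6, 0.9)
    jit = tuple(
        (float(np.clip(rng.normal(0, spec.jitter_px), -3 * spec.jitter_px, 3 * spec.jitter_px)),
         float(np.clip(rng.normal(0, spec.jitter_px), -3 * spec.jitter_px, 3 * spec.jitter_px)),
         float(np.clip(rng.normal(0, spec.jitter_deg), -3 * spec.jitter_deg, 3 * spec.jitter_deg)))
        for _ in range(5))
    return PhantomParams(values["mouth_opening"], values["thyromental_distance"],
                         values["neck_extension"], values["facial_ratio"], skin, jit)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _grids(size: int, jitter, scale: float):
    """Image coordinate grids, rotated/translated by the per-view jitter,
    in units where the face centre is the origin."""
    dx, dy, rot = jitter
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    cx = size / 2 + dx * scale
    cy = size / 2 + dy * scale
    th = np.deg2rad(rot)
    xr = np.cos(th) * (x - cx) - np.sin(th) * (y - cy)
    yr = np.sin(th) * (x - cx) + np.cos(th) * (y - cy)
    return xr, yr


def _ellipse(xr, yr, x0, y0, a, b):
    return ((xr - x0) / a) ** 2 + ((yr - y0) / b) ** 2 <= 1.0


def render_views(params: PhantomParams, spec: CohortSpec) -> dict[ViewRole, np.ndarray]:
    """Deterministically render the five views as ``image_size`` square
    grayscale images with values in [0, 1]."""
    s = spec.image_size
    scale = s / 224.0
    # background texture is shared across the cohort (keyed on the cohort
    # seed and view role only) — the same clinic backdrop behind every
    # subject.  It is independent of the latent geometry, so class features
    # perturb exactly the pixels they draw: mouth parameters leave lateral
    # views untouched and vice versa (complementarity by construction), and
    # the background carries no subject identity a classifier could memorise.
    key = np.array([float(spec.seed), spec.noise_sd, float(s)], dtype=np.float64)
    out: dict[ViewRole, np.ndarray] = {}
    for vi, role in enumerate(ViewRole.ordered()):
        rng_bg = np.random.default_rng(zlib.crc32(key.tobytes() + bytes([vi])))
        img = 0.30 + spec.noise_sd * rng_bg.standard_normal((s, s))
        xr, yr = _grids(s, params.per_view_jitter[vi], scale)
        face_w = 0.30 * s
        face_h = min(face_w * params.facial_ratio, 0.48 * s)
        if role in ViewRole.frontal():
            face = _ellipse(xr, yr, 0, 0, face_w, face_h)
            img[face] = params.skin_tone
            # eyes
            for ex in (-0.12 * s, 0.12 * s):
                img[_ellipse(xr, yr, ex, -0.15 * s, 0.05 * s, 0.025 * s)] = 0.15
            # nose
            img[_ellipse(xr, yr, 0, 0.02 * s, 0.02 * s, 0.07 * s)] = params.skin_tone * 0.8
            mouth_y = 0.22 * s
            if role == ViewRole.frontal_closed:
                img[_ellipse(xr, yr, 0, mouth_y, 0.10 * s, 0.008 * s)] = 0.2
            else:
                # aperture height scales 1:1 with the latent mouth opening so
                # the class shift stays discriminable at reduced resolutions
                aperture_h = params.mouth_opening * s
                mouth = _ellipse(xr, yr, 0, mouth_y, 0.11 * s, aperture_h / 2)
                img[mouth & face] = 0.05
                if role == ViewRole.frontal_tongue:
                    tongue = _ellipse(xr, yr, 0, mouth_y + aperture_h / 4,
                                      0.055 * s, aperture_h / 3 + 1.0)
                    img[tongue & face] = 0.55
        else:
            # profile: skull ellipse offset left, jaw, neck; pitch = neck
            # extension (+ fixed increment for the chin-lift view)
            pitch = params.neck_extension + (15.0 if role == ViewRole.lateral_chinlift else 0.0)
            th = np.deg2rad(pitch)
            img[_ellipse(xr, yr, -0.03 * s, -0.05 * s, 0.26 * s, 0.30 * s)] = params.skin_tone
            img[_ellipse(xr, yr, 0.14 * s, -0.12 * s, 0.05 * s, 0.025 * s)] = 0.15  # eye
            # chin point rotates forward/up with pitch
            chin = np.array([0.20 * s * np.cos(th) * 0.8, 0.22 * s - 0.10 * s * np.sin(th)])
            tmd = params.thyromental_distance * s
            thy = chin + tmd * np.array([-np.sin(th) * 0.3 - 0.15, np.cos(th) * 0.9])
            # thyromental segment: dark capsule from chin to thyroid notch
            seg = thy - chin
            seg_len = np.hypot(*seg) + 1e-9
            t = ((xr - chin[0]) * seg[0] + (yr - chin[1]) * seg[1]) / seg_len ** 2
            t = np.clip(t, 0, 1)
            px = chin[0] + t * seg[0]
            py = chin[1] + t * seg[1]
            dist = np.hypot(xr - px, yr - py)
            img[dist <= 0.015 * s + 1.0] = 0.08
            # neck column below
            img[(np.abs(xr + 0.05 * s) < 0.08 * s) & (yr > 0.26 * s)] = params.skin_tone * 0.95
        out[role] = np.clip(img, 0.0, 1.0).astype(np.float32)
    return out


def default_crop_boxes(spec: CohortSpec) -> dict[ViewRole, tuple[int, int, int, int]]:
    """Face-region crop rectangles (forehead to neck base, face edge to face
    edge, with a jitter margin) — the central-cropping step that strips most
    of the background texture before resizing."""
    s = spec.image_size
    frontal = (int(0.13 * s), int(0.01 * s), int(0.87 * s), s)
    lateral = (int(0.10 * s), int(0.05 * s), int(0.84 * s), s)
    return {r: (frontal if r in ViewRole.frontal() else lateral)
            for r in ViewRole.ordered()}


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _subject_stream(spec: CohortSpec):
    """Yield (subject_id, label, params) deterministically from the spec seed."""
    root = np.random.SeedSequence(spec.seed)
    n_total = spec.n_neg + spec.n_pos
    children = root.spawn(n_total)
    labels = [0] * spec.n_neg + [1] * spec.n_pos
    for i, (label, child) in enumerate(zip(labels, children)):
        sid = f"{'pos' if label else 'neg'}_{i:04d}"
        yield sid, label, sample_subject(label, spec, np.random.default_rng(child))


def generate_cohort_memory(spec: CohortSpec) -> tuple[CohortManifest, pd.DataFrame]:
    """In-memory cohort: manifest with pixel-array images + latent table."""
    records, latents = [], []
    crops = default_crop_boxes(spec)
    for sid, label, params in _subject_stream(spec):
        images = render_views(params, spec)
        records.append(MultiViewRecord(subject_id=sid, label=label,
                                       images=dict(images), crop_boxes=dict(crops)))
        latents.append({"subject_id": sid, "label": label, **params.as_dict()})
    return (CohortManifest(records=records, provenance="synthetic"),
            pd.DataFrame(latents))


def generate_cohort(spec: CohortSpec, out_dir: str) -> CohortManifest:
    """Write PNG images, a manifest CSV (with full-frame crop boxes) and a
    latent-parameter sidecar CSV; return the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    rows, latents, records = [], [], []
    crops = default_crop_boxes(spec)
    for sid, label, params in _subject_stream(spec):
        images = render_views(params, spec)
        row: dict = {"subject_id": sid, "label": label}
        rec_imgs = {}
        for role, img in images.items():
            fname = os.path.join("images", f"{sid}_{role.value}.png")
            fpath = os.path.join(out_dir, fname)
            Image.fromarray((img * 255).round().astype(np.uint8)).save(fpath)
            row[role.value] = fname
            rec_imgs[role] = fpath
            for k, v in zip(("x0", "y0", "x1", "y1"), crops[role]):
                row[f"{role.value}_crop_{k}"] = v
        rows.append(row)
        latents.append({"subject_id": sid, "label": label, **params.as_dict()})
        records.append(MultiViewRecord(subject_id=sid, label=label, images=rec_imgs,
                                       crop_boxes=dict(crops)))
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    pd.DataFrame(latents).to_csv(os.path.join(out_dir, "latents.csv"), index=False)
    return CohortManifest(records=records, provenance="synthetic")
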