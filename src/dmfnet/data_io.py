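"""Cohort manifest handling and image preprocessing.

The manifest is a CSV with columns ``subject_id,label`` plus one image-path
column per view role; optional per-view crop columns
(``<role>_crop_x0`` .. ``<role>_crop_y1``) give half-open 0-based crop
rectangles spanning forehead to neck base.  Preprocessing is a crop followed
by a bilinear resize to a square model input (224 px by default); pixel values
are scaled to [0, 1] and grayscale inputs replicated to three channels.

The network consumes the five preprocessed views as two channel-stacked
groups: a 9-channel frontal stack and a 6-channel lateral stack, in the fixed
role order of :class:`~dmfnet.types.ViewRole`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .types import CohortManifest, CropBox, ImageSource, MultiViewRecord, ViewRole

DEFAULT_SIZE = 224


def load_manifest(path: str) -> CohortManifest:
    """Read a cohort manifest CSV into an ordered list of records."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = ["subject_id", "label"] + [r.value for r in ViewRole.ordered()]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest {path} missing column(s): {missing_cols}")
    base = os.path.dirname(os.path.abspath(path))
    records = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        label = row["label"]
        if label not in (0, 1):
            raise ValueError(f"subject {sid!r}: label must be 0 or 1, got {label!r}")
        images: dict[ViewRole, ImageSource] = {}
        crops: dict[ViewRole, CropBox] = {}
        for role in ViewRole.ordered():
            p = row[role.value]
            if not isinstance(p, str) or not p:
                raise ValueError(f"incomplete record {sid!r}: missing path for {role.value}")
            full = p if os.path.isabs(p) else os.path.join(base, p)
            images[role] = full
            ck = [f"{role.value}_crop_{k}" for k in ("x0", "y0", "x1", "y1")]
            if all(c in df.columns for c in ck) and not any(pd.isna(row[c]) for c in ck):
                crops[role] = tuple(int(row[c]) for c in ck)  # type: ignore[assignment]
        records.append(MultiViewRecord(subject_id=sid, label=int(label), images=images,
                                       crop_boxes=crops or None))
    return CohortManifest(records=records, provenance="real")


def save_manifest(manifest: CohortManifest, path: str):
    rows = []
    for rec in manifest.records:
        row: dict = {"subject_id": rec.subject_id, "label": rec.label}
        for role in ViewRole.ordered():
            src = rec.images[role]
            if not isinstance(src, str):
                raise ValueError("save_manifest requires file-backed images")
            row[role.value] = src
            if rec.crop_boxes and role in rec.crop_boxes:
                for k, v in zip(("x0", "y0", "x1", "y1"), rec.crop_boxes[role]):
                    row[f"{role.value}_crop_{k}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _load_pixels(src: ImageSource) -> np.ndarray:
    """Return an H x W x 3 float array in [0, 1]."""
    if isinstance(src, str):
        with Image.open(src) as im:
            arr = np.asarray(im)
    else:
        arr = np.asarray(src)
    if arr.dtype.kind in "ui":
        arr = arr.astype(np.float32) / 255.0
    else:
        arr = arr.astype(np.float32)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    elif arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def preprocess_image(image: ImageSource, crop_box: CropBox | None = None,
                     size: int = DEFAULT_SIZE) -> np.ndarray:
    """Crop, bilinearly resize to ``size`` x ``size`` and return a 3 x S x S
    array in [0, 1]."""
    arr = _load_pixels(image)
    h, w = arr.shape[:2]
    if crop_box is None:
        crop_box = (0, 0, w, h)
    x0, y0, x1, y1 = crop_box
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"crop box {crop_box} outside or degenerate for image {w}x{h}")
    arr = arr[y0:y1, x0:x1]
    if arr.shape[0] != size or arr.shape[1] != size:
        arr = _sk_resize(arr, (size, size), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    out = np.clip(arr, 0.0, 1.0).astype(np.float32)
    return np.ascontiguousarray(out.transpose(2, 0, 1))


def assemble_view_groups(record: MultiViewRecord,
                         crop_boxes: dict[ViewRole, CropBox] | None = None,
                         size: int = DEFAULT_SIZE) -> tuple[np.ndarray, np.ndarray]:
    """Build the network input pair: (front 9 x S x S, side 6 x S x S).

    Channel blocks of three follow the fixed role order regardless of how the
    record's image mapping is ordered.
    """
    crops = crop_boxes if crop_boxes is not None else (record.crop_boxes or {})
    views = {role: preprocess_image(record.images[role], crops.get(role), size=size)
             for role in ViewRole.ordered()}
    front = np.concatenate([views[r] for r in ViewRole.frontal()], axis=0)
    side = np.concatenate([views[r] for r in ViewRole.lateral()], axis=0)
    return front, side


def validate_manifest(manifest: CohortManifest) -> dict:
    """Integrity report: record/class counts and per-view file availability."""
    n_neg, n_pos = manifest.class_counts()
    per_view = {}
    for role in ViewRole.ordered():
        ok = 0
        for rec in manifest.records:
            src = rec.images[role]
            if not isinstance(src, str) or os.path.exists(src):
                ok += 1
        per_view[role.value] = {"present": ok, "missing": len(manifest) - ok}
    return {"n_records": len(manifest), "n_negative": n_neg, "n_positive": n_pos,
            "provenance": manifest.provenance, "views": per_view}
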