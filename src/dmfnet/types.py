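"""Core domain types: view roles, per-subject records, cohort manifests.

A subject is photographed in five standardised views.  The first three are
frontal (closed mouth, open mouth, tongue protruding) and the last two lateral
(closed mouth, chin lift); this order is fixed and governs the channel layout
of the network input everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Union

import numpy as np


class ViewRole(str, Enum):
    frontal_closed = "frontal_closed"
    frontal_open = "frontal_open"
    frontal_tongue = "frontal_tongue"
    lateral_closed = "lateral_closed"
    lateral_chinlift = "lateral_chinlift"

    @classmethod
    def ordered(cls) -> tuple["ViewRole", ...]:
        return (cls.frontal_closed, cls.frontal_open, cls.frontal_tongue,
                cls.lateral_closed, cls.lateral_chinlift)

    @classmethod
    def frontal(cls) -> tuple["ViewRole", ...]:
        return cls.ordered()[:3]

    @classmethod
    def lateral(cls) -> tuple["ViewRole", ...]:
        return cls.ordered()[3:]


ImageSource = Union[str, np.ndarray]

#: half-open crop rectangle (x0, y0, x1, y1) in 0-based pixel coordinates
CropBox = tuple[int, int, int, int]


@dataclass
class MultiViewRecord:
    """One subject: five role-tagged images plus the binary airway label."""

    subject_id: str
    label: int
    images: dict[ViewRole, ImageSource]
    crop_boxes: dict[ViewRole, CropBox] | None = None
    source_id: str | None = None  # original subject for augmented copies

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label for {self.subject_id!r} must be 0 or 1, got {self.label}")
        missing = [r for r in ViewRole.ordered() if r not in self.images]
        if missing:
            raise ValueError(
                f"incomplete record {self.subject_id!r}: missing view(s) "
                + ", ".join(r.value for r in missing))
        if self.source_id is None:
            self.source_id = self.subject_id


@dataclass
class CohortManifest:
    records: list[MultiViewRecord]
    provenance: str = "real"

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id(s): {dupes}")

    def __len__(self):
        return len(self.records)

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        labels = [r.label for r in self.records]
        return labels.count(0), labels.count(1)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)
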