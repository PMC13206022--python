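"""From native segmented slices to normalized model inputs and patient-level splits.

The preparation chain mirrors standard practice for segmented liver MR:
apply the binary liver mask, crop to the mask's tight bounding box, resample
to the fixed model resolution of 80 x 95 pixels, and scale intensities into
[0, 1] by the fixed 16-bit dynamic range. Normalization is deliberately by
a *fixed* dynamic range and not per-image min-max: absolute parenchymal
intensity is what carries the fat-fraction signal, and per-image rescaling
would destroy it.

Data splitting is patient-level: every subject's slices land in exactly one
of train/validation/test, so evaluation measures generalization to unseen
subjects rather than to adjacent slices of a subject already trained on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .synthetic_phantom import MAX_DN

__all__ = [
    "ModelInput",
    "SplitAssignment",
    "MODEL_SHAPE",
    "isolate_liver",
    "resize_to_model",
    "normalize01",
    "compute_split_counts",
    "split_by_subject",
    "prepare_slice",
]

#: Fixed model input resolution (rows, cols).
MODEL_SHAPE = (80, 95)

PARTITIONS = ("train", "validation", "test")


@dataclass
class ModelInput:
    """One network-ready slice: 80 x 95 pixels in [0, 1]."""

    pixels: np.ndarray
    subject_id: str
    slice_index: int

    def __post_init__(self) -> None:
        if self.pixels.shape != MODEL_SHAPE:
            raise ValueError(f"model input must be {MODEL_SHAPE}, got {self.pixels.shape}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"model input pixels must lie in [0, 1], got range [{lo}, {hi}]")


@dataclass
class SplitAssignment:
    """Subject -> partition mapping with the slice counts that produced it."""

    by_subject: dict[str, str]
    slice_counts: dict[str, int]

    def partition_of(self, subject_id: str) -> str:
        return self.by_subject[subject_id]

    def subjects_in(self, partition: str) -> list[str]:
        return [s for s, p in self.by_subject.items() if p == partition]

    def slices_in(self, partition: str) -> int:
        return sum(self.slice_counts[s] for s in self.subjects_in(partition))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"subject_id": s, "partition": p} for s, p in sorted(self.by_subject.items())]
        )


def isolate_liver(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out non-liver pixels and crop to the mask's tight bounding box."""
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} differ in shape")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty liver mask: nothing to quantify")
    masked = np.where(mask, image, 0)
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return masked[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def resize_to_model(image: np.ndarray) -> np.ndarray:
    """Bilinear resample to the fixed 80 x 95 model resolution."""
    if image.size == 0:
        raise ValueError("cannot resize an empty image")
    out = resize(
        image.astype(np.float64),
        MODEL_SHAPE,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return out


def normalize01(image: np.ndarray, max_dn: float = MAX_DN) -> np.ndarray:
    """Scale pixel values into [0, 1] by the fixed dynamic range ``max_dn``."""
    if max_dn <= 0:
        raise ValueError("max_dn must be positive")
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < 0 or arr.max() > max_dn:
        raise ValueError(
            f"pixel values outside [0, {max_dn}]: range [{arr.min()}, {arr.max()}] - corrupt input?"
        )
    return arr / max_dn


def prepare_slice(image: np.ndarray, mask: np.ndarray, subject_id: str, slice_index: int, max_dn: float = MAX_DN) -> ModelInput:
    """Full chain: isolate liver, resize, normalize, wrap as :class:`ModelInput`."""
    cropped = isolate_liver(image, mask)
    resized = resize_to_model(cropped)
    pixels = normalize01(np.clip(resized, 0.0, max_dn), max_dn)
    return ModelInput(pixels=pixels, subject_id=subject_id, slice_index=slice_index)


def compute_split_counts(n_total: int, proportions: tuple[float, float, float] = (0.70, 0.15, 0.15)) -> tuple[int, int, int]:
    """Apportion ``n_total`` items into three counts by largest remainder.

    Each count starts at floor(n_total * p); leftover units go to the
    partitions with the largest fractional remainders, earlier partitions
    winning ties. The counts always sum to ``n_total``.
    """
    if n_total < 3:
        raise ValueError("need at least 3 items to fill three partitions")
    props = np.asarray(proportions, dtype=float)
    if props.shape != (3,) or (props <= 0).any():
        raise ValueError("proportions must be three positive fractions")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {props.sum()}")
    exact = n_total * props
    counts = np.floor(exact).astype(int)
    remainders = exact - counts
    for _ in range(n_total - int(counts.sum())):
        # argmax returns the first (earliest-partition) maximum on ties
        k = int(np.argmax(remainders))
        counts[k] += 1
        remainders[k] = -1.0
    return int(counts[0]), int(counts[1]), int(counts[2])


def split_by_subject(
    label_table: pd.DataFrame,
    proportions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole subjects to train/validation/test by slice-count targets.

    Subjects are shuffled with ``seed`` and assigned greedily: each goes to
    the partition whose remaining slice deficit (target minus current count)
    is largest, ties resolved in train/validation/test order. Per-partition
    slice counts therefore land within one subject's slice count of the
    targets from :func:`compute_split_counts`.
    """
    slice_counts = label_table.groupby("subject_id").size().to_dict()
    subjects = sorted(slice_counts)
    if len(subjects) < 3:
        raise ValueError(f"patient-level split needs >= 3 subjects, got {len(subjects)}")
    n_total = int(sum(slice_counts.values()))
    targets = dict(zip(PARTITIONS, compute_split_counts(n_total, proportions)))

    order = list(np.random.default_rng(seed).permutation(subjects))
    filled = {p: 0 for p in PARTITIONS}
    occupied = {p: 0 for p in PARTITIONS}
    assignment: dict[str, str] = {}
    for i, subj in enumerate(order):
        deficits = {p: targets[p] - filled[p] for p in PARTITIONS}
        candidates = PARTITIONS
        # never strand a partition empty: once the remaining subjects are only
        # just enough to cover the still-empty partitions, fill those first
        empty = [p for p in PARTITIONS if occupied[p] == 0]
        if empty and len(order) - i <= len(empty):
            candidates = tuple(empty)
        best = max(candidates, key=lambda p: (deficits[p], -PARTITIONS.index(p)))
        assignment[subj] = best
        filled[best] += slice_counts[subj]
        occupied[best] += 1
    return SplitAssignment(by_subject=assignment, slice_counts={s: int(c) for s, c in slice_counts.items()})
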