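"""Image samples, dataset container, manifest and PNG I/O.

Images are held as ``(H, W, C)`` float64 arrays in [0, 1].  A dataset is a
list of :class:`ImageSample` records; on disk it is a class-per-directory
tree of PNGs plus a CSV manifest with columns ``path, label, u, v, split``
(``u, v`` are the planted lesion centre for synthetic data, empty for real
data).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ValidationError

MANIFEST_COLUMNS = ["path", "label", "u", "v", "split"]


@dataclass
class ImageSample:
    """One labelled image, optionally with planted-lesion ground truth."""

    image: np.ndarray  # (H, W, C) float in [0, 1]
    label: int
    lesion_center: Optional[Tuple[int, int]] = None  # (u, v) pixel coords
    path: Optional[str] = None

    @property
    def image_dims(self) -> Tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class LeafDataset:
    """A homogeneous collection of samples plus the label-space size."""

    samples: List[ImageSample]
    num_classes: int

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i: int) -> ImageSample:
        return self.samples[i]

    def subset(self, indices: Sequence[int]) -> "LeafDataset":
        return LeafDataset([self.samples[i] for i in indices], self.num_classes)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)


def save_png(image: np.ndarray, path: os.PathLike) -> None:
    """Write a float [0, 1] image as an 8-bit PNG."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path, format="PNG")


def load_png(path: os.PathLike) -> np.ndarray:
    """Read a PNG as a float [0, 1] ``(H, W, 3)`` array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=float) / 255.0


def write_manifest(rows: pd.DataFrame, path: os.PathLike) -> None:
    missing = set(MANIFEST_COLUMNS) - set(rows.columns)
    if missing:
        raise ValidationError(f"manifest missing columns {sorted(missing)}")
    if rows["path"].duplicated().any():
        raise ValidationError("manifest paths must be unique")
    rows[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: os.PathLike) -> pd.DataFrame:
    rows = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(rows.columns)
    if missing:
        raise ValidationError(f"manifest {path} missing columns {sorted(missing)}")
    return rows


def load_dataset(
    manifest_path: os.PathLike, split: Optional[str] = None
) -> LeafDataset:
    """Load samples listed in a manifest, optionally restricted to one split.

    Relative image paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    rows = read_manifest(manifest_path)
    num_classes = int(rows["label"].max()) + 1
    if split is not None:
        rows = rows[rows["split"] == split]
        if rows.empty:
            raise ValidationError(f"no rows with split={split!r} in {manifest_path}")
    root = manifest_path.parent
    samples = []
    for row in rows.itertuples(index=False):
        center = None
        if pd.notna(row.u) and pd.notna(row.v):
            center = (int(row.u), int(row.v))
        samples.append(
            ImageSample(
                image=load_png(root / row.path),
                label=int(row.label),
                lesion_center=center,
                path=str(row.path),
            )
        )
    return LeafDataset(samples, num_classes)
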