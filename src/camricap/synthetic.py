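"""Synthetic leaf-disease images with planted, localised lesions.

Real leaf-disease photographs carry their class identity in localised
symptoms (spots, streaks, mottling) on an otherwise class-neutral leaf.
The generator emulates exactly that structure: a green, smoothed-noise
background that is identical in distribution across classes, plus one
Gaussian-profiled lesion blob whose *colour* encodes the class, planted at
a known, uniformly drawn centre.  Because the discriminative evidence has
a known position, region-recovery by the CAM-guided cropper is directly
checkable, and because nothing else distinguishes the classes, a
classifier must attend to the lesion to succeed.

Images are 224 x 224 RGB by default.  Datasets are written as PNGs in a
class-per-directory layout with a CSV manifest recording path, label,
lesion centre and a stratified 80/10/10 train/val/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .adapters import AnalyticLesionAdapter
from .data import ImageSample, LeafDataset, save_png, write_manifest
from .errors import ValidationError

# lesion colours per class: brown, yellow, grey, rust, pale
DEFAULT_LESION_COLORS = (
    (0.45, 0.26, 0.08),
    (0.85, 0.78, 0.15),
    (0.55, 0.55, 0.55),
    (0.75, 0.20, 0.15),
    (0.95, 0.95, 0.90),
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic leaf-image family."""

    image_size: int = 224
    channels: int = 3
    num_classes: int = 3
    lesion_sigma: float = 10.0
    lesion_amplitude: float = 1.0  # blend weight of the lesion colour at its centre
    background_color: Tuple[float, float, float] = (0.18, 0.42, 0.16)
    texture_sigma: float = 12.0   # px, smoothing of the background noise field
    texture_amplitude: float = 0.06
    noise_sd: float = 0.02        # additive per-pixel noise, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValidationError("need at least two classes")
        if self.image_size % 2:
            raise ValidationError("image_size must be even")
        if 2 * 3 * self.lesion_sigma >= self.image_size:
            raise ValidationError(
                f"lesion (3 sigma = {3 * self.lesion_sigma}) cannot fit inside "
                f"a {self.image_size}px image"
            )
        if self.num_classes > len(DEFAULT_LESION_COLORS):
            raise ValidationError(
                f"at most {len(DEFAULT_LESION_COLORS)} classes have distinct lesion colours"
            )

    @property
    def image_dims(self) -> Tuple[int, int]:
        return (self.image_size, self.image_size)

    def lesion_color(self, class_id: int) -> np.ndarray:
        return np.asarray(DEFAULT_LESION_COLORS[class_id])


def generate_leaf_image(
    class_id: int,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    center: Optional[Tuple[int, int]] = None,
) -> ImageSample:
    """One leaf image: textured green background + class-coloured lesion.

    The lesion centre is drawn uniformly with a 3-sigma margin from the
    border (or fixed via ``center``).  At the centre the pixel is the
    class colour blended at full ``lesion_amplitude``.
    """
    if not 0 <= class_id < spec.num_classes:
        raise ValidationError(f"class id {class_id} out of range")
    n = spec.image_size
    margin = int(np.ceil(3 * spec.lesion_sigma))
    if center is None:
        u = int(rng.integers(margin, n - margin))
        v = int(rng.integers(margin, n - margin))
    else:
        u, v = center
        if not (margin <= u < n - margin and margin <= v < n - margin):
            raise ValidationError(f"lesion centre {center} leaves the {n}px image at 3 sigma")

    texture = gaussian_filter(rng.standard_normal((n, n)), spec.texture_sigma)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    image = np.empty((n, n, spec.channels))
    channel_gain = np.array([0.5, 1.0, 0.5])[: spec.channels]
    image[:] = np.asarray(spec.background_color)[: spec.channels]
    image += spec.texture_amplitude * texture[:, :, None] * channel_gain

    vv, uu = np.mgrid[0:n, 0:n]
    alpha = spec.lesion_amplitude * np.exp(
        -((uu - u) ** 2 + (vv - v) ** 2) / (2 * spec.lesion_sigma ** 2)
    )
    color = spec.lesion_color(class_id)[: spec.channels]
    image = (1 - alpha[:, :, None]) * image + alpha[:, :, None] * color

    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, image.shape)
    return ImageSample(
        image=np.clip(image, 0.0, 1.0), label=class_id, lesion_center=(u, v)
    )


def _split_sizes(n: int) -> Tuple[int, int, int]:
    """Stratified 80/10/10 split sizes for one class (floors, remainder to test)."""
    n_train = int(np.floor(0.8 * n))
    n_val = int(np.floor(0.1 * n))
    return n_train, n_val, n - n_train - n_val


def generate_samples(n_per_class: int, spec: SyntheticSpec) -> Tuple[LeafDataset, List[str]]:
    """In-memory dataset plus the per-sample split assignment."""
    rng = np.random.default_rng(spec.seed)
    samples: List[ImageSample] = []
    splits: List[str] = []
    for class_id in range(spec.num_classes):
        n_train, n_val, _ = _split_sizes(n_per_class)
        for i in range(n_per_class):
            samples.append(generate_leaf_image(class_id, spec, rng))
            splits.append("train" if i < n_train else "val" if i < n_train + n_val else "test")
    return LeafDataset(samples, spec.num_classes), splits


def generate_dataset(n_per_class: int, spec: SyntheticSpec, out_dir) -> pd.DataFrame:
    """Write PNGs (class-per-directory) plus a manifest CSV; return the manifest.

    The split is stratified per class: 80% train, 10% validation, the
    remainder test (8/1/1 for ``n_per_class=10``).
    """
    if n_per_class < 10:
        raise ValidationError("n_per_class must be >= 10 to populate all three splits")
    out_dir = Path(out_dir)
    dataset, splits = generate_samples(n_per_class, spec)
    rows = []
    counters: dict = {}
    for sample, split in zip(dataset.samples, splits):
        class_dir = out_dir / f"class_{sample.label}"
        class_dir.mkdir(parents=True, exist_ok=True)
        idx = counters.get(sample.label, 0)
        counters[sample.label] = idx + 1
        rel = f"class_{sample.label}/img_{idx:04d}.png"
        save_png(sample.image, out_dir / rel)
        u, v = sample.lesion_center
        rows.append({"path": rel, "label": sample.label, "u": u, "v": v, "split": split})
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def analytic_cam_provider(
    spec: SyntheticSpec, map_dims: Tuple[int, int] = (7, 7)
) -> AnalyticLesionAdapter:
    """Adapter whose CAM peak sits on each sample's planted lesion."""
    return AnalyticLesionAdapter(
        map_dims=map_dims,
        image_dims=spec.image_dims,
        sigma=spec.lesion_sigma,
        num_classes=spec.num_classes,
    )
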