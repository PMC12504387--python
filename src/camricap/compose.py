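"""Four-image patch composition and CAM-proportional label mixing.

The augmentation builds each training sample from four source images: one
"anchor" (the batch in its original order) and three partners drawn by
independently shuffling the batch.  For every source the class activation
map picks the most salient pixel, a crop ratio ``gamma`` sets the region
size, and the clamped region around the peak becomes that source's patch.
The four patches tile a fresh canvas, and the composite's soft label gives
each source a weight

    lambda_i  ∝  mass(CAM_i restricted to region_i) / mass(CAM_i),

i.e. the share of the source's (rectified, image-space) activation mass
its patch carries.  The weights are normalised to sum to one so the soft
label is a probability vector.  When a source's CAM carries no positive
mass at all (an untrained network, say), its weight falls back to the
patch's area fraction — the classic RICAP weighting — so the procedure
degrades gracefully rather than dividing by zero.

``classic_ricap`` implements the original area-weighted RICAP as a
reference baseline: a Beta-distributed boundary point splits the canvas
into four rectangles, each filled by a uniformly placed random crop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cam import ActivationMap, PeakCoord, bilinear_resize, cam_mass, compute_cam, locate_peak, map_to_image_coords, upsample_cam
from .data import ImageSample, save_png
from .errors import ConfigError, ShapeError, ValidationError
from .regions import RegionBox, crop, region_from_center, sample_gamma

LAYOUTS = ("quadrant_resize", "anchored_overwrite")


@dataclass
class AugmentConfig:
    """Options of the CAM-guided mixer.

    gamma_min, gamma_max
        Range of the uniform crop-ratio draw (fraction of each image side
        used for the discriminative region).
    layout
        ``quadrant_resize`` (default): each patch is bilinearly resized to
        a half-size quadrant, so the canvas is tiled exactly.
        ``anchored_overwrite``: patches keep their native size, anchored at
        their quadrant's outer corner; later pastes overwrite earlier
        overlap and uncovered pixels show the first source's image.
    """

    gamma_min: float = 0.25
    gamma_max: float = 0.75
    layout: str = "quadrant_resize"

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma_min <= self.gamma_max <= 1.0):
            raise ConfigError(
                f"need 0 < gamma_min <= gamma_max <= 1, got ({self.gamma_min}, {self.gamma_max})"
            )
        if self.layout not in LAYOUTS:
            raise ConfigError(f"layout must be one of {LAYOUTS}, got {self.layout!r}")


@dataclass
class Patch:
    """One source's contribution to a composite."""

    pixels: np.ndarray
    source_index: int
    region: RegionBox
    lambda_raw: float  # CAM-mass fraction before normalisation, in [0, 1]


@dataclass
class MixedSample:
    """A composite image with its soft label and provenance."""

    image: np.ndarray
    soft_label: np.ndarray
    provenance: List[Tuple[int, RegionBox, float]]  # (source index, region, lambda)

    def __post_init__(self) -> None:
        total = float(np.sum(self.soft_label))
        if np.any(np.asarray(self.soft_label) < -1e-12) or abs(total - 1.0) > 1e-9:
            raise ValidationError(f"soft label must be a distribution, sums to {total}")


@dataclass
class BatchQuadruple:
    """Index vectors pairing each batch position with its four sources."""

    indices: List[np.ndarray]  # four length-B vectors; indices[0] is the identity


def select_quadruple(batch_size: int, rng: np.random.Generator) -> BatchQuadruple:
    """Identity ordering plus three independent random permutations."""
    if batch_size < 1:
        raise ValidationError("batch_size must be >= 1")
    identity = np.arange(batch_size)
    return BatchQuadruple([identity] + [rng.permutation(batch_size) for _ in range(3)])


def compose_image(
    patches: Sequence[np.ndarray],
    layout: str,
    image_dims: Tuple[int, int],
    canvas: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Tile four patches onto a ``(H, W)`` canvas.

    Placement order is top-left, top-right, bottom-left, bottom-right.
    ``canvas`` (the first source's full image) is required for the
    ``anchored_overwrite`` layout to fill pixels no patch covers.
    """
    if len(patches) != 4:
        raise ShapeError(f"need exactly four patches, got {len(patches)}")
    H, W = image_dims
    if H % 2 or W % 2:
        raise ConfigError(f"composite dims must be even, got ({H}, {W})")
    if layout == "quadrant_resize":
        hh, hw = H // 2, W // 2
        out = np.empty((H, W) + patches[0].shape[2:])
        corners = [(0, 0), (0, hw), (hh, 0), (hh, hw)]
        for patch, (r, c) in zip(patches, corners):
            resized = patch if patch.shape[:2] == (hh, hw) else bilinear_resize(patch, (hh, hw))
            out[r : r + hh, c : c + hw] = resized
        return out
    if layout == "anchored_overwrite":
        if canvas is None:
            raise ValidationError("anchored_overwrite layout needs a fill canvas")
        out = np.array(canvas, dtype=float, copy=True)
        for k, patch in enumerate(patches):
            ph, pw = patch.shape[:2]
            r = 0 if k < 2 else H - ph
            c = 0 if k % 2 == 0 else W - pw
            out[r : r + ph, c : c + pw] = patch
        return out
    raise ConfigError(f"unknown layout {layout!r}")


def label_weights(
    patch_masses: Sequence[float],
    total_masses: Sequence[float],
    areas: Sequence[float],
    image_area: float,
) -> np.ndarray:
    """Normalised label weights from per-source CAM masses.

    ``lambda_raw_i = patch_mass_i / total_mass_i`` (the share of source
    ``i``'s activation mass inside its patch), with the patch's area
    fraction substituted when the source has zero total mass.  The raw
    weights are normalised to sum to one; if every raw weight is zero the
    four sources share the label equally.
    """
    patch_masses = np.asarray(patch_masses, dtype=float)
    total_masses = np.asarray(total_masses, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if np.any(patch_masses < 0) or np.any(total_masses < 0) or np.any(areas < 0):
        raise ValidationError("masses and areas must be non-negative")
    raw = np.where(
        total_masses > 0,
        patch_masses / np.where(total_masses > 0, total_masses, 1.0),
        areas / image_area,
    )
    total = raw.sum()
    if total == 0:
        return np.full(len(raw), 1.0 / len(raw))
    return raw / total


def mix_labels(
    lambdas: Sequence[float], class_ids: Sequence[int], num_classes: int
) -> np.ndarray:
    """Soft label ``sum_i lambda_i * onehot(class_ids[i])``."""
    lambdas = np.asarray(lambdas, dtype=float)
    if abs(lambdas.sum() - 1.0) > 1e-9:
        raise ValidationError(f"lambdas must sum to 1, got {lambdas.sum()}")
    label = np.zeros(num_classes)
    for lam, cid in zip(lambdas, class_ids):
        cid = int(cid)
        if not 0 <= cid < num_classes:
            raise ValidationError(f"class id {cid} out of range [0, {num_classes})")
        label[cid] += lam
    return label


def _cam_summary(sample: ImageSample, provider) -> Tuple[ActivationMap, PeakCoord, float]:
    """Image-space CAM, pixel-space peak and total rectified mass of one sample."""
    try:
        cam = compute_cam(provider.features(sample), provider.class_weights(sample.label))
    except ShapeError as exc:
        raise ShapeError(f"adapter output mismatch for sample at path={sample.path!r}: {exc}") from exc
    peak = locate_peak(cam)
    center = map_to_image_coords(peak, cam.shape, sample.image_dims)
    cam_img = upsample_cam(cam, sample.image_dims)
    return cam_img, center, cam_mass(cam_img)


def enhanced_ricap(
    batch: Sequence[ImageSample],
    provider,
    config: AugmentConfig,
    rng: np.random.Generator,
    num_classes: int,
) -> List[MixedSample]:
    """CAM-guided four-image mixing over one batch.

    Returns one :class:`MixedSample` per batch position.  The provider is
    only read (features and classifier weights); no training state is
    mutated.  Each source image's own ground-truth class selects the CAM
    weights, and each source draws its own crop ratio.
    """
    B = len(batch)
    quadruple = select_quadruple(B, rng)
    H, W = batch[0].image_dims
    cache: Dict[int, Tuple[ActivationMap, PeakCoord, float]] = {}
    out: List[MixedSample] = []
    for b in range(B):
        sources = [int(quadruple.indices[k][b]) for k in range(4)]
        patches: List[Patch] = []
        patch_masses, total_masses, areas = [], [], []
        for si in sources:
            sample = batch[si]
            if si not in cache:
                cache[si] = _cam_summary(sample, provider)
            cam_img, center, total_mass = cache[si]
            gamma = sample_gamma(config.gamma_min, config.gamma_max, rng)
            region = region_from_center(center, gamma, sample.image_dims)
            patch_mass = cam_mass(cam_img, region)
            lam_raw = patch_mass / total_mass if total_mass > 0 else region.area / (W * H)
            patches.append(Patch(crop(sample.image, region), si, region, lam_raw))
            patch_masses.append(patch_mass)
            total_masses.append(total_mass)
            areas.append(region.area)
        lambdas = label_weights(patch_masses, total_masses, areas, W * H)
        image = compose_image(
            [p.pixels for p in patches], config.layout, (H, W),
            canvas=batch[sources[0]].image,
        )
        soft = mix_labels(lambdas, [batch[si].label for si in sources], num_classes)
        out.append(MixedSample(image, soft, [
            (p.source_index, p.region, float(lam)) for p, lam in zip(patches, lambdas)
        ]))
    return out


def classic_ricap(
    batch: Sequence[ImageSample],
    beta: float,
    rng: np.random.Generator,
    num_classes: int,
) -> List[MixedSample]:
    """Original RICAP baseline: random crops, area-proportional labels.

    A boundary point ``(w, h)`` with ``w = round(W * b)``, ``b ~
    Beta(beta, beta)`` (and likewise ``h``) splits the canvas into four
    rectangles; each is filled with a uniformly offset crop of its source
    image and weighted by its area fraction.  Zero-area rectangles simply
    contribute nothing to the label.
    """
    if beta <= 0:
        raise ValidationError("beta must be positive")
    B = len(batch)
    quadruple = select_quadruple(B, rng)
    H, W = batch[0].image_dims
    out: List[MixedSample] = []
    for b in range(B):
        sources = [int(quadruple.indices[k][b]) for k in range(4)]
        w = int(round(W * rng.beta(beta, beta)))
        h = int(round(H * rng.beta(beta, beta)))
        sizes = [(h, w), (h, W - w), (H - h, w), (H - h, W - w)]
        corners = [(0, 0), (0, w), (h, 0), (h, w)]
        image = np.zeros((H, W) + batch[0].image.shape[2:])
        provenance = []
        lambdas = []
        for si, (ph, pw), (r, c) in zip(sources, sizes, corners):
            lam = (ph * pw) / (H * W)
            lambdas.append(lam)
            if ph == 0 or pw == 0:
                provenance.append((si, None, lam))
                continue
            u0 = int(rng.integers(0, W - pw + 1))
            v0 = int(rng.integers(0, H - ph + 1))
            region = RegionBox(u_l=u0, u_r=u0 + pw, v_t=v0, v_b=v0 + ph)
            image[r : r + ph, c : c + pw] = crop(batch[si].image, region)
            provenance.append((si, region, lam))
        soft = mix_labels(lambdas, [batch[si].label for si in sources], num_classes)
        out.append(MixedSample(image, soft, provenance))
    return out


def export_mixed_samples(
    mixed: Sequence[MixedSample], out_dir, seed: Optional[int] = None
) -> List[Path]:
    """Write composites as PNGs with JSON sidecars (sources, boxes, weights)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, ms in enumerate(mixed):
        png_path = out_dir / f"composite_{i:04d}.png"
        save_png(ms.image, png_path)
        sidecar = {
            "sources": [
                {
                    "source_index": src,
                    "region": None if region is None else
                        {"u_l": region.u_l, "u_r": region.u_r,
                         "v_t": region.v_t, "v_b": region.v_b},
                    "lambda": lam,
                }
                for src, region, lam in ms.provenance
            ],
            "soft_label": [float(x) for x in ms.soft_label],
            "seed": seed,
        }
        with open(out_dir / f"composite_{i:04d}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
        written.append(png_path)
    return written
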