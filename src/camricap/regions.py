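"""Discriminative-region geometry: crop ratios, boxes, clamping, cropping.

A crop ratio ``gamma`` in (0, 1] fixes the region size ``w_i = round(W *
gamma)``, ``h_i = round(H * gamma)``.  The region is centred on the CAM
peak and then clamped back into the image with its size preserved, so the
box invariants (integer bounds, exact size, containment) always hold.
Boxes are half-open ``[u_l, u_r) x [v_t, v_b)`` in pixel units with ``v``
increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .cam import PeakCoord
from .errors import ConfigError, ValidationError


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned half-open pixel rectangle ``[u_l, u_r) x [v_t, v_b)``."""

    u_l: int
    u_r: int
    v_t: int
    v_b: int

    def __post_init__(self) -> None:
        if not (self.u_l < self.u_r and self.v_t < self.v_b):
            raise ValidationError(f"degenerate region {self}")
        if min(self.u_l, self.v_t) < 0:
            raise ValidationError(f"region {self} has negative bounds")

    @property
    def width(self) -> int:
        return self.u_r - self.u_l

    @property
    def height(self) -> int:
        return self.v_b - self.v_t

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains(self, u: float, v: float) -> bool:
        return self.u_l <= u < self.u_r and self.v_t <= v < self.v_b


def sample_gamma(gamma_min: float, gamma_max: float, rng: np.random.Generator) -> float:
    """Draw a crop ratio uniformly from ``[gamma_min, gamma_max]``."""
    if not (0.0 < gamma_min <= gamma_max <= 1.0):
        raise ConfigError(
            f"gamma range must satisfy 0 < gamma_min <= gamma_max <= 1, got ({gamma_min}, {gamma_max})"
        )
    if gamma_min == gamma_max:
        return gamma_min
    return float(rng.uniform(gamma_min, gamma_max))


def region_size(gamma: float, image_dims: Tuple[int, int]) -> Tuple[int, int]:
    """Region height/width ``(h_i, w_i) = round(H * gamma), round(W * gamma)``.

    Rounding is ties-to-even; sizes are floored at one pixel only through
    validation (a gamma giving a sub-pixel region is rejected).
    """
    H, W = image_dims
    if not (0.0 < gamma <= 1.0):
        raise ValidationError(f"gamma must lie in (0, 1], got {gamma}")
    w_i = int(round(W * gamma))
    h_i = int(round(H * gamma))
    if w_i < 1 or h_i < 1:
        raise ValidationError(f"gamma {gamma} yields a sub-pixel region on image {image_dims}")
    return h_i, w_i


def region_from_center(
    center: PeakCoord, gamma: float, image_dims: Tuple[int, int]
) -> RegionBox:
    """Clamped box of size ``round(W*gamma) x round(H*gamma)`` centred on a peak.

    The raw box is ``[u - w_i/2, u + w_i/2) x [v - h_i/2, v + h_i/2)``;
    whenever a bound falls outside the image the box is slid back inside
    with its size preserved (left < 0 -> [0, w_i]; right > W -> [W - w_i, W];
    likewise vertically).
    """
    if center.space != "image":
        raise ValidationError("region centre must be in image space")
    H, W = image_dims
    if not (0 <= center.u < W and 0 <= center.v < H):
        raise ValidationError(f"centre {center} outside image {image_dims}")
    h_i, w_i = region_size(gamma, image_dims)

    u_l = int(round(center.u - w_i / 2))
    v_t = int(round(center.v - h_i / 2))
    if u_l < 0:
        u_l = 0
    elif u_l + w_i > W:
        u_l = W - w_i
    if v_t < 0:
        v_t = 0
    elif v_t + h_i > H:
        v_t = H - h_i
    return RegionBox(u_l=u_l, u_r=u_l + w_i, v_t=v_t, v_b=v_t + h_i)


def crop(image: np.ndarray, region: RegionBox) -> np.ndarray:
    """Copy the half-open sub-array of an ``(H, W[, C])`` image.

    Returns a copy, so mutating the patch never alters the source image.
    """
    image = np.asarray(image)
    H, W = image.shape[:2]
    if not (region.u_r <= W and region.v_b <= H):
        raise ValidationError(f"region {region} outside image of shape {image.shape}")
    return image[region.v_t : region.v_b, region.u_l : region.u_r].copy()
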