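"""Class activation maps (CAMs) and peak localisation.

A CAM for class ``y`` is the classifier-weighted sum of the last
convolutional layer's feature maps,

    Cam(x)[r, c] = sum_l  w_y[l] * F_l(x)[r, c],

where ``F(x)`` has shape ``(d, h, w)`` and ``w_y`` is the row of the final
linear layer (after global average pooling) belonging to class ``y``.  The
CAM lives on the coarse ``h x w`` grid of the last convolutional layer;
this module also provides the two ways of moving it into image space that
the augmentation pipeline needs: mapping the argmax coordinate alone
(cheap, used to centre the crop) and bilinearly upsampling the whole map
(used to weigh each patch by its share of activation mass).

Coordinates follow image convention: ``u`` is the horizontal index
(column), ``v`` the vertical index (row), ``v`` increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Tuple, TYPE_CHECKING

import numpy as np

from .errors import ShapeError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .regions import RegionBox

Space = Literal["map", "image"]


@dataclass(frozen=True)
class ActivationMap:
    """A 2-D activation map plus the coordinate space it lives in.

    ``space == "map"`` means the coarse grid of the last convolutional
    layer; ``space == "image"`` means pixel coordinates of the input image.
    """

    values: np.ndarray
    space: Space = "map"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ShapeError(f"activation map must be 2-D and non-empty, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("activation map contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape  # (rows, cols) == (h, w)


@dataclass(frozen=True)
class PeakCoord:
    """A single (u, v) coordinate in map or image space."""

    u: int
    v: int
    space: Space = "map"


def validate_feature_stack(features: np.ndarray) -> np.ndarray:
    """Check a (d, h, w) stack of last-conv-layer feature maps."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 3:
        raise ShapeError(f"feature stack must have shape (d, h, w), got {features.shape}")
    if min(features.shape) < 1:
        raise ShapeError(f"feature stack dims must be >= 1, got {features.shape}")
    if not np.all(np.isfinite(features)):
        raise ValidationError("feature stack contains non-finite values")
    return features


def compute_cam(features: np.ndarray, class_weights: np.ndarray) -> ActivationMap:
    """Weighted sum of feature maps: ``cam[r, c] = sum_l w[l] * F[l, r, c]``.

    Parameters
    ----------
    features
        Array of shape ``(d, h, w)`` from the last convolutional layer.
    class_weights
        Length-``d`` classifier weight vector of the target class.
    """
    features = validate_feature_stack(features)
    weights = np.asarray(class_weights, dtype=float)
    if weights.ndim != 1:
        raise ShapeError(f"class weights must be a vector, got shape {weights.shape}")
    if weights.shape[0] != features.shape[0]:
        raise ShapeError(
            f"class weights length {weights.shape[0]} != channel count {features.shape[0]}"
        )
    if not np.all(np.isfinite(weights)):
        raise ValidationError("class weights contain non-finite values")
    return ActivationMap(np.tensordot(weights, features, axes=1), space="map")


def locate_peak(cam: ActivationMap) -> PeakCoord:
    """Argmax coordinate of a map-space CAM.

    Ties are broken by first occurrence in a row-major scan (top-to-bottom,
    left-to-right), so the operator is deterministic.
    """
    if cam.space != "map":
        raise ValidationError("locate_peak expects a map-space CAM")
    flat_index = int(np.argmax(cam.values))  # argmax is row-major first-occurrence
    v, u = divmod(flat_index, cam.values.shape[1])
    return PeakCoord(u=u, v=v, space="map")


def map_to_image_coords(
    peak: PeakCoord, map_dims: Tuple[int, int], image_dims: Tuple[int, int]
) -> PeakCoord:
    """Convert a map-space peak to pixel coordinates.

    Uses the cell-origin scaling ``u_img = round(u * W / w)`` (and likewise
    for ``v``), clipped into image bounds.  ``map_dims`` and ``image_dims``
    are ``(height, width)`` pairs.
    """
    if peak.space != "map":
        raise ValidationError("peak must be in map space")
    h, w = map_dims
    H, W = image_dims
    if min(h, w, H, W) < 1:
        raise ValidationError(f"dimensions must be positive, got map {map_dims}, image {image_dims}")
    u_img = int(np.clip(round(peak.u * W / w), 0, W - 1))
    v_img = int(np.clip(round(peak.v * H / h), 0, H - 1))
    return PeakCoord(u=u_img, v=v_img, space="image")


def _resize_axis_coords(n_out: int, n_in: int) -> np.ndarray:
    """Continuous source coordinates for half-pixel-centre bilinear resizing."""
    coords = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    return np.clip(coords, 0.0, n_in - 1)


def bilinear_resize(values: np.ndarray, out_dims: Tuple[int, int]) -> np.ndarray:
    """Bilinearly resize a 2-D (or 2-D + channels) array to ``(H, W)``.

    Uses the half-pixel-centre sampling convention.  Output values are
    convex combinations of input values, so they never overshoot the input
    range.
    """
    values = np.asarray(values, dtype=float)
    H, W = out_dims
    if H < 1 or W < 1:
        raise ValidationError(f"output dims must be positive, got {out_dims}")
    rows = _resize_axis_coords(H, values.shape[0])
    cols = _resize_axis_coords(W, values.shape[1])
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    r1 = np.minimum(r0 + 1, values.shape[0] - 1)
    c1 = np.minimum(c0 + 1, values.shape[1] - 1)
    fr = rows - r0
    fc = cols - c0
    if values.ndim == 3:
        fr = fr[:, None, None]
        fc = fc[None, :, None]
    else:
        fr = fr[:, None]
        fc = fc[None, :]
    top = values[np.ix_(r0, c0)] * (1 - fc) + values[np.ix_(r0, c1)] * fc
    bottom = values[np.ix_(r1, c0)] * (1 - fc) + values[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bottom * fr


def upsample_cam(cam: ActivationMap, image_dims: Tuple[int, int]) -> ActivationMap:
    """Bilinearly enlarge a map-space CAM to image resolution ``(H, W)``."""
    if cam.space != "map":
        raise ValidationError("upsample_cam expects a map-space CAM")
    return ActivationMap(bilinear_resize(cam.values, image_dims), space="image")


def cam_mass(cam_img: ActivationMap, region: Optional["RegionBox"] = None) -> float:
    """Rectified activation mass of an image-space CAM over a region.

    Negative CAM values are clamped to zero before summation so the mass is
    a valid non-negative measure (label weights derived from mass ratios
    must land in [0, 1]).  With ``region=None`` the whole image is summed.
    """
    if cam_img.space != "image":
        raise ValidationError("cam_mass expects an image-space CAM")
    rectified = np.maximum(cam_img.values, 0.0)
    if region is None:
        return float(rectified.sum())
    H, W = rectified.shape
    if not (0 <= region.u_l < region.u_r <= W and 0 <= region.v_t < region.v_b <= H):
        raise ValidationError(f"region {region} outside image bounds ({H}, {W})")
    return float(rectified[region.v_t : region.v_b, region.u_l : region.u_r].sum())
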