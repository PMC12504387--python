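"""CAM heatmap overlays for qualitative inspection."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from matplotlib import colormaps

from .cam import ActivationMap, bilinear_resize, compute_cam, locate_peak, map_to_image_coords, upsample_cam
from .data import ImageSample
from .regions import RegionBox, region_from_center

CAM_ALPHA = 0.4  # fixed display blend of heatmap over image


def cam_overlay(
    image: np.ndarray,
    cam: ActivationMap,
    region: Optional[RegionBox] = None,
    peak: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Alpha-blend a min-max-normalised CAM heatmap over an image.

    The map-space CAM is upsampled to the image, scaled to [0, 1]
    (a constant CAM becomes a uniform mid-tint), coloured with the 'jet'
    colormap and blended at a fixed 0.4 alpha.  Optionally draws the
    extracted region's outline (white, 2 px) and the peak (red cross).
    """
    H, W = image.shape[:2]
    values = cam.values if cam.space == "image" else bilinear_resize(cam.values, (H, W))
    span = values.max() - values.min()
    norm = (values - values.min()) / span if span > 0 else np.full_like(values, 0.5)
    heat = colormaps["jet"](norm)[:, :, :3]
    out = (1 - CAM_ALPHA) * image + CAM_ALPHA * heat
    if region is not None:
        t = 2
        out[region.v_t : region.v_t + t, region.u_l : region.u_r] = 1.0
        out[region.v_b - t : region.v_b, region.u_l : region.u_r] = 1.0
        out[region.v_t : region.v_b, region.u_l : region.u_l + t] = 1.0
        out[region.v_t : region.v_b, region.u_r - t : region.u_r] = 1.0
    if peak is not None:
        u, v = peak
        r = 4
        out[max(v - r, 0) : v + r + 1, u, :] = [1.0, 0.0, 0.0]
        out[v, max(u - r, 0) : u + r + 1, :] = [1.0, 0.0, 0.0]
    return np.clip(out, 0.0, 1.0)


def visualize_sample(sample: ImageSample, adapter, gamma: float = 0.5) -> np.ndarray:
    """Full pipeline view for one sample: CAM, peak and extracted region."""
    cam = compute_cam(adapter.features(sample), adapter.class_weights(sample.label))
    peak = locate_peak(cam)
    center = map_to_image_coords(peak, cam.shape, sample.image_dims)
    region = region_from_center(center, gamma, sample.image_dims)
    cam_img = upsample_cam(cam, sample.image_dims)
    return cam_overlay(sample.image, cam_img, region=region, peak=(center.u, center.v))
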