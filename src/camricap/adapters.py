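"""Model adapters: objects that expose feature maps and classifier weights.

The augmentation pipeline is framework-agnostic.  Anything that implements
the adapter contract can drive it:

* ``features(sample) -> (d, h, w) array`` — last-convolutional-layer
  activations for one :class:`~camricap.data.ImageSample`;
* ``class_weights(class_id) -> (d,) array`` — the final linear layer's
  weight vector for one class (the network must end in global average
  pooling followed by a linear head for CAMs to be well defined);
* ``predict_logits(sample) -> (num_classes,) array``.

Three adapters ship with the package: a small trainable CNN written with
numpy (im2col convolutions, Adam updates), an analytic adapter whose
feature map is a Gaussian bump planted at a sample's known lesion centre,
and a constant-CAM adapter whose activation mass is uniform (useful for
checking that CAM weighting degrades to area weighting).
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .cam import bilinear_resize
from .data import ImageSample
from .errors import ShapeError, ValidationError


# ---------------------------------------------------------------------------
# numpy convolution plumbing


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(B, H, W, C) -> (B, H, W, k*k*C) patches with 'same' zero padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    B, H, W, C = x.shape
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(B, H, W, k, k, C), strides=(s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return np.ascontiguousarray(view).reshape(B, H, W, k * k * C)


def _col2im(dcol: np.ndarray, in_shape: Tuple[int, ...], k: int = 3) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    B, H, W, C = in_shape
    pad = k // 2
    dxp = np.zeros((B, H + 2 * pad, W + 2 * pad, C))
    dcol = dcol.reshape(B, H, W, k, k, C)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + H, j : j + W, :] += dcol[:, :, :, i, j, :]
    return dxp[:, pad : pad + H, pad : pad + W, :]


def _maxpool2(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    B, H, W, C = x.shape
    xr = x.reshape(B, H // 2, 2, W // 2, 2, C)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    # split gradient equally among tied maxima so the backward pass is
    # deterministic regardless of tie layout
    mask = mask / mask.sum(axis=(2, 4), keepdims=True)
    return out, mask.reshape(x.shape)


def _maxpool2_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    B, Ho, Wo, C = dout.shape
    expanded = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2)
    return expanded * mask


class _Adam:
    """Adam with additive (L2) weight decay, one slot per parameter array."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, p in self.params.items():
            g = grads[key] + self.wd * p
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    """Plain SGD with L2 weight decay (selectable alternative to Adam)."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.wd = weight_decay

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        for key, p in self.params.items():
            p -= self.lr * (grads[key] + self.wd * p)


# ---------------------------------------------------------------------------
# trainable CNN adapter


class TinyCnnAdapter:
    """A small trainable CNN ending in global average pooling + linear head.

    Architecture: the input is area-averaged down to ``pool_to x pool_to``
    (default 16) and centred by subtracting its median colour (leaf images
    are background-dominated, so this cancels the class-neutral background
    and lets localised symptom colour dominate).  Then: a 3x3 convolution
    whose first six filters are a fixed signed colour basis, two 1x1
    convolution blocks (leaky ReLU, 2x2 max-pool after the first two
    layers), global average pooling and a bias-free linear classifier.
    Keeping the later convolutions pointwise makes the last-layer features
    spatially local, which keeps the CAM aligned with the evidence.  The
    third convolution's activations are the CAM feature stack (default 32
    channels on a 4 x 4 grid).

    All arithmetic is float64 numpy; updates are Adam or SGD with L2
    weight decay.  The same object serves as the CAM provider during
    augmented training: ``features``/``class_weights`` read the current
    weights without mutating any training state.
    """

    def __init__(
        self,
        num_classes: int,
        channels: Tuple[int, int, int] = (8, 16, 32),
        pool_to: int = 16,
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-5,
        optimizer: str = "adam",
        cam_resolution: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ):
        if num_classes < 2:
            raise ValidationError("need at least two classes")
        if pool_to % 4 != 0:
            raise ValidationError("pool_to must be divisible by 4 (two 2x2 pools)")
        rng = rng or np.random.default_rng(0)
        c1, c2, c3 = channels
        self.num_classes = num_classes
        self.pool_to = pool_to
        self.cam_resolution = cam_resolution or pool_to  # input side of the CAM feature pass
        self.leak = 0.1  # leaky-ReLU slope; avoids dead units in a very small net
        he = lambda k, cin, cout: rng.standard_normal((k, k, cin, cout)) * np.sqrt(
            2.0 / (k * k * cin)
        )
        W1 = he(3, 3, c1)
        # colour-basis stem: the first filters are signed single-channel
        # centre taps (+R, -R, +G, -G, ...), so channel-opponent detectors
        # exist from the first step instead of having to emerge by descent
        for j in range(min(2 * 3, c1)):
            W1[:, :, :, j] = 0.0
            W1[1, 1, j // 2, j] = 1.0 if j % 2 == 0 else -1.0
        self.params: Dict[str, np.ndarray] = {
            "W1": W1, "b1": np.zeros(c1),
            "W2": he(1, c1, c2), "b2": np.zeros(c2),
            "W3": he(1, c2, c3), "b3": np.zeros(c3),
            "Wfc": rng.standard_normal((c3, num_classes)) * 0.01,
        }
        if optimizer == "adam":
            self.optimizer = _Adam(self.params, learning_rate, weight_decay)
        elif optimizer == "sgd":
            self.optimizer = _SGD(self.params, learning_rate, weight_decay)
        else:
            raise ValidationError(f"unknown optimizer {optimizer!r}")

    # -- forward ---------------------------------------------------------

    def _prepare(self, images: np.ndarray, side: Optional[int] = None) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim == 3:
            images = images[None]
        if images.ndim != 4:
            raise ShapeError(f"expected (B, H, W, C) images, got shape {images.shape}")
        side = side or self.pool_to
        if images.shape[1] != side or images.shape[2] != side:
            B, H, W, C = images.shape
            if H % side == 0 and W % side == 0:
                # area averaging: integrates small structures instead of
                # point-sampling them, the right filter for heavy downscaling
                fh, fw = H // side, W // side
                images = images.reshape(B, side, fh, side, fw, C).mean(axis=(2, 4))
            else:
                images = np.stack([bilinear_resize(im, (side, side)) for im in images])
        # subtract each image's median colour: leaves are background-dominated,
        # so this cancels the (class-neutral) background and makes localised
        # symptom colour the dominant signal
        return images - np.median(images, axis=(1, 2), keepdims=True)

    def _forward(self, images: np.ndarray, keep_cache: bool = False,
                 side: Optional[int] = None):
        p = self.params
        x = self._prepare(images, side=side)
        col1 = _im2col(x)
        z1 = col1 @ p["W1"].reshape(-1, p["W1"].shape[-1]) + p["b1"]
        a1 = np.where(z1 > 0, z1, self.leak * z1)
        p1, mask1 = _maxpool2(a1)
        col2 = _im2col(p1, k=1)
        z2 = col2 @ p["W2"].reshape(-1, p["W2"].shape[-1]) + p["b2"]
        a2 = np.where(z2 > 0, z2, self.leak * z2)
        p2, mask2 = _maxpool2(a2)
        col3 = _im2col(p2, k=1)
        z3 = col3 @ p["W3"].reshape(-1, p["W3"].shape[-1]) + p["b3"]
        feat = np.where(z3 > 0, z3, self.leak * z3)  # (B, 8, 8, c3) CAM feature stack
        gap = feat.mean(axis=(1, 2))
        logits = gap @ p["Wfc"]
        if not keep_cache:
            return logits, feat
        cache = dict(x=x, col1=col1, z1=z1, a1=a1, mask1=mask1, p1=p1,
                     col2=col2, z2=z2, a2=a2, mask2=mask2, p2=p2,
                     col3=col3, z3=z3, feat=feat, gap=gap)
        return logits, feat, cache

    # -- adapter contract ------------------------------------------------

    def features(self, sample: ImageSample) -> np.ndarray:
        """(d, h, w) last-conv-layer activations, evaluated fully convolutionally.

        The stack is run at ``cam_resolution`` input side (finer than the
        training side), which the weights support because every layer is
        convolutional; this gives the CAM a usefully fine grid.
        """
        _, feat = self._forward(sample.image[None], side=self.cam_resolution)
        return np.transpose(feat[0], (2, 0, 1))

    def class_weights(self, class_id: int) -> np.ndarray:
        if not 0 <= class_id < self.num_classes:
            raise ValidationError(f"class id {class_id} out of range")
        return self.params["Wfc"][:, class_id].copy()

    def predict_logits(self, sample: ImageSample) -> np.ndarray:
        logits, _ = self._forward(sample.image[None])
        return logits[0]

    def predict_logits_batch(self, images: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(images)
        return logits

    # -- training --------------------------------------------------------

    def train_step(self, images: np.ndarray, soft_labels: np.ndarray) -> float:
        """One forward/backward/update pass; returns the mean batch loss."""
        p = self.params
        soft_labels = np.asarray(soft_labels, dtype=float)
        logits, _, c = self._forward(images, keep_cache=True)
        B = logits.shape[0]
        shifted = logits - logits.max(axis=1, keepdims=True)
        log_z = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        log_probs = shifted - log_z
        loss = float(-(soft_labels * log_probs).sum(axis=1).mean())

        dlogits = (np.exp(log_probs) - soft_labels) / B
        grads: Dict[str, np.ndarray] = {}
        grads["Wfc"] = c["gap"].T @ dlogits
        dgap = dlogits @ p["Wfc"].T
        h, w = c["feat"].shape[1:3]
        dfeat = np.broadcast_to(dgap[:, None, None, :] / (h * w), c["feat"].shape)
        dz3 = dfeat * np.where(c["z3"] > 0, 1.0, self.leak)
        grads["W3"] = (c["col3"].reshape(-1, c["col3"].shape[-1]).T
                       @ dz3.reshape(-1, dz3.shape[-1])).reshape(p["W3"].shape)
        grads["b3"] = dz3.sum(axis=(0, 1, 2))
        dp2 = _col2im(dz3 @ p["W3"].reshape(-1, p["W3"].shape[-1]).T, c["p2"].shape, k=1)
        da2 = _maxpool2_backward(dp2, c["mask2"])
        dz2 = da2 * np.where(c["z2"] > 0, 1.0, self.leak)
        grads["W2"] = (c["col2"].reshape(-1, c["col2"].shape[-1]).T
                       @ dz2.reshape(-1, dz2.shape[-1])).reshape(p["W2"].shape)
        grads["b2"] = dz2.sum(axis=(0, 1, 2))
        dp1 = _col2im(dz2 @ p["W2"].reshape(-1, p["W2"].shape[-1]).T, c["p1"].shape, k=1)
        da1 = _maxpool2_backward(dp1, c["mask1"])
        dz1 = da1 * np.where(c["z1"] > 0, 1.0, self.leak)
        grads["W1"] = (c["col1"].reshape(-1, c["col1"].shape[-1]).T
                       @ dz1.reshape(-1, dz1.shape[-1])).reshape(p["W1"].shape)
        grads["b1"] = dz1.sum(axis=(0, 1, 2))

        self.optimizer.step(grads)
        return loss

    # -- persistence -----------------------------------------------------

    def save_weights(self, directory) -> None:
        """Write one .npy per parameter (bytewise reproducible)."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for key, value in self.params.items():
            np.save(directory / f"{key}.npy", value)

    def load_weights(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        for key in self.params:
            self.params[key] = np.load(directory / f"{key}.npy")
        self.optimizer.params = self.params


# ---------------------------------------------------------------------------
# analytic adapters (test doubles with known structure)


class AnalyticLesionAdapter:
    """Adapter whose feature map is a Gaussian bump at the known lesion.

    For a sample with lesion centre ``(u, v)`` in pixel coordinates, the
    feature stack is a single ``h x w`` channel with a Gaussian profile
    centred at ``(u * w / W, v * h / H)`` and width ``sigma * w / W`` map
    cells; the class weight is 1.  The CAM peak therefore sits on the
    lesion by construction, which makes region-recovery testable.

    ``predict_logits`` returns a one-hot of the sample's true label: the
    adapter is an oracle classifier for synthetic data.
    """

    def __init__(self, map_dims: Tuple[int, int] = (7, 7),
                 image_dims: Tuple[int, int] = (224, 224),
                 sigma: float = 10.0, num_classes: int = 3):
        self.map_dims = map_dims
        self.image_dims = image_dims
        self.sigma = sigma
        self.num_classes = num_classes

    def features(self, sample: ImageSample) -> np.ndarray:
        if sample.lesion_center is None:
            raise ValidationError("analytic adapter needs samples with lesion_center metadata")
        h, w = self.map_dims
        H, W = self.image_dims
        u, v = sample.lesion_center
        cu = u * w / W
        cv = v * h / H
        sigma_map = max(self.sigma * w / W, 1e-6)
        vv, uu = np.mgrid[0:h, 0:w]
        bump = np.exp(-((uu - cu) ** 2 + (vv - cv) ** 2) / (2 * sigma_map ** 2))
        return bump[None]

    def class_weights(self, class_id: int) -> np.ndarray:
        return np.ones(1)

    def predict_logits(self, sample: ImageSample) -> np.ndarray:
        logits = np.zeros(self.num_classes)
        logits[sample.label] = 1.0
        return logits


class ConstantCamAdapter:
    """Adapter with a spatially uniform CAM (every location equally salient).

    CAM mass over a patch is then proportional to patch area, so label
    weights collapse to relative areas — the classic RICAP weighting.
    """

    def __init__(self, map_dims: Tuple[int, int] = (7, 7), value: float = 1.0,
                 num_classes: int = 3):
        self.map_dims = map_dims
        self.value = value
        self.num_classes = num_classes

    def features(self, sample: ImageSample) -> np.ndarray:
        return np.full((1,) + tuple(self.map_dims), self.value)

    def class_weights(self, class_id: int) -> np.ndarray:
        return np.ones(1)

    def predict_logits(self, sample: ImageSample) -> np.ndarray:
        return np.zeros(self.num_classes)
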