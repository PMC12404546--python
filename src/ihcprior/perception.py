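"""Feature-importance attention over backbone feature maps.

The perception pipeline scores each feature channel by how it overlaps with
the stained structures visible in the image itself, then uses the scores to
build a class activation map (CAM) that re-weights the features:

1. the RGB patch is converted to grayscale and area-averaged down to the
   feature grid (``grayscale_downsample``);
2. each feature channel is min-max normalized to [0, 1] and multiplied by
   the grayscale image, giving a stack of masks (``build_masks``);
3. a small learnable head, the feature weighting block (FWB), maps the mask
   stack to one importance score per channel (``FeatureWeightingBlock``);
4. the CAM is ``ReLU(sum_c S_c * F_c)`` (``build_cam``) and the attended
   features are ``(1 + CAM) * F`` (``apply_attention``), so a zero CAM
   leaves the features untouched.

Spatial arrays here are channels-last (``h x w x c``), matching how feature
maps are usually displayed; the training engine transposes as needed.
"""

from __future__ import annotations

import numpy as np

from .nn import core as _nncore
from .nn.core import Conv2d, GlobalAvgPool2d, Linear, Module, ReLU, Sequential

__all__ = [
    "grayscale_downsample",
    "normalize_channels",
    "build_masks",
    "FeatureWeightingBlock",
    "build_cam",
    "apply_attention",
    "upsample_cam",
    "LUMA_WEIGHTS",
]

#: ITU-R 601 luminance weights for rgb -> gray
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def grayscale_downsample(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Luminance conversion + area-average downsampling, rescaled to [0, 1].

    ``image`` is ``H x W x 3`` (or ``N x H x W x 3``), uint8 in [0, 255] or
    float already in [0, 1].  ``target`` must evenly divide the input grid
    and may not exceed it.
    """
    image = np.asarray(image)
    if image.shape[-1] != 3:
        raise ValueError(f"expected 3 channels last, got shape {image.shape}")
    h, w = target
    H, W = image.shape[-3], image.shape[-2]
    if h > H or w > W:
        raise ValueError(f"cannot upsample {H}x{W} to {h}x{w}")
    if H % h or W % w:
        raise ValueError(f"target {h}x{w} must evenly divide input {H}x{W}")
    arr = image.astype(float)
    if image.dtype == np.uint8 or arr.max() > 1.0:
        arr = arr / 255.0
    gray = arr @ LUMA_WEIGHTS
    lead = gray.shape[:-2]
    blocks = gray.reshape(*lead, h, H // h, w, W // w)
    return blocks.mean(axis=(-3, -1))


def normalize_channels(f: np.ndarray) -> np.ndarray:
    """Min-max scale each feature channel to [0, 1], per sample.

    ``f`` is ``(..., h, w, c)``; spatial min/max are taken per channel.
    Constant channels map to all zeros.
    """
    f = np.asarray(f, dtype=float)
    lo = f.min(axis=(-3, -2), keepdims=True)
    hi = f.max(axis=(-3, -2), keepdims=True)
    span = hi - lo
    out = np.zeros_like(f)
    np.divide(f - lo, span, out=out, where=span > 0)
    return out


def build_masks(gray: np.ndarray, f_norm: np.ndarray) -> np.ndarray:
    """Elementwise product of the grayscale image with each feature channel."""
    gray = np.asarray(gray, dtype=float)
    f_norm = np.asarray(f_norm, dtype=float)
    if gray.shape[-2:] != f_norm.shape[-3:-1]:
        raise ValueError(
            f"gray grid {gray.shape[-2:]} does not match features {f_norm.shape[-3:-1]}"
        )
    return gray[..., None] * f_norm


class FeatureWeightingBlock(Module):
    """Learnable per-channel scorer for the mask stack.

    The same tiny scorer (two 3x3 convs -> global average pool -> linear) is
    applied to every mask channel independently with shared weights, so the
    block is equivariant to channel permutations: permuting the channels of
    the mask stack permutes the scores identically.

    The score head's bias starts at +0.5, so the initial CAM is plain
    feature-magnitude saliency (a uniformly positive combination of the
    post-ReLU channels); training then reshapes the per-channel weights
    around that positive operating point.  With a zero-centered start the
    scores hover near zero and the attention map degenerates into sign
    noise instead of highlighting the stained structures.
    """

    def __init__(
        self,
        hidden: int = 4,
        channels: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.hidden = hidden
        self.body = Sequential(
            Conv2d(1, hidden, 3, rng=rng),
            ReLU(),
            Conv2d(hidden, hidden, 3, rng=rng),
            ReLU(),
            GlobalAvgPool2d(),
        )
        self.head = Linear(hidden, 1, rng=rng)
        self.head.bias.data[...] = 0.5  # positive saliency at init

    def forward(self, masks: np.ndarray, train: bool = False) -> np.ndarray:
        """Mask stack ``(h, w, c)`` or ``(N, h, w, c)`` -> scores ``(c,)``/``(N, c)``."""
        masks = np.asarray(masks, dtype=_nncore.DTYPE)
        single = masks.ndim == 3
        if single:
            masks = masks[None]
        n, h, w, c = masks.shape
        if self.channels is not None and c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        # fold channels into the batch so one shared scorer sees each mask
        folded = np.ascontiguousarray(masks.transpose(0, 3, 1, 2)).reshape(n * c, h, w, 1)
        feats = self.body.forward(folded, train=train)
        scores = self.head.forward(feats, train=train).reshape(n, c)
        if train:
            self._nc = (n, c)
        return scores[0] if single else scores

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c = self._nc
        grad = np.asarray(grad, dtype=_nncore.DTYPE).reshape(n * c, 1)
        dfolded = self.body.backward(self.head.backward(grad))
        h, w = dfolded.shape[1:3]
        return dfolded.reshape(n, c, h, w).transpose(0, 2, 3, 1)

    __call__ = forward


def build_cam(scores: np.ndarray, f: np.ndarray) -> np.ndarray:
    """``ReLU(sum_c S_c * F_c)``: nonnegative activation map ``(..., h, w)``."""
    scores = np.asarray(scores, dtype=float)
    f = np.asarray(f, dtype=float)
    if scores.shape[-1] != f.shape[-1]:
        raise ValueError(
            f"{scores.shape[-1]} scores for {f.shape[-1]} feature channels"
        )
    weighted = np.einsum("...hwc,...c->...hw", f, scores)
    return np.maximum(weighted, 0.0)


def apply_attention(cam: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Re-weight features as ``(1 + CAM) * F``; a zero CAM is the identity."""
    cam = np.asarray(cam, dtype=float)
    f = np.asarray(f, dtype=float)
    if cam.shape[-2:] != f.shape[-3:-1]:
        raise ValueError(
            f"CAM grid {cam.shape[-2:]} does not match features {f.shape[-3:-1]}"
        )
    return (1.0 + cam)[..., None] * f


def upsample_cam(cam: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear upsample a CAM to image resolution, max-scaled to [0, 1]."""
    from skimage.transform import resize

    cam = np.asarray(cam, dtype=float)
    up = resize(cam, size, order=1, mode="edge", anti_aliasing=False)
    peak = up.max()
    if peak > 0:
        up = up / peak
    return np.clip(up, 0.0, 1.0)
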