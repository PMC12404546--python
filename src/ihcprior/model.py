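"""The prior-guided two-branch classifier.

An IHC branch extracts features from the RGB patch and re-weights them with
the perception module's CAM attention; a CD (color deconvolution) branch
extracts features from the single-channel DAB anomaly map.  Both branches
are globally average-pooled to one vector per branch, concatenated to a
``2c`` feature, layer-normalized and mapped by a single linear layer to the
class logits.  Either the prior branch or the attention can be switched off
to obtain the ablation baselines.

`IHCClassifier` wraps the network in a model-object API: construct it from
labeled patch records, call :meth:`IHCClassifier.fit`, and inspect the
returned results object (curves, metrics, summary table, CAM export).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.backbones import BACKBONE_GRID, build_backbone
from .perception import (
    FeatureWeightingBlock,
    build_masks,
    grayscale_downsample,
    normalize_channels,
)

__all__ = [
    "PriorGuidedNetwork",
    "global_pool",
    "count_parameters",
    "parameter_millions",
    "IHCClassifier",
]

#: inputs are scaled from [0, 1] to zero mean / unit-ish spread
_INPUT_MEAN = 0.5
_INPUT_SCALE = 0.25


class PriorGuidedNetwork(nn.Module):
    """Two-branch CNN with CAM attention and a fused LayerNorm+linear head.

    Parameters
    ----------
    backbone : {"small_cnn", "resnet18"}
        Feature extractor for both branches.
    num_classes : int
        Length of the logit vector (4 for the negative/weak/positive/strong
        task, 2 for binary screening).
    input_size : int
        Side length of the square input patch; must map to a 16x16 grid.
    feature_channels : int
        Channel count ``c`` of the backbone output (small_cnn only;
        resnet18 is fixed at 512).
    use_prior : bool
        Include the CD branch on the DAB anomaly map.
    use_attention : bool
        Include the FWB/CAM attention in the IHC branch.
    """

    def __init__(
        self,
        backbone: str = "small_cnn",
        num_classes: int = 4,
        input_size: int = 64,
        feature_channels: int = 64,
        use_prior: bool = True,
        use_attention: bool = True,
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.backbone_name = backbone
        self.num_classes = num_classes
        self.input_size = input_size
        self.use_prior = use_prior
        self.use_attention = use_attention
        self.backbone_o = build_backbone(backbone, 3, input_size, feature_channels, rng)
        self.c = self.backbone_o.out_channels
        if use_prior:
            self.backbone_p = build_backbone(backbone, 1, input_size, feature_channels, rng)
        if use_attention:
            self.fwb = FeatureWeightingBlock(rng=rng)
        feat_dim = 2 * self.c if use_prior else self.c
        self.norm = nn.LayerNorm(feat_dim)
        self.head = nn.Linear(feat_dim, num_classes, rng=rng)
        # small-init the classifier head: near-uniform class probabilities
        # at initialization, so the initial loss is ~ln(num_classes)
        self.head.weight.data *= 0.01

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        io: np.ndarray,
        ip: np.ndarray | None = None,
        train: bool = False,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Classify a batch of patches.

        ``io`` is ``(N, H, W, 3)`` uint8 (or float in [0, 255]); ``ip`` is
        the aligned ``(N, H, W)`` anomaly map in [0, 1], required when the
        prior branch is enabled.  Returns ``(logits, cam)`` with ``cam`` the
        per-sample max-normalized 16x16 activation map in [0, 1].
        """
        io = np.asarray(io)
        if io.ndim != 4 or io.shape[-1] != 3:
            raise ValueError(f"expected (N, H, W, 3) images, got {io.shape}")
        if io.shape[1] != self.input_size or io.shape[2] != self.input_size:
            raise ValueError(
                f"expected {self.input_size}px patches, got {io.shape[1]}x{io.shape[2]}"
            )
        n = io.shape[0]
        dtype = nn.core.DTYPE
        x = ((io.astype(dtype) / 255.0 - _INPUT_MEAN) / _INPUT_SCALE).astype(dtype)
        feats = self.backbone_o.forward(x, train=train)  # (N, 16, 16, c)

        if self.use_attention:
            gray = grayscale_downsample(io, (BACKBONE_GRID, BACKBONE_GRID))
            masks = build_masks(gray, normalize_channels(feats)).astype(dtype)
            scores = self.fwb.forward(masks, train=train)  # (N, c)
            pre_cam = np.einsum("nhwc,nc->nhw", feats, scores)
            raw_cam = np.maximum(pre_cam, 0.0)
            # max-normalize per sample so (1 + CAM) stays in [1, 2]; an
            # unbounded CAM would rescale the IHC branch with the channel
            # count and drown the CD branch out of the fused LayerNorm
            peak = raw_cam.max(axis=(1, 2), keepdims=True)
            inv_peak = 1.0 / np.where(peak > 0, peak, 1.0)  # stop-gradient
            cam = raw_cam * inv_peak
            attended = (1.0 + cam)[..., None] * feats
        else:
            scores = None
            pre_cam = None
            inv_peak = None
            cam = np.zeros((n, BACKBONE_GRID, BACKBONE_GRID))
            attended = feats

        f_o = attended.mean(axis=(1, 2))  # global average pool, (N, c)

        if self.use_prior:
            if ip is None:
                raise ValueError("prior branch enabled but no anomaly map given")
            ip = np.asarray(ip)
            if ip.ndim == 4 and ip.shape[-1] == 1:
                ip = ip[..., 0]
            if ip.shape != io.shape[:3]:
                raise ValueError(
                    f"anomaly maps {ip.shape} not aligned with images {io.shape[:3]}"
                )
            xp = ((ip.astype(dtype) - _INPUT_MEAN) / _INPUT_SCALE)[..., None]
            feats_p = self.backbone_p.forward(xp, train=train)
            f_p = feats_p.mean(axis=(1, 2))
            fused = np.concatenate([f_o, f_p], axis=1)
        else:
            fused = f_o

        logits = self.head.forward(self.norm.forward(fused, train=train), train=train)
        if train:
            self._cache = (feats, scores, pre_cam, cam, inv_peak)
        return logits, cam

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a logit gradient through both branches.

        Gradients flow through the CAM into the FWB parameters and the
        backbone features; the min-max-normalized mask stack and the CAM's
        per-sample peak are treated as stop-gradient (see the methods note).
        """
        feats, scores, pre_cam, cam, inv_peak = self._cache
        n = dlogits.shape[0]
        hw = BACKBONE_GRID * BACKBONE_GRID
        dfused = self.norm.backward(self.head.backward(dlogits))
        if self.use_prior:
            df_o, df_p = dfused[:, : self.c], dfused[:, self.c :]
            dfeats_p = np.broadcast_to(
                df_p[:, None, None, :] / hw, (n, BACKBONE_GRID, BACKBONE_GRID, self.c)
            ).copy()
            self.backbone_p.backward(dfeats_p)
        else:
            df_o = dfused
        dattended = np.broadcast_to(
            df_o[:, None, None, :] / hw, (n, BACKBONE_GRID, BACKBONE_GRID, self.c)
        ).copy()
        if self.use_attention:
            dfeats = (1.0 + cam)[..., None] * dattended
            dcam = (dattended * feats).sum(axis=-1)
            dpre = dcam * inv_peak * (pre_cam > 0)
            dscores = np.einsum("nhw,nhwc->nc", dpre, feats)
            dfeats += dpre[..., None] * scores[:, None, None, :]
            self.fwb.backward(dscores)
        else:
            dfeats = dattended
        self.backbone_o.backward(dfeats)
        self._cache = None

    # convenience ----------------------------------------------------------

    def predict_logits(self, io: np.ndarray, ip: np.ndarray | None = None) -> np.ndarray:
        return self.forward(io, ip, train=False)[0]


def global_pool(f: np.ndarray) -> np.ndarray:
    """Adaptive average pooling: spatial mean per channel.

    ``(h, w, c)`` -> ``(c,)`` or ``(N, h, w, c)`` -> ``(N, c)``.
    """
    f = np.asarray(f)
    if f.ndim == 3:
        return f.mean(axis=(0, 1))
    if f.ndim == 4:
        return f.mean(axis=(1, 2))
    raise ValueError(f"expected a (h, w, c) or (N, h, w, c) tensor, got {f.shape}")


def count_parameters(model: nn.Module) -> int:
    """Exact number of trainable parameters of a network (or any module)."""
    return nn.count_parameters(model)


def parameter_millions(model: nn.Module) -> float:
    """Parameter count in millions, rounded to 2 decimals (report style)."""
    return round(count_parameters(model) / 1e6, 2)


# ---------------------------------------------------------------------------
# model-object facade
# ---------------------------------------------------------------------------

@dataclass
class _DataBundle:
    train: list
    val: list


class IHCClassifier:
    """Prior-guided IHC patch classifier with a fit/results workflow.

    Parameters
    ----------
    train_records, val_records : list of PatchRecord
        Labeled patches (from `ihcprior.synth` or loaded from a manifest).
    backbone : {"small_cnn", "resnet18"}
    use_prior, use_attention : bool
        Ablation switches for the CD branch and the CAM attention.
    classes : tuple of str
        Label set, in logit order.

    Examples
    --------
    >>> from ihcprior import synth
    >>> records = synth.generate_dataset({c: 12 for c in synth.CLASS_NAMES},
    ...                                  patch_size=64, seed=0)
    >>> manifest = synth.split_dataset(records, seed=0)
    >>> train = [r for r in records if r.split == "train"]
    >>> val = [r for r in records if r.split == "val"]
    >>> model = IHCClassifier(train, val)
    >>> results = model.fit(epochs=2, seed=0)   # doctest: +SKIP
    >>> print(results.summary())                # doctest: +SKIP
    """

    def __init__(
        self,
        train_records: list,
        val_records: list,
        backbone: str = "small_cnn",
        use_prior: bool = True,
        use_attention: bool = True,
        classes: tuple[str, ...] | None = None,
        feature_channels: int = 64,
    ) -> None:
        from .synth import CLASS_NAMES

        if not train_records or not val_records:
            raise ValueError("both train and validation records are required")
        self.data = _DataBundle(train=list(train_records), val=list(val_records))
        self.backbone = backbone
        self.use_prior = use_prior
        self.use_attention = use_attention
        self.classes = tuple(classes) if classes is not None else CLASS_NAMES
        self.feature_channels = feature_channels
        self.input_size = int(np.asarray(train_records[0].image).shape[0])

    @classmethod
    def from_manifest(cls, manifest_path: str, **kwargs) -> "IHCClassifier":
        """Build from a manifest.csv with a populated ``split`` column."""
        from .synth import load_dataset

        records = load_dataset(manifest_path)
        train = [r for r in records if r.split == "train"]
        val = [r for r in records if r.split == "val"]
        return cls(train, val, **kwargs)

    def build_network(self, seed: int = 0) -> PriorGuidedNetwork:
        return PriorGuidedNetwork(
            backbone=self.backbone,
            num_classes=len(self.classes),
            input_size=self.input_size,
            feature_channels=self.feature_channels,
            use_prior=self.use_prior,
            use_attention=self.use_attention,
            seed=seed,
        )

    def fit(self, config=None, seed: int = 0, verbose: bool = False, **overrides):
        """Train the network and return an :class:`IHCClassifierResults`.

        ``config`` is a `TrainConfig`; keyword overrides (``epochs=...``,
        ``lr=...``) are applied on top of the desk-scale preset when no
        config is given.
        """
        from .traineval import IHCClassifierResults, TrainConfig, desk_config, train

        if config is None:
            config = desk_config(**overrides)
        elif overrides:
            from dataclasses import replace

            config = replace(config, **overrides)
        if not isinstance(config, TrainConfig):
            raise TypeError("config must be a TrainConfig")
        network = self.build_network(seed=seed)
        outcome = train(
            network,
            self.data.train,
            self.data.val,
            config,
            classes=self.classes,
            seed=seed,
            verbose=verbose,
        )
        return IHCClassifierResults(model=self, network=network, outcome=outcome, seed=seed)
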