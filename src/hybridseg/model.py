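"""Encoder-decoder segmentation network and its three hybrid fusion variants.

The baseline is a U-Net-style network: four encoder stages (default channel
widths 64, 128, 256, 512), each a pair of 3x3 convolutions + ReLU followed by
2x2 max pooling, a bottleneck at the deepest width, and a mirrored decoder
with nearest-neighbour upsampling and skip connections, ending in a 1x1
convolution to ``n_classes`` with a per-pixel softmax.

Handcrafted feature channels can be fused in at three points:

* ``input_channel``  — concatenated to the image modalities at the input;
* ``feature_map``    — average-pool downsampled and concatenated to the
  output of an intermediate encoder stage (after its pooling, before the
  next stage's convolution);
* ``decision_level`` — concatenated to the last decoder feature map, so the
  final classifier sees ``64 + k`` channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Var

FUSION_MODES = ("none", "input_channel", "feature_map", "decision_level")


@dataclass
class HybridModelConfig:
    """Architecture + fusion-strategy description."""

    input_size: int = 256
    in_channels: int = 4
    encoder_channels: tuple[int, ...] = (64, 128, 256, 512)
    n_classes: int = 4
    fusion: str = "none"
    handcrafted_channels: int = 0
    fusion_depth: int = 0  # encoder stage index, feature_map mode only

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.handcrafted_channels < 0:
            raise ValueError("handcrafted_channels must be >= 0")
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        stages = len(self.encoder_channels)
        if self.input_size % (2**stages) != 0:
            raise ValueError(
                f"invalid input size: {self.input_size} not divisible by {2 ** stages}"
            )
        if self.fusion == "feature_map" and not (
            0 <= self.fusion_depth < stages
        ):
            raise ValueError("bad fusion point")


@dataclass
class PredictionMap:
    """Per-pixel class probabilities and the argmax label mask."""

    probabilities: np.ndarray  # (N, n_classes, H, W)
    labels: np.ndarray  # (N, H, W) int

    def __post_init__(self):
        s = self.probabilities.sum(axis=1)
        if not np.allclose(s, 1.0, atol=1e-5):
            raise ValueError("probabilities do not sum to 1 per pixel")


class SegmentationCNN:
    """A built network: parameter arrays plus the forward graph."""

    def __init__(self, config: HybridModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self._shapes: list[tuple[str, int, int, int]] = []  # name, cin, cout, k
        rng = np.random.default_rng(seed)

        c = config.encoder_channels
        k = config.handcrafted_channels
        self._fusion_conv = {  # layer name -> fused channel count
            "input_channel": {"enc0_conv1": k},
            "feature_map": {
                (
                    f"enc{config.fusion_depth + 1}_conv1"
                    if config.fusion_depth + 1 < len(c)
                    else "bott_conv1"
                ): k
            },
            "decision_level": {"head": k},
            "none": {},
        }[config.fusion]

        self._add("enc0_conv1", config.in_channels, c[0], 3, rng)
        self._add("enc0_conv2", c[0], c[0], 3, rng)
        for i in range(1, len(c)):
            self._add(f"enc{i}_conv1", c[i - 1], c[i], 3, rng)
            self._add(f"enc{i}_conv2", c[i], c[i], 3, rng)
        self._add("bott_conv1", c[-1], c[-1], 3, rng)
        self._add("bott_conv2", c[-1], c[-1], 3, rng)
        for i in reversed(range(len(c))):
            src = c[i + 1] if i + 1 < len(c) else c[-1]
            self._add(f"dec{i}_conv1", src, c[i], 3, rng)
            self._add(f"dec{i}_conv2", 2 * c[i], c[i], 3, rng)
        self._add("head", c[0], config.n_classes, 1, rng)
        # fusion weight slices last, so same-seed builds share backbone draws
        for name, extra_k in self._fusion_conv.items():
            kk = 1 if name == "head" else 3
            cout = next(s[2] for s in self._shapes if s[0] == name)
            std = np.sqrt(2.0 / (extra_k * kk * kk))
            self.params[f"{name}.wf"] = (
                rng.standard_normal((cout, extra_k, kk, kk)) * std
            ).astype(np.float32)

    # -- construction helpers ------------------------------------------------

    def _add(self, name: str, cin: int, cout: int, k: int, rng) -> None:
        std = np.sqrt(2.0 / (cin * k * k))
        self.params[f"{name}.w"] = (
            rng.standard_normal((cout, cin, k, k)) * std
        ).astype(np.float32)
        self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)
        self._shapes.append((name, cin, cout, k))

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward -------------------------------------------------------------

    def _check_inputs(self, x: np.ndarray, feats: np.ndarray | None) -> None:
        cfg = self.config
        if cfg.fusion != "none" and feats is None:
            raise ValueError("fusion input required")
        if x.shape[1] != cfg.in_channels:
            raise ValueError(
                f"expected {cfg.in_channels} image channels, got {x.shape[1]}"
            )
        if feats is not None and feats.shape[1] != cfg.handcrafted_channels:
            raise ValueError(
                f"expected {cfg.handcrafted_channels} handcrafted channels, "
                f"got {feats.shape[1]}"
            )

    def forward_graph(
        self,
        x: np.ndarray,
        feats: np.ndarray | None = None,
        pvars: dict[str, Var] | None = None,
    ) -> Var:
        """Build the graph and return the logits node (N, n_classes, H, W)."""
        cfg = self.config
        self._check_inputs(x, feats)
        if pvars is None:
            pvars = {k: Var(v, requires_grad=False) for k, v in self.params.items()}

        def raw(name, t, fuse=None):
            out = nn.conv2d(
                t, pvars[f"{name}.w"], pvars[f"{name}.b"],
                pad=0 if name == "head" else None,
            )
            if fuse is not None:
                # two-path fused convolution: the shared weight never sees the
                # handcrafted channels, so zeroed fusion weights reproduce the
                # baseline bit-exactly
                zero_b = Var(
                    np.zeros_like(pvars[f"{name}.b"].data), requires_grad=False
                )
                out = nn.add(out, nn.conv2d(fuse, pvars[f"{name}.wf"], zero_b,
                                            pad=0 if name == "head" else None))
            return out

        def cv(name, t, fuse=None):
            return nn.relu(raw(name, t, fuse))

        x = np.ascontiguousarray(x, dtype=np.float32)
        fvar = None
        if feats is not None:
            fvar = Var(
                np.ascontiguousarray(feats, dtype=np.float32), requires_grad=False
            )
        t = Var(x, requires_grad=False)

        c = cfg.encoder_channels
        skips = []
        t = cv("enc0_conv1", t, fvar if cfg.fusion == "input_channel" else None)
        t = cv("enc0_conv2", t)
        skips.append(t)
        t = nn.maxpool2(t)
        fm_fuse = None
        if cfg.fusion == "feature_map" and cfg.fusion_depth == 0:
            fm_fuse = self._pooled_feats(fvar, x.shape[2] // t.data.shape[2])
        for i in range(1, len(c)):
            t = cv(f"enc{i}_conv1", t, fm_fuse)
            fm_fuse = None
            t = cv(f"enc{i}_conv2", t)
            skips.append(t)
            t = nn.maxpool2(t)
            if cfg.fusion == "feature_map" and cfg.fusion_depth == i:
                fm_fuse = self._pooled_feats(fvar, x.shape[2] // t.data.shape[2])
        t = cv("bott_conv1", t, fm_fuse)
        t = cv("bott_conv2", t)
        for i in reversed(range(len(c))):
            t = nn.upsample2(t)
            t = cv(f"dec{i}_conv1", t)
            t = nn.concat(t, skips[i])
            t = cv(f"dec{i}_conv2", t)
        fuse = fvar if cfg.fusion == "decision_level" else None
        return raw("head", t, fuse)

    @staticmethod
    def _pooled_feats(fvar: Var, factor: int) -> Var:
        return Var(
            nn.avgpool(fvar.data, factor).astype(np.float32), requires_grad=False
        )

    # -- weight surgery for fusion ablations ---------------------------------

    def zero_fusion_weights(self) -> None:
        """Zero the fusion weight slices reading handcrafted channels."""
        for name in self._fusion_conv:
            self.params[f"{name}.wf"][...] = 0.0

    def load_shared_weights(self, baseline: "SegmentationCNN") -> None:
        """Copy backbone weights from a fusion-free network.

        Fusion weight slices (``*.wf``) are untouched; the backbone weights
        are shared one-to-one.
        """
        for key, val in baseline.params.items():
            self.params[key][...] = val

    # -- inspection / persistence --------------------------------------------

    def summary(self) -> list[dict]:
        size = self.config.input_size
        c = self.config.encoder_channels
        out = []
        for name, cin, cout, k in self._shapes:
            if name.startswith("enc"):
                stage = int(name[3])
                res = size // (2**stage)
            elif name.startswith("bott"):
                res = size // (2 ** len(c))
            elif name.startswith("dec"):
                stage = int(name[3])
                res = size // (2**stage)
            else:
                res = size
            fused = self._fusion_conv.get(name, 0)
            out.append(
                {
                    "layer": name,
                    "kernel": k,
                    "in_channels": cin + fused,
                    "fused_channels": fused,
                    "out_channels": cout,
                    "output_shape": [res, res, cout],
                }
            )
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k][...] = state[k]

    def save(self, path) -> None:
        np.savez(path, **self.params)

    @classmethod
    def load(cls, path, config: HybridModelConfig) -> "SegmentationCNN":
        model = cls(config)
        with np.load(path) as data:
            model.load_state_dict(dict(data))
        return model


def build_cnn(config: HybridModelConfig | None = None, seed: int = 0) -> SegmentationCNN:
    """Build the fusion-free baseline network."""
    config = config or HybridModelConfig()
    if config.fusion != "none":
        raise ValueError("build_cnn requires fusion='none'; use build_hybrid")
    return SegmentationCNN(config, seed=seed)


def build_hybrid(config: HybridModelConfig, seed: int = 0) -> SegmentationCNN:
    """Build a hybrid variant with ``handcrafted_channels`` fused channels."""
    if config.fusion == "none":
        raise ValueError("build_hybrid requires a fusion mode; use build_cnn")
    if config.handcrafted_channels < 1:
        raise ValueError("no handcrafted channels")
    return SegmentationCNN(config, seed=seed)


def forward_predict(
    model: SegmentationCNN,
    batch: np.ndarray,
    feats: np.ndarray | None = None,
    batch_size: int = 16,
) -> PredictionMap:
    """Run inference on a batch of slices; deterministic for fixed weights.

    ``batch`` is (N, 4, H, W); ``feats`` (N, k, H, W) when the model fuses
    handcrafted channels.  Ties in the argmax break toward the smaller
    class index.
    """
    probs = []
    for i in range(0, batch.shape[0], batch_size):
        f = None if feats is None else feats[i : i + batch_size]
        logits = model.forward_graph(batch[i : i + batch_size], f)
        probs.append(nn.softmax(logits.data.astype(np.float64), axis=1))
    p = np.concatenate(probs, axis=0)
    return PredictionMap(probabilities=p, labels=p.argmax(axis=1))
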