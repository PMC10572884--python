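"""Modified Double U-Net for multi-class hotspot segmentation.

The architecture chains two U-Net-style encoder--decoder sub-networks.
Sub-network 1 ends in an atrous spatial pooling block at its bottleneck and
a SoftMax head; its foreground probability (1 minus the air-background
channel) multiplies the input image, focusing sub-network 2 on body
regions.  Sub-network 2's decoder concatenates skip features from *both*
encoders and ends in a second SoftMax head, which is the final prediction.
Both heads emit ``n_classes`` channels so either or both can be supervised.

The network is built on the package's numpy autodiff engine and is fully
configurable in width and input size, so a "tiny" preset trains in seconds
per hundred steps on one CPU core.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "NetworkConfig",
    "PredictionMap",
    "DoubleUNet",
    "build_double_unet",
    "predict",
    "tiny_config",
]


class NetworkConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Shape and capacity of the Double U-Net.

    ``encoder_widths`` gives the channel count per resolution level; the
    number of 2x downsamplings is ``len(encoder_widths) - 1`` and the input
    dimensions must be divisible by ``2**that``.  ``use_pretrained_encoder``
    replicates the single grey channel to three so externally trained RGB
    encoder weights can be loaded; no weights ship with the package.
    """

    input_shape: tuple[int, int] = (640, 512)
    n_classes: int = 3
    encoder_widths: tuple[int, ...] = (32, 64, 128)
    use_pretrained_encoder: bool = False
    dual_output: bool = False
    aspp_rates: tuple[int, ...] = (1, 2, 4)
    input_scale: float = 1.0 / 255.0  # maps 8-bit intensities to ~[0, 1]
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise NetworkConfigError("n_classes must be >= 2")
        if not self.encoder_widths or any(w <= 0 for w in self.encoder_widths):
            raise NetworkConfigError("encoder widths must be strictly positive")
        factor = 2 ** (len(self.encoder_widths) - 1)
        h, w = self.input_shape
        if h % factor or w % factor:
            raise NetworkConfigError(
                f"input shape {self.input_shape} not divisible by "
                f"downsampling factor {factor}"
            )


def tiny_config(n_classes: int = 3, seed: int = 0) -> NetworkConfig:
    """Desk-scale preset: 64x64 inputs, widths (8, 16, 32)."""
    return NetworkConfig(
        input_shape=(64, 64),
        n_classes=n_classes,
        encoder_widths=(8, 16, 32),
        seed=seed,
    )


@dataclass(frozen=True)
class PredictionMap:
    """Per-pixel class probabilities (C, H, W) and their argmax classes."""

    probabilities: np.ndarray
    argmax_classes: np.ndarray = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "argmax_classes", np.argmax(self.probabilities, axis=0).astype(np.uint8)
        )


class DoubleUNet:
    """Two chained U-Nets with shared-skip decoding and SoftMax heads."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)
        cin = 3 if config.use_pretrained_encoder else 1
        self._build_subnet("n1", cin, rng, aspp=True)
        self._build_subnet("n2", cin, rng, aspp=False, extra_skips=True)

    # -- construction ------------------------------------------------------
    def _add_conv(
        self, name: str, cin: int, cout: int, rng, k: int = 3, norm: bool = True
    ) -> None:
        self.params[f"{name}.w"] = nn.he_init(rng, (cout, cin, k, k))
        self.params[f"{name}.b"] = Tensor(
            np.zeros(cout, dtype=np.float32), requires_grad=True
        )
        if norm:
            self.params[f"{name}.g"] = Tensor(
                np.ones(cout, dtype=np.float32), requires_grad=True
            )
            self.params[f"{name}.be"] = Tensor(
                np.zeros(cout, dtype=np.float32), requires_grad=True
            )

    def _build_subnet(self, prefix, cin, rng, aspp, extra_skips=False):
        widths = self.config.encoder_widths
        c = cin
        for i, w in enumerate(widths[:-1]):
            self._add_conv(f"{prefix}.enc{i}", c, w, rng)
            c = w
        bott = widths[-1]
        if aspp:
            for r in self.config.aspp_rates:
                self._add_conv(f"{prefix}.aspp{r}", c, bott, rng)
        else:
            self._add_conv(f"{prefix}.bott", c, bott, rng)
        c = bott
        for i in reversed(range(len(widths) - 1)):
            skip_c = widths[i] * (2 if extra_skips else 1)
            self._add_conv(f"{prefix}.dec{i}", c + skip_c, widths[i], rng)
            c = widths[i]
        self._add_conv(f"{prefix}.head", c, self.config.n_classes, rng, k=1, norm=False)

    # -- forward -----------------------------------------------------------
    def _conv(self, name, x, dilation=1):
        h = nn.conv2d(x, self.params[f"{name}.w"], self.params[f"{name}.b"], dilation)
        h = nn.instance_norm(h, self.params[f"{name}.g"], self.params[f"{name}.be"])
        return nn.relu(h)

    def _subnet(self, prefix, x, other_skips=None):
        widths = self.config.encoder_widths
        skips = []
        h = x
        for i in range(len(widths) - 1):
            h = self._conv(f"{prefix}.enc{i}", h)
            skips.append(h)
            h = nn.max_pool2d(h)
        if f"{prefix}.bott.w" in self.params:
            h = self._conv(f"{prefix}.bott", h)
        else:
            parts = [
                self._conv(f"{prefix}.aspp{r}", h, dilation=r)
                for r in self.config.aspp_rates
            ]
            acc = parts[0]
            for part in parts[1:]:
                acc = acc + part
            h = acc
        for i in reversed(range(len(widths) - 1)):
            h = nn.upsample2d(h)
            cat = [h, skips[i]]
            if other_skips is not None:
                cat.append(other_skips[i])
            h = self._conv(f"{prefix}.dec{i}", nn.concat(cat))
        logits = nn.conv2d(
            h, self.params[f"{prefix}.head.w"], self.params[f"{prefix}.head.b"]
        )
        return nn.softmax(logits, axis=1), skips

    def forward(self, x) -> tuple[Tensor, Tensor]:
        """Run the full network.  ``x``: (N, 1, H, W) array or Tensor.
        Returns the SoftMax outputs of both heads; the second is the final
        prediction."""
        x = nn.as_tensor(x) * self.config.input_scale
        if self.config.use_pretrained_encoder and x.shape[1] == 1:
            x = nn.concat([x, x, x], axis=1)
        out1, skips1 = self._subnet("n1", x)
        fg = 1.0 - out1[:, 0:1]  # foreground probability (1 - BG channel)
        x2 = x * fg
        out2, _ = self._subnet("n2", x2, other_skips=skips1)
        return out1, out2

    # -- parameter utilities ----------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise NetworkConfigError("checkpoint does not match architecture")
        for k, v in state.items():
            if v.shape != self.params[k].data.shape:
                raise NetworkConfigError(f"shape mismatch for parameter {k}")
            self.params[k].data = v.astype(np.float32).copy()

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config, "state": self.state_dict()}, fh)

    @staticmethod
    def load(path) -> "DoubleUNet":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = DoubleUNet(blob["config"])
        model.load_state_dict(blob["state"])
        return model


def build_double_unet(config: NetworkConfig) -> DoubleUNet:
    """Construct a Double U-Net with seeded He-initialised weights."""
    return DoubleUNet(config)


def predict(model: DoubleUNet, image: np.ndarray) -> PredictionMap:
    """Segment one image (H, W); returns the final head's probabilities."""
    img = np.asarray(image, dtype=np.float32)
    if img.shape != tuple(model.config.input_shape):
        raise ValueError(
            f"image shape {img.shape} != network input {model.config.input_shape}"
        )
    x = img[None, None]
    _, out2 = model.forward(x)
    return PredictionMap(probabilities=out2.data[0])
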