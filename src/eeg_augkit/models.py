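"""The three CNN baseline architectures, parameterised by input geometry.

All builders take a :class:`ModelSpec` plus a seed and return a
:class:`~eeg_augkit.nn.Sequential` operating on ``(batch, channels, time)``
arrays. Classifier input widths are always computed from the spec geometry by a
dry forward pass, never hard-coded, so the same architecture serves 30-s sleep
epochs at 100 Hz and 20-s iEEG segments at 512 Hz.

* **DeepConvNet** — five temporal convolution stages (widths 32, 32, 64, 64,
  128; kernel 10), each with batch norm, ReLU and max-pool 4, followed by four
  fully connected layers (1024, 512, 256, 128) with batch norm and dropout and
  a final linear map to the classes.
* **ShallowConvNet** — a spatial (across-electrode) convolution into 40
  filters, a depthwise temporal convolution (kernel 25), batch norm, ReLU, a
  large max-pool (kernel 35, stride 7) emphasising slow dynamics, and a single
  fully connected classifier.
* **EEGNet** — a temporal filter bank (kernel 50, F1 = 8) shared across
  electrodes, a depthwise spatial convolution spanning all electrodes with
  depth multiplier D = 2, then a depthwise-separable convolution (kernel 16,
  F2 = 16); ELU activations, average pooling 4 and 8, dropout in both blocks,
  and a dense head (hidden width 64).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

ARCHITECTURES = ("deep", "shallow", "eegnet")

DEEP_WIDTHS = (32, 32, 64, 64, 128)
DEEP_KERNEL = 10
DEEP_POOL = 4
DEEP_FC = (1024, 512, 256, 128)
SHALLOW_FILTERS = 40
SHALLOW_KERNEL = 25
SHALLOW_POOL = (35, 7)
EEGNET_F1 = 8
EEGNET_D = 2
EEGNET_F2 = EEGNET_F1 * EEGNET_D
EEGNET_TEMPORAL_KERNEL = 50
EEGNET_SEP_KERNEL = 16
EEGNET_POOLS = (4, 8)
EEGNET_HIDDEN = 64


class BuildError(ValueError):
    """Raised when a spec's geometry cannot produce a valid feature map."""


@dataclass
class ModelSpec:
    """Architecture name plus the input geometry and class count."""

    architecture: str
    n_channels: int
    n_samples: int
    n_classes: int
    dropout_rate: float | None = None  # None -> architecture default

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}")
        if self.n_channels < 1 or self.n_samples < 2 or self.n_classes < 2:
            raise ValueError("need n_channels >= 1, n_samples >= 2, n_classes >= 2")
        if self.dropout_rate is not None and not 0 <= self.dropout_rate <= 1:
            raise ValueError(f"dropout_rate must be in [0, 1], got {self.dropout_rate}")


def _conv_same_len(length: int, kernel: int) -> int:
    # 'same' padding of (k-1)//2 per side: odd kernels keep the length,
    # even kernels shorten it by one
    return length + 2 * ((kernel - 1) // 2) - kernel + 1


def _pool_len(length: int, kernel: int, stride: int) -> int:
    if length < kernel:
        return 0
    return (length - kernel) // stride + 1


def _feature_len(architecture: str, n_samples: int) -> int:
    """Temporal length of the final feature map (0 if geometry collapses)."""
    L = n_samples
    if architecture == "deep":
        for _ in DEEP_WIDTHS:
            L = _conv_same_len(L, DEEP_KERNEL)
            L = _pool_len(L, DEEP_POOL, DEEP_POOL)
            if L == 0:
                return 0
        return L
    if architecture == "shallow":
        L = _conv_same_len(L, SHALLOW_KERNEL)
        return _pool_len(L, *SHALLOW_POOL)
    L = _conv_same_len(L, EEGNET_TEMPORAL_KERNEL)
    L = _pool_len(L, EEGNET_POOLS[0], EEGNET_POOLS[0])
    if L == 0:
        return 0
    L = _conv_same_len(L, EEGNET_SEP_KERNEL)
    return _pool_len(L, EEGNET_POOLS[1], EEGNET_POOLS[1])


def min_admissible_samples(architecture: str) -> int:
    """Smallest n_samples for which every pooling stage keeps >= 1 output step."""
    n = 2
    while _feature_len(architecture, n) < 1:
        n += 1
        if n > 1 << 20:  # pragma: no cover - defensive
            raise RuntimeError("no admissible input length found")
    return n


def _check_geometry(spec: ModelSpec) -> int:
    L = _feature_len(spec.architecture, spec.n_samples)
    if L < 1:
        raise BuildError(
            f"{spec.architecture}: n_samples={spec.n_samples} collapses the feature "
            f"map; minimum admissible n_samples is "
            f"{min_admissible_samples(spec.architecture)}")
    return L


def build_deepconvnet(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Five conv stages + four-layer fully connected classifier."""
    if spec.architecture != "deep":
        raise ValueError("spec.architecture must be 'deep'")
    final_len = _check_geometry(spec)
    p = 0.5 if spec.dropout_rate is None else spec.dropout_rate
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    cin = spec.n_channels
    for width in DEEP_WIDTHS:
        layers += [
            nn.Conv1d(cin, width, DEEP_KERNEL, rng),
            nn.BatchNorm(width),
            nn.ReLU(),
            nn.MaxPool1d(DEEP_POOL),
        ]
        cin = width
    layers.append(nn.Flatten())
    flat = DEEP_WIDTHS[-1] * final_len
    for width in DEEP_FC:
        layers += [
            nn.Linear(flat, width, rng),
            nn.BatchNorm(width),
            nn.ReLU(),
            nn.Dropout(p),
        ]
        flat = width
    layers.append(nn.Linear(flat, spec.n_classes, rng))
    return nn.Sequential(layers)


def build_shallowconvnet(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Spatial conv + depthwise temporal conv + large max-pool + one FC layer."""
    if spec.architecture != "shallow":
        raise ValueError("spec.architecture must be 'shallow'")
    final_len = _check_geometry(spec)
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        # spatial convolution: kernel length 1 mixes electrodes only
        nn.Conv1d(spec.n_channels, SHALLOW_FILTERS, 1, rng),
        nn.Conv1d(SHALLOW_FILTERS, SHALLOW_FILTERS, SHALLOW_KERNEL, rng,
                  groups=SHALLOW_FILTERS),
        nn.BatchNorm(SHALLOW_FILTERS),
        nn.ReLU(),
        nn.MaxPool1d(*SHALLOW_POOL),
        nn.Flatten(),
        nn.Linear(SHALLOW_FILTERS * final_len, spec.n_classes, rng),
    ]
    return nn.Sequential(layers)


def build_eegnet(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Temporal filter bank + depthwise spatial filter + separable conv + dense head."""
    if spec.architecture != "eegnet":
        raise ValueError("spec.architecture must be 'eegnet'")
    final_len = _check_geometry(spec)
    p = 0.25 if spec.dropout_rate is None else spec.dropout_rate
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        nn.SharedTemporalConv(spec.n_channels, EEGNET_F1, EEGNET_TEMPORAL_KERNEL, rng),
        nn.BatchNorm(spec.n_channels * EEGNET_F1),
        nn.SpatialDepthwiseConv(spec.n_channels, EEGNET_F1, EEGNET_D, rng),
        nn.BatchNorm(EEGNET_F2),
        nn.ELU(),
        nn.AvgPool1d(EEGNET_POOLS[0]),
        nn.Dropout(p),
        nn.Conv1d(EEGNET_F2, EEGNET_F2, EEGNET_SEP_KERNEL, rng,
                  groups=EEGNET_F2, bias=False),
        nn.Conv1d(EEGNET_F2, EEGNET_F2, 1, rng),
        nn.BatchNorm(EEGNET_F2),
        nn.ELU(),
        nn.AvgPool1d(EEGNET_POOLS[1]),
        nn.Dropout(p),
        nn.Flatten(),
        nn.Linear(EEGNET_F2 * final_len, EEGNET_HIDDEN, rng),
        nn.ELU(),
        nn.Dropout(p),
        nn.Linear(EEGNET_HIDDEN, spec.n_classes, rng),
    ]
    return nn.Sequential(layers)


_BUILDERS = {
    "deep": build_deepconvnet,
    "shallow": build_shallowconvnet,
    "eegnet": build_eegnet,
}


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Build any architecture by name."""
    return _BUILDERS[spec.architecture](spec, seed)


def count_parameters(net: nn.Sequential) -> int:
    """Total number of trainable scalar parameters."""
    return net.n_params()


def architecture_summary(net: nn.Sequential, spec: ModelSpec) -> dict:
    """Layer-by-layer summary (name, parameter count, output shape) as a dict."""
    x = np.zeros((1, spec.n_channels, spec.n_samples), dtype=nn.DTYPE)
    rows = []
    for layer in net.layers:
        x = layer.forward(x, train=False)
        rows.append({
            "layer": type(layer).__name__,
            "params": layer.n_params(),
            "output_shape": list(x.shape[1:]),
        })
    return {
        "architecture": spec.architecture,
        "n_channels": spec.n_channels,
        "n_samples": spec.n_samples,
        "n_classes": spec.n_classes,
        "total_params": count_parameters(net),
        "layers": rows,
    }
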