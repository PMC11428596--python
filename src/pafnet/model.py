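"""The 26-layer 1D CNN architecture, parameterized by window size N.

The network is five convolution blocks (conv -> batchnorm -> ReLU, the
last four followed by length-2 max pooling), a flatten, a 512-unit dense
block with batchnorm/ReLU/dropout, and a single sigmoid output unit: the
probability that the input window precedes a PAF episode. The input layer
is N R-R intervals in seconds; changing N changes only the flatten length
and hence the first dense layer.

Published layer tables of this architecture leave a few accounting details
open (first-conv kernel length, convolution bias, parameters tracked per
batch-norm feature, pooling length rounding). ``calibrate_architecture``
resolves them by exhaustively enumerating the small variant space and
keeping the unique variant whose closed-form parameter totals match the
published counts at all three input sizes (50, 100, 200) simultaneously.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import nn

__all__ = [
    "ArchVariant",
    "LayerSpec",
    "ModelSpec",
    "ParamCount",
    "REFERENCE_TOTALS",
    "build_pafnet",
    "count_params",
    "calibrate_architecture",
    "instantiate",
]

logger = logging.getLogger(__name__)

CONV_CHANNELS = (16, 32, 64, 128, 256)
CONV_KERNEL = 8
DENSE_UNITS = 512
DROPOUT_RATE = 0.25
MIN_INPUT = 16

#: Published total parameter counts (trainable + non-trainable) of the
#: reference implementation at the three studied input sizes.
REFERENCE_TOTALS = {50: 878_017, 100: 1_271_233, 200: 2_057_665}


@dataclass(frozen=True)
class ArchVariant:
    """One point of the discrete calibration space."""

    first_kernel: int = 1          # kernel length of the first convolution
    conv_bias: bool = True         # convolutions carry a bias term
    bn_params_per_feature: int = 4  # scale+shift (+running mean/var if 4)
    pool_rounding: str = "ceil"    # output-length rounding of pool layers

    def __post_init__(self) -> None:
        if self.first_kernel not in (1, 8):
            raise ValueError(f"first_kernel must be 1 or 8, got {self.first_kernel}")
        if self.bn_params_per_feature not in (2, 4):
            raise ValueError(f"bn_params_per_feature must be 2 or 4, got {self.bn_params_per_feature}")
        if self.pool_rounding not in ("floor", "ceil"):
            raise ValueError(f"pool_rounding must be 'floor' or 'ceil', got {self.pool_rounding}")

    @property
    def tag(self) -> str:
        return (f"k{self.first_kernel}-bias{int(self.conv_bias)}"
                f"-bn{self.bn_params_per_feature}-{self.pool_rounding}")


@dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor: a kind plus its hyperparameters."""

    kind: str  # input | conv1d | batchnorm | activation | pool1d | flatten | dense | dropout
    hyper: tuple[tuple[str, object], ...] = ()

    def get(self, key: str, default=None):
        return dict(self.hyper).get(key, default)

    def __str__(self) -> str:
        args = " ".join(f"{k}={v}" for k, v in self.hyper)
        return f"{self.kind} {args}".strip()


@dataclass
class ModelSpec:
    """Ordered layer list of the network for one input size."""

    input_size: int
    layers: list[LayerSpec]
    resolved_variant: ArchVariant | None = None

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def to_manifest(self) -> str:
        head = f"# pafnet model, input_size={self.input_size}, variant={self.resolved_variant.tag if self.resolved_variant else 'unresolved'}\n"
        return head + "\n".join(f"{i + 1}\t{ls}" for i, ls in enumerate(self.layers)) + "\n"


@dataclass
class ParamCount:
    """Per-layer and total parameter accounting (trainable + non-trainable)."""

    per_layer: list[tuple[int, int]] = field(default_factory=list)  # (layer index, count)
    total: int = 0


def _pool_out(length: int, rounding: str) -> int:
    return math.ceil(length / 2) if rounding == "ceil" else length // 2


def build_pafnet(N: int, variant: ArchVariant | None = None) -> ModelSpec:
    """Build the layer list for input size ``N``.

    ``N`` must be at least 16 so that four pool halvings leave a usable
    feature-map length. Without an explicit ``variant`` the calibrated one
    is used.
    """
    if N < MIN_INPUT:
        raise ValueError(f"input size N must be >= {MIN_INPUT}, got {N}")
    v = variant or calibrate_architecture()

    def H(**kw) -> tuple[tuple[str, object], ...]:
        return tuple(kw.items())

    layers: list[LayerSpec] = [LayerSpec("input", H(size=N))]
    length = N
    in_ch = 1
    for block, out_ch in enumerate(CONV_CHANNELS):
        kernel = v.first_kernel if block == 0 else CONV_KERNEL
        layers.append(LayerSpec("conv1d", H(out=out_ch, kernel=kernel, stride=1,
                                            padding="same", bias=v.conv_bias,
                                            in_ch=in_ch, out_len=length)))
        layers.append(LayerSpec("batchnorm", H(features=out_ch,
                                               params_per_feature=v.bn_params_per_feature)))
        layers.append(LayerSpec("activation", H(fn="relu")))
        if block > 0:
            length = _pool_out(length, v.pool_rounding)
            layers.append(LayerSpec("pool1d", H(size=2, rounding=v.pool_rounding,
                                                out_len=length)))
        in_ch = out_ch
    flat = in_ch * length
    layers.append(LayerSpec("flatten", H(out=flat)))
    layers.append(LayerSpec("dense", H(units=DENSE_UNITS, in_features=flat)))
    layers.append(LayerSpec("batchnorm", H(features=DENSE_UNITS,
                                           params_per_feature=v.bn_params_per_feature)))
    layers.append(LayerSpec("activation", H(fn="relu")))
    layers.append(LayerSpec("dropout", H(rate=DROPOUT_RATE)))
    layers.append(LayerSpec("dense", H(units=1, in_features=DENSE_UNITS,
                                       activation="sigmoid")))
    return ModelSpec(input_size=N, layers=layers, resolved_variant=variant or v)


def count_params(spec: ModelSpec) -> ParamCount:
    """Closed-form parameter accounting of a resolved layer list.

    conv: (kernel x in_channels + bias) x out_channels;
    batchnorm: params_per_feature x features;
    dense: (in_features + 1) x units.
    """
    if spec.resolved_variant is None:
        raise ValueError("unresolved architecture variant; run calibrate_architecture() first")
    per_layer: list[tuple[int, int]] = []
    for i, ls in enumerate(spec.layers):
        if ls.kind == "conv1d":
            n = (ls.get("kernel") * ls.get("in_ch") + (1 if ls.get("bias") else 0)) * ls.get("out")
        elif ls.kind == "batchnorm":
            n = ls.get("params_per_feature") * ls.get("features")
        elif ls.kind == "dense":
            n = (ls.get("in_features") + 1) * ls.get("units")
        else:
            n = 0
        per_layer.append((i + 1, n))
    return ParamCount(per_layer=per_layer, total=sum(n for _, n in per_layer))


def _variant_space() -> list[ArchVariant]:
    return [
        ArchVariant(first_kernel=k, conv_bias=b, bn_params_per_feature=p, pool_rounding=r)
        for k in (1, 8) for b in (True, False) for p in (2, 4) for r in ("floor", "ceil")
    ]


@lru_cache(maxsize=4)
def _calibrate_cached(targets_items: tuple[tuple[int, int], ...]) -> ArchVariant:
    targets = dict(targets_items)
    matches: list[ArchVariant] = []
    misses: list[tuple[str, dict[int, int]]] = []
    for v in _variant_space():
        totals = {n: count_params(build_pafnet(n, variant=v)).total for n in targets}
        if totals == targets:
            matches.append(v)
        else:
            misses.append((v.tag, {n: totals[n] - targets[n] for n in targets}))
    if len(matches) != 1:
        detail = "; ".join(f"{tag}: offsets {off}" for tag, off in misses)
        raise RuntimeError(
            f"architecture calibration found {len(matches)} matching variants "
            f"(expected exactly 1). Mismatches: {detail}"
        )
    logger.info("architecture calibration selected variant %s", matches[0].tag)
    return matches[0]


def calibrate_architecture(targets: dict[int, int] | None = None) -> ArchVariant:
    """Resolve the accounting variant against the published totals.

    Enumerates the 16-variant space and returns the unique variant whose
    totals match all target input sizes simultaneously; raises with the
    per-variant misses otherwise. The result is cached.
    """
    t = targets or REFERENCE_TOTALS
    return _calibrate_cached(tuple(sorted(t.items())))


def instantiate(spec: ModelSpec, seed: int = 0, dtype=np.float32) -> nn.Sequential:
    """Materialize a layer list as a trainable network."""
    if spec.resolved_variant and spec.resolved_variant.pool_rounding != "ceil":
        raise ValueError("only ceil pooling is supported by the runtime engine")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    for ls in spec.layers:
        if ls.kind == "input":
            continue
        if ls.kind == "conv1d":
            layers.append(nn.Conv1D(in_ch, ls.get("out"), ls.get("kernel"), rng,
                                    bias=ls.get("bias", True), dtype=dtype))
            in_ch = ls.get("out")
        elif ls.kind == "batchnorm":
            layers.append(nn.BatchNorm(ls.get("features"), dtype=dtype))
        elif ls.kind == "activation":
            layers.append(nn.ReLU())
        elif ls.kind == "pool1d":
            layers.append(nn.MaxPool1D(ls.get("size")))
        elif ls.kind == "flatten":
            layers.append(nn.Flatten())
        elif ls.kind == "dense":
            layers.append(nn.Dense(ls.get("in_features"), ls.get("units"), rng, dtype=dtype))
            if ls.get("activation") == "sigmoid":
                layers.append(nn.Sigmoid())
        elif ls.kind == "dropout":
            layers.append(nn.Dropout(ls.get("rate"), rng))
        else:
            raise ValueError(f"unknown layer kind {ls.kind!r}")
    net = nn.Sequential(layers)
    expected = count_params(spec).total
    if net.n_params != expected:
        raise AssertionError(
            f"instantiated network has {net.n_params} parameters, accounting says {expected}")
    return net
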