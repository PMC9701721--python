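"""The four segment-classification architectures.

All four consume the same batch object — a dict with a ``"tensor"`` view of
shape (B, 2, N, N) and a ``"raw"`` view of shape (B, M, N), i.e. the segment
read as a length-M time series of N-dimensional samples:

* ``cnn`` — instance branch alone: three [conv -> batch-norm -> ReLU]
  blocks, max-pooled after the first two, flattened into the FC head.
* ``lstm`` — sequence branch alone: one LSTM (256 cells by default) whose
  final hidden state feeds the FC head.
* ``multiframe`` — both branches run in parallel on the same segment and
  their features are concatenated before the FC head.
* ``cnn_lstm`` — the sequential baseline: the conv trunk's pre-flatten
  feature map is unrolled along one spatial axis into a sequence of feature
  vectors fed to the LSTM, whose output feeds the FC head.

The FC head is Dense(128)-ReLU-Dropout(0.5), Dense(64)-ReLU-Dropout(0.5),
Dense(2); class probabilities come from a softmax over the two logits.
Dropout is active only during training.  Exact convolution hyperparameters
(filter counts, kernel size) are configurable on :class:`ModelSpec`; the
defaults are a conventional LeNet/AlexNet-style schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.layers import Layer

__all__ = ["ModelSpec", "ConvTrunk", "FCHead", "SegmentClassifier",
           "build_cnn_branch", "build_lstm_branch", "build_multiframe",
           "build_cnn_lstm", "build_model", "MODEL_KINDS"]

MODEL_KINDS = ("cnn", "lstm", "cnn_lstm", "multiframe")


@dataclass
class ModelSpec:
    """Declarative description of one architecture.

    ``n_channels`` is the electrode count N (the tensor view is (2, N, N));
    ``seq_len`` is the samples-per-segment M fed to the sequence branch.
    """
    kind: str
    n_channels: int
    seq_len: int
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    conv_kernel: int = 3
    pool: int = 2
    lstm_units: int = 256
    fc_sizes: tuple[int, int, int] = (128, 64, 2)
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        if len(self.conv_filters) != 3:
            raise ValueError("conv_filters must list 3 block widths")
        if self.fc_sizes[-1] != 2:
            raise ValueError("fc_sizes must end in 2 (binary softmax output)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.lstm_units < 1:
            raise ValueError("lstm_units must be positive")
        if self.kind in ("cnn", "cnn_lstm", "multiframe"):
            extent = self.n_channels
            for _ in range(2):  # pooling after blocks 1 and 2
                extent //= self.pool
            if extent < 1:
                raise ValueError(
                    f"n_channels={self.n_channels} too small for two "
                    f"{self.pool}x{self.pool} poolings; need N >= {self.pool ** 2}")

    def cnn_map_shape(self) -> tuple[int, int, int]:
        """(channels, height, width) of the conv trunk's output feature map."""
        extent = self.n_channels
        for _ in range(2):
            extent //= self.pool
        return self.conv_filters[2], extent, extent

    def cnn_flat_len(self) -> int:
        c, h, w = self.cnn_map_shape()
        return c * h * w


class ConvTrunk(Layer):
    """Three [conv -> batch-norm -> ReLU] blocks; max-pool after 1 and 2."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        f1, f2, f3 = spec.conv_filters
        k = spec.conv_kernel
        self.layers: list[Layer] = [
            nn.Conv2d(2, f1, k, rng, dtype), nn.BatchNorm2d(f1, dtype=dtype),
            nn.ReLU(), nn.MaxPool2d(spec.pool),
            nn.Conv2d(f1, f2, k, rng, dtype), nn.BatchNorm2d(f2, dtype=dtype),
            nn.ReLU(), nn.MaxPool2d(spec.pool),
            nn.Conv2d(f2, f3, k, rng, dtype), nn.BatchNorm2d(f3, dtype=dtype),
            nn.ReLU(),
        ]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class FCHead(Layer):
    """The shared fully connected classification head ending in 2 logits."""

    def __init__(self, in_dim: int, spec: ModelSpec, rng: np.random.Generator,
                 dropout_rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        s1, s2, s3 = spec.fc_sizes
        self.layers: list[Layer] = [
            nn.Dense(in_dim, s1, rng, dtype=dtype), nn.ReLU(),
            nn.Dropout(spec.dropout, dropout_rng),
            nn.Dense(s1, s2, rng, dtype=dtype), nn.ReLU(),
            nn.Dropout(spec.dropout, dropout_rng),
            nn.Dense(s2, s3, rng, relu_init=False, dtype=dtype),
        ]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class SegmentClassifier:
    """One of the four architectures, wired per ``spec.kind``.

    ``forward`` takes a batch dict with float arrays ``"tensor"``
    (B, 2, N, N) and ``"raw"`` (B, M, N); models that do not use a view
    ignore it.  ``predict_proba`` runs in inference mode (deterministic:
    dropout off, batch-norm on running statistics).
    """

    def __init__(self, spec: ModelSpec, seed: int = 0,
                 dtype=np.float32) -> None:
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0xD0]))
        self.trunk: ConvTrunk | None = None
        self.lstm: nn.LSTM | None = None
        head_in = 0
        if spec.kind in ("cnn", "multiframe", "cnn_lstm"):
            self.trunk = ConvTrunk(spec, rng, dtype)
        if spec.kind in ("lstm", "multiframe"):
            self.lstm = nn.LSTM(spec.n_channels, spec.lstm_units, rng, dtype)
        if spec.kind == "cnn_lstm":
            c, h, _ = spec.cnn_map_shape()
            self.lstm = nn.LSTM(c * h, spec.lstm_units, rng, dtype)
        if spec.kind == "cnn":
            head_in = spec.cnn_flat_len()
        elif spec.kind == "lstm" or spec.kind == "cnn_lstm":
            head_in = spec.lstm_units
        elif spec.kind == "multiframe":
            head_in = spec.cnn_flat_len() + spec.lstm_units
        self.head = FCHead(head_in, spec, rng, self.dropout_rng, dtype)

    # -- plumbing ----------------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        if self.trunk is not None:
            out.extend(self.trunk.layers)
        if self.lstm is not None:
            out.append(self.lstm)
        out.extend(self.head.layers)
        return out

    def param_handles(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers
                for name in layer.params]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def state_dict(self) -> list[dict]:
        return [layer.state_dict() for layer in self.layers]

    def load_state_dict(self, state: list[dict]) -> None:
        for layer, s in zip(self.layers, state, strict=True):
            layer.load_state_dict(s)

    # -- forward / backward ------------------------------------------------
    def forward(self, batch: dict[str, np.ndarray], train: bool = False
                ) -> np.ndarray:
        kind = self.spec.kind
        if kind == "cnn":
            fmap = self.trunk.forward(batch["tensor"], train)
            self._fmap_shape = fmap.shape
            feat = fmap.reshape(fmap.shape[0], -1)
        elif kind == "lstm":
            feat = self.lstm.forward(batch["raw"], train)
        elif kind == "multiframe":
            fmap = self.trunk.forward(batch["tensor"], train)
            self._fmap_shape = fmap.shape
            cnn_feat = fmap.reshape(fmap.shape[0], -1)
            lstm_feat = self.lstm.forward(batch["raw"], train)
            self._split = cnn_feat.shape[1]
            feat = np.concatenate([cnn_feat, lstm_feat], axis=1)
        elif kind == "cnn_lstm":
            fmap = self.trunk.forward(batch["tensor"], train)
            self._fmap_shape = fmap.shape
            b, c, h, w = fmap.shape
            # unroll the feature map along its width into a length-w sequence
            seq = fmap.transpose(0, 3, 1, 2).reshape(b, w, c * h)
            feat = self.lstm.forward(seq, train)
        return self.head.forward(feat, train)

    def backward(self, dlogits: np.ndarray) -> None:
        kind = self.spec.kind
        dfeat = self.head.backward(dlogits)
        if kind == "cnn":
            self.trunk.backward(dfeat.reshape(self._fmap_shape))
        elif kind == "lstm":
            self.lstm.backward(dfeat)
        elif kind == "multiframe":
            self.lstm.backward(dfeat[:, self._split:])
            self.trunk.backward(
                dfeat[:, :self._split].reshape(self._fmap_shape))
        elif kind == "cnn_lstm":
            b, c, h, w = self._fmap_shape
            dseq = self.lstm.backward(dfeat)
            self.trunk.backward(
                dseq.reshape(b, w, c, h).transpose(0, 2, 3, 1))

    def predict_proba(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        return nn.softmax(self.forward(batch, train=False))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

class _Branch:
    """A feature extractor: one branch of the network plus a flatten."""

    def __init__(self, module, reshape=None) -> None:
        self.module, self.reshape = module, reshape

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.module.forward(x, train)
        return out.reshape(out.shape[0], -1) if self.reshape else out

    __call__ = forward


def build_cnn_branch(spec: ModelSpec, seed: int = 0, dtype=np.float32) -> _Branch:
    """Instance branch: (B, 2, N, N) tensor -> flat feature vector."""
    rng = np.random.default_rng(seed)
    return _Branch(ConvTrunk(spec, rng, dtype), reshape=True)


def build_lstm_branch(spec: ModelSpec, seed: int = 0, dtype=np.float32) -> _Branch:
    """Sequence branch: (B, M, N) series -> (B, lstm_units) feature."""
    rng = np.random.default_rng(seed)
    return _Branch(nn.LSTM(spec.n_channels, spec.lstm_units, rng, dtype))


def build_multiframe(spec: ModelSpec, seed: int = 0,
                     dtype=np.float32) -> SegmentClassifier:
    """The parallel two-branch classifier."""
    return SegmentClassifier(_with_kind(spec, "multiframe"), seed, dtype)


def build_cnn_lstm(spec: ModelSpec, seed: int = 0,
                   dtype=np.float32) -> SegmentClassifier:
    """The sequential conv-then-recurrent baseline."""
    return SegmentClassifier(_with_kind(spec, "cnn_lstm"), seed, dtype)


def build_model(spec: ModelSpec, seed: int = 0,
                dtype=np.float32) -> SegmentClassifier:
    """Build any of the four architectures from its spec."""
    return SegmentClassifier(spec, seed, dtype)


def _with_kind(spec: ModelSpec, kind: str) -> ModelSpec:
    if spec.kind != kind:
        from dataclasses import replace
        return replace(spec, kind=kind)
    return spec
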