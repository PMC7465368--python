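"""Dense-connectivity backbone with multi-level feature-map fusion.

The network takes 224x224x3 patches through a 7x7 stride-2 stem, four dense
blocks (growth rate 32, bottleneck 4x growth) separated by halving transition
layers, and taps a global-average-pool (GAP) vector after each chosen stage.
The tapped vectors are concatenated into one fused descriptor that feeds a
dropout -> batch-norm -> softmax head. With the default depth (block repeats
6/12/48/32) the per-tap GAP widths are 128, 256, 896 and 1920, so the full
fusion vector has 3200 features.

A closed-form parameter ledger accompanies the builder. Its accounting
convention is: convolutions carry no bias; every normalization layer
contributes 4 parameters per channel (scale, shift and the two tracked batch
statistics); the last dense block includes a trailing normalization over its
output channels. Under this convention the ledger and the built model count
parameters identically, which the test suite checks for every tap subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .nn import (
    AvgPool2d,
    BatchNorm1d,
    BatchNorm2d,
    Conv2d,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool2d,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

FULL_BLOCK_REPEATS = (6, 12, 48, 32)
REDUCED_BLOCK_REPEATS = (2, 2, 4, 2)


@dataclass(frozen=True)
class ArchitectureSpec:
    """All integers defining the backbone, taps and head."""

    input_side: int = 224
    stem_channels: int = 64
    growth_rate: int = 32
    block_repeats: tuple[int, ...] = FULL_BLOCK_REPEATS
    taps: tuple[int, ...] = (1, 2, 3, 4)
    compression: float = 0.5
    dropout: float = 0.5
    n_classes: int = 8

    @property
    def bottleneck_width(self) -> int:
        return 4 * self.growth_rate

    @property
    def n_blocks(self) -> int:
        return len(self.block_repeats)

    def validate(self) -> None:
        if not self.taps:
            raise ValueError("taps must be a non-empty subset of the blocks")
        if any(t < 1 or t > self.n_blocks for t in self.taps):
            raise ValueError(
                f"taps {self.taps} reference absent blocks "
                f"(1..{self.n_blocks})")
        if len(set(self.taps)) != len(self.taps):
            raise ValueError("duplicate taps")
        if not 0 < self.compression <= 1:
            raise ValueError("compression must be in (0, 1]")

    def channel_plan(self) -> dict:
        """Channel recursion: per-block input/output and tap widths.

        Only blocks up to max(taps) are built; blocks before the last built
        one are followed by a transition, the last built block by a trailing
        normalization when it is the final block of the full plan, otherwise
        by its transition (taps 1..3 sit after the transitions).
        """
        self.validate()
        m = max(self.taps)
        c = self.stem_channels
        block_in, block_out, tap_width = {}, {}, {}
        for k in range(1, m + 1):
            block_in[k] = c
            c = c + self.block_repeats[k - 1] * self.growth_rate
            block_out[k] = c
            if k < self.n_blocks:
                c = int(c * self.compression)
                tap_width[k] = c
            else:
                tap_width[k] = block_out[k]
        fused = sum(tap_width[t] for t in sorted(self.taps))
        return {
            "last_block": m,
            "block_in": block_in,
            "block_out": block_out,
            "tap_width": tap_width,
            "fused_width": fused,
        }

    @property
    def fused_width(self) -> int:
        return self.channel_plan()["fused_width"]

    def with_taps(self, taps: Sequence[int]) -> "ArchitectureSpec":
        return replace(self, taps=tuple(sorted(taps)))


def reduced_spec(n_classes: int = 2, taps=(1, 2, 3, 4)) -> ArchitectureSpec:
    """Desk-scale configuration: same topology, block repeats 2/2/4/2."""
    return ArchitectureSpec(block_repeats=REDUCED_BLOCK_REPEATS,
                            taps=tuple(taps), n_classes=n_classes)


# ---------------------------------------------------------------------------
# closed-form parameter accounting
# ---------------------------------------------------------------------------

def dense_layer_param_count(c_in: int, growth: int = 32,
                            bottleneck: int = 128) -> int:
    """Parameters of one BN-ReLU-1x1conv-BN-ReLU-3x3conv dense layer.

    4*c_in for the first normalization, c_in*bottleneck for the 1x1
    convolution, 4*bottleneck for the second normalization and
    9*bottleneck*growth for the 3x3 convolution. With the defaults this is
    132*c_in + 37,376.
    """
    if c_in < 1:
        raise ValueError("c_in must be >= 1")
    return 4 * c_in + c_in * bottleneck + 4 * bottleneck \
        + 9 * bottleneck * growth


def transition_param_count(c_in: int) -> int:
    """Parameters of a halving transition: 4*c_in (BN) + c_in*(c_in/2)."""
    if c_in % 2:
        raise ValueError(f"transition input channels must be even: {c_in}")
    return c_in * (c_in // 2 + 4)


def dense_block_param_count(c_in: int, repeats: int, growth: int = 32,
                            bottleneck: int = 128,
                            trailing_norm: bool = False) -> int:
    """Sum of a block's dense layers, plus its trailing normalization."""
    total = sum(dense_layer_param_count(c_in + i * growth, growth, bottleneck)
                for i in range(repeats))
    if trailing_norm:
        total += 4 * (c_in + repeats * growth)
    return total


@dataclass
class LedgerEntry:
    name: str
    count: int
    percent: float = field(default=0.0)


@dataclass
class ParamLedger:
    entries: list[LedgerEntry]
    total: int

    def __getitem__(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.count
        raise KeyError(name)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(e.name, e.count, round(e.percent, 1)) for e in self.entries],
            columns=["layer", "n_params", "pct_params"],
        )


def param_ledger(spec: ArchitectureSpec) -> ParamLedger:
    """Closed-form per-stage parameter counts for a spec."""
    spec.validate()
    plan = spec.channel_plan()
    g, b = spec.growth_rate, spec.bottleneck_width
    entries = [
        LedgerEntry("stem_conv", 7 * 7 * 3 * spec.stem_channels),
        LedgerEntry("stem_bn", 4 * spec.stem_channels),
    ]
    m = plan["last_block"]
    for k in range(1, m + 1):
        trailing = k == spec.n_blocks
        entries.append(LedgerEntry(
            f"db{k}",
            dense_block_param_count(plan["block_in"][k],
                                    spec.block_repeats[k - 1], g, b,
                                    trailing_norm=trailing)))
        if not trailing:
            entries.append(LedgerEntry(
                f"trans{k}", transition_param_count(plan["block_out"][k])))
    fused = plan["fused_width"]
    entries.append(LedgerEntry("head_bn", 4 * fused))
    entries.append(LedgerEntry(
        "softmax", fused * spec.n_classes + spec.n_classes))
    total = sum(e.count for e in entries)
    for e in entries:
        e.percent = 100.0 * e.count / total
    return ParamLedger(entries, total)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class _DenseLayer:
    """BN-ReLU-1x1conv -> BN-ReLU-3x3conv producing `growth` new maps."""

    def __init__(self, c_in, growth, bottleneck, rng, dtype):
        self.ops = [
            BatchNorm2d(c_in, dtype=dtype),
            ReLU(),
            Conv2d(c_in, bottleneck, 1, rng=rng, dtype=dtype),
            BatchNorm2d(bottleneck, dtype=dtype),
            ReLU(),
            Conv2d(bottleneck, growth, 3, pad=1, rng=rng, dtype=dtype),
        ]

    def forward(self, x, training):
        for op in self.ops:
            x = op.forward(x, training)
        return x

    def backward(self, dg):
        for op in reversed(self.ops):
            dg = op.backward(dg)
        return dg

    def layers(self):
        return self.ops


class _DenseBlock:
    def __init__(self, c_in, repeats, growth, bottleneck, rng, dtype):
        self.growth = growth
        self.dense_layers = [
            _DenseLayer(c_in + i * growth, growth, bottleneck, rng, dtype)
            for i in range(repeats)
        ]
        self._offsets = [c_in + i * growth for i in range(repeats)]

    def forward(self, x, training):
        feats = x
        for layer in self.dense_layers:
            g = layer.forward(feats, training)
            feats = np.concatenate([feats, g], axis=1)
        return feats

    def backward(self, dfeats):
        g = self.growth
        for off, layer in zip(reversed(self._offsets),
                              reversed(self.dense_layers)):
            dg = dfeats[:, off:off + g]
            dfront = layer.backward(dg)
            dfeats = dfeats[:, :off] + dfront
        return dfeats

    def layers(self):
        return [op for dl in self.dense_layers for op in dl.layers()]


class _Seq:
    def __init__(self, ops):
        self.ops = ops

    def forward(self, x, training):
        for op in self.ops:
            x = op.forward(x, training)
        return x

    def backward(self, dy):
        for op in reversed(self.ops):
            dy = op.backward(dy)
        return dy

    def layers(self):
        out = []
        for op in self.ops:
            out.extend(op.layers() if hasattr(op, "layers") else [op])
        return out


class MultiScaleFusionNet:
    """The backbone + GAP-fusion classifier as a trainable object.

    Patches from the four pyramid scales are pooled as independent 3-channel
    samples (the first convolution's 9,408 parameters pin a 3-channel input),
    so one model serves every scale. ``forward`` returns class probabilities;
    ``train_step``-style use goes through :meth:`loss_and_grads`.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0,
                 dtype=np.float32):
        spec.validate()
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.rng = rng
        plan = spec.channel_plan()
        self.plan = plan
        g, b = spec.growth_rate, spec.bottleneck_width

        self.stem = _Seq([
            Conv2d(3, spec.stem_channels, 7, stride=2, pad=3, first=True,
                   rng=rng, dtype=dtype),
            BatchNorm2d(spec.stem_channels, dtype=dtype),
            ReLU(),
            MaxPool2d(3, 2, 1),
        ])
        self.segments = []  # segment k ends where tap k would attach
        m = plan["last_block"]
        for k in range(1, m + 1):
            ops = [_DenseBlock(plan["block_in"][k], spec.block_repeats[k - 1],
                               g, b, rng, dtype)]
            if k < spec.n_blocks:
                c = plan["block_out"][k]
                ops += [
                    BatchNorm2d(c, dtype=dtype),
                    ReLU(),
                    Conv2d(c, int(c * spec.compression), 1, rng=rng,
                           dtype=dtype),
                    AvgPool2d(2, 2),
                ]
            else:
                ops += [BatchNorm2d(plan["block_out"][k], dtype=dtype),
                        ReLU()]
            self.segments.append(_Seq(ops))
        self.gaps = {k: GlobalAvgPool() for k in spec.taps}
        self.head = _Seq([
            Dropout(spec.dropout, rng=rng),
            BatchNorm1d(plan["fused_width"], dtype=dtype),
            Dense(plan["fused_width"], spec.n_classes, rng=rng, dtype=dtype),
        ])
        self.spatial_sizes: list[int] = []

    # -- bookkeeping --------------------------------------------------------

    def _all_layers(self):
        out = self.stem.layers()
        for seg in self.segments:
            out.extend(seg.layers())
        out.extend(self.gaps.values())
        out.extend(self.head.layers())
        return out

    def parameters(self):
        ps = []
        for layer in self._all_layers():
            ps.extend(layer.params())
        return ps

    def count_params(self, include_state: bool = True) -> int:
        """Framework-side parameter count (learned + tracked statistics)."""
        return sum(layer.n_params(include_state)
                   for layer in self._all_layers())

    @property
    def fused_width(self) -> int:
        return self.plan["fused_width"]

    # -- passes -------------------------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False):
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected NCHW input with 3 channels, "
                             f"got shape {x.shape}")
        x = np.asarray(x, self.dtype)
        self.spatial_sizes = []
        h = x
        for op in self.stem.ops:
            h = op.forward(h, training)
            if isinstance(op, (Conv2d, MaxPool2d)):
                self.spatial_sizes.append(h.shape[2])
        pooled = {}
        for k, seg in enumerate(self.segments, start=1):
            h = seg.forward(h, training)
            self.spatial_sizes.append(h.shape[2])
            if k in self.gaps:
                pooled[k] = self.gaps[k].forward(h, training)
        fused = np.concatenate([pooled[k] for k in sorted(pooled)], axis=1)
        self.last_fused_width = fused.shape[1]
        self._tap_slices = {}
        off = 0
        for k in sorted(pooled):
            self._tap_slices[k] = slice(off, off + pooled[k].shape[1])
            off += pooled[k].shape[1]
        return self.head.forward(fused, training)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probability vectors, rows summing to one."""
        return softmax(self.forward_logits(x, training))

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        out = [self.forward(x[i:i + batch_size])
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        m = self.plan["last_block"]
        dmain = None
        for k in range(m, 0, -1):
            if k in self.gaps:
                dtap = self.gaps[k].backward(dfused[:, self._tap_slices[k]])
                dmain = dtap if dmain is None else dmain + dtap
            dmain = self.segments[k - 1].backward(dmain)
        self.stem.backward(dmain)

    def loss_and_grads(self, x: np.ndarray, onehot: np.ndarray):
        """One forward/backward pass; returns (loss, probabilities)."""
        logits = self.forward_logits(x, training=True)
        loss, probs, dlogits = softmax_cross_entropy(logits, onehot)
        self.backward(dlogits)
        return loss, probs

    # -- persistence ---------------------------------------------------------

    def _arrays(self):
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i}"] = p.data
        states = [a for layer in self._all_layers()
                  for a in layer.state_arrays()]
        for i, a in enumerate(states):
            out[f"state_{i}"] = a
        return out

    def save(self, path) -> None:
        import json
        from dataclasses import asdict

        np.savez_compressed(path, spec=json.dumps(asdict(self.spec)),
                            **self._arrays())

    @classmethod
    def load(cls, path) -> "MultiScaleFusionNet":
        import json

        with np.load(path, allow_pickle=False) as npz:
            d = json.loads(str(npz["spec"]))
            d["block_repeats"] = tuple(d["block_repeats"])
            d["taps"] = tuple(d["taps"])
            model = cls(ArchitectureSpec(**d))
            for key, arr in model._arrays().items():
                stored = npz[key]
                if stored.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}")
                arr[...] = stored
        return model


def build_model(spec: ArchitectureSpec, n_classes: int | None = None,
                init: str = "random", seed: int = 0) -> MultiScaleFusionNet:
    """Construct the fusion network; warns for unusual class counts."""
    if n_classes is not None:
        spec = replace(spec, n_classes=n_classes)
    if spec.n_classes not in (2, 4, 8):
        import warnings

        warnings.warn(f"unusual number of classes: {spec.n_classes}",
                      stacklevel=2)
    if init not in ("random", "pretrained"):
        raise ValueError(f"unknown init {init!r}")
    if init == "pretrained":
        raise NotImplementedError(
            "pretrained initialization requires external weights; "
            "use init='random'")
    return MultiScaleFusionNet(spec, seed=seed)


def build_baseline(spec: ArchitectureSpec,
                   n_classes: int | None = None,
                   seed: int = 0) -> MultiScaleFusionNet:
    """Single-tap baseline: same backbone, only the final GAP feeds the head."""
    return build_model(spec.with_taps([spec.n_blocks]), n_classes, seed=seed)
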