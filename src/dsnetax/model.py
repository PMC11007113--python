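"""The deep-shallow parallel species classifier.

The (L' x d) per-token embedding matrix of a sequence is treated as a
single-channel 2-D feature map (image convention) and fed to two parallel
branches:

* a **deep branch** — a ResNeSt-style backbone of four stages holding
  2, 3, 2 and 2 Split-Attention blocks, capturing global sequence-level
  features through progressive downsampling and global average pooling;
* a **shallow branch** — three successive Conv+ReLU layers with limited
  downsampling, preserving local detail that the deep stack smooths away.

Both branch outputs are globally pooled and fused (concatenation by
default) into a linear species-classification head.  Baseline topologies
(a plain 3-layer CNN, and a 34-layer-style residual network with stage
blocks [3,4,6,3]) are provided as variants for ablation.

A Split-Attention block splits its channels into ``cardinality`` groups x
``radix`` branches; the branches are convolved, summed, globally pooled,
squeezed through a bottleneck MLP and recombined with r-softmax attention
weights (softmax across the radix axis, degenerating to a sigmoid gate at
radix 1), plus a residual connection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    BatchNorm2d, Conv2d, GlobalAvgPool2d, Linear, MaxPool2d, Module,
    ReLU, Sequential, Tensor, concat, softmax,
)

VARIANTS = ("cnn3", "resnet34", "resnest", "dsnetax")


@dataclass
class SplitAttnConfig:
    """Split-Attention geometry: channel groups, radix splits, bottleneck."""

    cardinality: int = 1
    radix: int = 2
    reduction: int = 4

    def __post_init__(self) -> None:
        if self.cardinality < 1 or self.radix < 1:
            raise ValueError("cardinality and radix must be >= 1")


@dataclass
class DSNetaxConfig:
    """Architecture hyperparameters of the classifier and its ablation variants.

    Defaults describe the full-scale network; desk-scale runs shrink
    ``stem_width``/``stage_widths``/``shallow_width``.  ``stage_blocks``
    sums to 9 Split-Attention blocks; ``shallow_layers`` in {3,4,5} covers
    the shallow-depth ablation.
    """

    n_classes: int = 2
    variant: str = "dsnetax"
    stage_blocks: tuple[int, ...] = (2, 3, 2, 2)
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    stem_width: int = 64
    shallow_layers: int = 3
    shallow_width: int = 64
    fusion: str = "concat"  # concat | sum
    split_attn: SplitAttnConfig = field(default_factory=SplitAttnConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.stage_blocks) != len(self.stage_widths):
            raise ValueError("stage_blocks and stage_widths must align")
        if self.fusion not in ("concat", "sum"):
            raise ValueError("fusion must be 'concat' or 'sum'")


def rsoftmax(logits: Tensor, radix: int, cardinality: int) -> Tensor:
    """Attention weights over radix branches: (B, width*radix) -> (B, radix, width).

    Softmax across the radix axis per (cardinality group, channel); at
    radix 1 this degenerates to an independent sigmoid gate.
    """
    B = logits.shape[0]
    width = logits.shape[1] // radix
    per_group = width // cardinality
    x = logits.reshape(B, cardinality, radix, per_group)
    if radix > 1:
        w = softmax(x, axis=2)
    else:
        w = x.sigmoid()
    return w.transpose(0, 2, 1, 3).reshape(B, radix, width)


class SplitAttentionBlock(Module):
    """Bottleneck block: 1x1 reduce -> radix-split 3x3 -> r-softmax recombine -> 1x1 expand."""

    def __init__(self, in_ch: int, width: int, rng: np.random.Generator,
                 cfg: SplitAttnConfig, stride: int = 1, out_ch: int | None = None):
        super().__init__()
        out_ch = out_ch or width
        if width % (cfg.cardinality * cfg.radix):
            raise ValueError(
                f"stage width {width} not divisible by cardinality*radix="
                f"{cfg.cardinality * cfg.radix}"
            )
        self.cfg = cfg
        self.width = width
        self.stride = stride
        self.conv_reduce = Conv2d(in_ch, width, 1, rng, bias=False)
        self.bn1 = BatchNorm2d(width)
        self.conv_radix = Conv2d(width, width * cfg.radix, 3, rng, stride=stride,
                                 groups=cfg.cardinality * cfg.radix, bias=False)
        self.bn2 = BatchNorm2d(width * cfg.radix)
        attn_ch = max(width * cfg.radix // cfg.reduction, 8)
        self.fc1 = Conv2d(width, attn_ch, 1, rng, groups=cfg.cardinality)
        self.fc2 = Conv2d(attn_ch, width * cfg.radix, 1, rng, groups=cfg.cardinality)
        self.conv_expand = Conv2d(width, out_ch, 1, rng, bias=False)
        self.bn3 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.downsample = Sequential(
                Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False),
                BatchNorm2d(out_ch),
            )
        else:
            self.downsample = None

    def forward(self, x: Tensor) -> Tensor:
        radix, width = self.cfg.radix, self.width
        y = self.bn1(self.conv_reduce(x)).relu()
        y = self.bn2(self.conv_radix(y)).relu()      # (B, width*radix, H, W)
        B, _, H, W = y.shape
        splits = [y[:, r * width:(r + 1) * width] for r in range(radix)]
        gathered = splits[0]
        for s in splits[1:]:
            gathered = gathered + s                  # sum over radix
        pooled = gathered.mean(axis=(2, 3))          # (B, width)
        gate = self.fc1(pooled.reshape(B, width, 1, 1)).relu()
        gate = self.fc2(gate).reshape(B, width * radix)
        attn = rsoftmax(gate, radix, self.cfg.cardinality)  # (B, radix, width)
        out = None
        for r in range(radix):
            contrib = splits[r] * attn[:, r].reshape(B, width, 1, 1)
            out = contrib if out is None else out + contrib
        out = self.bn3(self.conv_expand(out))
        identity = x if self.downsample is None else self.downsample(x)
        return (out + identity).relu()


class BasicBlock(Module):
    """Plain two-conv residual block (the 34-layer-style baseline unit)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, stride=stride, bias=False)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, bias=False)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.downsample = Sequential(
                Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False),
                BatchNorm2d(out_ch),
            )
        else:
            self.downsample = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        identity = x if self.downsample is None else self.downsample(x)
        return (y + identity).relu()


class Stem(Module):
    """3x3 conv stride 2 + BN/ReLU + 3x3 max-pool stride 2."""

    def __init__(self, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(1, out_ch, 3, rng, stride=2, bias=False)
        self.bn = BatchNorm2d(out_ch)
        self.pool = MaxPool2d(3, 2, 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.pool(self.bn(self.conv(x)).relu())


class DeepBranch(Module):
    """Stem + four stages of residual blocks + global average pooling."""

    def __init__(self, cfg: DSNetaxConfig, rng: np.random.Generator,
                 block_kind: str = "split_attention"):
        super().__init__()
        self.stem = Stem(cfg.stem_width, rng)
        self.stages: list[Sequential] = []
        in_ch = cfg.stem_width
        for si, (n_blocks, width) in enumerate(zip(cfg.stage_blocks, cfg.stage_widths)):
            blocks = []
            for bi in range(n_blocks):
                stride = 2 if (si > 0 and bi == 0) else 1
                if block_kind == "split_attention":
                    blocks.append(SplitAttentionBlock(in_ch, width, rng,
                                                      cfg.split_attn, stride=stride))
                else:
                    blocks.append(BasicBlock(in_ch, width, rng, stride=stride))
                in_ch = width
            self.stages.append(Sequential(*blocks))
        self.pool = GlobalAvgPool2d()
        self.out_features = in_ch

    def forward(self, x: Tensor) -> Tensor:
        y = self.stem(x)
        for stage in self.stages:
            y = stage(y)
        return self.pool(y)


class ShallowBranch(Module):
    """``shallow_layers`` Conv+ReLU pairs, <= 4x total downsampling, then pooling."""

    def __init__(self, cfg: DSNetaxConfig, rng: np.random.Generator):
        super().__init__()
        layers: list[Module] = []
        in_ch = 1
        for i in range(cfg.shallow_layers):
            stride = 2 if i < 2 else 1  # downsample at most 4x overall
            layers.append(Conv2d(in_ch, cfg.shallow_width, 3, rng, stride=stride))
            layers.append(ReLU())
            in_ch = cfg.shallow_width
        self.convs = Sequential(*layers)
        self.pool = GlobalAvgPool2d()
        self.out_features = cfg.shallow_width

    def forward(self, x: Tensor) -> Tensor:
        return self.pool(self.convs(x))


class SpeciesClassifier(Module):
    """Variant-dispatching classifier over (B, 1, L', d) embedding maps."""

    def __init__(self, cfg: DSNetaxConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 17]))
        self.deep: DeepBranch | None = None
        self.shallow: ShallowBranch | None = None
        if cfg.variant == "cnn3":
            self.shallow = ShallowBranch(cfg, rng)
            head_in = self.shallow.out_features
        elif cfg.variant == "resnet34":
            rcfg = DSNetaxConfig(**{**asdict_shallow(cfg),
                                    "stage_blocks": (3, 4, 6, 3)})
            self.deep = DeepBranch(rcfg, rng, block_kind="basic")
            head_in = self.deep.out_features
        elif cfg.variant == "resnest":
            self.deep = DeepBranch(cfg, rng, block_kind="split_attention")
            head_in = self.deep.out_features
        else:  # dsnetax: deep + shallow in parallel
            self.deep = DeepBranch(cfg, rng, block_kind="split_attention")
            self.shallow = ShallowBranch(cfg, rng)
            if cfg.fusion == "concat":
                head_in = self.deep.out_features + self.shallow.out_features
            else:
                if self.deep.out_features != self.shallow.out_features:
                    raise ValueError("sum fusion needs equal branch widths")
                head_in = self.deep.out_features
        self.head = Linear(head_in, cfg.n_classes, rng)

    def features(self, x: Tensor) -> Tensor:
        parts = []
        if self.deep is not None:
            parts.append(self.deep(x))
        if self.shallow is not None:
            parts.append(self.shallow(x))
        if len(parts) == 1:
            return parts[0]
        if self.cfg.fusion == "concat":
            return concat(parts, axis=1)
        return parts[0] + parts[1]

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.features(x))

    # -- introspection ---------------------------------------------------------
    def count_blocks(self) -> dict[str, int]:
        counts = {"split_attention": 0, "basic": 0, "shallow_convs": 0}
        for m in self.modules():
            if isinstance(m, SplitAttentionBlock):
                counts["split_attention"] += 1
            elif isinstance(m, BasicBlock):
                counts["basic"] += 1
        if self.shallow is not None:
            counts["shallow_convs"] = sum(
                isinstance(layer, Conv2d) for layer in self.shallow.convs.layers
            )
        return counts

    def describe(self) -> str:
        c = self.count_blocks()
        return (f"variant={self.cfg.variant} split_attention_blocks={c['split_attention']} "
                f"basic_blocks={c['basic']} shallow_convs={c['shallow_convs']} "
                f"parameters={self.n_parameters()}")


def asdict_shallow(cfg: DSNetaxConfig) -> dict:
    d = asdict(cfg)
    d["split_attn"] = SplitAttnConfig(**d["split_attn"])
    d["stage_blocks"] = tuple(d["stage_blocks"])
    d["stage_widths"] = tuple(d["stage_widths"])
    return d


def build_model(cfg: DSNetaxConfig) -> SpeciesClassifier:
    return SpeciesClassifier(cfg)


def predict_topk(logits: np.ndarray, ktop: int) -> np.ndarray:
    """Labels of the ktop largest logits per row, descending.

    Ties are broken by ascending label id, so predictions are deterministic.
    Accepts a single logit vector or a (B, C) batch.
    """
    z = np.asarray(logits, dtype=np.float64)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    C = z.shape[1]
    if not 1 <= ktop <= C:
        raise ValueError(f"ktop must be in 1..{C}, got {ktop}")
    ids = np.broadcast_to(np.arange(C), z.shape)
    order = np.lexsort((ids, -z), axis=1)[:, :ktop]
    return order[0] if single else order


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(path: str | Path, model: SpeciesClassifier,
                    vocab_fingerprint: str, extra: dict | None = None) -> None:
    """Single-file archive of weights + config + vocabulary fingerprint."""
    meta = {
        "config": asdict(model.cfg),
        "vocab_fingerprint": vocab_fingerprint,
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path,
                    expect_vocab_fingerprint: str | None = None) -> SpeciesClassifier:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    if (expect_vocab_fingerprint is not None
            and meta["vocab_fingerprint"] != expect_vocab_fingerprint):
        raise ValueError(
            f"vocabulary fingerprint mismatch: checkpoint has "
            f"{meta['vocab_fingerprint']!r}, expected {expect_vocab_fingerprint!r}"
        )
    cd = meta["config"]
    cd["split_attn"] = SplitAttnConfig(**cd["split_attn"])
    cd["stage_blocks"] = tuple(cd["stage_blocks"])
    cd["stage_widths"] = tuple(cd["stage_widths"])
    model = SpeciesClassifier(DSNetaxConfig(**cd))
    model.load_state_dict(state)
    return model
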