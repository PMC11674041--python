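"""The three U-net variants built from inception-style blocks.

Each network follows a classic U shape: a contracting path that alternates
a convolutional block with 2x2 stride-2 max pooling, a bottleneck block,
and an expanding path of 2x2 up-convolutions, skip concatenations with the
same-level contracting output, and another block.  A 1x1 convolution with a
sigmoid produces a per-pixel probability map; every other activation is a
leaky ReLU.

The blocks are channel concatenations of five parallel branches.  Writing
``conv(k)`` for a k x k convolution followed by batch normalization and a
leaky ReLU:

    variant 1:  [conv(1)] [conv(3)]                   [conv(1)]                   [conv(1)] [pool2x2 -> conv(1)]
    variant 2:  [conv(1)] [conv(3) -> conv(3)]        [conv(1) -> conv(3)]        [conv(1)] [pool2x2 -> conv(1)]
    variant 3:  [conv(1)] [conv(3) -> conv(3)]        [conv(1) -> conv(3) -> conv(3)]  [conv(1)] [pool2x2 -> conv(1)]

The 2x2 pool inside a branch runs at stride 1 with edge padding so its
output stays concatenable with the other branches (the inception
convention); its 1x1 convolution carries a leaky ReLU but no batch norm.
With f filters per branch a block emits 5*f channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "BlockSpec",
    "NetworkSpec",
    "InceptionBlock",
    "UNet",
    "build_block",
    "build_unet",
    "count_parameters",
    "describe_network",
    "save_weights",
    "load_weights",
]


@dataclass
class BlockSpec:
    """One inception-style block: the variant and the per-branch channels."""

    variant: int
    filters: int

    def __post_init__(self) -> None:
        if self.variant not in (1, 2, 3):
            raise ValueError(f"variant must be 1, 2 or 3, got {self.variant}")
        if self.filters < 1:
            raise ValueError(f"filters must be >= 1, got {self.filters}")


@dataclass
class NetworkSpec:
    """Declarative description of a U-net variant.

    depth counts the contracting levels (poolings); the printed architecture
    uses 5, i.e. six blocks.  base_filters is the per-branch channel count of
    the shallowest block; deeper levels double it, capped at 16x.  With
    ``symmetric_decoder`` (default) the expanding path mirrors all ``depth``
    levels so the output matches the input size natively.  The alternative
    ``symmetric_decoder=False`` reproduces the printed four-up-stage layout
    and restores the input size with a final bilinear upsampling.
    """

    variant: int
    base_filters: int = 8
    depth: int = 5
    input_size: int = 512
    leaky_slope: float = 0.3
    symmetric_decoder: bool = True
    filter_cap_mult: int = 16

    def __post_init__(self) -> None:
        if self.variant not in (1, 2, 3):
            raise ValueError(f"variant must be 1, 2 or 3, got {self.variant}")
        if self.base_filters < 1:
            raise ValueError(f"base_filters must be >= 1, got {self.base_filters}")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2**self.depth}"
            )

    def level_filters(self, level: int) -> int:
        return min(self.base_filters * 2**level, self.filter_cap_mult * self.base_filters)


def _conv_bn_act(in_ch: int, out_ch: int, kernel: int, slope: float,
                 rng: np.random.Generator) -> list[nn.Module]:
    return [nn.Conv2d(in_ch, out_ch, kernel, rng), nn.BatchNorm2d(out_ch), nn.LeakyReLU(slope)]


_BRANCH_KERNELS: dict[int, list[list[int]]] = {
    # kernel sizes of the conv+BN chain in branches (i)-(iv); branch (v) is
    # always pool -> 1x1 conv
    1: [[1], [3], [1], [1]],
    2: [[1], [3, 3], [1, 3], [1]],
    3: [[1], [3, 3], [1, 3, 3], [1]],
}


class InceptionBlock(nn.Module):
    """Five-branch block; output channels = 5 * filters, spatial size kept."""

    def __init__(self, spec: BlockSpec, in_ch: int, slope: float = 0.3,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.spec = spec
        self.in_ch = in_ch
        self.out_ch = 5 * spec.filters
        branches: list[nn.Module] = []
        for kernels in _BRANCH_KERNELS[spec.variant]:
            layers: list[nn.Module] = []
            c = in_ch
            for k in kernels:
                layers += _conv_bn_act(c, spec.filters, k, slope, rng)
                c = spec.filters
            branches.append(nn.Sequential(*layers))
        branches.append(nn.Sequential(
            nn.MaxPoolSame2x2(),
            nn.Conv2d(in_ch, spec.filters, 1, rng),
            nn.LeakyReLU(slope),
        ))
        self.concat = nn.Concat(branches)

    def params(self) -> list[nn.Param]:
        return self.concat.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise ValueError(f"block needs spatial dims >= 2, got {x.shape[2:]}")
        return self.concat.forward(x, train=train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.concat.backward(g)


def build_block(spec: BlockSpec, input_tensor: np.ndarray, slope: float = 0.3,
                seed: int = 0) -> np.ndarray:
    """Construct a block sized to ``input_tensor``'s channels and apply it
    (inference mode). Convenience wrapper around :class:`InceptionBlock`."""
    x = np.asarray(input_tensor, dtype=nn._F32)
    if x.ndim != 4:
        raise ValueError("input tensor must be NCHW")
    block = InceptionBlock(spec, in_ch=x.shape[1], slope=slope,
                           rng=np.random.default_rng(seed))
    return block.forward(x, train=False)


class UNet(nn.Module):
    """Encoder-decoder network of inception blocks with skip connections.

    ``forward`` returns per-pixel probabilities in (0, 1); pass
    ``return_logits=True`` to get the pre-sigmoid map (used with the fused
    cross-entropy gradient during training — ``backward`` expects the
    gradient with respect to the logits).
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        s = spec.leaky_slope
        d = spec.depth

        self.enc_blocks: list[InceptionBlock] = []
        self.pools: list[nn.MaxPool2x2] = []
        c = 1
        for level in range(d):
            blk = InceptionBlock(BlockSpec(spec.variant, spec.level_filters(level)), c, s, rng)
            self.enc_blocks.append(blk)
            self.pools.append(nn.MaxPool2x2())
            c = blk.out_ch
        self.bottleneck = InceptionBlock(
            BlockSpec(spec.variant, spec.level_filters(d)), c, s, rng)
        c = self.bottleneck.out_ch

        self.n_up = d if spec.symmetric_decoder else min(d, 4)
        self.up_levels = list(range(d - 1, d - 1 - self.n_up, -1))
        self.ups: list[nn.UpConv2x2] = []
        self.dec_blocks: list[InceptionBlock] = []
        for level in self.up_levels:
            skip_ch = self.enc_blocks[level].out_ch
            up = nn.UpConv2x2(c, skip_ch, rng)
            blk = InceptionBlock(
                BlockSpec(spec.variant, spec.level_filters(level)), 2 * skip_ch, s, rng)
            self.ups.append(up)
            self.dec_blocks.append(blk)
            c = blk.out_ch
        self.head = nn.Conv2d(c, 1, 1, rng)
        self.final_upsample = (
            None if spec.symmetric_decoder or d <= 4
            else nn.BilinearUpsample(2 ** (d - self.n_up))
        )

    # -- plumbing ---------------------------------------------------------
    def _modules(self) -> list[nn.Module]:
        mods: list[nn.Module] = list(self.enc_blocks) + [self.bottleneck]
        mods += self.ups + self.dec_blocks + [self.head]
        return mods

    def params(self) -> list[nn.Param]:
        return [p for m in self._modules() for p in m.params()]

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                return_logits: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=nn._F32)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected NCHW input with 1 channel, got shape {x.shape}")
        if x.shape[2] != self.spec.input_size or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"input spatial size {x.shape[2:]} does not match the network's "
                f"{self.spec.input_size}x{self.spec.input_size}"
            )
        skips: list[np.ndarray] = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, train=train)
            skips.append(h)
            h = pool.forward(h, train=train)
        h = self.bottleneck.forward(h, train=train)
        for i, level in enumerate(self.up_levels):
            h = self.ups[i].forward(h, train=train)
            h = np.concatenate([h, skips[level]], axis=1)
            h = self.dec_blocks[i].forward(h, train=train)
        logits = self.head.forward(h, train=train)
        if self.final_upsample is not None:
            logits = self.final_upsample.forward(logits, train=train)
        if return_logits:
            return logits
        return nn.sigmoid(logits)

    def backward(self, g_logits: np.ndarray) -> np.ndarray:
        g = g_logits
        if self.final_upsample is not None:
            g = self.final_upsample.backward(g)
        g = self.head.backward(g)
        skip_grads: dict[int, np.ndarray] = {}
        for i in reversed(range(self.n_up)):
            level = self.up_levels[i]
            g = self.dec_blocks[i].backward(g)
            up_ch = self.ups[i].out_ch
            g_up, g_skip = g[:, :up_ch], g[:, up_ch:]
            skip_grads[level] = g_skip
            g = self.ups[i].backward(g_up)
        g = self.bottleneck.backward(g)
        for level in reversed(range(self.spec.depth)):
            g = self.pools[level].backward(g)
            if level in skip_grads:
                g = g + skip_grads[level]
            g = self.enc_blocks[level].backward(g)
        return g


def build_unet(spec: NetworkSpec, seed: int = 0) -> UNet:
    """Instantiate a U-net with Glorot-uniform weights drawn from ``seed``."""
    return UNet(spec, seed=seed)


def count_parameters(network: nn.Module) -> int:
    """Total trainable parameter count (stable across rebuilds of a spec)."""
    return int(sum(p.value.size for p in network.params()))


def describe_network(spec: NetworkSpec) -> str:
    """Human-readable layer table of the contracting and expanding paths."""
    lines = [f"U-net-{spec.variant}: base_filters={spec.base_filters} depth={spec.depth} "
             f"input={spec.input_size}x{spec.input_size}",
             "Layers - contracting:"]
    for level in range(spec.depth):
        f = spec.level_filters(level)
        lines.append(f"  Block {spec.variant} (filters/branch {f}, out {5 * f})")
        lines.append("  2x2 max pooling (stride 2)")
    f = spec.level_filters(spec.depth)
    lines.append(f"  Block {spec.variant} (filters/branch {f}, out {5 * f})  [bottleneck]")
    lines.append("Layers - expanding:")
    n_up = spec.depth if spec.symmetric_decoder else min(spec.depth, 4)
    for level in range(spec.depth - 1, spec.depth - 1 - n_up, -1):
        f = spec.level_filters(level)
        lines.append(f"  2x2 up convolution (out {5 * f})")
        lines.append(f"  concatenation (-> {10 * f})")
        lines.append(f"  Block {spec.variant} (filters/branch {f}, out {5 * f})")
    if not spec.symmetric_decoder and spec.depth > 4:
        lines.append(f"  bilinear upsampling x{2 ** (spec.depth - 4)}")
    lines.append("  1x1 convolution + sigmoid")
    return "\n".join(lines)


def _stateful_modules(network: UNet) -> list[nn.Module]:
    """Flatten a network into primitive layers, depth-first, in a stable
    order (used by checkpointing)."""
    out: list[nn.Module] = []

    def walk(m: nn.Module) -> None:
        if isinstance(m, InceptionBlock):
            walk(m.concat)
        elif isinstance(m, nn.Sequential):
            for layer in m.layers:
                walk(layer)
        elif isinstance(m, nn.Concat):
            for b in m.branches:
                walk(b)
        else:
            out.append(m)

    for m in network._modules():
        walk(m)
    return out


def save_weights(network: UNet, path: str) -> None:
    """Checkpoint parameters and batch-norm moving statistics to .npz."""
    arrays: dict[str, np.ndarray] = {}
    for i, m in enumerate(_stateful_modules(network)):
        for j, p in enumerate(m.params()):
            arrays[f"m{i}_p{j}"] = p.value
        if isinstance(m, nn.BatchNorm2d):
            arrays[f"m{i}_mean"] = m.moving_mean
            arrays[f"m{i}_var"] = m.moving_var
            arrays[f"m{i}_updates"] = np.array(m.updates)
    np.savez(path, **arrays)


def load_weights(network: UNet, path: str) -> UNet:
    data = np.load(path)
    for i, m in enumerate(_stateful_modules(network)):
        for j, p in enumerate(m.params()):
            key = f"m{i}_p{j}"
            if data[key].shape != p.value.shape:
                raise ValueError(f"checkpoint mismatch at {key}: "
                                 f"{data[key].shape} vs {p.value.shape}")
            p.value = data[key].astype(np.float32)
        if isinstance(m, nn.BatchNorm2d):
            m.moving_mean = data[f"m{i}_mean"].astype(np.float32)
            m.moving_var = data[f"m{i}_var"].astype(np.float32)
            m.updates = int(data[f"m{i}_updates"])
    return network
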