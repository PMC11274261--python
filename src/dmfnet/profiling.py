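"""Parameter and multiply-accumulate accounting.

Architectures are described as ordered layer tables (conv / batch-norm /
pooling / linear entries with explicit shapes).  ``count_params`` sums
trainable weights; ``count_conv_macs`` sums, over convolution layers, weight
count x output spatial positions — the convention under which a standard
ResNet18 at a 224 px input counts ~1.81 G MACs.

Reference backbones (resnet18, mobilenet_v2) are included as accounting
tables to pin the counting convention against their well-known footprints;
``dmfnet_backbone`` is the trimmed single-block-per-stage extractor actually
used by the network, and its table count is cross-checked against the
instantiated module in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class _Conv:
    cin: int
    cout: int
    k: tuple[int, int]
    stride: int = 1
    padding: int = 0
    groups: int = 1
    bias: bool = False
    in_div: int = 1   # cumulative network stride at this layer's input

    @property
    def params(self) -> int:
        return (self.cout * self.cin // self.groups * self.k[0] * self.k[1]
                + (self.cout if self.bias else 0))

    def out_size(self, s: int) -> int:
        return (s + 2 * self.padding - self.k[0]) // self.stride + 1

    def macs(self, s: int) -> int:
        so = self.out_size(s)
        return self.cout * (self.cin // self.groups) * self.k[0] * self.k[1] * so * so


@dataclass
class _BN:
    ch: int

    @property
    def params(self) -> int:
        return 2 * self.ch


@dataclass
class _Pool:
    k: int
    stride: int
    padding: int

    def out_size(self, s: int) -> int:
        return (s + 2 * self.padding - self.k) // self.stride + 1


@dataclass
class _Linear:
    fin: int
    fout: int

    @property
    def params(self) -> int:
        return self.fin * self.fout + self.fout


def _basic_block(cin, cout, stride, div):
    layers = [_Conv(cin, cout, (3, 3), stride, 1, in_div=div), _BN(cout),
              _Conv(cout, cout, (3, 3), 1, 1, in_div=div * stride), _BN(cout)]
    if stride != 1 or cin != cout:
        # projection shortcut sees the block input, in parallel with conv1
        layers += [_Conv(cin, cout, (1, 1), stride, in_div=div), _BN(cout)]
    return layers, div * stride


def _resnet_table(in_channels: int, blocks_per_stage: tuple[int, ...]):
    layers: list = [_Conv(in_channels, 64, (7, 7), 2, 3, in_div=1), _BN(64),
                    _Pool(3, 2, 1)]
    cin, div = 64, 4
    for stage, (cout, n) in enumerate(zip((64, 128, 256, 512), blocks_per_stage)):
        for b in range(n):
            stride = 2 if (stage > 0 and b == 0) else 1
            block, div = _basic_block(cin, cout, stride, div)
            layers += block
            cin = cout
    head = [_Linear(512, 1000)]
    return layers, head


def _inverted_residual(cin, cout, expand, stride, div):
    hidden = cin * expand
    layers = []
    if expand != 1:
        layers += [_Conv(cin, hidden, (1, 1), in_div=div), _BN(hidden)]
    layers += [_Conv(hidden, hidden, (3, 3), stride, 1, groups=hidden, in_div=div),
               _BN(hidden),
               _Conv(hidden, cout, (1, 1), in_div=div * stride), _BN(cout)]
    return layers, div * stride


def _mobilenet_v2_table(in_channels: int):
    cfg = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
           (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]
    layers: list = [_Conv(in_channels, 32, (3, 3), 2, 1, in_div=1), _BN(32)]
    cin, div = 32, 2
    for t, c, n, s in cfg:
        for b in range(n):
            block, div = _inverted_residual(cin, c, t, s if b == 0 else 1, div)
            layers += block
            cin = c
    layers += [_Conv(cin, 1280, (1, 1), in_div=div), _BN(1280)]
    head = [_Linear(1280, 1000)]
    return layers, head


_ARCHS = {
    "dmfnet_backbone": lambda cin: _resnet_table(cin, (1, 1, 1, 1)),
    "resnet18": lambda cin: _resnet_table(cin, (2, 2, 2, 2)),
    "mobilenet_v2": _mobilenet_v2_table,
}


def _table(name: str, in_channels: int):
    if name not in _ARCHS:
        raise ValueError(f"unknown architecture {name!r}; known: {sorted(_ARCHS)}")
    return _ARCHS[name](in_channels)


def count_params(name: str, in_channels: int = 3, include_head: bool = False) -> int:
    """Trainable parameter count; ``include_head=False`` drops the final
    classification layer (the convention reference footprints are quoted in)."""
    body, head = _table(name, in_channels)
    total = sum(getattr(l, "params", 0) for l in body)
    if include_head:
        total += sum(l.params for l in head)
    return int(total)


def _size_at_div(input_size: int, div: int) -> int:
    """Spatial size after ``log2(div)`` ceil-halvings (every stride-2 layer in
    these tables maps s -> ceil(s / 2) given its kernel/padding)."""
    s = input_size
    while div > 1:
        s = (s - 1) // 2 + 1
        div //= 2
    return s


def count_conv_macs(name: str, input_size: int = 224, in_channels: int = 3) -> int:
    """Convolution multiply-accumulates at a square ``input_size`` input."""
    body, _head = _table(name, in_channels)
    total = 0
    for layer in body:
        if isinstance(layer, _Conv):
            total += layer.macs(_size_at_div(input_size, layer.in_div))
    return int(total)


def profile(name: str, in_channels: int = 3, input_size: int = 224) -> dict:
    return {
        "arch": name,
        "in_channels": in_channels,
        "input_size": input_size,
        "params": count_params(name, in_channels),
        "params_M": round(count_params(name, in_channels) / 1e6, 2),
        "macs": count_conv_macs(name, input_size, in_channels),
        "macs_G": round(count_conv_macs(name, input_size, in_channels) / 1e9, 2),
    }
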