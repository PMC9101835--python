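"""Encoder–decoder segmentation backbone with skip connections."""

from __future__ import annotations

import numpy as np

from .core import Conv2d, MaxPool2, Module, Param, ReLU, Sequential, UpNearest2

__all__ = ["ConvBlock", "UNet"]


class ConvBlock(Sequential):
    """conv3×3 → ReLU → conv3×3 → ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__(
            Conv2d(cin, cout, rng=rng), ReLU(),
            Conv2d(cout, cout, rng=rng), ReLU(),
        )


class UNet(Module):
    """U-shaped network returning per-pixel logits.

    ``depth`` pooling stages; channel widths double per stage starting from
    ``base``.  Input spatial size must be divisible by 2**depth.
    """

    def __init__(self, in_ch: int, base: int = 16, depth: int = 4,
                 out_ch: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.depth = depth
        self.enc = []
        ch = in_ch
        for d in range(depth):
            self.enc.append(ConvBlock(ch, base * 2 ** d, rng))
            ch = base * 2 ** d
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = ConvBlock(ch, base * 2 ** depth, rng)
        self.ups = [UpNearest2() for _ in range(depth)]
        self.dec = []
        for d in reversed(range(depth)):
            skip_ch = base * 2 ** d
            up_ch = base * 2 ** (d + 1)
            self.dec.append(ConvBlock(up_ch + skip_ch, skip_ch, rng))
        self.head = Conv2d(base, out_ch, k=1, pad=0, rng=rng)

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for m in [*self.enc, self.bottleneck, *self.dec, self.head]:
            ps.extend(m.params())
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            s = blk.forward(h)
            skips.append(s)
            h = pool.forward(s)
        h = self.bottleneck.forward(h)
        self._skip_ch = [s.shape[1] for s in skips]
        for up, blk, s in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            h = blk.forward(np.concatenate([h, s], axis=1))
        return self.head.forward(h)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.head.backward(gout)
        gskips = []
        for up, blk, sc in zip(reversed(self.ups), reversed(self.dec),
                               self._skip_ch):
            gcat = blk.backward(g)
            gup, gskip = gcat[:, :-sc], gcat[:, -sc:]
            gskips.append(gskip)
            g = up.backward(gup)
        g = self.bottleneck.backward(g)
        # gskips were collected shallow-first; encoder unwinds deep-first
        for blk, pool, gskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(gskips)):
            g = pool.backward(g) + gskip
            g = blk.backward(g)
        return g
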