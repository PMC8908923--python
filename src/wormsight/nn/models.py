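"""Network wiring: U-Net (binary / multi-class), HydraNet, WormNet.

The U-Nets follow the classic encoder-decoder scheme: ``depth`` encoder
stages of (conv3x3-BN-ReLU) x2 with 2x2 max pooling + spatial dropout between
stages and filter counts doubling per stage, a bottleneck block, and a
mirrored decoder built from 2x2 transposed convolutions whose input is
concatenated with the skip tensor of the matching encoder stage.  HydraNet
keeps one shared encoder and attaches an independent full decoder per body
part, each ending in its own 1-channel sigmoid head.  WormNet is a shallow
5-block classifier: (conv3x3-BN-ReLU-maxpool-spatial dropout) x5 followed by
either flatten + fully-connected head or a global-average-pooling head that
supports class activation maps.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm,
    Conv1x1,
    Conv3x3,
    ConvTranspose2x2,
    Dense,
    Flatten,
    GlobalAvgPool,
    MaxPool2x2,
    ReLU,
    Sequential,
    Sigmoid,
    Softmax,
    SpatialDropout,
)

_STATE_ATTRS = ("W", "b", "gamma", "beta", "running_mean", "running_var")


def _conv_block(c_in, c_out, rng, dtype):
    return Sequential([
        Conv3x3(c_in, c_out, rng, dtype), BatchNorm(c_out, dtype=dtype), ReLU(),
        Conv3x3(c_out, c_out, rng, dtype), BatchNorm(c_out, dtype=dtype), ReLU(),
    ])


def _iter_layers(layer):
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _iter_layers(sub)
    else:
        yield layer


class _Model:
    """State (de)serialization shared by the three architectures."""

    def _flat_layers(self):
        out = []
        for layer in self._layer_roots:
            out.extend(_iter_layers(layer))
        return out

    def params_and_grads(self):
        out = []
        for layer in self._layer_roots:
            out.extend(layer.params_and_grads())
        return out

    def state_dict(self):
        state = {}
        for i, layer in enumerate(self._flat_layers()):
            for attr in _STATE_ATTRS:
                if hasattr(layer, attr):
                    state[f"{i}.{attr}"] = getattr(layer, attr)
        return state

    def load_state_dict(self, state):
        for i, layer in enumerate(self._flat_layers()):
            for attr in _STATE_ATTRS:
                if hasattr(layer, attr):
                    getattr(layer, attr)[...] = state[f"{i}.{attr}"]


class _Encoder:
    def __init__(self, c_in, depth, base, dropout, rng, dtype):
        self.depth = depth
        self.blocks = []
        c, f = c_in, base
        for _ in range(depth):
            self.blocks.append(_conv_block(c, f, rng, dtype))
            c, f = f, 2 * f
        self.pools = [MaxPool2x2() for _ in range(depth)]
        self.drops = [SpatialDropout(dropout, rng) for _ in range(depth)]
        self.bottleneck = _conv_block(c, f, rng, dtype)

    def roots(self):
        return [*self.blocks, *self.drops, self.bottleneck]

    def forward(self, x, train):
        skips = []
        for block, pool, drop in zip(self.blocks, self.pools, self.drops):
            x = block.forward(x, train)
            skips.append(x)
            x = drop.forward(pool.forward(x, train), train)
        return self.bottleneck.forward(x, train), skips

    def backward(self, dbott, dskips):
        d = self.bottleneck.backward(dbott)
        for i in reversed(range(self.depth)):
            d = self.pools[i].backward(self.drops[i].backward(d))
            d = self.blocks[i].backward(d + dskips[i])
        return d


class _Decoder:
    def __init__(self, depth, base, out_channels, head, rng, dtype):
        self.depth = depth
        self.base = base
        self.ups = []
        self.blocks = []
        for i in reversed(range(depth)):
            f = base * 2 ** i
            self.ups.append(ConvTranspose2x2(2 * f, f, rng, dtype))
            self.blocks.append(_conv_block(2 * f, f, rng, dtype))
        self.out_conv = Conv1x1(base, out_channels, rng, dtype)
        self.head = Sigmoid() if head == "sigmoid" else Softmax()

    def roots(self):
        return [*self.ups, *self.blocks, self.out_conv]

    def forward(self, x, skips, train):
        for j, i in enumerate(reversed(range(self.depth))):
            x = self.ups[j].forward(x, train)
            x = np.concatenate([skips[i], x], axis=-1)
            x = self.blocks[j].forward(x, train)
        return self.head.forward(self.out_conv.forward(x, train), train)

    def backward(self, dprob):
        d = self.out_conv.backward(self.head.backward(dprob))
        dskips = [None] * self.depth
        for j, i in zip(reversed(range(self.depth)), range(self.depth)):
            f = self.base * 2 ** i
            d = self.blocks[j].backward(d)
            dskips[i] = d[..., :f]
            d = self.ups[j].backward(d[..., f:])
        return d, dskips


class UNetModel(_Model):
    """Single-decoder U-Net with a sigmoid (1 ch) or softmax (n ch) head."""

    def __init__(self, input_size=96, depth=4, base_filters=16, dropout=0.25,
                 out_channels=1, head="sigmoid", seed=0, dtype=np.float32):
        if input_size % (2 ** depth) != 0:
            raise ValueError(
                f"input_size {input_size} not divisible by 2^depth = {2 ** depth}")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.encoder = _Encoder(1, depth, base_filters, dropout, rng, dtype)
        self.decoder = _Decoder(depth, base_filters, out_channels, head, rng, dtype)
        self._layer_roots = [*self.encoder.roots(), *self.decoder.roots()]

    def forward(self, x, train=False):
        bott, self._skips = self.encoder.forward(x, train)
        return self.decoder.forward(bott, self._skips, train)

    def backward(self, dprob):
        dbott, dskips = self.decoder.backward(dprob)
        return self.encoder.backward(dbott, dskips)


class HydraNetModel(_Model):
    """Shared U-Net encoder with one independent sigmoid decoder per head."""

    def __init__(self, head_names, input_size=96, depth=4, base_filters=16,
                 dropout=0.25, seed=0, dtype=np.float32):
        head_names = list(head_names)
        if len(set(head_names)) != len(head_names):
            raise ValueError(f"duplicate head names: {head_names}")
        if input_size % (2 ** depth) != 0:
            raise ValueError(
                f"input_size {input_size} not divisible by 2^depth = {2 ** depth}")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.head_names = head_names
        self.encoder = _Encoder(1, depth, base_filters, dropout, rng, dtype)
        self.decoders = [
            _Decoder(depth, base_filters, 1, "sigmoid", rng, dtype)
            for _ in head_names
        ]
        self._layer_roots = [*self.encoder.roots()]
        for dec in self.decoders:
            self._layer_roots.extend(dec.roots())

    def forward(self, x, train=False):
        bott, skips = self.encoder.forward(x, train)
        maps = [dec.forward(bott, skips, train) for dec in self.decoders]
        return np.concatenate(maps, axis=-1)  # (N, H, W, n_heads)

    def backward(self, dprob):
        dbott_total = None
        dskips_total = None
        for k, dec in enumerate(self.decoders):
            dbott, dskips = dec.backward(np.ascontiguousarray(dprob[..., k : k + 1]))
            if dbott_total is None:
                dbott_total, dskips_total = dbott, list(dskips)
            else:
                dbott_total += dbott
                for i, ds in enumerate(dskips):
                    dskips_total[i] = dskips_total[i] + ds
        return self.encoder.backward(dbott_total, dskips_total)


class WormNetModel(_Model):
    """Shallow 5-block CNN for binary lifespan / motility classification."""

    def __init__(self, input_size=96, filters=(16, 32, 64, 128, 256),
                 dropout=0.25, fc_width=64, head_mode="flatten_fc",
                 n_classes=2, seed=0, dtype=np.float32):
        if input_size % 32 != 0:
            raise ValueError(f"input_size {input_size} not divisible by 2^5 = 32")
        if len(filters) != 5:
            raise ValueError("WormNet uses exactly 5 convolutional blocks")
        if head_mode not in ("flatten_fc", "gap_cam"):
            raise ValueError(f"unknown head_mode: {head_mode}")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.head_mode = head_mode
        self.n_classes = n_classes
        blocks = []
        c = 1
        for i, f in enumerate(filters):
            blocks += [Conv3x3(c, f, rng, dtype), BatchNorm(f, dtype=dtype), ReLU()]
            if head_mode == "flatten_fc" or i < len(filters) - 1:
                blocks += [MaxPool2x2(), SpatialDropout(dropout, rng)]
            else:
                # CAM head: GAP sits directly on the final conv maps (no 5th
                # pool), giving the saliency map a 2x finer grid
                blocks += [SpatialDropout(dropout, rng)]
            c = f
        self.features = Sequential(blocks)
        grid = input_size // 32 if head_mode == "flatten_fc" else input_size // 16
        if head_mode == "flatten_fc":
            self.head = Sequential([
                Flatten(),
                Dense(grid * grid * c, fc_width, rng, dtype), ReLU(),
                Dense(fc_width, n_classes, rng, dtype),
            ])
            self.class_dense = None
        else:
            self.gap = GlobalAvgPool()
            self.class_dense = Dense(c, n_classes, rng, dtype)
            self.head = Sequential([self.gap, self.class_dense])
        self.softmax = Softmax()
        self._layer_roots = [self.features, self.head]

    def forward(self, x, train=False):
        feats = self.features.forward(x, train)
        self.feature_maps_ = feats  # (N, g, g, K); the maps averaged by GAP
        return self.softmax.forward(self.head.forward(feats, train), train)

    def backward(self, dprob):
        d = self.head.backward(self.softmax.backward(dprob))
        return self.features.backward(d)

    @property
    def cam_weights(self):
        """(K, n_classes) dense weights of the GAP head; CAM = sum_k w_kc f_k."""
        if self.class_dense is None:
            raise ValueError(
                "class activation maps need head_mode='gap_cam'; "
                "this model was built with head_mode='flatten_fc'")
        return self.class_dense.W
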