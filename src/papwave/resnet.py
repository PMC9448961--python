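"""1-D residual convolutional network, implemented in numpy.

The architecture mirrors the bottleneck ResNet-50 family adapted to 1-D
signals: a strided stem convolution, four stages of bottleneck residual
blocks (each block = 1x1 -> 3 -> 1x1 convolutions with a shortcut
connection), and a 1x1 pre-head convolution, followed by global average
pooling, dropout and a linear output layer trained with mean-squared
error.  With the canonical stage plan (3, 4, 6, 3) the network contains
exactly 16 residual blocks and 50 convolutional layers
(1 stem + 16 x 3 block convs + 1 pre-head), both verifiable by
introspection.  Shortcut projections are parameter-free (stride
subsampling plus zero channel padding) so they do not alter the
convolution count.

An input sample has shape (n_signals, n_features, n_channels); it is
presented to the network as n_signals * n_channels input planes convolved
along the feature/time axis.

Forward and backward passes are written out explicitly (im2col
convolutions); optimisation is minibatch SGD with momentum, fully
deterministic given the seed.  A reduced profile (one block per stage,
narrow widths) keeps training affordable on a single CPU; the full
16-block network is built the same way and differs only in the stage plan
and widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, ParameterError

FULL_STAGE_PLAN = (3, 4, 6, 3)
REDUCED_STAGE_PLAN = (1, 1, 1, 1)


class Conv1D:
    """Same-padded 1-D convolution (cross-correlation) with stride."""

    def __init__(self, in_ch, out_ch, kernel, stride, rng):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.w = rng.normal(0.0, scale, (out_ch, in_ch * kernel))
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def out_len(self, n):
        return (n + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x):
        b, c, n = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        idx = (np.arange(self.out_len(n)) * self.stride)[:, None] + \
            np.arange(self.kernel)[None, :]
        patches = xp[:, :, idx]                 # (B, C, L_out, K)
        patches = patches.transpose(0, 2, 1, 3).reshape(b, -1, self.in_ch * self.kernel)
        self._cache = (patches, x.shape, idx)
        out = patches @ self.w.T + self.b       # (B, L_out, O)
        return out.transpose(0, 2, 1)

    def backward(self, grad):
        patches, x_shape, idx = self._cache
        b, c, n = x_shape
        g = grad.transpose(0, 2, 1)             # (B, L_out, O)
        self.dw += g.reshape(-1, self.out_ch).T @ patches.reshape(-1, patches.shape[-1])
        self.db += g.sum(axis=(0, 1))
        dpatches = (g @ self.w).reshape(b, -1, self.in_ch, self.kernel)
        dpatches = dpatches.transpose(0, 2, 1, 3)   # (B, C, L_out, K)
        dxp = np.zeros((b, c, n + 2 * self.pad))
        np.add.at(dxp, (slice(None), slice(None), idx), dpatches)
        return dxp[:, :, self.pad:self.pad + n] if self.pad else dxp

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BottleneckBlock:
    """1x1 -> kx1 -> 1x1 convolutions with a parameter-free shortcut."""

    def __init__(self, in_ch, mid_ch, out_ch, stride, rng, kernel=3):
        self.conv1 = Conv1D(in_ch, mid_ch, 1, 1, rng)
        self.conv2 = Conv1D(mid_ch, mid_ch, kernel, stride, rng)
        self.conv3 = Conv1D(mid_ch, out_ch, 1, 1, rng)
        self.relu1, self.relu2, self.relu3 = ReLU(), ReLU(), ReLU()
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride

    def _shortcut(self, x):
        s = x[:, :, ::self.stride] if self.stride > 1 else x
        if self.in_ch < self.out_ch:
            pad = self.out_ch - self.in_ch
            s = np.pad(s, ((0, 0), (0, pad), (0, 0)))
        return s

    def forward(self, x):
        self._x_in = x
        h = self.relu1.forward(self.conv1.forward(x))
        h = self.relu2.forward(self.conv2.forward(h))
        h = self.conv3.forward(h)
        self._short = self._shortcut(x)
        # Strided same-padding can differ by one sample from subsampling.
        n = min(h.shape[2], self._short.shape[2])
        self._n = n
        return self.relu3.forward(h[:, :, :n] + self._short[:, :, :n])

    def backward(self, grad):
        g = self.relu3.backward(grad)
        l3 = self.conv3._cache[1][2]  # conv3 is 1x1/stride-1: out len = in len
        gh = np.zeros((g.shape[0], self.out_ch, l3))
        gh[:, :, :self._n] = g
        dx_main = self.conv1.backward(
            self.relu1.backward(
                self.conv2.backward(
                    self.relu2.backward(self.conv3.backward(gh))
                )
            )
        )
        gs = np.zeros_like(self._short)
        gs[:, :, :self._n] = g
        if self.in_ch < self.out_ch:
            gs = gs[:, :self.in_ch, :]
        dx_short = np.zeros_like(self._x_in)
        dx_short[:, :, ::self.stride] = gs
        return dx_main + dx_short

    def convs(self):
        return [self.conv1, self.conv2, self.conv3]

    def params(self):
        return [p for c in self.convs() for p in c.params()]


class Dense:
    def __init__(self, n_in, n_out, rng):
        self.w = rng.normal(0.0, np.sqrt(1.0 / n_in), (n_out, n_in))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.dw += grad.T @ self._x
        self.db += grad.sum(axis=0)
        return grad @ self.w

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


@dataclass
class ResNetConfig:
    stage_plan: tuple[int, ...] = REDUCED_STAGE_PLAN
    base_width: int = 8
    dropout: float = 0.0
    seed: int = 0


class ResNet1D:
    """Residual 1-D regression network with explicit introspection."""

    def __init__(self, input_shape, output_dim, config: ResNetConfig | None = None):
        n_signals, n_features, n_channels = input_shape
        if min(n_signals, n_features, n_channels) < 1 or output_dim < 1:
            raise ParameterError(
                f"dimensions must be positive, got input_shape={input_shape}, "
                f"output_dim={output_dim}"
            )
        self.input_shape = tuple(input_shape)
        self.output_dim = int(output_dim)
        self.config = config or ResNetConfig()
        rng = np.random.default_rng(self.config.seed)

        in_planes = n_signals * n_channels
        w = self.config.base_width
        self.stem = Conv1D(in_planes, w, 7, 2, rng)
        self.stem_relu = ReLU()
        self.blocks: list[BottleneckBlock] = []
        ch_in = w
        n = self.stem.out_len(n_features)
        for i, n_blocks in enumerate(self.config.stage_plan):
            mid = w * 2 ** i
            out = mid * 2
            for j in range(n_blocks):
                stride = 2 if (j == 0 and i > 0 and n >= 8) else 1
                blk = BottleneckBlock(ch_in, mid, out, stride, rng)
                if stride > 1:
                    n = blk.conv2.out_len(n)
                self.blocks.append(blk)
                ch_in = out
        self.pre_head = Conv1D(ch_in, ch_in, 1, 1, rng)
        self.pre_head_relu = ReLU()
        # Linear readout of the flattened final feature map: a
        # position-aware head, needed because the output is itself a
        # time-resolved window (waveform or coefficient vector).
        self._head_ch, self._head_len = ch_in, n
        self.head = Dense(ch_in * n, self.output_dim, rng)
        self._dropout_rng = np.random.default_rng(self.config.seed + 1)

    # -- introspection ------------------------------------------------------

    def conv_layers(self):
        return [self.stem] + [c for b in self.blocks for c in b.convs()] + \
            [self.pre_head]

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_layers())

    @property
    def n_residual_blocks(self) -> int:
        return len(self.blocks)

    def params(self):
        out = list(self.stem.params())
        for b in self.blocks:
            out.extend(b.params())
        out.extend(self.pre_head.params())
        out.extend(self.head.params())
        return out

    # -- forward / backward -------------------------------------------------

    def _to_planes(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim != 4 or x.shape[1:] != self.input_shape:
            raise InputError(
                f"expected batch of shape (B, {self.input_shape}), got {x.shape}"
            )
        b = x.shape[0]
        # (B, signals, features, channels) -> (B, signals*channels, features)
        return x.transpose(0, 1, 3, 2).reshape(b, -1, self.input_shape[1])

    def forward(self, x, train: bool = False):
        h = self._to_planes(x)
        h = self.stem_relu.forward(self.stem.forward(h))
        for blk in self.blocks:
            h = blk.forward(h)
        h = self.pre_head_relu.forward(self.pre_head.forward(h))
        self._feat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        if train and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            self._drop_mask = (
                self._dropout_rng.random(h.shape) < keep
            ).astype(float) / keep
            h = h * self._drop_mask
        else:
            self._drop_mask = None
        return self.head.forward(h)

    def backward(self, grad):
        g = self.head.backward(grad)
        if self._drop_mask is not None:
            g = g * self._drop_mask
        g = g.reshape(self._feat_shape)
        g = self.pre_head.backward(self.pre_head_relu.backward(g))
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        self.stem.backward(self.stem_relu.backward(g))

    def zero_grad(self):
        for _, grad in self.params():
            grad[:] = 0.0

    def predict(self, x, batch_size: int = 64):
        outs = [self.forward(x[i:i + batch_size])
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs) if outs else np.empty((0, self.output_dim))

    # -- training -----------------------------------------------------------

    def fit(self, x, y, epochs=1, batch_size=8, learning_rate=1e-3,
            momentum=0.9, seed=0, x_val=None, y_val=None):
        """Minibatch SGD on the MSE loss; returns the per-epoch loss log."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) == 0:
            raise InputError("empty training set")
        rng = np.random.default_rng(seed)
        velocity = [np.zeros_like(p) for p, _ in self.params()]
        history = {"epoch": [], "train_loss": [], "val_loss": [], "steps": []}
        for epoch in range(epochs):
            order = rng.permutation(len(x))
            losses, steps = [], 0
            for i in range(0, len(x), batch_size):
                idx = order[i:i + batch_size]
                self.zero_grad()
                pred = self.forward(x[idx], train=True)
                err = pred - y[idx]
                losses.append(float(np.mean(err ** 2)))
                self.backward(2.0 * err / err.size)
                for v, (p, g) in zip(velocity, self.params()):
                    v *= momentum
                    v -= learning_rate * g
                    p += v
                steps += 1
            history["epoch"].append(epoch + 1)
            history["train_loss"].append(float(np.mean(losses)))
            history["steps"].append(steps)
            if x_val is not None and len(x_val):
                vp = self.predict(x_val)
                history["val_loss"].append(float(np.mean((vp - y_val) ** 2)))
            else:
                history["val_loss"].append(np.nan)
        return history


def build_resnet(input_shape, output_dim, full: bool = True,
                 config: ResNetConfig | None = None) -> ResNet1D:
    """Construct the residual network.

    ``full=True`` builds the canonical 16-block / 50-convolution network;
    ``full=False`` the reduced single-block-per-stage profile used for
    affordable CPU training.  An explicit ``config`` overrides both.
    """
    if config is None:
        config = ResNetConfig(
            stage_plan=FULL_STAGE_PLAN if full else REDUCED_STAGE_PLAN
        )
    return ResNet1D(input_shape, output_dim, config)
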