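"""Minimal seeded neural-network primitives (numpy, analytic backprop).

Two small architectures are provided: a fully connected regressor used as
the localization network of the reorientation spatial transformer, and a
2D U-Net used by the nonrigid deformation network.  Everything is plain
numpy with explicit forward caches and hand-derived gradients; all
stochasticity (initialization, data order) flows from a caller-provided
``numpy.random.Generator`` so training is bit-reproducible on one device.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = ["MLP", "UNet2D", "Adam"]


class Adam:
    """Adam optimizer updating a list of parameter arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class MLP:
    """Fully connected ReLU network with a linear output layer."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            self.weights.append(_he(rng, (fan_out, fan_in), fan_in))
            self.biases.append(np.zeros(fan_out))

    def parameters(self) -> list[np.ndarray]:
        out = []
        for w, b in zip(self.weights, self.biases):
            out.extend([w, b])
        return out

    def forward(self, x: np.ndarray):
        acts = [np.asarray(x, float).ravel()]
        n = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = w @ acts[-1] + b
            acts.append(z if i == n - 1 else np.maximum(z, 0.0))
        return acts[-1], acts

    def backward(self, dout: np.ndarray, acts: list[np.ndarray]) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        delta = np.asarray(dout, float)
        n = len(self.weights)
        for i in range(n - 1, -1, -1):
            if i != n - 1:
                delta = delta * (acts[i + 1] > 0)
            grads.insert(0, delta.copy())          # bias grad
            grads.insert(0, np.outer(delta, acts[i]))  # weight grad
            delta = self.weights[i].T @ delta
        return grads

    def save(self, path, extra: dict | None = None) -> None:
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        meta = {"sizes": self.sizes, "extra": extra or {}}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            net = cls.__new__(cls)
            net.sizes = meta["sizes"]
            net.weights = []
            net.biases = []
            i = 0
            while f"w{i}" in z:
                net.weights.append(z[f"w{i}"].copy())
                net.biases.append(z[f"b{i}"].copy())
                i += 1
        return net, meta["extra"]


# ---------------------------------------------------------------------------
# 2D convolutional blocks
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, H, W) -> (H*W, C*k*k) patch matrix with same-padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    c, h, w = x.shape
    # (C, H, W, k, k) -> (H*W, C*k*k), BLAS-friendly
    return np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(h * w, c * k * k)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded kxk convolution; x: (C, H, W), w: (O, C, k, k)."""
    o, c, k, _ = w.shape
    _, h, wd = x.shape
    cols = _im2col(x, k)
    out = (cols @ w.reshape(o, c * k * k).T).T.reshape(o, h, wd) + b[:, None, None]
    return out, (x.shape, cols)


def _conv_backward(gout: np.ndarray, w: np.ndarray, cache):
    x_shape, cols = cache
    o, c, k, _ = w.shape
    h, wd = gout.shape[1:]
    gflat = gout.reshape(o, h * wd)
    gw = (gflat @ cols).reshape(o, c, k, k)
    gb = gout.sum(axis=(1, 2))
    # gradient w.r.t. input: correlate gout with flipped kernels
    gcols = _im2col(gflat.reshape(o, h, wd), k)
    wflip = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    gx = (gcols @ wflip.reshape(c, o * k * k).T).T.reshape(c, h, wd)
    return gx, gw, gb


def _pool2_forward(x: np.ndarray):
    c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    # windows last: (c, h2, w2, 4)
    win = (
        x[:, : h2 * 2, : w2 * 2]
        .reshape(c, h2, 2, w2, 2)
        .transpose(0, 1, 3, 2, 4)
        .reshape(c, h2, w2, 4)
    )
    out = win.max(axis=-1)
    # break ties deterministically: route gradient to the first max per window
    first = np.argmax(win, axis=-1)
    mask = np.zeros_like(win, dtype=bool)
    np.put_along_axis(mask, first[..., None], True, axis=-1)
    return out, (x.shape, mask)


def _pool2_backward(gout: np.ndarray, cache):
    x_shape, mask = cache
    c, h, w = x_shape
    h2, w2 = h // 2, w // 2
    gx = np.zeros(x_shape)
    expanded = mask * gout[..., None]  # (c, h2, w2, 4)
    gx[:, : h2 * 2, : w2 * 2] = (
        expanded.reshape(c, h2, w2, 2, 2)
        .transpose(0, 1, 3, 2, 4)
        .reshape(c, h2 * 2, w2 * 2)
    )
    return gx


def _upsample2_to(x: np.ndarray, target_hw):
    """Nearest-neighbor x2 upsample, then crop/pad to the skip's spatial size."""
    up = np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)
    th, tw = target_hw
    c, h, w = up.shape
    out = np.zeros((c, th, tw))
    out[:, : min(h, th), : min(w, tw)] = up[:, : min(h, th), : min(w, tw)]
    return out, (x.shape, (th, tw))


def _upsample2_back(gout: np.ndarray, cache):
    x_shape, (th, tw) = cache
    c, h, w = x_shape
    gup = np.zeros((c, h * 2, w * 2))
    gup[:, : min(h * 2, th), : min(w * 2, tw)] = gout[:, : min(h * 2, th), : min(w * 2, tw)]
    return gup.reshape(c, h, 2, w, 2).sum(axis=(2, 4))


class UNet2D:
    """Small encoder-decoder with skip connections predicting a dense field.

    ``depth`` down/up steps; widths double per level.  The final convolution
    is zero-initialized so the network starts from the identity deformation.
    """

    def __init__(self, in_channels: int, out_channels: int, base_width: int,
                 depth: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.base_width = base_width
        self.depth = depth
        self._params: list[np.ndarray] = []
        self._layers: list[tuple[int, int]] = []  # (w_index, layer kind marker)

        def add_conv(cin, cout, zero=False):
            if zero:
                w = np.zeros((cout, cin, 3, 3))
            else:
                w = _he(rng, (cout, cin, 3, 3), cin * 9)
            b = np.zeros(cout)
            self._params.extend([w, b])
            return len(self._params) - 2

        self.enc_convs = []
        cin = in_channels
        width = base_width
        for _d in range(depth):
            self.enc_convs.append((add_conv(cin, width), add_conv(width, width)))
            cin = width
            width *= 2
        self.mid_convs = (add_conv(cin, width), add_conv(width, width))
        self.dec_convs = []
        cup = width
        for _d in range(depth):
            width //= 2
            self.dec_convs.append((add_conv(cup + width, width), add_conv(width, width)))
            cup = width
        self.final_conv = add_conv(width, out_channels, zero=True)

    def parameters(self) -> list[np.ndarray]:
        return self._params

    def _w(self, idx):
        return self._params[idx], self._params[idx + 1]

    def forward(self, x: np.ndarray):
        x = np.asarray(x, float)
        cache = {"relu": [], "conv": [], "pool": [], "up": [], "skips": []}
        h = x
        skips = []
        for c1, c2 in self.enc_convs:
            for ci in (c1, c2):
                w, b = self._w(ci)
                h, cc = _conv_forward(h, w, b)
                cache["conv"].append(cc)
                cache["relu"].append(h > 0)
                h = np.maximum(h, 0.0)
            skips.append(h)
            h, pc = _pool2_forward(h)
            cache["pool"].append(pc)
        for ci in self.mid_convs:
            w, b = self._w(ci)
            h, cc = _conv_forward(h, w, b)
            cache["conv"].append(cc)
            cache["relu"].append(h > 0)
            h = np.maximum(h, 0.0)
        for (c1, c2), skip in zip(self.dec_convs, reversed(skips)):
            h, uc = _upsample2_to(h, skip.shape[1:])
            cache["up"].append(uc)
            cache["skips"].append(skip.shape[0])
            h = np.concatenate([h, skip], axis=0)
            for ci in (c1, c2):
                w, b = self._w(ci)
                h, cc = _conv_forward(h, w, b)
                cache["conv"].append(cc)
                cache["relu"].append(h > 0)
                h = np.maximum(h, 0.0)
        w, b = self._w(self.final_conv)
        out, cc = _conv_forward(h, w, b)
        cache["conv"].append(cc)
        return out, cache

    def backward(self, gout: np.ndarray, cache) -> list[np.ndarray]:
        grads = [np.zeros_like(p) for p in self._params]
        conv_caches = list(cache["conv"])
        relu_masks = list(cache["relu"])

        def back_conv(g, ci):
            w, _b = self._w(ci)
            gx, gw, gb = _conv_backward(g, w, conv_caches.pop())
            grads[ci] += gw
            grads[ci + 1] += gb
            return gx

        g = back_conv(np.asarray(gout, float), self.final_conv)
        skip_grads = []
        for (c1, c2), up_cache in zip(reversed(self.dec_convs), reversed(cache["up"])):
            for ci in (c2, c1):
                g = g * relu_masks.pop()
                g = back_conv(g, ci)
            # split concatenated gradient: first channels came from the upsample
            n_up = cache["up"][len(cache["up"]) - 1 - len(skip_grads)][0][0]
            g_up = g[:n_up]
            g_skip = g[n_up:]
            skip_grads.append(g_skip)
            g = _upsample2_back(g_up, up_cache)
        for ci in reversed(self.mid_convs):
            g = g * relu_masks.pop()
            g = back_conv(g, ci)
        # skip_grads were collected shallowest-first; the encoder unwinds
        # deepest-first
        for (c1, c2), pool_cache, g_skip in zip(
            reversed(self.enc_convs), reversed(cache["pool"]), reversed(skip_grads)
        ):
            g = _pool2_backward(g, pool_cache)
            g = g + g_skip
            for ci in (c2, c1):
                g = g * relu_masks.pop()
                g = back_conv(g, ci)
        return grads

    def save(self, path, extra: dict | None = None) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self._params)}
        meta = {
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "base_width": self.base_width,
            "depth": self.depth,
            "extra": extra or {},
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            net = cls(
                meta["in_channels"], meta["out_channels"], meta["base_width"],
                meta["depth"], np.random.default_rng(0),
            )
            for i in range(len(net._params)):
                net._params[i][...] = z[f"p{i}"]
        return net, meta["extra"]
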