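"""A small numpy neural-network engine for 3-D convolutional classifiers.

Layers keep their forward caches and implement explicit backward passes, so
training is plain reverse-mode differentiation without an external framework.
Everything is float64 and seeded, which buys bit-level reproducibility of
training runs on CPU — a property the test suite leans on.

Conventions: activations are (N, C, D, H, W); convolution weights are
(out_ch, in_ch, kd, kh, kw); models end in a sigmoid and return per-sample
probabilities of shape (N,).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "vel")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.vel = np.zeros_like(value)


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3-D convolution via sliding windows + einsum."""

    def __init__(self, in_ch: int, out_ch: int, kernel, stride=(1, 1, 1),
                 padding=None, bias: bool = True, *, rng: np.random.Generator):
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        # default padding keeps "same" size at stride 1 for odd kernels
        self.padding = tuple(k // 2 for k in self.kernel) if padding is None else tuple(padding)
        fan_in = in_ch * int(np.prod(self.kernel))
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.w = Param(rng.normal(0.0, scale, size=(out_ch, in_ch, *self.kernel)))
        self.b = Param(np.zeros(out_ch)) if bias else None
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pd_, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pd_, pd_), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        sd, sh, sw = self.stride
        win = win[:, :, ::sd, ::sh, ::sw, :, :, :]
        out = np.einsum("ncdhwijk,ocijk->nodhw", win, self.w.value, optimize=True)
        if self.b is not None:
            out += self.b.value[None, :, None, None, None]
        if train:
            self._cache = (xp.shape, win, out.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp_shape, win, _ = self._cache
        self.w.grad += np.einsum("nodhw,ncdhwijk->ocijk", grad, win, optimize=True)
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        sd, sh, sw = self.stride
        kd, kh, kw = self.kernel
        _, _, do, ho, wo = grad.shape
        gxp = np.zeros(xp_shape)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    contrib = np.einsum("nodhw,oc->ncdhw", grad,
                                        self.w.value[:, :, i, j, k], optimize=True)
                    gxp[:, :, i:i + sd * do:sd, j:j + sh * ho:sh, k:k + sw * wo:sw] += contrib
        pd_, ph, pw = self.padding
        n, c, d, h, w = xp_shape
        return gxp[:, :, pd_:d - pd_ or None, ph:h - ph or None, pw:w - pw or None]


class BatchNorm3d(Layer):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None, None]) / std[None, :, None, None, None]
        if train:
            self._cache = (xhat, std)
        return self.gamma.value[None, :, None, None, None] * xhat \
            + self.beta.value[None, :, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        axes = (0, 2, 3, 4)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value[None, :, None, None, None]
        s1 = dxhat.sum(axis=axes)[None, :, None, None, None]
        s2 = (dxhat * xhat).sum(axis=axes)[None, :, None, None, None]
        return (dxhat - s1 / m - xhat * s2 / m) / std[None, :, None, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool3d(Layer):
    """Non-overlapping max pooling (kernel == stride); dims must divide."""

    def __init__(self, kernel):
        self.kernel = tuple(kernel)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        kd, kh, kw = self.kernel
        if d % kd or h % kh or w % kw:
            raise ValueError(
                f"input dims {(d, h, w)} not divisible by pooling kernel {self.kernel}; "
                "pick an input size or pooling layout that divides evenly")
        windows = (x.reshape(n, c, d // kd, kd, h // kh, kh, w // kw, kw)
                   .transpose(0, 1, 2, 4, 6, 3, 5, 7)
                   .reshape(n, c, d // kd, h // kh, w // kw, kd * kh * kw))
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, idx)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, idx = self._cache
        n, c, d, h, w = x_shape
        kd, kh, kw = self.kernel
        gw = np.zeros((n, c, d // kd, h // kh, w // kw, kd * kh * kw))
        np.put_along_axis(gw, idx[..., None], grad[..., None], axis=-1)
        return (gw.reshape(n, c, d // kd, h // kh, w // kw, kd, kh, kw)
                .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                .reshape(x_shape))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None, None], self._shape) / (d * h * w)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.w = Param(rng.normal(0.0, scale, size=(in_features, out_features)))
        self.b = Param(np.zeros(out_features))

    def parameters(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class BasicBlock3d(Layer):
    """Residual basic block: conv-BN-ReLU-conv-BN plus (projected) identity."""

    def __init__(self, in_ch: int, out_ch: int, stride=(1, 1, 1), *,
                 rng: np.random.Generator):
        self.conv1 = Conv3d(in_ch, out_ch, (3, 3, 3), stride=stride, rng=rng, bias=False)
        self.bn1 = BatchNorm3d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_ch, out_ch, (3, 3, 3), rng=rng, bias=False)
        self.bn2 = BatchNorm3d(out_ch)
        self.relu2 = ReLU()
        if in_ch != out_ch or stride != (1, 1, 1):
            self.proj_conv = Conv3d(in_ch, out_ch, (1, 1, 1), stride=stride,
                                    padding=(0, 0, 0), rng=rng, bias=False)
            self.proj_bn = BatchNorm3d(out_ch)
        else:
            self.proj_conv = None
            self.proj_bn = None

    def parameters(self) -> list[Param]:
        ps = (self.conv1.parameters() + self.bn1.parameters()
              + self.conv2.parameters() + self.bn2.parameters())
        if self.proj_conv is not None:
            ps += self.proj_conv.parameters() + self.proj_bn.parameters()
        return ps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.proj_conv is not None:
            shortcut = self.proj_bn.forward(self.proj_conv.forward(x, train), train)
        else:
            shortcut = x
        return self.relu2.forward(out + shortcut, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(grad)
        g_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(g)))))
        if self.proj_conv is not None:
            g_short = self.proj_conv.backward(self.proj_bn.backward(g))
        else:
            g_short = g
        return g_main + g_short


class Network:
    """A feed-forward stack of layers ending in a probability output."""

    def __init__(self, layers: list[Layer], name: str):
        self.layers = layers
        self.name = name

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x.reshape(-1)  # (N, 1) -> (N,)

    def backward(self, grad_p: np.ndarray) -> None:
        g = grad_p.reshape(-1, 1)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        vals = [p.value.copy() for p in self.parameters()]
        for layer in self._bn_layers():
            vals.append(layer.running_mean.copy())
            vals.append(layer.running_var.copy())
        return vals

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        rest = state[len(params):]
        for i, layer in enumerate(self._bn_layers()):
            layer.running_mean[...] = rest[2 * i]
            layer.running_var[...] = rest[2 * i + 1]

    def _bn_layers(self) -> list[BatchNorm3d]:
        found: list[BatchNorm3d] = []

        def visit(layer):
            if isinstance(layer, BatchNorm3d):
                found.append(layer)
            elif isinstance(layer, BasicBlock3d):
                visit(layer.bn1)
                visit(layer.bn2)
                if layer.proj_bn is not None:
                    visit(layer.proj_bn)

        for layer in self.layers:
            visit(layer)
        return found


class SGD:
    """SGD with Nesterov momentum and (decoupled-from-nothing) L2 weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, nesterov: bool = True):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.nesterov = nesterov

    def step(self) -> None:
        for p in self.params:
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            p.vel[...] = self.momentum * p.vel + g
            if self.nesterov:
                p.value -= self.lr * (g + self.momentum * p.vel)
            else:
                p.value -= self.lr * p.vel


def tiny3d(in_shape: tuple[int, int, int], seed: int = 0) -> Network:
    """Two-stage 3-D CNN for desk-scale experiments (input H×W×D, 1 channel)."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [
        Conv3d(1, 8, (3, 3, 3), stride=(1, 2, 2), rng=rng),
        BatchNorm3d(8), ReLU(),
        Conv3d(8, 16, (3, 3, 3), stride=(1, 2, 2), rng=rng),
        BatchNorm3d(16), ReLU(),
        GlobalAvgPool(),
        Linear(16, 1, rng=rng),
        Sigmoid(),
    ]
    return Network(layers, "tiny3d")


def resnet34_3d(in_shape: tuple[int, int, int], seed: int = 0) -> Network:
    """3-D ResNet-34: basic-block stages (3, 4, 6, 3), sigmoid head.

    The stem uses a (3, 7, 7) kernel with depth stride 1 and the residual
    stages downsample only in-plane — at a 5-slice depth there is no room for
    depth striding, so the depth axis collapses only at the global pool.
    """
    h, w, d = in_shape
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [
        Conv3d(1, 64, (3, 7, 7), stride=(1, 2, 2), padding=(1, 3, 3), rng=rng, bias=False),
        BatchNorm3d(64), ReLU(),
        MaxPool3d((1, 2, 2)),
    ]
    stages = [(64, 3, (1, 1, 1)), (128, 4, (1, 2, 2)),
              (256, 6, (1, 2, 2)), (512, 3, (1, 2, 2))]
    in_ch = 64
    for out_ch, n_blocks, first_stride in stages:
        for b in range(n_blocks):
            stride = first_stride if b == 0 else (1, 1, 1)
            layers.append(BasicBlock3d(in_ch, out_ch, stride=stride, rng=rng))
            in_ch = out_ch
    layers += [GlobalAvgPool(), Linear(512, 1, rng=rng), Sigmoid()]
    net = Network(layers, "resnet34_3d")
    # fail fast on pooling-incompatible inputs before any training time is spent
    if (h // 2) % 2 or (w // 2) % 2:
        raise ValueError(
            f"in-plane size {h}x{w} is incompatible with the stem stride and pool; "
            "use dimensions divisible by 4 (e.g. 240x240, 64x64)")
    return net
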