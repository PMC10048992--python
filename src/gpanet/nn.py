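"""Layers, parameter containers and the SGD/cosine-annealing optimizer."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, conv2d

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "SiLU",
    "ReLU",
    "Identity",
    "SGD",
    "cosine_annealing_lr",
    "calibrate_batchnorm",
    "count_parameters",
]


class Module:
    """Tiny module base: parameter discovery, train/eval flag, state dict."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_state(self, prefix=""):
        """All persistent arrays (parameters and buffers), flattened."""
        out = {}
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.named_state(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_state(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item.data
        return out

    def load_state(self, state, prefix=""):
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor) and key in state:
                v.data = np.asarray(state[key], dtype=np.float32)
            elif isinstance(v, np.ndarray) and key in state:
                self.__dict__[k] = np.asarray(state[key])
            elif isinstance(v, Module):
                v.load_state(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state(state, prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and f"{key}.{i}" in state:
                        item.data = np.asarray(state[f"{key}.{i}"], dtype=np.float32)

    def train(self, mode=True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=None, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if pad is None:
            pad = kernel // 2
        self.stride, self.pad = stride, pad
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, in_dim, out_dim, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_kaiming(rng, (in_dim, out_dim), in_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Inference statistics are bias-corrected exponential moving averages of the
    batch statistics, so they are well calibrated even after very few
    training steps (the toy budgets train for tens of batches, not thousands).
    """

    def __init__(self, num_ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(num_ch, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_ch, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_ch, dtype=np.float32)
        self.running_var = np.zeros(num_ch, dtype=np.float32)
        self.num_updates = np.zeros(1, dtype=np.float64)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            if getattr(self, "_calibrating", False):
                self._acc_mean = self._acc_mean + mu.data.ravel().astype(np.float64)
                self._acc_sq = self._acc_sq + np.square(mu.data.ravel().astype(np.float64))
                self._acc_var = self._acc_var + var.data.ravel().astype(np.float64)
                self._acc_n += 1
            else:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mu.data.ravel()).astype(np.float32)
                self.running_var = ((1 - m) * self.running_var + m * var.data.ravel()).astype(np.float32)
                self.num_updates = self.num_updates + 1
        else:
            t = float(self.num_updates[0])
            if t == 0:
                mu = Tensor(np.zeros((1, len(self.running_mean), 1, 1), np.float32))
                var = Tensor(np.ones((1, len(self.running_var), 1, 1), np.float32))
            else:
                corr = 1.0 - (1.0 - self.momentum) ** t
                mu = Tensor((self.running_mean / corr).reshape(1, -1, 1, 1).astype(np.float32))
                var = Tensor((self.running_var / corr).reshape(1, -1, 1, 1).astype(np.float32))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Identity(Module):
    def forward(self, x):
        return x


class SGD:
    """SGD with momentum and optional weight decay."""

    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0, clip_norm=None):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        scale = 1.0
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((p.grad ** 2).sum()) for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v


def _collect_batchnorms(module: Module):
    bns = []
    stack = [module]
    while stack:
        m = stack.pop()
        if isinstance(m, BatchNorm2d):
            bns.append(m)
        for v in vars(m).values():
            if isinstance(v, Module):
                stack.append(v)
            elif isinstance(v, (list, tuple)):
                stack.extend(x for x in v if isinstance(x, Module))
    return bns


def calibrate_batchnorm(module: Module, forward_fn, batches) -> None:
    """Precise-BN: replace EMA statistics with exact per-channel statistics
    computed by running ``forward_fn`` over ``batches`` (equal-weighted)."""
    from .autograd import no_grad

    bns = _collect_batchnorms(module)
    for bn in bns:
        bn._calibrating = True
        bn._acc_mean = np.zeros_like(bn.running_mean, dtype=np.float64)
        bn._acc_sq = np.zeros_like(bn.running_mean, dtype=np.float64)
        bn._acc_var = np.zeros_like(bn.running_var, dtype=np.float64)
        bn._acc_n = 0
    was_training = module.training
    module.train()
    with no_grad():
        for batch in batches:
            forward_fn(batch)
    for bn in bns:
        if bn._acc_n:
            n = bn._acc_n
            mean = bn._acc_mean / n
            # total variance = mean within-batch variance + between-batch
            # variance of the means
            var = bn._acc_var / n + np.maximum(bn._acc_sq / n - mean**2, 0.0)
            bn.running_mean = mean.astype(np.float32)
            bn.running_var = var.astype(np.float32)
            bn.num_updates = np.array([1e12])  # bias correction becomes a no-op
        bn._calibrating = False
    module.train(was_training)


def cosine_annealing_lr(base_lr: float, epoch: int, period: int, min_lr: float = 0.0) -> float:
    """Cosine-annealed learning rate, restarting every ``period`` epochs."""
    t = epoch % period
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + math.cos(math.pi * t / period))


def count_parameters(module: Module) -> int:
    """Number of learnable scalars in a module tree."""
    return sum(p.data.size for p in module.parameters())
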