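"""Minimal neural-network layers and an Adam optimizer on the autodiff core.

Initialisation is always driven by an explicit :class:`numpy.random.Generator`
so that every model in the package is a pure function of its seed.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from ._autodiff import Tensor

__all__ = ["Module", "Parameter", "Linear", "Conv2d", "Sequential", "Adam"]


class Parameter(Tensor):
    """A leaf tensor that is updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters track grads even under no_grad


class Module:
    training: bool = True

    def train(self, mode: bool = True):
        self.training = mode
        for value in vars(self).values():
            for mod in _submodules(value):
                mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def parameters(self):
        params = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def named_parameters(self, prefix: str = ""):
        out = OrderedDict()
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item
        return out

    def named_buffers(self, prefix: str = ""):
        out = OrderedDict()
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Module):
                for bname in getattr(value, "_buffer_attrs", ()):
                    out[f"{key}.{bname}"] = getattr(value, bname)
                out.update(value.named_buffers(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for bname in getattr(item, "_buffer_attrs", ()):
                            out[f"{key}.{i}.{bname}"] = getattr(item, bname)
                        out.update(item.named_buffers(prefix=f"{key}.{i}."))
        for bname in getattr(self, "_buffer_attrs", ()) if prefix == "" else ():
            out[bname] = getattr(self, bname)
        return out

    def state_dict(self):
        out = OrderedDict(
            (k, v.data.copy()) for k, v in self.named_parameters().items()
        )
        for k, v in self.named_buffers().items():
            out[f"buffer::{k}"] = v.copy()
        return out

    def load_state_dict(self, state):
        params = self.named_parameters()
        buffers = self.named_buffers()
        missing = set(params) - {k for k in state if not k.startswith("buffer::")}
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for k, buf in buffers.items():
            key = f"buffer::{k}"
            if key in state:
                buf[...] = np.asarray(state[key], dtype=np.float64)

    def modules(self):
        """All modules in the tree, depth-first, including self."""
        yield self
        for value in vars(self).values():
            for sub in _submodules(value):
                yield from sub.modules()

    def astype(self, dtype):
        """Cast all parameters and buffers in place (e.g. to float32)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for bname in getattr(m, "_buffer_attrs", ()):
                setattr(m, bname, getattr(m, bname).astype(dtype))
        return self

    def dtype(self):
        params = self.parameters()
        return params[0].data.dtype if params else np.float64

    def freeze(self):
        """Stop gradient updates and switch to evaluation semantics, so
        neither parameters nor running statistics change afterwards."""
        for p in self.parameters():
            p.requires_grad = False
        self.eval()

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value):
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for item in value:
            out.extend(_collect(item))
        return out
    return []


def _submodules(value):
    if isinstance(value, Module):
        yield value
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _submodules(item)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias=True):
        self.weight = Parameter(he_normal(rng, (d_in, d_out), d_in))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel_size,
        rng: np.random.Generator,
        stride: int = 1,
        padding=None,
        bias=True,
    ):
        kh, kw = (
            (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        )
        fan_in = c_in * kh * kw
        self.weight = Parameter(he_normal(rng, (c_out, c_in, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride = stride
        # default: 'same' padding for odd kernels at stride 1
        self.padding = (kh // 2, kw // 2) if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm(Module):
    """Batch normalisation over the batch (and spatial, for 2d) axes.

    Training mode normalises with batch statistics and maintains running
    estimates (momentum 0.1); evaluation mode uses the running estimates,
    making inference deterministic and batch-independent.
    """

    _buffer_attrs = ("running_mean", "running_var")

    def __init__(self, num_features: int, spatial: bool, eps: float = 1e-5,
                 momentum: float = 0.1):
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps = eps
        self.momentum = momentum
        self.spatial = spatial

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3) if self.spatial else (0,)
        shape = (1, -1, 1, 1) if self.spatial else (1, -1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xhat = centred / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var + self.eps).reshape(shape)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class BatchNorm2d(BatchNorm):
    def __init__(self, num_features: int, **kw):
        super().__init__(num_features, spatial=True, **kw)


class BatchNorm1d(BatchNorm):
    def __init__(self, num_features: int, **kw):
        super().__init__(num_features, spatial=False, **kw)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    grads = [p.grad for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((g * g).sum()) for g in grads))) if grads else 0.0
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale
    return total


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to grads."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = [p for p in params if isinstance(p, Tensor)]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None or not p.requires_grad:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state):
        self.t = state["t"]
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]
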