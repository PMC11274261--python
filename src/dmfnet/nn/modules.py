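"""Layer modules over the autodiff primitives.

Modules own named parameters (Tensor with requires_grad=True) and optional
buffers (plain arrays, e.g. batch-norm running statistics).  Parameter
initialisation is Kaiming-style for convolutions and linear layers; batch-norm
starts at gamma=1, beta=0.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        super().__setattr__(name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for child in self._children.values():
            yield from child.parameters()

    def named_parameters(self, prefix=""):
        for k, p in self._params.items():
            yield (f"{prefix}{k}", p)
        for name, child in self._children.items():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def named_buffers(self, prefix=""):
        for k, b in self._buffers.items():
            yield (f"{prefix}{k}", b)
        for name, child in self._children.items():
            yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = value.copy()
            else:
                self._set_buffer(name, value.copy())

    def _set_buffer(self, dotted: str, value: np.ndarray):
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj._children[part]
        obj._buffers[parts[-1]] = value
        object.__setattr__(obj, parts[-1], value)

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.stride, self.padding = stride, padding
        self.weight = _kaiming(rng, (out_ch, in_ch, kh, kw), in_ch * kh * kw)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features, out_features, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = _kaiming(rng, (in_features, out_features), in_features)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return ag.add(ag.matmul(x, self.weight), self.bias)


class BatchNorm2d(Module):
    """Batch normalisation with explicit backward for the training path."""

    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(num_features, dtype=np.float32)
        self._buffers["running_var"] = np.ones(num_features, dtype=np.float32)

    def forward(self, x):
        x = ag.as_tensor(x)
        gamma, beta = self.gamma, self.beta
        if self.training:
            axes = (0, 2, 3)
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            self._buffers["running_mean"] = ((1 - self.momentum) * self._buffers["running_mean"]
                                             + self.momentum * mean)
            # unbiased variance for the running estimate
            unbiased = var * m / max(m - 1, 1)
            self._buffers["running_var"] = ((1 - self.momentum) * self._buffers["running_var"]
                                            + self.momentum * unbiased)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
            out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

            def backward(g):
                gsum = g.sum(axis=axes)
                gx = (g * xhat).sum(axis=axes)
                if gamma.requires_grad:
                    gamma._accum(gx)
                if beta.requires_grad:
                    beta._accum(gsum)
                if x.requires_grad:
                    coef = gamma.data * inv_std
                    dx = coef[None, :, None, None] * (
                        g - (gsum / m)[None, :, None, None]
                        - xhat * (gx / m)[None, :, None, None])
                    x._accum(dx)

            return ag._make(out.astype(x.data.dtype), (x, gamma, beta), backward)
        # evaluation: affine transform with frozen statistics
        inv_std = 1.0 / np.sqrt(self._buffers["running_var"] + self.eps)
        scale = (gamma.data * inv_std)[None, :, None, None]
        shift = (beta.data - gamma.data * self._buffers["running_mean"] * inv_std)[None, :, None, None]

        def backward_eval(g):
            if gamma.requires_grad:
                xhat = ((x.data - self._buffers["running_mean"][None, :, None, None])
                        * inv_std[None, :, None, None])
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accum(g * scale)

        out = x.data * scale + shift
        return ag._make(out.astype(x.data.dtype), (x, gamma, beta), backward_eval)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)
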