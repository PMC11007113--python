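"""Neural-network modules on top of the autograd engine.

Initialization is explicit: every module takes a ``numpy.random.Generator``
so model construction is a pure function of the seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, conv2d, embedding, max_pool2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)
        self.requires_grad = True  # Parameters record gradients even if created under no_grad


class Module:
    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self._children():
            yield from child.modules()

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    out.append(v)
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, v in self.__dict__.items():
            qual = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out.append((qual, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=qual + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{qual}.{i}."))
        return out

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bnstats{i}.mean"] = m.running_mean.copy()
                state[f"__bnstats{i}.var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"__bnstats{i}.mean"].copy()
                m.running_var = state[f"__bnstats{i}.var"].copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.standard_normal((in_features, out_features)) * scale)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """2-D convolution; ``groups`` splits channels into independent groups."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int | tuple[int, int],
                 rng: np.random.Generator, stride: int | tuple[int, int] = 1,
                 padding: int | tuple[int, int] | None = None,
                 groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if in_ch % groups or out_ch % groups:
            raise ValueError(f"channels ({in_ch}->{out_ch}) not divisible by groups={groups}")
        self.stride = (stride, stride) if isinstance(stride, int) else stride
        if padding is None:
            padding = (kh // 2, kw // 2)  # "same" for odd kernels at stride 1
        self.padding = (padding, padding) if isinstance(padding, int) else padding
        self.groups = groups
        fan_in = in_ch // groups * kh * kw
        self.weight = Parameter(
            rng.standard_normal((out_ch, in_ch // groups, kh, kw)) * np.sqrt(2.0 / fan_in)
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.groups == 1:
            return conv2d(x, self.weight, self.bias, self.stride, self.padding)
        from .autograd import concat
        cin = x.shape[1] // self.groups
        cout = self.weight.shape[0] // self.groups
        outs = []
        for g in range(self.groups):
            xg = x[:, g * cin:(g + 1) * cin]
            wg = self.weight[g * cout:(g + 1) * cout]
            bg = self.bias[g * cout:(g + 1) * cout] if self.bias is not None else None
            outs.append(conv2d(xg, wg, bg, self.stride, self.padding))
        return concat(outs, axis=1)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel = (kernel, kernel)
        self.stride = (stride, stride)
        self.padding = (padding, padding)

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class GlobalAvgPool2d(Module):
    """(B,C,H,W) -> (B,C): mean over the spatial grid."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        from .autograd import batchnorm2d
        if self.training:
            out, mu, var = batchnorm2d(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        out, _, _ = batchnorm2d(x, self.gamma, self.beta, self.eps,
                                self.running_mean, self.running_var)
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) * (x - mu)).mean(axis=-1, keepdims=True)
        return self.gamma * ((x - mu) * ((var + self.eps) ** -0.5)) + self.beta


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.standard_normal((n_tokens, dim)) * 0.02)

    def forward(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)
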