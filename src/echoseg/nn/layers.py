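"""Layer/module system on top of the autodiff core.

Modules hold named parameters (trainable tensors) and buffers (running
statistics); ``state_dict``/``load_state_dict`` use flat ``dot.separated``
names so checkpoints are plain name→array mappings.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, relu

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ConvBlock", "Sequential"]


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    # -- registration ------------------------------------------------------
    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def add_param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def add_buffer(self, name: str, array: np.ndarray) -> np.ndarray:
        self._buffers[name] = np.asarray(array, dtype=np.float32)
        return self._buffers[name]

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, mod in self._modules.items():
            out.update(mod.named_parameters(prefix + name + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def num_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._buffers.items()}
        for name, mod in self._modules.items():
            out.update(mod.named_buffers(prefix + name + "."))
        return out

    def modules(self):
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- serialization -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        state.update({k: v.copy() for k, v in self.named_buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = (set(params) | set(self.named_buffers())) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]} ...")
        for k, t in params.items():
            if t.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = np.ascontiguousarray(state[k], dtype=np.float32)
        self._load_buffers(state, "")

    def _load_buffers(self, state, prefix):
        for k in self._buffers:
            self._buffers[k][...] = state[prefix + k]
        for name, mod in self._modules.items():
            mod._load_buffers(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Conv with He-normal init; optional bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None, bias: bool = True, zero_init: bool = False):
        super().__init__()
        self.padding = (kernel // 2) if padding is None else padding
        fan_in = in_ch * kernel * kernel
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel, kernel), dtype=np.float32)
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        self.weight = self.add_param("weight", w.astype(np.float32))
        self.bias = self.add_param("bias", np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by batch statistics (biased variance) and
    updates the running estimates with momentum 0.1; eval mode uses the
    running estimates.  Backward follows the standard closed form.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.add_param("gamma", np.ones(channels, dtype=np.float32))
        self.beta = self.add_param("beta", np.zeros(channels, dtype=np.float32))
        self.add_buffer("running_mean", np.zeros(channels))
        self.add_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        # channels-last input (B, H, W, C): per-channel stats broadcast naturally
        gamma, beta = self.gamma, self.beta
        if self.training:
            mu = x.data.mean(axis=(0, 1, 2))
            var = x.data.var(axis=(0, 1, 2))
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm *= 1.0 - self.momentum
            rm += self.momentum * mu
            rv *= 1.0 - self.momentum
            rv += self.momentum * var
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        ivstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x.data - mu) * ivstd
        out = gamma.data * xhat + beta.data
        n = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
        training = self.training

        def bwd(g):
            dgamma = (g * xhat).sum(axis=(0, 1, 2))
            dbeta = g.sum(axis=(0, 1, 2))
            gi = gamma.data * ivstd
            if training:
                dx = gi / n * (n * g - dbeta - xhat * dgamma)
            else:
                dx = gi * g
            return dx, dgamma, dbeta

        return Tensor(out, parents=(x, gamma, beta), backward=bwd)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.items = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x


class ConvBlock(Module):
    """Two 3×3 conv + BN + ReLU stages (the standard nested-U-Net node body)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, bias=False)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, bias=False)
        self.bn2 = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = relu(self.bn1(self.conv1(x)))
        return relu(self.bn2(self.conv2(x)))
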