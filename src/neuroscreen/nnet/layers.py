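"""Layers: dense, 1-D convolution, batch norm, dropout, containers."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Module:
    """Base class: parameter discovery, train/eval mode, state export."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(Tensor.as_tensor(x))

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for mod in self.modules():
            for value in vars(mod).values():
                if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
        return params

    def named_state(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters and buffers."""
        state: dict[str, np.ndarray] = {}
        self._collect_state(state, prefix="")
        return state

    def _collect_state(self, state: dict[str, np.ndarray], prefix: str) -> None:
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                state[f"{prefix}{name}"] = value.data
            elif isinstance(value, np.ndarray):
                state[f"{prefix}{name}"] = value
            elif isinstance(value, Module):
                value._collect_state(state, prefix=f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item._collect_state(state, prefix=f"{prefix}{name}.{i}.")

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                value.data = np.array(state[f"{prefix}{name}"], dtype=np.float64)
            elif isinstance(value, np.ndarray):
                setattr(self, name, np.array(state[f"{prefix}{name}"]))
            elif isinstance(value, Module):
                value.load_state(state, prefix=f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state(state, prefix=f"{prefix}{name}.{i}.")

    def train(self, mode: bool = True) -> "Module":
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _kaiming(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, in_dim, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Needs an explicit rng."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class BatchNorm1d(Module):
    """Normalize over the batch axis (axis 0) of a (B, D) input."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            inv = (var + self.eps) ** -0.5
            return self.gamma * (centered * inv) + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * ((x - self.running_mean) * inv) + self.beta


class Conv1d(Module):
    """1-D convolution over (B, C_in, L) inputs, 'valid' padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel
        self.weight = Tensor(
            _kaiming(rng, fan_in, (out_channels, in_channels, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        data = x.data
        batch, c_in, length = data.shape
        k, stride = self.kernel, self.stride
        n_out = (length - k) // stride + 1
        if n_out < 1:
            raise ValueError(f"input length {length} shorter than kernel {k}")
        # im2col: (B, L_out, C_in*K)
        s0, s1, s2 = data.strides
        cols = np.lib.stride_tricks.as_strided(
            data, shape=(batch, n_out, c_in, k), strides=(s0, s2 * stride, s1, s2)
        ).reshape(batch, n_out, c_in * k)
        w2 = w.data.reshape(w.data.shape[0], -1)  # (C_out, C_in*K)
        out_data = cols @ w2.T + b.data  # (B, L_out, C_out)
        out_data = out_data.transpose(0, 2, 1)

        def backward(g):
            # g: (B, C_out, L_out)
            gt = g.transpose(0, 2, 1)  # (B, L_out, C_out)
            if b.requires_grad:
                b._accumulate(gt.sum(axis=(0, 1)))
            if w.requires_grad:
                gw = np.einsum("blo,blk->ok", gt, cols)
                w._accumulate(gw.reshape(w.data.shape))
            if x.requires_grad:
                gcols = gt @ w2  # (B, L_out, C_in*K)
                gx = np.zeros_like(data)
                gcols = gcols.reshape(batch, n_out, c_in, k)
                for j in range(k):
                    gx[:, :, j:j + n_out * stride:stride] += gcols[:, :, :, j].transpose(0, 2, 1)
                x._accumulate(gx)

        return Tensor._result(out_data, (x, w, b), backward)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax on raw arrays (inference-side use)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and target distributions.

    ``targets`` is a (B, K) array of probability rows (hard or smoothed);
    fused forward/backward for numerical stability.
    """
    targets = np.asarray(targets, dtype=np.float64)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    batch = logits.data.shape[0]
    loss = -(targets * logp).sum() / batch

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            logits._accumulate(g * (p - targets) / batch)

    return Tensor._result(np.array(loss), (logits,), backward)
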