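"""Small neural-network layer library on top of :mod:`dnaturbo.autodiff`."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import DTYPE, Tensor


class Module:
    """Base class: tracks parameters of itself and registered submodules."""

    def __init__(self):
        self._params = {}
        self._modules = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self, prefix: str = "") -> dict:
        out = {}
        for name, p in self._params.items():
            out[prefix + name] = p
        for name, m in self._modules.items():
            out.update(m.parameters(prefix + name + "."))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict):
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise ValueError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: checkpoint {arr.shape} vs "
                    f"model {p.data.shape}"
                )
            p.data = arr.copy()


def param(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "glorot"):
        super().__init__()
        if init == "identity":
            # near-identity: copies the first min(n_in, n_out) inputs; extra
            # output columns start as repetitions of the leading inputs (a
            # repetition-code seed) plus small noise
            w = np.zeros((n_in, n_out))
            m = min(n_in, n_out)
            w[:m, :m] = np.eye(m)
            for j in range(m, n_out):
                w[(j - m) % n_in, j] = 1.0
            if n_out > m:
                w[:, m:] += rng.normal(0, 0.05, size=(n_in, n_out - m))
        elif init == "zero":
            w = np.zeros((n_in, n_out))
        else:
            scale = np.sqrt(2.0 / (n_in + n_out))
            w = rng.normal(0, scale, size=(n_in, n_out))
        self.w = param(w)
        self.b = param(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.w) + self.b


class Conv1d(Module):
    """Same-padding 1-D convolution over (B, C, L) tensors."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, zero: bool = False):
        super().__init__()
        if zero:
            w = np.zeros((c_out, c_in, k))
        else:
            scale = np.sqrt(2.0 / (c_in * k + c_out))
            w = rng.normal(0, scale, size=(c_out, c_in, k))
        self.w = param(w)
        self.b = param(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.w, self.b)


class ConvStack(Module):
    """``layers`` ELU conv layers followed by a 1x1 projection to 1 channel.

    The projection is zero-initialized so a fresh stack is a no-op, which
    lets surrounding residual wiring start from a clean identity.
    """

    def __init__(self, c_in: int, units: int, layers: int, k: int,
                 rng: np.random.Generator, zero_head: bool = True):
        super().__init__()
        convs = []
        c = c_in
        for _ in range(layers):
            convs.append(Conv1d(c, units, k, rng))
            c = units
        self.convs = convs
        self.head = Conv1d(c, 1, 1, rng, zero=zero_head)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = ad.elu(conv(h))
        return self.head(h)  # (B, 1, L)


class ResBlock(Module):
    def __init__(self, channels: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = Conv1d(channels, channels, k, rng)
        self.c2 = Conv1d(channels, channels, k, rng, zero=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.c2(ad.elu(self.c1(x)))


class ResNetStack(Module):
    def __init__(self, c_in: int, units: int, layers: int, k: int,
                 rng: np.random.Generator):
        super().__init__()
        self.inp = Conv1d(c_in, units, k, rng)
        self.blocks = [ResBlock(units, k, rng) for _ in range(layers)]
        self.head = Conv1d(units, 1, 1, rng, zero=True)

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.elu(self.inp(x))
        for blk in self.blocks:
            h = blk(h)
        return self.head(h)


class BiRNNStack(Module):
    """Bidirectional Elman RNN over (B, C, L), projected to 1 channel."""

    def __init__(self, c_in: int, units: int, layers: int,
                 rng: np.random.Generator):
        super().__init__()
        del layers  # single recurrent layer; depth comes from bidirection
        self.units = units
        scale = np.sqrt(1.0 / (c_in + units))
        self.wx_f = param(rng.normal(0, scale, size=(c_in, units)))
        self.wh_f = param(rng.normal(0, scale, size=(units, units)))
        self.b_f = param(np.zeros(units))
        self.wx_b = param(rng.normal(0, scale, size=(c_in, units)))
        self.wh_b = param(rng.normal(0, scale, size=(units, units)))
        self.b_b = param(np.zeros(units))
        self.head = Linear(2 * units, 1, rng, init="zero")

    def _run(self, xs, wx, wh, b):
        h = Tensor(np.zeros((xs[0].shape[0], self.units)))
        out = []
        for x_t in xs:
            h = ad.tanh(ad.matmul(x_t, wx) + ad.matmul(h, wh) + b)
            out.append(h)
        return out

    def __call__(self, x: Tensor) -> Tensor:
        B, C, L = x.shape
        xt = ad.transpose(x, (2, 0, 1))  # L, B, C
        steps = [ad.reshape(ad.take(xt, np.array([t]), axis=0), (B, C))
                 for t in range(L)]
        fwd = self._run(steps, self.wx_f, self.wh_f, self.b_f)
        bwd = self._run(steps[::-1], self.wx_b, self.wh_b, self.b_b)[::-1]
        outs = [self.head(ad.concat([f, b], axis=-1)) for f, b in zip(fwd, bwd)]
        stacked = ad.concat([ad.reshape(o, (B, 1, 1)) for o in outs], axis=2)
        return stacked  # (B, 1, L)


def layer_norm(x: Tensor, axis: int = -1, eps: float = 1e-5) -> Tensor:
    mu = ad.tmean(x, axis=axis, keepdims=True)
    xc = x - mu
    var = ad.tmean(xc * xc, axis=axis, keepdims=True)
    return xc * ad.power(var + eps, -0.5)


class TransformerStack(Module):
    """One self-attention block + FFN over (B, C, L), projected to 1 channel."""

    def __init__(self, c_in: int, units: int, layers: int,
                 rng: np.random.Generator):
        super().__init__()
        del layers
        d = units
        self.embed = Linear(c_in, d, rng)
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.ff1 = Linear(d, 2 * d, rng)
        self.ff2 = Linear(2 * d, d, rng)
        self.head = Linear(d, 1, rng, init="zero")
        self.d = d
        self.pos = param(rng.normal(0, 0.02, size=(1, 512, d)))

    def __call__(self, x: Tensor) -> Tensor:
        B, C, L = x.shape
        h = self.embed(ad.transpose(x, (0, 2, 1)))  # B, L, d
        pos = ad.take(self.pos, np.arange(L), axis=1)
        h = h + pos
        q, k, v = self.wq(h), self.wk(h), self.wv(h)
        att = ad.softmax(
            ad.matmul(q, ad.transpose(k, (0, 2, 1))) * (1.0 / np.sqrt(self.d)),
            axis=-1,
        )
        h = layer_norm(h + self.wo(ad.matmul(att, v)))
        h = layer_norm(h + self.ff2(ad.relu(self.ff1(h))))
        out = self.head(h)  # B, L, 1
        return ad.transpose(out, (0, 2, 1))


class Adam:
    """Adam over a name->Tensor parameter dict, with savable state."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, only: set | None = None):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None or (only is not None and k not in only):
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p.data = p.data - self.lr * (self.m[k] / corr1) / (
                np.sqrt(self.v[k] / corr2) + self.eps
            )

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def state_dict(self) -> dict:
        out = {"__t__": np.array(self.t)}
        for k in self.params:
            out[f"m::{k}"] = self.m[k]
            out[f"v::{k}"] = self.v[k]
        return out

    def load_state_dict(self, state: dict):
        self.t = int(state["__t__"])
        for k in self.params:
            self.m[k] = np.asarray(state[f"m::{k}"], dtype=DTYPE).copy()
            self.v[k] = np.asarray(state[f"v::{k}"], dtype=DTYPE).copy()
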