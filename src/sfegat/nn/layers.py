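"""Dense graph neural-network layers on the package's autodiff engine.

All layers operate on batches of equally-sized graphs: node features are
``(N, C, F)`` arrays and adjacency information is carried as dense
``(N, C, C)`` matrices (C = 22 electrodes for the reference montage, so a
dense representation is both simpler and faster than sparse message
passing at this scale).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, where_const

__all__ = [
    "Module",
    "Linear",
    "BatchNorm",
    "Dropout",
    "DenseGATv2",
    "DenseGATv1",
    "DenseGCN",
    "gcn_normalize",
    "add_self_loops",
]

_NEG_INF = -1e30


def _gatv2_energies(src: Tensor, dst: Tensor, att: Tensor, slope: float) -> Tensor:
    """Fused e[n,i,j,h] = att_h . LeakyReLU(dst[n,i,h,:] + src[n,j,h,:]).

    One autodiff node instead of four keeps the (N, C, C, heads, d)
    intermediates to a minimum — this pairwise tensor dominates the cost of
    a dense attention layer.
    """
    pair = dst.data[:, :, None] + src.data[:, None, :]  # (N, C, C, h, d)
    neg = pair < 0
    act = np.where(neg, slope * pair, pair)
    energies = np.einsum("nijhd,hd->nijh", act, att.data, optimize=True)

    def backward(g):
        g_act = g[..., None] * att.data
        g_pair = np.where(neg, slope * g_act, g_act)
        g_att = np.einsum("nijhd,nijh->hd", act, g, optimize=True)
        return (g_pair.sum(axis=1), g_pair.sum(axis=2), g_att)

    return Tensor._from_op(energies, (src, dst, att), backward)


def _attention_aggregate(alpha: Tensor, src: Tensor) -> Tensor:
    """Fused out[n,i,h,d] = sum_j alpha[n,i,j,h] * src[n,j,h,d]."""
    out = np.einsum("nijh,njhd->nihd", alpha.data, src.data, optimize=True)

    def backward(g):
        g_alpha = np.einsum("nihd,njhd->nijh", g, src.data, optimize=True)
        g_src = np.einsum("nijh,nihd->njhd", alpha.data, g, optimize=True)
        return (g_alpha, g_src)

    return Tensor._from_op(out, (alpha, src), backward)


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[-1], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Tiny module base: parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, obj in vars(self).items():
            if isinstance(obj, Module):
                yield name, obj
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def _named_buffers(self, prefix: str = ""):
        for key, value in self._buffers().items():
            yield f"{prefix}{key}", np.array(value)
        for name, child in self._children():
            yield from child._named_buffers(prefix=f"{prefix}{name}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update(self._named_buffers())
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float64)
        self._load_buffers(state, prefix="")
        return self

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def _load_buffers(self, state, prefix: str):
        for key, value in self._buffers().items():
            full = f"{prefix}{key}"
            if full in state:
                self._set_buffer(key, state[full])
        for name, child in self._children():
            child._load_buffers(state, prefix=f"{prefix}{name}.")

    def _set_buffer(self, key: str, value):  # pragma: no cover - overridden
        setattr(self, key, np.array(value))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(glorot(rng, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Batch normalization over every leading axis of a feature array.

    For node features of shape (N, C, F) the statistics of feature j are
    computed over all N*C node instances in the mini-batch (train mode) or
    taken from running estimates (eval mode), then scaled by gamma and
    shifted by beta.  Eval mode before any training batch is an error.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.num_batches_tracked = 0

    def _buffers(self):
        return {
            "running_mean": self.running_mean,
            "running_var": self.running_var,
            "num_batches_tracked": self.num_batches_tracked,
        }

    def _set_buffer(self, key, value):
        if key == "num_batches_tracked":
            self.num_batches_tracked = int(value)
        else:
            setattr(self, key, np.array(value, dtype=np.float64))

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            n = int(np.prod([x.shape[a] for a in axes]))
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * unbiased
            self.num_batches_tracked += 1
        else:
            if self.num_batches_tracked == 0:
                raise RuntimeError(
                    "BatchNorm used in eval mode before any training batch: "
                    "running statistics are uninitialized"
                )
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0:
            return x
        if rng is None:
            raise ValueError("train-mode dropout needs an rng")
        keep = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


def add_self_loops(support: np.ndarray) -> np.ndarray:
    """Binary (N, C, C) support with the diagonal forced on."""
    support = np.asarray(support, dtype=bool).copy()
    idx = np.arange(support.shape[-1])
    support[..., idx, idx] = True
    return support


class _DenseAttentionBase(Module):
    """Shared machinery for the GAT / GATv2 variants.

    Parameters follow the common GATv2 layer layout: separate source and
    target input projections (each with bias), a per-head attention vector,
    and an output bias on the concatenated heads.
    """

    def __init__(
        self,
        in_dim: int,
        heads: int,
        head_dim: int,
        rng: np.random.Generator,
        negative_slope: float = 0.2,
    ):
        super().__init__()
        out = heads * head_dim
        self.heads = heads
        self.head_dim = head_dim
        self.negative_slope = negative_slope
        self.weight_src = Parameter(glorot(rng, (in_dim, out)))
        self.bias_src = Parameter(np.zeros(out))
        self.weight_dst = Parameter(glorot(rng, (in_dim, out)))
        self.bias_dst = Parameter(np.zeros(out))
        self.att = Parameter(glorot(rng, (1, head_dim * heads)).reshape(heads, head_dim))
        self.bias = Parameter(np.zeros(out))

    def _energies(self, src_h: Tensor, dst_h: Tensor) -> Tensor:
        raise NotImplementedError

    def _forward(
        self,
        x: Tensor,
        support: np.ndarray,
        edge_weight: np.ndarray | None,
        return_alpha: bool,
    ):
        support = np.asarray(support, dtype=bool)
        if not support.any(axis=2).all():
            raise ValueError(
                "a node has an empty neighbourhood; enable self-loops to keep "
                "the attention softmax defined"
            )
        n, c, _ = x.shape
        src = (x @ self.weight_src + self.bias_src).reshape(n, c, self.heads, self.head_dim)
        dst = (x @ self.weight_dst + self.bias_dst).reshape(n, c, self.heads, self.head_dim)
        energies = self._energies(src, dst)  # (N, C, C, heads)
        energies = where_const(support[..., None], energies, _NEG_INF)
        shift = energies.data.max(axis=2, keepdims=True)
        scores = (energies - Tensor(shift)).exp()
        if edge_weight is not None:
            # |w| as a multiplicative softmax prior; gradients flow into
            # Tensor-valued edge weights (the probability-scaled adjacency).
            ew = edge_weight if isinstance(edge_weight, Tensor) else Tensor(
                np.asarray(edge_weight, dtype=np.float64)
            )
            scores = scores * ew.abs().expand_dims(-1)
        denom = scores.sum(axis=2, keepdims=True)
        alpha = scores / denom
        if return_alpha:
            return alpha
        out = _attention_aggregate(alpha, src).reshape(n, c, self.heads * self.head_dim)
        return out + self.bias

    def attention(
        self, x: Tensor, support: np.ndarray, edge_weight: np.ndarray | None = None
    ) -> Tensor:
        """Per-head attention coefficients, shape (N, C, C, heads)."""
        return self._forward(x, support, edge_weight, return_alpha=True)

    def __call__(
        self, x: Tensor, support: np.ndarray, edge_weight: np.ndarray | None = None
    ) -> Tensor:
        return self._forward(x, support, edge_weight, return_alpha=False)


class DenseGATv2(_DenseAttentionBase):
    """Graph attention with the 'dynamic' (GATv2) energy ordering.

    e_ij = a_h . LeakyReLU(W_dst x_i + W_src x_j); the nonlinearity is
    applied before the attention vector, so the attention ranking can differ
    per query node.
    """

    def _energies(self, src_h: Tensor, dst_h: Tensor) -> Tensor:
        return _gatv2_energies(src_h, dst_h, self.att, self.negative_slope)


class DenseGATv1(_DenseAttentionBase):
    """Original GAT ordering: e_ij = LeakyReLU(a . [W x_i || W x_j]).

    The concatenated attention vector splits into a destination half and a
    source half, so the energy decomposes as a_dst.Wx_i + a_src.Wx_j before
    the LeakyReLU (static attention).  Kept behind a flag: the printed energy
    formula has this ordering, while the named mechanism is GATv2.
    """

    def __init__(self, in_dim, heads, head_dim, rng, negative_slope=0.2):
        super().__init__(in_dim, heads, head_dim, rng, negative_slope)
        self.att_src = Parameter(
            glorot(rng, (1, head_dim * heads)).reshape(heads, head_dim)
        )

    def _energies(self, src_h: Tensor, dst_h: Tensor) -> Tensor:
        e = (dst_h * self.att).sum(axis=-1).expand_dims(2) + (
            src_h * self.att_src
        ).sum(axis=-1).expand_dims(1)
        return e.leaky_relu(self.negative_slope)


def gcn_normalize(adjacency, add_loops: bool = True):
    """Symmetric GCN propagation operator D^-1/2 (A + I) D^-1/2.

    Accepts an ndarray or a Tensor (gradients flow through edge weights).
    Degrees use absolute edge weights plus the unit self-loop, so the
    operator stays defined when standardized-PLV edge weights are negative.
    """
    a = adjacency if isinstance(adjacency, Tensor) else Tensor(np.asarray(adjacency, float))
    c = a.shape[-1]
    eye = np.eye(c)
    a_tilde = a + Tensor(np.broadcast_to(eye, a.shape).copy()) if add_loops else a
    deg = a.abs().sum(axis=-1) + (1.0 if add_loops else 0.0)
    dinv = deg ** (-0.5)
    return a_tilde * dinv.expand_dims(-1) * dinv.expand_dims(-2)


class DenseGCN(Module):
    """Graph convolution: out = A_hat x W + b with A_hat from gcn_normalize."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(glorot(rng, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor, a_hat) -> Tensor:
        a_hat = a_hat if isinstance(a_hat, Tensor) else Tensor(np.asarray(a_hat, float))
        return a_hat @ (x @ self.weight) + self.bias
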