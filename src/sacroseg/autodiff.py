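"""A compact reverse-mode automatic differentiation engine over NumPy.

The sequence models in this package are small enough that a tape-based
engine over dense ``float64`` arrays is entirely adequate on a CPU.  The
design follows the usual pattern: a :class:`Tensor` wraps an ``ndarray``,
every operation records its parents and a gradient callback, and
:meth:`Tensor.backward` walks the tape in reverse topological order.

Recurrent layers get a dedicated fused op (:func:`lstm_layer`) that runs the
whole backward-through-time pass inside one tape node; everything else is
composed from the primitives below.  Gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "matmul", "concat", "softmax", "layer_norm", "embedding",
           "lstm_layer", "weighted_softmax_cross_entropy", "Adam"]


class Tensor:
    __slots__ = ("data", "grad", "parents", "requires_grad", "name")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence[Tuple["Tensor", Callable]] = (), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.parents = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    # -- graph walking ------------------------------------------------------

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node.parents:
                stack.append((parent, False))
        self.grad = grad
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, fn in node.parents:
                if not parent.requires_grad:
                    continue
                contrib = fn(g)
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += contrib

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=[
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (other, lambda g: _unbroadcast(g, other.data.shape)),
        ])
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        return Tensor(self.data - other.data, parents=[
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (other, lambda g: _unbroadcast(-g, other.data.shape)),
        ])

    def __mul__(self, other) -> "Tensor":
        if np.isscalar(other):
            return Tensor(self.data * other, parents=[(self, lambda g: g * other)])
        other = _as_tensor(other)
        return Tensor(self.data * other.data, parents=[
            (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
        ])

    __rmul__ = __mul__

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        return Tensor(self.data.reshape(*shape),
                      parents=[(self, lambda g: g.reshape(old))])

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(*axes),
                      parents=[(self, lambda g: g.transpose(*inv))])

    def __getitem__(self, idx) -> "Tensor":
        def back(g, idx=idx, shape=self.data.shape):
            full = np.zeros(shape, dtype=g.dtype)
            full[idx] = g
            return full
        return Tensor(self.data[idx], parents=[(self, back)])

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        return Tensor(y, parents=[(self, lambda g: g * (1.0 - y * y))])

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(y, parents=[(self, lambda g: g * y * (1.0 - y))])

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(self.data * mask, parents=[(self, lambda g: g * mask)])

    def sum(self) -> "Tensor":
        shape = self.data.shape
        return Tensor(self.data.sum(),
                      parents=[(self, lambda g: np.broadcast_to(g, shape).copy())])


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    out = a.data @ b.data

    def da(g):
        return _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)

    def db(g):
        return _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)

    return Tensor(out, parents=[(a, da), (b, db)])


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
        def back(g, lo=int(lo), hi=int(hi)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]
        parents.append((t, back))
    return Tensor(np.concatenate(datas, axis=axis), parents=parents)


def softmax(x: Tensor, mask: Optional[np.ndarray] = None) -> Tensor:
    """Softmax over the last axis; ``mask`` (boolean, True = blocked) adds -inf."""
    z = x.data
    if mask is not None:
        z = np.where(mask, -1e30, z)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def back(g):
        return p * (g - (g * p).sum(axis=-1, keepdims=True))

    return Tensor(p, parents=[(x, back)])


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gain.data + bias.data
    n = x.data.shape[-1]

    def dx(g):
        gg = g * gain.data
        return inv * (gg - gg.mean(axis=-1, keepdims=True)
                      - xhat * (gg * xhat).mean(axis=-1, keepdims=True))

    def dgain(g):
        return _unbroadcast(g * xhat, gain.data.shape)

    def dbias(g):
        return _unbroadcast(g, bias.data.shape)

    return Tensor(out, parents=[(x, dx), (gain, dgain), (bias, dbias)])


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.int64)

    def back(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, idx.reshape(-1), g.reshape(-1, g.shape[-1]))
        return full

    return Tensor(weight.data[idx], parents=[(weight, back)])


# ---------------------------------------------------------------------------
# Fused LSTM layer: one tape node runs the full backward-through-time pass.
# Gate order in the packed weight matrices is (input, forget, cell, output).
# ---------------------------------------------------------------------------

def lstm_layer(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor,
               h0: Optional[Tensor] = None, c0: Optional[Tensor] = None
               ) -> Tuple[Tensor, Tensor, Tensor]:
    """Run an LSTM over ``x`` of shape (T, B, D); hidden size H = wh.shape[0].

    Returns ``(H_seq, h_T, c_T)`` with shapes (T, B, H), (B, H), (B, H).
    The three outputs carry independent backward passes; because gradients
    are linear in the output adjoints, their contributions sum correctly on
    the shared parents.
    """
    T, B, _ = x.data.shape
    H = wh.data.shape[0]
    h = h0.data if h0 is not None else np.zeros((B, H))
    c = c0.data if c0 is not None else np.zeros((B, H))

    i_s = np.empty((T, B, H)); f_s = np.empty((T, B, H))
    g_s = np.empty((T, B, H)); o_s = np.empty((T, B, H))
    tc_s = np.empty((T, B, H))          # tanh(c_t)
    cprev_s = np.empty((T, B, H)); hprev_s = np.empty((T, B, H))
    hs = np.empty((T, B, H))

    for t in range(T):
        cprev_s[t] = c; hprev_s[t] = h
        z = x.data[t] @ wx.data + h @ wh.data + b.data
        i = _sig(z[:, :H]); f = _sig(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H]); o = _sig(z[:, 3 * H:])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        i_s[t], f_s[t], g_s[t], o_s[t], tc_s[t], hs[t] = i, f, g, o, tc, h

    def bptt(dH: Optional[np.ndarray], dhT: Optional[np.ndarray],
             dcT: Optional[np.ndarray]):
        dx = np.zeros_like(x.data)
        dwx = np.zeros_like(wx.data); dwh = np.zeros_like(wh.data)
        db = np.zeros_like(b.data)
        dh_next = dhT.copy() if dhT is not None else np.zeros((B, H))
        dc_next = dcT.copy() if dcT is not None else np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            dh = dh_next + (dH[t] if dH is not None else 0.0)
            i, f, g, o, tc = i_s[t], f_s[t], g_s[t], o_s[t], tc_s[t]
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz = np.concatenate([
                dc * g * i * (1.0 - i),
                dc * cprev_s[t] * f * (1.0 - f),
                dc * i * (1.0 - g * g),
                dh * tc * o * (1.0 - o),
            ], axis=1)
            dx[t] = dz @ wx.data.T
            dwx += x.data[t].T @ dz
            dwh += hprev_s[t].T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ wh.data.T
            dc_next = dc * f_s[t]
        return dx, dwx, dwh, db, dh_next, dc_next

    def make_parents(which: str):
        cache = {"g": None, "out": None}  # one backward pass feeds all parents

        def grads_for(g):
            if cache["g"] is not g:
                if which == "H":
                    cache["out"] = bptt(g, None, None)
                elif which == "hT":
                    cache["out"] = bptt(None, g, None)
                else:
                    cache["out"] = bptt(None, None, g)
                cache["g"] = g
            return cache["out"]

        parents = []
        for pos, parent in ((0, x), (1, wx), (2, wh), (3, b), (4, h0), (5, c0)):
            if parent is None:
                continue
            parents.append((parent, lambda g, pos=pos: grads_for(g)[pos]))
        return parents

    out_H = Tensor(hs, parents=make_parents("H"))
    out_h = Tensor(hs[-1].copy(), parents=make_parents("hT"))
    out_c = Tensor(c.copy(), parents=make_parents("cT"))
    return out_H, out_h, out_c


def _sig(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def weighted_softmax_cross_entropy(logits: Tensor, onehot: np.ndarray,
                                   weights: np.ndarray) -> Tensor:
    """Mean weighted cross-entropy over all leading axes of ``logits``.

    ``onehot`` matches ``logits`` in shape; ``weights`` has one entry per
    class.  Positions whose one-hot row is all zeros (excluded classes)
    contribute nothing but still count in the averaging denominator, matching
    the sequence loss's 1/(t*d) normalisation.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    logp = z - np.log(e.sum(axis=-1, keepdims=True))
    denom = int(np.prod(logits.data.shape[:-1]))
    wy = onehot * weights  # broadcast over the class axis
    loss = -(wy * logp).sum() / denom

    def back(g):
        pos_w = wy.sum(axis=-1, keepdims=True)  # weight of the true class
        return g * (pos_w * p - wy) / denom

    return Tensor(loss, parents=[(logits, back)])


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1; m += (1 - self.b1) * g
            v *= self.b2; v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
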