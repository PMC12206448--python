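"""Selective state-space (Mamba-style) sequence branch over SMILES tokens.

A continuous linear state-space system

    x'(t) = A x(t) + B u(t),    y(t) = C x(t)

is discretized per step with zero-order hold for the state transition,
A_bar = exp(Delta * A), and the simplified Euler rule B_bar = Delta * B, where
Delta > 0 is a data-dependent step size (softplus of a linear projection of the
input).  Selectivity comes from making (Delta, B, C) functions of the token
features; A (diagonal, negative) and the skip coefficient D are input
independent.  The scan is the sequential recurrence

    x_k = A_bar_k * x_{k-1} + B_bar_k * u_k,    y_k = C_k . x_k + D * u_k,

run left to right over the token sequence, so information propagates strictly
causally.  Each block follows the usual dataflow: linear projection doubling
the width, split into a main and a gate path, causal depthwise 1-D convolution
plus SiLU on the main path, the selective scan, multiplication by the SiLU'd
gate path, and an output projection with a residual connection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemio import TokenizedSMILES
from .minigrad import _GRAD_ENABLED, Parameter, Tensor, concat
from .nn import Embedding, LayerNorm, Linear, Module

__all__ = [
    "DiscretizedSSM",
    "discretize",
    "selective_scan",
    "MambaBlock",
    "MambaEncoder",
]


@dataclass
class DiscretizedSSM:
    """Per-step discretized system matrices."""

    A_bar: np.ndarray | Tensor  # elementwise exp(Delta * A)
    B_bar: np.ndarray | Tensor  # Delta * B


def discretize(A, B, delta) -> DiscretizedSSM:
    """Zero-order-hold state transition and simplified-Euler input weight.

    Works on plain arrays or autograd tensors; shapes follow broadcasting.
    Requires Delta > 0.
    """
    is_tensor = any(isinstance(x, Tensor) for x in (A, B, delta))
    dval = delta.data if isinstance(delta, Tensor) else np.asarray(delta, dtype=np.float64)
    if np.any(dval <= 0):
        raise ValueError("step size Delta must be positive")
    if is_tensor:
        A = A if isinstance(A, Tensor) else Tensor(A)
        B = B if isinstance(B, Tensor) else Tensor(B)
        delta = delta if isinstance(delta, Tensor) else Tensor(delta)
        return DiscretizedSSM(A_bar=(delta * A).exp(), B_bar=delta * B)
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    return DiscretizedSSM(A_bar=np.exp(dval * A), B_bar=dval * B)


def selective_scan(disc: DiscretizedSSM, C, u, D=None):
    """Sequential selective scan (the reference semantics).

    Parameters are per-step: with m steps, d channels and state width N,
    ``disc.A_bar`` and ``disc.B_bar`` have shape (m, d, N) (or broadcastable),
    ``C`` has shape (m, N), ``u`` has shape (m, d).  Returns y of shape (m, d).
    Plain NumPy arrays stay NumPy; autograd tensors build the graph.

    x_0 = 0;  x_k = A_bar_k * x_{k-1} + B_bar_k * u_k;  y_k = x_k . C_k (+ D*u_k).
    """
    is_tensor = any(isinstance(t, Tensor) for t in (disc.A_bar, disc.B_bar, C, u, D))
    if is_tensor:
        return _scan_tensor(disc, C, u, D)
    A_bar = np.asarray(disc.A_bar, dtype=np.float64)
    B_bar = np.asarray(disc.B_bar, dtype=np.float64)
    C = np.asarray(C, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    m = u.shape[0]
    if not (A_bar.shape[0] == B_bar.shape[0] == C.shape[0] == m):
        raise ValueError("per-step parameter sequences must share length m")
    d = u.shape[1] if u.ndim > 1 else 1
    u2 = u.reshape(m, d)
    N = C.shape[-1]
    x = np.zeros((d, N))
    ys = np.empty((m, d))
    for k in range(m):
        x = np.broadcast_to(A_bar[k], (d, N)) * x + np.broadcast_to(B_bar[k], (d, N)) * u2[k][:, None]
        ys[k] = x @ C[k]
    if D is not None:
        ys = ys + u2 * np.asarray(D).reshape(1, d)
    return ys if u.ndim > 1 else ys.ravel()


def _scan_tensor(disc: DiscretizedSSM, C, u, D=None) -> Tensor:
    """Autograd scan as a single graph node with a hand-derived adjoint.

    The forward pass is the same sequential recurrence as the NumPy reference;
    the backward pass runs the adjoint recurrence
    lambda_k = dy_k c_k + A_bar_{k+1} lambda_{k+1} right to left, which avoids
    building one graph node per time step.
    """
    A_bar = disc.A_bar if isinstance(disc.A_bar, Tensor) else Tensor(disc.A_bar)
    B_bar = disc.B_bar if isinstance(disc.B_bar, Tensor) else Tensor(disc.B_bar)
    C = C if isinstance(C, Tensor) else Tensor(C)
    u = u if isinstance(u, Tensor) else Tensor(u)
    m, d = u.shape
    N = C.shape[-1]
    if not (A_bar.shape[0] == B_bar.shape[0] == C.shape[0] == m):
        raise ValueError("per-step parameter sequences must share length m")
    a = np.broadcast_to(A_bar.data, (m, d, N))
    bb = np.broadcast_to(B_bar.data, (m, d, N))
    uu = u.data
    cc = C.data
    xs = np.empty((m, d, N))
    x = np.zeros((d, N))
    for k in range(m):
        x = a[k] * x + bb[k] * uu[k][:, None]
        xs[k] = x
    y = np.einsum("mdn,mn->md", xs, cc)
    has_d = D is not None
    if has_d:
        D = D if isinstance(D, Tensor) else Tensor(D)
        y = y + uu * D.data.reshape(1, d)

    parents = (A_bar, B_bar, C, u) + ((D,) if has_d else ())

    def bwd(out):
        g = out.grad  # (m, d)
        dC = np.einsum("mdn,md->mn", xs, g)
        du = g * D.data.reshape(1, d) if has_d else np.zeros_like(uu)
        dA = np.empty((m, d, N))
        dB = np.empty((m, d, N))
        carry = np.zeros((d, N))
        for k in range(m - 1, -1, -1):
            lam = g[k][:, None] * cc[k][None, :] + carry
            x_prev = xs[k - 1] if k > 0 else 0.0
            dA[k] = lam * x_prev
            dB[k] = lam * uu[k][:, None]
            du[k] = du[k] + (lam * bb[k]).sum(axis=-1)
            carry = a[k] * lam
        from .minigrad import _unbroadcast

        Tensor._accum(A_bar, _unbroadcast(dA, A_bar.shape))
        Tensor._accum(B_bar, _unbroadcast(dB, B_bar.shape))
        Tensor._accum(C, dC)
        Tensor._accum(u, du)
        if has_d:
            Tensor._accum(D, (g * uu).sum(axis=0))

    out = Tensor(y)
    if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = bwd
    return out


class MambaBlock(Module):
    """One selective-SSM block (pre-norm, residual added by the caller)."""

    def __init__(
        self,
        width: int,
        state_dim: int = 16,
        conv_kernel: int = 4,
        dt_rank: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.width = width
        self.state_dim = state_dim
        self.conv_kernel = conv_kernel
        self.dt_rank = dt_rank or max(width // 16, 1)
        self.norm = LayerNorm(width)
        self.in_proj = Linear(width, 2 * width, rng)  # doubles the feature dimension
        self.conv_w = Parameter(rng.normal(0.0, 0.3, size=(conv_kernel, width)))
        self.conv_b = Parameter(np.zeros(width))
        self.x_proj = Linear(width, self.dt_rank + 2 * state_dim, rng, bias=False)
        self.dt_proj = Linear(self.dt_rank, width, rng)
        # negative-range diagonal A (S4/Mamba convention): A = -exp(A_log)
        self.A_log = Parameter(np.log(np.tile(np.arange(1, state_dim + 1, dtype=np.float64), (width, 1))))
        self.D = Parameter(np.ones(width))
        self.out_proj = Linear(width, width, rng)

    def _causal_conv(self, x: Tensor) -> Tensor:
        """Depthwise causal 1-D convolution along the sequence axis."""
        m, d = x.shape
        pad = Tensor(np.zeros((self.conv_kernel - 1, d)))
        xp = concat([pad, x], axis=0)  # (m + k - 1, d)
        out = None
        for i in range(self.conv_kernel):
            term = xp[i : i + m, :] * self.conv_w[i]
            out = term if out is None else out + term
        return out + self.conv_b

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[0] == 0:
            raise ValueError("empty token sequence")
        h = self.norm(x)
        proj = self.in_proj(h)  # (m, 2*width)
        u = proj[:, : self.width]
        gate = proj[:, self.width :]
        u = self._causal_conv(u).silu()
        params = self.x_proj(u)  # (m, dt_rank + 2N)
        dt = self.dt_proj(params[:, : self.dt_rank]).softplus()  # (m, width) > 0
        B = params[:, self.dt_rank : self.dt_rank + self.state_dim]  # (m, N)
        C = params[:, self.dt_rank + self.state_dim :]  # (m, N)
        A = -self.A_log.exp()  # (width, N), strictly negative
        # per-step discretization: A_bar_k = exp(dt_k * A), B_bar_k = dt_k * B_k
        A_bar = (dt.reshape(*dt.shape, 1) * A).exp()  # (m, width, N)
        B_bar = dt.reshape(*dt.shape, 1) * B.reshape(B.shape[0], 1, self.state_dim)
        y = _scan_tensor(DiscretizedSSM(A_bar, B_bar), C, u, self.D)
        y = y * gate.silu()
        return self.out_proj(y)


class MambaEncoder(Module):
    """Token embedding + stacked Mamba blocks + final norm -> z2 (m, width)."""

    def __init__(
        self,
        width: int = 512,
        n_layers: int = 2,
        vocab_size: int = 100,
        state_dim: int = 16,
        conv_kernel: int = 4,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed + 17)
        self.width = width
        self.embed = Embedding(vocab_size, width, rng)
        self.blocks = [
            MambaBlock(width, state_dim, conv_kernel, rng=rng) for _ in range(n_layers)
        ]
        self.final_norm = LayerNorm(width)

    def __call__(self, tokens: TokenizedSMILES | np.ndarray) -> Tensor:
        ids = tokens.token_ids if isinstance(tokens, TokenizedSMILES) else np.asarray(tokens)
        if len(ids) == 0:
            raise ValueError("empty token sequence")
        x = self.embed(ids)
        for blk in self.blocks:
            x = x + blk(x)
        return self.final_norm(x)

    def encode(self, tokens) -> Tensor:
        return self(tokens)
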