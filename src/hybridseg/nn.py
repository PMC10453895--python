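"""Minimal reverse-mode autodiff core for 2-D segmentation networks.

Implements exactly the operations the encoder-decoder needs — 3x3/1x1
convolution via im2col, ReLU, 2x2 max pooling, nearest-neighbour x2
upsampling, channel concatenation — plus a fused softmax + cross-entropy +
soft-Dice loss with an analytic gradient.  Everything is float32 numpy;
single-threaded runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var",
    "backward",
    "conv2d",
    "relu",
    "maxpool2",
    "upsample2",
    "concat",
    "avgpool",
    "softmax",
    "combined_loss_op",
]


class Var:
    """A node in the computation graph: an ndarray plus backward plumbing."""

    __slots__ = ("data", "grad", "_parents", "_back", "requires_grad")

    def __init__(self, data, parents=(), back=None, requires_grad=True):
        self.data = data
        self.grad = None
        self._parents = parents
        self._back = back
        self.requires_grad = requires_grad


def _acc(v: Var, g) -> None:
    if not v.requires_grad:
        return
    if v.grad is None:
        v.grad = g
    else:
        v.grad = v.grad + g


def backward(root: Var, grad=None) -> None:
    """Run reverse-mode accumulation from ``root`` in topological order."""
    order: list[Var] = []
    seen: set[int] = set()
    stack: list[tuple[Var, bool]] = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    root.grad = np.asarray(1.0, dtype=np.float32) if grad is None else grad
    for node in reversed(order):
        if node._back is not None and node.grad is not None:
            node._back(node.grad)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, k: int, pad: int):
    """(N,C,H,W) -> (N*Ho*Wo, C*k*k) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    s = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, ho, wo, c, k, k), (s[0], s[2], s[3], s[1], s[2], s[3])
    )
    return np.ascontiguousarray(cols).reshape(n * ho * wo, c * k * k), (ho, wo)


def _col2im(dcols: np.ndarray, xshape, k: int, pad: int, ho: int, wo: int):
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + ho, j : j + wo] += d[:, :, i, j]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


def conv2d(x: Var, w: Var, b: Var, pad: int | None = None) -> Var:
    """2-D convolution (cross-correlation), 'same' padding by default."""
    cout, cin, k, _ = w.data.shape
    if pad is None:
        pad = k // 2
    if x.data.shape[1] != cin:
        raise ValueError(
            f"conv2d: input has {x.data.shape[1]} channels, weight expects {cin}"
        )
    cols, (ho, wo) = _im2col(x.data, k, pad)
    wmat = w.data.reshape(cout, -1)
    out = cols @ wmat.T
    out += b.data
    n = x.data.shape[0]
    y = np.ascontiguousarray(out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2))

    def back(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        if w.requires_grad:
            _acc(w, (gm.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            _acc(b, gm.sum(axis=0))
        if x.requires_grad:
            _acc(x, _col2im(gm @ wmat, x.data.shape, k, pad, ho, wo))

    return Var(y, (x, w, b), back)


# ---------------------------------------------------------------------------
# pointwise / structural ops


def add(a: Var, b: Var) -> Var:
    y = a.data + b.data

    def back(g):
        _acc(a, g)
        _acc(b, g)

    return Var(y, (a, b), back)


def relu(x: Var) -> Var:
    mask = x.data > 0
    y = x.data * mask

    def back(g):
        _acc(x, g * mask)

    return Var(y, (x,), back)


def maxpool2(x: Var) -> Var:
    n, c, h, w = x.data.shape
    r = (
        x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = r.argmax(axis=-1)  # ties -> first index, deterministic
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def back(g):
        dr = np.zeros_like(r)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dx = (
            dr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        _acc(x, dx)

    return Var(y, (x,), back)


def upsample2(x: Var) -> Var:
    """Nearest-neighbour x2 upsampling."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def back(g):
        _acc(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Var(y, (x,), back)


def concat(a: Var, b: Var) -> Var:
    ca = a.data.shape[1]
    y = np.concatenate([a.data, b.data], axis=1)

    def back(g):
        _acc(a, g[:, :ca])
        _acc(b, g[:, ca:])

    return Var(y, (a, b), back)


def avgpool(x: np.ndarray, factor: int) -> np.ndarray:
    """Plain (non-graph) average pooling used to downsample feature stacks."""
    if factor == 1:
        return x
    *lead, h, w = x.shape
    r = x.reshape(*lead, h // factor, factor, w // factor, factor)
    return r.mean(axis=(-3, -1))


# ---------------------------------------------------------------------------
# loss


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def combined_loss_op(
    logits: Var,
    target: np.ndarray,
    epsilon: float = 1e-6,
    foreground_classes: tuple[int, ...] = (1, 2, 3),
):
    """Fused softmax + (cross-entropy + soft-Dice) loss.

    Returns ``(loss_var, ce_value, dice_value)`` where ``loss_var`` is a
    scalar graph node whose backward injects the analytic gradient into
    ``logits``.  The soft Dice term is computed over the whole batch per
    foreground class (batch Dice) and averaged over those classes.
    """
    p = softmax(logits.data.astype(np.float64), axis=1)
    n, ncls = p.shape[:2]
    onehot = np.zeros_like(p)
    idx0 = np.arange(n)[:, None, None]
    rows = np.arange(p.shape[2])[None, :, None]
    cols = np.arange(p.shape[3])[None, None, :]
    onehot[idx0, target, rows, cols] = 1.0

    npix = n * p.shape[2] * p.shape[3]
    p_true = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    ce = float(-np.log(np.clip(p_true, 1e-7, 1.0)).mean())
    dce_dz = (p - onehot) / npix

    fg = list(foreground_classes)
    kfg = len(fg)
    ddice_dp = np.zeros_like(p)
    dice_ratio = 0.0
    for c in fg:
        yc, pc = onehot[:, c], p[:, c]
        num = 2.0 * float((yc * pc).sum()) + epsilon
        den = float(yc.sum() + pc.sum()) + epsilon
        dice_ratio += num / den
        # d(num/den)/dp_c = (2*y_c*den - num) / den^2
        ddice_dp[:, c] = -(2.0 * yc * den - num) / (den * den) / kfg
    dice = 1.0 - dice_ratio / kfg

    # chain rule through softmax: dL/dz_i = p_i * (dL/dp_i - sum_c dL/dp_c p_c)
    inner = (ddice_dp * p).sum(axis=1, keepdims=True)
    ddice_dz = p * (ddice_dp - inner)
    dz = (dce_dz + ddice_dz).astype(np.float32)

    def back(g):
        _acc(logits, float(g) * dz)

    loss = Var(np.asarray(ce + dice, dtype=np.float32), (logits,), back)
    return loss, ce, dice
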