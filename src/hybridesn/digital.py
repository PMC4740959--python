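"""Bit-faithful emulation of the digital (RTL) reservoir datapath.

The hardware datapath stores weights and states in Q(int_bits.frac_bits)
two's-complement fixed point (default Q(10.20)), multiplies and adds with
quantisation after every operation, approximates tanh with a five-band
piecewise-linear function whose slopes are powers of two (shift-friendly),
and realises the alpha = 0.5 leaky blend as an add followed by a one-bit
right shift.  Inter-neuron values are registered: every neuron reads its
neighbours' *previous* outputs, which is exactly the Eq.-style update the
ideal model uses, so the two models converge as frac_bits grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ShapeError
from .esn import ESNState
from .topology import ReservoirWeights

__all__ = [
    "FixedPointFormat",
    "quantize",
    "pwl_tanh",
    "digital_step",
    "digital_harvest",
    "digital_harvest_batch",
]


@dataclass(frozen=True)
class FixedPointFormat:
    """Q(int_bits.frac_bits) two's-complement format.

    Rounding truncates toward negative infinity (floor, the natural
    behaviour of dropping low bits in two's complement); out-of-range
    values saturate to the representable limits
    ``[-2**(int_bits-1), 2**(int_bits-1) - 2**-frac_bits]``.
    """

    int_bits: int = 10
    frac_bits: int = 20

    @property
    def lo(self) -> float:
        return -(2.0 ** (self.int_bits - 1))

    @property
    def hi(self) -> float:
        return 2.0 ** (self.int_bits - 1) - 2.0 ** (-self.frac_bits)

    @property
    def lsb(self) -> float:
        return 2.0 ** (-self.frac_bits)


def quantize(x, fmt: FixedPointFormat = FixedPointFormat()):
    """Quantise to the fixed-point grid: floor to the LSB, then saturate."""
    scale = 2.0 ** fmt.frac_bits
    q = np.floor(np.asarray(x, dtype=float) * scale) / scale
    return np.clip(q, fmt.lo, fmt.hi)


def pwl_tanh(x):
    """Five-band piecewise-linear tanh with power-of-two slopes.

    Bands keyed on ``|x|`` against breakpoints 0.5 and 1.5::

        x >= 1.5          -> 1
        0.5 < x < 1.5     -> x/2 + 0.25
        |x| <= 0.5        -> x
        -1.5 < x < -0.5   -> x/2 - 0.25
        x <= -1.5         -> -1

    Continuous at every breakpoint, odd, monotone nondecreasing, and never
    outside [-1, 1].  Worst-case error vs. exact tanh is 1 - tanh(1.5)
    (~0.0949) at the outer breakpoints.
    """
    x = np.asarray(x, dtype=float)
    return np.where(
        np.abs(x) <= 0.5,
        x,
        np.where(
            np.abs(x) >= 1.5,
            np.sign(x),
            x / 2.0 + np.sign(x) * 0.25,
        ),
    )


def _quantized_dot(products: list[np.ndarray], fmt: FixedPointFormat) -> np.ndarray:
    """Sum pre-quantised products pairwise, quantising after each adder."""
    acc = products[0]
    for p in products[1:]:
        acc = quantize(acc + p, fmt)
    return acc


def digital_step(
    state: ESNState,
    u: np.ndarray,
    weights: ReservoirWeights,
    fmt: FixedPointFormat = FixedPointFormat(),
) -> ESNState:
    """One registered fixed-point reservoir update (alpha fixed at 0.5).

    Weights must already be quantised to ``fmt`` (see
    :func:`quantize_weights`).  Every multiplier and adder output is
    quantised; the activation is :func:`pwl_tanh`; the blend is
    ``(x_new + x_prev) >> 1``.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if u.shape[0] != weights.w_in.shape[1]:
        raise ShapeError(
            f"input u has {u.shape[0]} channels but w_in expects "
            f"{weights.w_in.shape[1]}"
        )
    x_prev = state.x
    kind = weights.kind

    # center (hub) neuron: linear accumulation of registered outputs
    xc = 0.0
    if weights.has_center:
        prods = quantize(weights.w_up * x_prev, fmt)
        acc = 0.0
        for p in prods:  # sequential adder chain
            acc = float(quantize(acc + p, fmt))
        xc = acc

    # per-neuron multiplier outputs, summed with quantisation per adder
    if u.shape[0] == 1:
        in_term = quantize(weights.w_in[:, 0] * u[0], fmt)
    else:
        in_term = np.zeros(weights.n)
        for ch in range(u.shape[0]):
            in_term = quantize(
                in_term + quantize(weights.w_in[:, ch] * u[ch], fmt), fmt
            )
    terms = [in_term]
    if kind in ("one_way_ring", "two_way_ring", "hybrid"):
        terms.append(quantize(weights.w_ring * np.roll(x_prev, 1), fmt))
    if kind == "two_way_ring":
        terms.append(quantize(weights.w_ring_rev * np.roll(x_prev, -1), fmt))
    if kind in ("center", "hybrid"):
        terms.append(quantize(weights.w_down * xc, fmt))
    if kind == "random":
        acc = np.zeros(weights.n)
        for j in range(weights.n):
            acc = quantize(acc + quantize(weights.w_x[:, j] * x_prev[j], fmt), fmt)
        terms.append(acc)

    pre = _quantized_dot(terms, fmt)
    activated = quantize(pwl_tanh(pre), fmt)
    # alpha = 0.5 blend: add then arithmetic right shift by one
    x = quantize((activated + x_prev) / 2.0, fmt)
    return ESNState(x=x, xc=xc, t=state.t + 1)


def quantize_weights(weights: ReservoirWeights, fmt: FixedPointFormat) -> ReservoirWeights:
    """Return a copy of the weight sets quantised to ``fmt`` (load-time)."""
    from dataclasses import replace

    return replace(
        weights,
        w_in=quantize(weights.w_in, fmt),
        w_ring=quantize(weights.w_ring, fmt),
        w_ring_rev=quantize(weights.w_ring_rev, fmt),
        w_up=quantize(weights.w_up, fmt),
        w_down=quantize(weights.w_down, fmt),
        w_x=None if weights.w_x is None else quantize(weights.w_x, fmt),
    )


def digital_harvest(
    signal: np.ndarray,
    weights: ReservoirWeights,
    fmt: FixedPointFormat = FixedPointFormat(),
    washout: int = 0,
) -> np.ndarray:
    """Fixed-point state harvest of one K x T signal; returns N x (T - washout)."""
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    wq = quantize_weights(weights, fmt)
    state = ESNState.zero(weights.n)
    cols = np.empty((weights.n, signal.shape[1]))
    for t in range(signal.shape[1]):
        state = digital_step(state, quantize(signal[:, t], fmt), wq, fmt)
        cols[:, t] = state.x
    return cols[:, washout:]


def digital_harvest_batch(
    signals: np.ndarray,
    weights: ReservoirWeights,
    fmt: FixedPointFormat = FixedPointFormat(),
    washout: int = 0,
) -> np.ndarray:
    """Vectorised fixed-point harvest of B equal-length segments.

    ``signals`` is B x K x T; returns B x N x (T - washout).  Matches
    :func:`digital_harvest` segment by segment.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 3:
        raise ShapeError(f"signals must be B x K x T, got shape {signals.shape}")
    b, k, t_len = signals.shape
    wq = quantize_weights(weights, fmt)
    n = weights.n
    x = np.zeros((n, b))
    out = np.empty((b, n, t_len))
    kind = weights.kind
    uq = quantize(signals, fmt)
    for t in range(t_len):
        u = uq[:, :, t].T  # K x B
        if weights.has_center:
            prods = quantize(wq.w_up[:, None] * x, fmt)  # N x B
            acc = np.zeros(b)
            for j in range(n):
                acc = quantize(acc + prods[j], fmt)
            xc = acc  # length B
        else:
            xc = np.zeros(b)
        terms = []
        if k == 1:
            terms.append(quantize(wq.w_in * u, fmt))
        else:
            acc = np.zeros((n, b))
            for ch in range(k):
                acc = quantize(acc + quantize(np.outer(wq.w_in[:, ch], u[ch]), fmt), fmt)
            terms.append(acc)
        if kind in ("one_way_ring", "two_way_ring", "hybrid"):
            terms.append(quantize(wq.w_ring[:, None] * np.roll(x, 1, axis=0), fmt))
        if kind == "two_way_ring":
            terms.append(quantize(wq.w_ring_rev[:, None] * np.roll(x, -1, axis=0), fmt))
        if kind in ("center", "hybrid"):
            terms.append(quantize(wq.w_down[:, None] * xc[None, :], fmt))
        if kind == "random":
            acc = np.zeros((n, b))
            for j in range(n):
                acc = quantize(acc + quantize(np.outer(wq.w_x[:, j], x[j]), fmt), fmt)
            terms.append(acc)
        pre = _quantized_dot(terms, fmt)
        x = quantize((quantize(pwl_tanh(pre), fmt) + x) / 2.0, fmt)
        out[:, :, t] = x.T
    return out[:, :, washout:]
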