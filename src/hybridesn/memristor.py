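"""Semi-empirical memristor model and the crossbar readout layer.

A memristor is a two-terminal device whose conductance depends on an
internal state variable ``gamma`` in [0, 1].  Conduction is tunnelling-
dominated (sinh I-V); the state moves only when the applied voltage
exceeds a positive (``v_tp``) or negative (``v_tn``) threshold, shaped by
a window function that pins gamma inside [0, 1].

The readout layer pairs two memristors per reservoir output — an
excitatory and an inhibitory row — so each column realises a signed
weight ``w = R (G+ - G-)/(G+ + G-)``.  Training applies supra-threshold
voltage pulses to the devices under a stochastic, sign-based
least-mean-squares rule.

Device fitting parameters are configurable; the defaults are placeholders
chosen for smooth monotone switching, not fits to any laboratory device.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np

from ._exceptions import ConfigurationError, InputError, ShapeError
from .esn import StateMatrix

__all__ = [
    "MemristorParams",
    "MemristorState",
    "CrossbarColumn",
    "device_conductance",
    "device_current",
    "device_update",
    "crossbar_weight",
    "readout_voltage",
    "pulse_train_readout",
]


@dataclass(frozen=True)
class MemristorParams:
    """Fitting parameters of the semi-empirical device model.

    ``xi1..xi6`` come in +/- pairs (positive/negative voltage branches);
    ``g_ratio`` is the on/off conductance ratio entering the
    ``(1 - gamma + g gamma)`` prefactor.  Defaults are synthetic
    placeholders giving smooth, monotone switching.
    """

    g_moff: float = 1e-6        # off-state conductance, S
    g_ratio: float = 100.0      # on/off conductance ratio
    v_tp: float = 0.5           # positive threshold, V
    v_tn: float = -0.5          # negative threshold, V
    xi1p: float = 1.0
    xi1n: float = 1.0
    xi2p: float = 1.0
    xi2n: float = 1.0
    xi3p: float = 0.9
    xi3n: float = 0.1
    xi4p: float = 1.0
    xi4n: float = 1.0
    xi5p: float = 2.0
    xi5n: float = 2.0
    xi6p: float = 2.0
    xi6n: float = 2.0

    def __post_init__(self) -> None:
        if not self.v_tp > 0:
            raise ConfigurationError(f"v_tp={self.v_tp} must be > 0")
        if not self.v_tn < 0:
            raise ConfigurationError(f"v_tn={self.v_tn} must be < 0")
        for name in ("g_moff", "g_ratio", "xi1p", "xi1n"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass(frozen=True)
class MemristorState:
    """Internal device state variable, pinned to [0, 1]."""

    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError(f"gamma={self.gamma} must lie in [0, 1]")


def _prefactor(gamma: float, p: MemristorParams) -> float:
    return 1.0 - gamma + p.g_ratio * gamma


def device_conductance(st: MemristorState, p: MemristorParams = MemristorParams()) -> float:
    """Small-signal conductance ``G = (1 - gamma + g gamma) G_moff``.

    Monotone increasing in gamma for g > 1; used to map device states to
    crossbar weights.
    """
    return _prefactor(st.gamma, p) * p.g_moff


def device_current(
    v_m: float, st: MemristorState, p: MemristorParams = MemristorParams()
) -> float:
    """Tunnelling I-V: ``i = (1 - gamma + g gamma) G_moff xi1 sinh(v xi1)``.

    The positive/negative branches use their own ``xi1`` parameter; zero
    voltage gives zero current.
    """
    xi1 = p.xi1p if v_m >= 0 else p.xi1n
    return _prefactor(st.gamma, p) * p.g_moff * xi1 * float(np.sinh(v_m * xi1))


def _window(gamma: float, v_m: float, p: MemristorParams) -> float:
    """Boundary window keeping gamma inside [0, 1]."""
    if v_m >= 0 and gamma >= p.xi3p:
        return float(
            np.exp(-p.xi2p * (gamma - p.xi3p)) * (1.0 - gamma) / (1.0 - p.xi3p)
        )
    if v_m < 0 and gamma <= p.xi3n:
        return float(np.exp(p.xi2n * (gamma - p.xi3n)) * gamma / p.xi3n)
    return 1.0


def state_rate(gamma: float, v_m: float, p: MemristorParams) -> float:
    """State velocity ``d(gamma)/dt`` = 0 between the thresholds."""
    if v_m > p.v_tp:
        return p.xi4p * float(np.sinh(p.xi5p * v_m - p.xi6p * p.v_tp)) * _window(
            gamma, v_m, p
        )
    if v_m < p.v_tn:
        return p.xi4n * float(np.sinh(p.xi5n * v_m - p.xi6n * p.v_tp)) * _window(
            gamma, v_m, p
        )
    return 0.0


def device_update(
    st: MemristorState,
    v_m: float,
    dt: float,
    p: MemristorParams = MemristorParams(),
) -> MemristorState:
    """Forward-Euler state step; the result is clipped to [0, 1].

    Voltages between ``v_tn`` and ``v_tp`` leave the state untouched
    (non-volatile reads).
    """
    if not dt > 0:
        raise ConfigurationError(f"dt={dt} must be > 0")
    gamma = st.gamma + dt * state_rate(st.gamma, v_m, p)
    return MemristorState(gamma=float(np.clip(gamma, 0.0, 1.0)))


@dataclass(frozen=True)
class CrossbarColumn:
    """One signed crossbar weight: an excitatory/inhibitory device pair.

    ``g_plus`` (excitatory, bottom row) and ``g_minus`` (inhibitory, top
    row) are the two conductances; ``r`` is the shared feedback resistance
    of the output amplifier.
    """

    g_plus: float
    g_minus: float
    r: float = 1.0

    def __post_init__(self) -> None:
        if not (self.g_plus > 0 and self.g_minus > 0):
            raise ConfigurationError(
                f"conductances must be > 0, got g_plus={self.g_plus}, "
                f"g_minus={self.g_minus}"
            )


def crossbar_weight(col: CrossbarColumn) -> float:
    """Signed weight ``w = R (G+ - G-)/(G+ + G-)``; |w| < R always."""
    return col.r * (col.g_plus - col.g_minus) / (col.g_plus + col.g_minus)


def readout_voltage(ix: np.ndarray, cols: Sequence[CrossbarColumn]) -> float:
    """Output voltage ``v = sum_j ix_j w_j`` of one crossbar output."""
    ix = np.asarray(ix, dtype=float).ravel()
    if len(cols) != ix.shape[0]:
        raise ShapeError(
            f"{ix.shape[0]} reservoir currents but {len(cols)} crossbar columns"
        )
    w = np.array([crossbar_weight(c) for c in cols])
    return float(ix @ w)


@dataclass
class _TrainableColumn:
    """Device-state view of a column during pulse training."""

    st_plus: MemristorState
    st_minus: MemristorState
    r: float

    def column(self, p: MemristorParams) -> CrossbarColumn:
        return CrossbarColumn(
            g_plus=device_conductance(self.st_plus, p),
            g_minus=device_conductance(self.st_minus, p),
            r=self.r,
        )


def pulse_train_readout(
    sm: StateMatrix,
    targets: np.ndarray,
    cols: Sequence[CrossbarColumn],
    pulse_amplitude: float = 1.0,
    epochs: int = 5,
    seed: int = 0,
    p: MemristorParams = MemristorParams(),
    dt: float = 0.05,
    gate_gain: float = 1.0,
) -> List[CrossbarColumn]:
    """Stochastic least-mean-squares pulse training of one crossbar output.

    Per presented state column, the signed output error picks which row's
    device of each column receives a supra-threshold pulse: a positive
    desired weight change (``sign(error * state_j) > 0``) pulses the
    excitatory device positively, a negative one pulses the inhibitory
    device.  Pulse application is stochastically gated with probability
    proportional to ``|error * state_j|`` (clipped to 1).  All conductance
    change flows through :func:`device_update`; device states therefore
    stay in [0, 1] by construction.

    ``cols`` supplies the initial conductances (inverted to device states)
    and the feedback resistance.  Returns the trained columns.
    """
    if not pulse_amplitude > max(p.v_tp, -p.v_tn):
        raise ConfigurationError(
            f"pulse_amplitude={pulse_amplitude} must exceed both thresholds "
            f"(v_tp={p.v_tp}, |v_tn|={-p.v_tn})"
        )
    x = np.atleast_2d(sm.x_all)
    t = np.asarray(targets, dtype=float).ravel()
    if x.shape[1] != t.shape[0]:
        raise ShapeError(
            f"states have {x.shape[1]} columns but targets have {t.shape[0]}"
        )
    if len(cols) != x.shape[0]:
        raise ShapeError(
            f"states have {x.shape[0]} rows but {len(cols)} crossbar columns"
        )
    rng = np.random.default_rng(seed)
    def _gamma_of(g: float) -> MemristorState:
        # invert G = (1 - gamma + g_ratio gamma) G_moff for the state
        gamma = (g / p.g_moff - 1.0) / (p.g_ratio - 1.0)
        return MemristorState(float(np.clip(gamma, 0.0, 1.0)))

    trainable = [
        _TrainableColumn(
            st_plus=_gamma_of(c.g_plus),
            st_minus=_gamma_of(c.g_minus),
            r=c.r,
        )
        for c in cols
    ]
    x_scale = float(np.max(np.abs(x))) or 1.0
    for _ in range(epochs):
        order = rng.permutation(x.shape[1])
        for idx in order:
            xi = x[:, idx]
            current_cols = [tc.column(p) for tc in trainable]
            out = readout_voltage(xi, current_cols)
            err = t[idx] - out
            if not np.isfinite(err):
                raise InputError(
                    f"non-finite training error at sample {idx}: training aborted"
                )
            if err == 0.0:
                continue
            probs = np.clip(gate_gain * np.abs(err * xi) / x_scale, 0.0, 1.0)
            gates = rng.random(len(trainable)) < probs
            signs = np.sign(err * xi)
            for j, tc in enumerate(trainable):
                if not gates[j] or signs[j] == 0:
                    continue
                if signs[j] > 0:  # weight up: potentiate the excitatory row
                    tc.st_plus = device_update(tc.st_plus, pulse_amplitude, dt, p)
                else:  # weight down: potentiate the inhibitory row
                    tc.st_minus = device_update(tc.st_minus, pulse_amplitude, dt, p)
    return [tc.column(p) for tc in trainable]
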