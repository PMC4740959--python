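"""Echo state network dynamics, readout training, and classification.

The reservoir state update is the leaky discrete-time recurrence

    Xc[n]  = W_up . X[n-1]                                (linear hub state)
    X~[n]  = f( W_in u[n] + W_down Xc[n] + W_ring X[n-1]<<rot>> )
    X[n]   = alpha X~[n] + (1 - alpha) X[n-1]

where ``<<rot>>`` denotes the one-step ring rotation (neuron s reads
neuron s-1) and f is tanh by default.  Only the linear readout is trained,
by the regularised normal equations

    W_out = (Y X^T)(X X^T + ridge I)^{-1}.

Two classification protocols are provided: a per-time-step threshold on a
single output (binary streams, e.g. seizure detection) and per-segment
winner-take-all over the time-averaged outputs (multi-class, e.g. gesture
recognition).

The module-level functions are the primitive surface; :class:`ESNClassifier`
wraps them in a scikit-learn estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._exceptions import ConfigurationError, InputError, ShapeError
from .topology import ReservoirWeights, TopologySpec, build_topology

__all__ = [
    "ESNState",
    "StateMatrix",
    "ReadoutWeights",
    "step",
    "harvest",
    "train_readout",
    "predict",
    "classify_threshold",
    "threshold_accuracy",
    "classify_wta",
    "wta_accuracy",
    "normalized_abs",
    "ESNClassifier",
]


@dataclass
class ESNState:
    """Reservoir activation vector, hub state and time index."""

    x: np.ndarray
    xc: float = 0.0
    t: int = 0

    @classmethod
    def zero(cls, n: int) -> "ESNState":
        return cls(x=np.zeros(n), xc=0.0, t=0)


@dataclass
class StateMatrix:
    """Harvested reservoir states (N x T) and aligned targets (M x T)."""

    x_all: np.ndarray
    y: Optional[np.ndarray] = None


@dataclass
class ReadoutWeights:
    """Trained linear readout, M x N."""

    w_out: np.ndarray


def _preactivation(
    x_prev: np.ndarray, xc: float, u: np.ndarray, weights: ReservoirWeights
) -> np.ndarray:
    kind = weights.kind
    pre = weights.w_in @ u
    if kind in ("one_way_ring", "two_way_ring", "hybrid"):
        pre = pre + weights.w_ring * np.roll(x_prev, 1)
    if kind == "two_way_ring":
        pre = pre + weights.w_ring_rev * np.roll(x_prev, -1)
    if kind in ("center", "hybrid"):
        pre = pre + weights.w_down * xc
    if kind == "random":
        pre = pre + weights.w_x @ x_prev
    return pre


def step(
    state: ESNState,
    u: np.ndarray,
    weights: ReservoirWeights,
    alpha: float = 0.5,
    activation: Callable[[np.ndarray], np.ndarray] = np.tanh,
) -> ESNState:
    """Advance the reservoir one time step.

    The hub state is the unactivated linear sum of the previous reservoir
    state; the leaky blend keeps a fraction ``1 - alpha`` of the previous
    activation.
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigurationError(f"alpha={alpha} must lie in (0, 1]")
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if u.shape[0] != weights.w_in.shape[1]:
        raise ShapeError(
            f"input u has {u.shape[0]} channels but w_in expects "
            f"{weights.w_in.shape[1]}"
        )
    if state.x.shape[0] != weights.n:
        raise ShapeError(
            f"state has {state.x.shape[0]} neurons but weights have {weights.n}"
        )
    xc = float(weights.w_up @ state.x) if weights.has_center else 0.0
    x_new = activation(_preactivation(state.x, xc, u, weights))
    x = alpha * x_new + (1.0 - alpha) * state.x
    return ESNState(x=x, xc=xc, t=state.t + 1)


def harvest(
    signal: np.ndarray,
    weights: ReservoirWeights,
    alpha: float = 0.5,
    activation: Callable[[np.ndarray], np.ndarray] = np.tanh,
    washout: int = 0,
) -> StateMatrix:
    """Run the reservoir over a K x T signal from the zero state.

    The first ``washout`` state columns are discarded.  Deterministic given
    the weights and signal.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    k, t_len = signal.shape
    if t_len == 0:
        raise InputError("empty signal: no time steps to harvest")
    if washout < 0 or washout >= t_len:
        raise InputError(f"washout={washout} must satisfy 0 <= washout < T={t_len}")
    state = ESNState.zero(weights.n)
    cols = np.empty((weights.n, t_len))
    for t in range(t_len):
        state = step(state, signal[:, t], weights, alpha, activation)
        cols[:, t] = state.x
    return StateMatrix(x_all=cols[:, washout:])


def harvest_batch(
    signals: np.ndarray,
    weights: ReservoirWeights,
    alpha: float = 0.5,
    activation: Callable[[np.ndarray], np.ndarray] = np.tanh,
    washout: int = 0,
) -> np.ndarray:
    """Harvest B equal-length segments in parallel.

    ``signals`` is B x K x T; each segment starts from its own zero state.
    Returns a B x N x (T - washout) state array.  Equivalent to calling
    :func:`harvest` per segment, but one vectorised time loop.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 3:
        raise ShapeError(f"signals must be B x K x T, got shape {signals.shape}")
    b, k, t_len = signals.shape
    if t_len == 0:
        raise InputError("empty signal: no time steps to harvest")
    n = weights.n
    x = np.zeros((n, b))
    out = np.empty((b, n, t_len))
    kind = weights.kind
    for t in range(t_len):
        u = signals[:, :, t].T  # K x B
        xc = weights.w_up @ x if weights.has_center else 0.0
        pre = weights.w_in @ u
        if kind in ("one_way_ring", "two_way_ring", "hybrid"):
            pre = pre + weights.w_ring[:, None] * np.roll(x, 1, axis=0)
        if kind == "two_way_ring":
            pre = pre + weights.w_ring_rev[:, None] * np.roll(x, -1, axis=0)
        if kind in ("center", "hybrid"):
            pre = pre + weights.w_down[:, None] * xc
        if kind == "random":
            pre = pre + weights.w_x @ x
        x = alpha * activation(pre) + (1.0 - alpha) * x
        out[:, :, t] = x.T
    return out[:, :, washout:]


def train_readout(sm: StateMatrix, ridge: float = 1e-8) -> ReadoutWeights:
    """Solve the regularised normal equations for the readout weights.

    W_out = (Y X^T)(X X^T + ridge I)^{-1}; with ``ridge=0`` this is the
    plain normal-equation solution and raises if X X^T is singular.
    """
    if sm.y is None:
        raise InputError("StateMatrix has no targets to train on")
    x = np.atleast_2d(sm.x_all)
    y = np.atleast_2d(sm.y)
    if x.shape[1] != y.shape[1]:
        raise ShapeError(
            f"states have {x.shape[1]} columns but targets have {y.shape[1]}"
        )
    if ridge < 0:
        raise ConfigurationError(f"ridge={ridge} must be >= 0")
    n = x.shape[0]
    gram = x @ x.T
    if ridge > 0:
        gram = gram + ridge * np.eye(n)
    try:
        # solve G^T W^T = X Y^T  (G symmetric)
        w_out = scipy.linalg.solve(gram, x @ y.T, assume_a="sym").T
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "X X^T is singular with ridge=0; pass ridge > 0 to regularise"
        ) from exc
    if not np.all(np.isfinite(w_out)):
        raise np.linalg.LinAlgError(
            "non-finite readout solution (X X^T nearly singular); "
            "pass ridge > 0 to regularise"
        )
    return ReadoutWeights(w_out=w_out)


def predict(w: ReadoutWeights, sm: StateMatrix) -> np.ndarray:
    """Linear readout y = W_out X (identity output activation)."""
    x = np.atleast_2d(sm.x_all)
    if w.w_out.shape[1] != x.shape[0]:
        raise ShapeError(
            f"w_out has {w.w_out.shape[1]} columns but states have {x.shape[0]} rows"
        )
    return w.w_out @ x


def classify_threshold(y: np.ndarray, thr: float = 0.5) -> np.ndarray:
    """Per-time-step binary labels: 1 where the output is >= ``thr``."""
    y = np.asarray(y).ravel()
    return (y >= thr).astype(int)


def threshold_accuracy(y: np.ndarray, reference: np.ndarray, thr: float = 0.5) -> float:
    """Fraction of time steps at which the thresholded output is correct."""
    labels = classify_threshold(y, thr)
    reference = np.asarray(reference).ravel().astype(int)
    if labels.shape != reference.shape:
        raise ShapeError(
            f"output track length {labels.shape[0]} != reference {reference.shape[0]}"
        )
    return float(np.mean(labels == reference))


def classify_wta(
    y: np.ndarray, segment_bounds: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Winner-take-all labels, one per segment.

    For each ``(start, stop)`` segment the label is the output row with the
    largest time-averaged response; ties go to the lowest row index
    (``argmax`` convention).
    """
    y = np.atleast_2d(y)
    if y.shape[0] < 2:
        raise ConfigurationError("winner-take-all needs at least 2 output rows")
    labels = np.empty(len(segment_bounds), dtype=int)
    for i, (start, stop) in enumerate(segment_bounds):
        if stop <= start:
            raise InputError(f"empty segment ({start}, {stop}) at index {i}")
        labels[i] = int(np.argmax(y[:, start:stop].mean(axis=1)))
    return labels


def wta_accuracy(
    y: np.ndarray,
    segment_bounds: Sequence[tuple[int, int]],
    reference: Sequence[int],
) -> float:
    """Fraction of segments whose winner-take-all label is correct."""
    labels = classify_wta(y, segment_bounds)
    reference = np.asarray(reference, dtype=int)
    return float(np.mean(labels == reference))


def normalized_abs(signal: np.ndarray, scale: Optional[float] = None):
    """Rectify-and-normalise preprocessing for EEG-style streams.

    Returns ``(|signal| / scale, scale)`` where ``scale`` defaults to the
    maximum absolute value of the signal (compute it on the training split
    and reuse on test data).
    """
    signal = np.asarray(signal, dtype=float)
    if scale is None:
        scale = float(np.max(np.abs(signal)))
        if scale == 0.0:
            scale = 1.0
    return np.abs(signal) / scale, scale


class ESNClassifier(BaseEstimator, ClassifierMixin):
    """Echo state network segment classifier in scikit-learn form.

    Each training sample is a ``(channels, samples)`` segment with a single
    class label; ``X`` is a ``(n_segments, channels, samples)`` array (or a
    list of equal-shaped segments).  The reservoir is built once from the
    chosen topology, every segment is harvested from a zero initial state,
    and a one-hot (or binary) linear readout is trained by ridge-regularised
    normal equations.

    Parameters
    ----------
    topology : str, default "hybrid"
        Reservoir interconnect kind (see :mod:`hybridesn.topology`).
    n_reservoir : int, default 100
        Number of reservoir neurons.
    alpha : float, default 0.5
        Leak rate of the state update.
    ridge : float, default 1e-8
        Normal-equation regulariser.
    washout : int, default 0
        Initial state columns discarded per segment.
    decision : {"wta", "threshold"}, default "wta"
        Segment decision rule. ``wta`` picks the class with the largest
        time-averaged output; ``threshold`` (binary only) thresholds the
        single output and takes the majority time step.
    threshold : float, default 0.5
        Decision threshold for the binary protocol.
    mode : {"ideal", "digital"}, default "ideal"
        ``digital`` runs the fixed-point datapath emulation (piecewise-
        linear tanh, quantised arithmetic, alpha = 0.5 shift blend).
    fixed_point : FixedPointFormat or None
        Number format for digital mode (default Q(10.20)).
    weight_law : str, default "uniform_pm1"
        Distribution of the frozen random weights.
    weight_scale : float, default 1.0
        Law parameter (half-width / sigma).
    connectivity : float, default 0.5
        Link density of the random topology.
    random_state : int, default 0
        Seed for the weight draw.

    Attributes
    ----------
    weights_ : ReservoirWeights
        The frozen reservoir built at fit time.
    readout_ : ReadoutWeights
        Trained readout matrix (n_classes x n_reservoir).
    classes_ : ndarray
        Sorted class labels.
    """

    def __init__(
        self,
        topology: str = "hybrid",
        n_reservoir: int = 100,
        alpha: float = 0.5,
        ridge: float = 1e-8,
        washout: int = 0,
        decision: str = "wta",
        threshold: float = 0.5,
        mode: str = "ideal",
        fixed_point=None,
        weight_law: str = "uniform_pm1",
        weight_scale: float = 1.0,
        connectivity: float = 0.5,
        random_state: int = 0,
    ):
        self.topology = topology
        self.n_reservoir = n_reservoir
        self.alpha = alpha
        self.ridge = ridge
        self.washout = washout
        self.decision = decision
        self.threshold = threshold
        self.mode = mode
        self.fixed_point = fixed_point
        self.weight_law = weight_law
        self.weight_scale = weight_scale
        self.connectivity = connectivity
        self.random_state = random_state

    # -- internal ----------------------------------------------------------

    def _as_segments(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:  # single-channel segments
            X = X[:, None, :]
        if X.ndim != 3:
            raise ShapeError(
                f"X must be (n_segments, channels, samples); got shape {X.shape}"
            )
        return X

    def _harvest(self, X: np.ndarray) -> np.ndarray:
        if self.mode == "digital":
            from .digital import FixedPointFormat, digital_harvest_batch

            fmt = self.fixed_point or FixedPointFormat()
            return digital_harvest_batch(X, self.weights_, fmt, washout=self.washout)
        if self.mode != "ideal":
            raise ConfigurationError(f"mode={self.mode!r} is not 'ideal' or 'digital'")
        return harvest_batch(
            X, self.weights_, alpha=self.alpha, washout=self.washout
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = self._as_segments(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ShapeError(
                f"{X.shape[0]} segments but {y.shape[0]} labels"
            )
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise InputError("need at least two classes to fit a classifier")
        if self.decision == "threshold" and n_classes != 2:
            raise ConfigurationError(
                "decision='threshold' is a binary protocol; "
                f"got {n_classes} classes"
            )
        spec = TopologySpec(
            kind=self.topology,
            n=self.n_reservoir,
            k=X.shape[1],
            m=1 if self.decision == "threshold" else n_classes,
            connectivity=self.connectivity,
            weight_law=self.weight_law,
            weight_scale=self.weight_scale,
            seed=self.random_state,
        )
        self.weights_ = build_topology(spec)

        states = self._harvest(X)  # B x N x T'
        b, n, t_eff = states.shape
        x_all = np.concatenate([states[i] for i in range(b)], axis=1)
        if self.decision == "threshold":
            targets = np.repeat(y_idx.astype(float), t_eff)[None, :]
        else:
            targets = np.zeros((n_classes, b * t_eff))
            for i, ci in enumerate(y_idx):
                targets[ci, i * t_eff : (i + 1) * t_eff] = 1.0
        self.readout_ = train_readout(StateMatrix(x_all, targets), ridge=self.ridge)
        return self

    def predict_timeseries(self, X) -> np.ndarray:
        """Raw readout traces, (n_segments, n_outputs, samples - washout)."""
        check_is_fitted(self, "readout_")
        X = self._as_segments(X)
        states = self._harvest(X)
        return np.einsum("mn,bnt->bmt", self.readout_.w_out, states)

    def decision_function(self, X) -> np.ndarray:
        """Time-averaged output per segment, (n_segments, n_outputs)."""
        return self.predict_timeseries(X).mean(axis=2)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "readout_")
        scores = self.decision_function(X)
        if self.decision == "threshold":
            traces = self.predict_timeseries(X)[:, 0, :]
            frac_high = (traces >= self.threshold).mean(axis=1)
            idx = (frac_high >= 0.5).astype(int)  # majority of time steps
        else:
            idx = np.argmax(scores, axis=1)
        return self.classes_[idx]

    def timestep_score(self, X, y) -> float:
        """Per-time-step threshold accuracy over the concatenated segments.

        Binary protocol only: every time step of every segment is compared
        against the segment's label.
        """
        check_is_fitted(self, "readout_")
        if self.decision != "threshold":
            raise ConfigurationError("timestep_score applies to decision='threshold'")
        X = self._as_segments(X)
        lookup = np.searchsorted(self.classes_, np.asarray(y))
        traces = self.predict_timeseries(X)[:, 0, :]
        ref = np.repeat(lookup, traces.shape[1])
        return threshold_accuracy(traces.ravel(), ref, self.threshold)
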