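"""Reservoir-quality metrics: kernel quality and a Lyapunov-style exponent.

Kernel quality is the numerical rank of the matrix whose columns are the
reservoir responses to a set of input cases; it measures how many linearly
independent directions the reservoir offers the readout (ideally the
reservoir size).

The Lyapunov-style exponent compares state-space to input-space
nearest-neighbour distances,

    lambda = k * sum_j ln( ||x_j - x_jhat|| / ||u_j - u_jhat|| ),

where u_jhat is the nearest distinct input to u_j and x_jhat the matching
reservoir response.  Positive values indicate chaotic expansion, negative
values contraction; zero marks the edge of chaos where reservoirs tend to
perform best.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._exceptions import InputError

__all__ = ["MetricReport", "kernel_quality", "lyapunov_exponent"]


@dataclass(frozen=True)
class MetricReport:
    """Bundle of reservoir-quality numbers for one evaluation set."""

    kernel_quality: int
    lyapunov: float
    n_cases: int
    k_scale: float = 1.0


def kernel_quality(states: np.ndarray, tol: Optional[float] = None) -> int:
    """Numerical rank of the N x m state matrix.

    Singular values above ``tol * sigma_max`` are counted; ``tol`` defaults
    to the standard machine-epsilon rule scaled by the larger matrix
    dimension.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.size == 0:
        raise InputError("empty state matrix has no rank")
    if not np.any(states):
        return 0
    sv = np.linalg.svd(states, compute_uv=False)
    if tol is None:
        tol = max(states.shape) * np.finfo(float).eps
    return int(np.sum(sv > tol * sv[0]))


def lyapunov_exponent(
    inputs: Sequence[np.ndarray],
    states: Sequence[np.ndarray],
    k_scale: float = 1.0,
) -> float:
    """Sum of log state/input nearest-neighbour distance ratios.

    For each case j the nearest neighbour is the distinct input minimising
    Euclidean distance (ties resolved toward the lowest index).  Exactly
    duplicated inputs make the ratio undefined and raise ``InputError``
    naming the offending indices.
    """
    u = np.stack([np.asarray(v, dtype=float).ravel() for v in inputs])
    x = np.stack([np.asarray(v, dtype=float).ravel() for v in states])
    if u.shape[0] != x.shape[0]:
        raise InputError(
            f"{u.shape[0]} inputs but {x.shape[0]} states; cases must pair up"
        )
    n = u.shape[0]
    if n < 2:
        raise InputError("need at least 2 cases for nearest-neighbour ratios")
    # pairwise input distances; diagonal masked out of the argmin
    d_u = np.linalg.norm(u[:, None, :] - u[None, :, :], axis=2)
    np.fill_diagonal(d_u, np.inf)
    nn = np.argmin(d_u, axis=1)  # argmin takes the lowest index on ties
    d_min = d_u[np.arange(n), nn]
    dup = np.nonzero(d_min == 0.0)[0]
    if dup.size:
        pairs = [(int(j), int(nn[j])) for j in dup]
        raise InputError(f"exactly duplicated input vectors at index pairs {pairs}")
    d_x = np.linalg.norm(x - x[nn], axis=1)
    return float(k_scale * np.sum(np.log(d_x / d_min)))
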