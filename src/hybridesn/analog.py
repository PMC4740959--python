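"""Analog (subthreshold mixed-signal) device models and cost reports.

The analog realisation of the reservoir uses current-mode subthreshold
circuits:

* the neuron is a differential pair whose output current follows
  ``I_max * tanh(i_s * R_in / (2 n V_T))`` — tanh for free;
* synapse weights come from threshold-voltage mismatch in current mirrors.
  A mirror's gain error is ``exp(dVth / (n V_T))`` with
  ``dVth ~ N(0, A_Vth^2 / (W L))`` (Pelgrom scaling), so weight magnitudes
  are lognormal with ``sigma_ln = A_Vth / (sqrt(W L) n V_T)``;
* the readout is a memristor crossbar (see :mod:`hybridesn.memristor`).

Alongside the device models this module carries the closed-form area and
power cost models used to compare reservoir topologies.

All quantities are SI (amperes, volts, metres, watts) unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from ._exceptions import ConfigurationError
from .topology import TopologySpec

__all__ = [
    "ProcessParams",
    "SynapseSample",
    "BaselineWeightSpec",
    "neuron_transfer",
    "mismatch_sigma_ln",
    "sample_mismatch_synapses",
    "synapse_output",
    "baseline_synapse_area",
    "proposed_synapse_area",
    "synapse_power",
    "area_report",
    "power_report",
]


@dataclass(frozen=True)
class ProcessParams:
    """Subthreshold/mismatch process constants.

    Defaults follow a 45 nm low-power predictive technology model:
    ``i_max`` 1 nA, thermal voltage 26 mV, subthreshold slope constant 1.2,
    Pelgrom mismatch coefficient ``a_vth`` 4 mV*um, minimal device
    45 nm x 45 nm, matched-device area 20250 nm^2 (10x minimal sizing),
    0.55 V supply (V_SS = V_DD), activity factor 0.5, 0.1 uA opamp bias.
    ``area_ratio`` is a = A_var / A_match in (0, 1], the sizing of the
    mismatch mirrors relative to the matched device.
    """

    i_max: float = 1e-9            # A
    v_t: float = 0.026             # V
    n: float = 1.2
    a_vth: float = 4e-3 * 1e-6     # V*m  (4 mV*um)
    w: float = 45e-9               # m
    l: float = 45e-9               # m
    a_match: float = 20250e-18     # m^2  (20250 nm^2)
    v_dd: float = 0.55             # V
    eta: float = 0.5
    i_bias: float = 0.1e-6         # A
    r_in: float = 1e8              # ohm, neuron input resistance
    area_ratio: float = 1.0        # a = A_var / A_match
    r1: float = 1.0                # nominal NMOS mirror ratio
    r2: float = 1.0                # nominal PMOS mirror ratio

    def __post_init__(self) -> None:
        positive = {
            "i_max": self.i_max, "v_t": self.v_t, "n": self.n,
            "a_vth": self.a_vth, "w": self.w, "l": self.l,
            "a_match": self.a_match, "v_dd": self.v_dd,
            "i_bias": self.i_bias, "r_in": self.r_in,
            "area_ratio": self.area_ratio, "r1": self.r1, "r2": self.r2,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigurationError(f"ProcessParams.{name}={value} must be > 0")
        if self.area_ratio > 1.0:
            raise ConfigurationError(
                f"ProcessParams.area_ratio={self.area_ratio} must be <= 1"
            )
        if not 0 <= self.eta <= 1:
            raise ConfigurationError(f"ProcessParams.eta={self.eta} must be in [0,1]")


@dataclass(frozen=True)
class SynapseSample:
    """One mismatch-synapse draw.

    ``w1`` (NMOS mirror gain) and ``w2`` (PMOS mirror gain) are lognormal
    and strictly positive; the effective signed weight is ``w = w1/2`` and
    the bias is ``b = w2 - w1/2``; ``sign`` records the random input
    polarity connection.
    """

    w1: float
    w2: float
    sign: int = 1

    @property
    def w(self) -> float:
        return 0.5 * self.w1

    @property
    def b(self) -> float:
        return self.w2 - 0.5 * self.w1


@dataclass(frozen=True)
class BaselineWeightSpec:
    """Discrete weight grid of the deterministic (geometry-ratio) synapse.

    Weights are multiples ``k * w_res`` with k >= 1; ``distribution``
    selects how k is distributed: ``uniform_pm1`` (|w| uniform over the
    grid in (0, 1]), ``normal`` (w ~ N(0, 0.1) rounded to the grid) or
    ``lognormal`` (|w| ~ lnN(0, 2.85) rounded to the grid).
    """

    w_res: float = 1.0 / 100.0
    distribution: str = "uniform_pm1"
    sigma: Optional[float] = None  # overrides the distribution default

    def __post_init__(self) -> None:
        inv = 1.0 / self.w_res
        if abs(inv - round(inv)) > 1e-9:
            raise ConfigurationError(
                f"w_res={self.w_res} must be a unit fraction (1/integer)"
            )
        if self.distribution not in ("uniform_pm1", "normal", "lognormal"):
            raise ConfigurationError(
                f"distribution={self.distribution!r} not recognised"
            )


def neuron_transfer(i_s: np.ndarray, p: ProcessParams = ProcessParams()) -> np.ndarray:
    """Differential output current of the subthreshold tanh neuron.

    ``i_x = I_max * tanh(i_s * R_in / (2 n V_T))``; saturates below I_max
    in magnitude for any finite input.
    """
    i_s = np.asarray(i_s, dtype=float)
    return p.i_max * np.tanh(i_s * p.r_in / (2.0 * p.n * p.v_t))


def mismatch_sigma_ln(p: ProcessParams = ProcessParams()) -> float:
    """Standard deviation of ln(weight) from threshold-voltage mismatch.

    ``sigma = A_Vth / (sqrt(W L) * n * V_T)``.  At minimal 45 nm sizing
    with the default constants this evaluates to ~2.85.
    """
    return p.a_vth / (math.sqrt(p.w * p.l) * p.n * p.v_t)


def sample_mismatch_synapses(
    count: int,
    p: ProcessParams = ProcessParams(),
    seed: int = 0,
) -> List[SynapseSample]:
    """Monte Carlo draw of mismatch synapses.

    Each mirror gets an independent threshold-voltage offset
    ``dVth ~ N(0, A_Vth^2/(W L))``; the mirror gains are
    ``w1 = r1 exp(dVth1/(n V_T))`` and ``w2 = r2 exp(dVth2/(n V_T))``, so
    ``ln w1`` has standard deviation :func:`mismatch_sigma_ln`.  Input
    polarity is +/-1 with probability 1/2 each.
    """
    if count < 1:
        raise ConfigurationError(f"count={count} must be >= 1")
    rng = np.random.default_rng(seed)
    sigma_v = p.a_vth / math.sqrt(p.w * p.l)
    dv1 = rng.normal(0.0, sigma_v, size=count)
    dv2 = rng.normal(0.0, sigma_v, size=count)
    w1 = p.r1 * np.exp(dv1 / (p.n * p.v_t))
    w2 = p.r2 * np.exp(dv2 / (p.n * p.v_t))
    signs = rng.choice([-1, 1], size=count)
    return [
        SynapseSample(w1=float(a), w2=float(b), sign=int(s))
        for a, b, s in zip(w1, w2, signs)
    ]


def synapse_output(
    ix_plus: float,
    ix_minus: float,
    s: SynapseSample,
    p: ProcessParams = ProcessParams(),
) -> float:
    """Output current of the mismatch synapse.

    ``i_s = w2 I_max - w1 ix_minus``, which for a complementary pair
    (``ix_plus + ix_minus = I_max``) equals
    ``(ix_plus - ix_minus) * w1/2 + I_max * b``.
    """
    if abs(ix_plus + ix_minus - p.i_max) > 1e-6 * p.i_max:
        raise ConfigurationError(
            f"ix_plus + ix_minus = {ix_plus + ix_minus!r} must equal "
            f"I_max = {p.i_max!r} (complementary differential pair)"
        )
    return s.w2 * p.i_max - s.w1 * ix_minus


def _k_distribution(spec: BaselineWeightSpec, k_max_mult: float = 8.0):
    """Probability mass over the multiplier k >= 1 for the baseline grid."""
    import scipy.stats

    inv = int(round(1.0 / spec.w_res))
    if spec.distribution == "uniform_pm1":
        ks = np.arange(1, inv + 1)
        pmf = np.full(inv, 1.0 / inv)
        return ks, pmf
    if spec.distribution == "normal":
        sigma = spec.sigma if spec.sigma is not None else 0.1
        dist = scipy.stats.halfnorm(scale=sigma)
    else:  # lognormal magnitudes
        sigma = spec.sigma if spec.sigma is not None else 2.85
        dist = scipy.stats.lognorm(s=sigma)
    hi = dist.ppf(0.9999)
    k_hi = max(1, int(math.ceil(hi / spec.w_res)))
    ks = np.arange(1, k_hi + 1)
    # |w| rounded to the nearest grid point k*w_res, with k clipped to >= 1
    edges = (ks + 0.5) * spec.w_res
    cdf = dist.cdf(edges)
    pmf = np.diff(np.concatenate([[0.0], cdf]))
    pmf[-1] += 1.0 - cdf[-1]
    pmf /= pmf.sum()
    return ks, pmf


def baseline_synapse_area(
    spec: BaselineWeightSpec, p: ProcessParams = ProcessParams()
) -> float:
    """Expected area of the deterministic geometry-ratio synapse.

    ``E[A] = 2 A_match E[k / gcd(1/w_res, k)]``: the mirror input device
    needs area ``(1/w_res)/gcd * A_match`` and the output device
    ``k/gcd * A_match`` — after reducing the ratio k : 1/w_res — but the
    expectation as printed tracks the output-device multiple, with the
    2 A_match floor from the two-MOSFET minimum.
    """
    inv = int(round(1.0 / spec.w_res))
    ks, pmf = _k_distribution(spec)
    mult = np.array([k // math.gcd(inv, int(k)) for k in ks], dtype=float)
    area = 2.0 * p.a_match * float(np.sum(mult * pmf))
    return max(area, 2.0 * p.a_match)


def proposed_synapse_area(p: ProcessParams = ProcessParams()) -> float:
    """Area of the mismatch synapse: ``A_match (2 + 4a)``, at most 6 A_match."""
    return p.a_match * (2.0 + 4.0 * p.area_ratio)


def _counts(spec: TopologySpec) -> dict:
    """Neuron and synapse counts used by the cost models.

    Synapse counts are deterministic per topology; the random kind uses the
    expected count ``connectivity * N^2`` (self-loops excluded at build
    time are a negligible N-order correction deliberately retained here as
    ``connectivity * N * N`` to match the expected-count contract).
    """
    n, k = spec.n, spec.k
    neurons = n + (1 if spec.kind in ("center", "hybrid") else 0)
    input_syn = n * k
    if spec.kind == "one_way_ring":
        recur = n
    elif spec.kind == "two_way_ring":
        recur = 2 * n
    elif spec.kind == "center":
        recur = 2 * n
    elif spec.kind == "hybrid":
        recur = 3 * n
    else:  # random
        recur = spec.connectivity * n * n
    return {"neurons": neurons, "synapses": input_syn + recur}


def area_report(
    spec: TopologySpec, p: ProcessParams = ProcessParams()
) -> dict:
    """Per-block and total silicon area of the analog reservoir (m^2).

    Neurons cost ``5 A_match`` each, mismatch synapses ``A_match (2+4a)``
    each, and the crossbar readout ``(N M + 9) A_match`` (N inputs times M
    outputs plus a seven-transistor opamp allowance).
    """
    c = _counts(spec)
    a_neuron = 5.0 * p.a_match
    a_syn = proposed_synapse_area(p)
    a_out = (spec.n * spec.m + 9.0) * p.a_match
    return {
        "neuron_each": a_neuron,
        "synapse_each": a_syn,
        "neurons_total": c["neurons"] * a_neuron,
        "synapses_total": c["synapses"] * a_syn,
        "output_layer": a_out,
        "total": c["neurons"] * a_neuron + c["synapses"] * a_syn + a_out,
        "n_neurons": c["neurons"],
        "n_synapses": c["synapses"],
    }


def synapse_power(s: SynapseSample, p: ProcessParams = ProcessParams()) -> float:
    """Static power of one mismatch synapse.

    ``P = V_DD I_max (2 eta + eta w1 + w2 + 2)``.
    """
    return p.v_dd * p.i_max * (2.0 * p.eta + p.eta * s.w1 + s.w2 + 2.0)


def power_report(
    spec: TopologySpec,
    p: ProcessParams = ProcessParams(),
    samples: Optional[Sequence[SynapseSample]] = None,
    mode: str = "median",
) -> dict:
    """Per-block and total static power of the analog reservoir (W).

    Neurons dissipate ``I_max V_DD`` each; synapses follow
    :func:`synapse_power` evaluated either at the distribution medians
    (``mode='median'``: w1 = r1, w2 = r2, the lognormal medians) or per
    Monte Carlo sample (``mode='per_sample'``, one sample per synapse);
    the readout costs ``eta N M I_max V_DD + 2 M I_bias V_DD``.
    """
    c = _counts(spec)
    p_neuron = p.i_max * p.v_dd
    if mode == "median":
        p_syn_total = c["synapses"] * synapse_power(
            SynapseSample(w1=p.r1, w2=p.r2), p
        )
    elif mode == "per_sample":
        if samples is None:
            raise ConfigurationError("per_sample mode requires synapse samples")
        n_syn = int(round(c["synapses"]))
        if len(samples) < n_syn:
            raise ConfigurationError(
                f"need {n_syn} samples (one per synapse), got {len(samples)}"
            )
        p_syn_total = float(sum(synapse_power(s, p) for s in samples[:n_syn]))
    else:
        raise ConfigurationError(f"mode={mode!r} is not 'median' or 'per_sample'")
    p_out = p.eta * spec.n * spec.m * p.i_max * p.v_dd + 2.0 * spec.m * p.i_bias * p.v_dd
    return {
        "neuron_each": p_neuron,
        "neurons_total": c["neurons"] * p_neuron,
        "synapses_total": p_syn_total,
        "output_layer": p_out,
        "total": c["neurons"] * p_neuron + p_syn_total + p_out,
        "n_neurons": c["neurons"],
        "n_synapses": c["synapses"],
        "mode": mode,
    }
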