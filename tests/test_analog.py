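"""Subthreshold neuron, mismatch synapse statistics, and cost models."""

import math

import numpy as np
import pytest
import scipy.stats

from hybridesn._exceptions import ConfigurationError
from hybridesn.analog import (
    BaselineWeightSpec,
    ProcessParams,
    SynapseSample,
    area_report,
    baseline_synapse_area,
    mismatch_sigma_ln,
    neuron_transfer,
    power_report,
    proposed_synapse_area,
    sample_mismatch_synapses,
    synapse_output,
    synapse_power,
)
from hybridesn.topology import TopologySpec

P = ProcessParams()


class TestNeuronTransfer:
    def test_zero_input_zero_output(self):
        assert neuron_transfer(0.0, P) == 0.0

    def test_saturates_to_imax(self):
        assert neuron_transfer(1.0, P) == pytest.approx(P.i_max)

    def test_closed_form_at_unity_argument(self):
        i_s = 2.0 * P.n * P.v_t / P.r_in  # makes the tanh argument exactly 1
        assert neuron_transfer(i_s, P) == pytest.approx(P.i_max * math.tanh(1.0))

    def test_magnitude_strictly_below_imax_and_odd(self):
        i = np.linspace(-1e-8, 1e-8, 201)  # pre-saturation argument range
        out = neuron_transfer(i, P)
        assert np.all(np.abs(out) < P.i_max)
        assert np.allclose(out, -neuron_transfer(-i, P))


class TestMismatchSampling:
    def test_analytic_sigma_at_minimal_sizing_is_2p85(self):
        assert mismatch_sigma_ln(P) == pytest.approx(2.85, abs=0.005)

    def test_empirical_std_within_5_percent_of_analytic(self):
        samples = sample_mismatch_synapses(10_000, P, seed=42)
        emp = np.std(np.log([s.w1 for s in samples]))
        assert emp == pytest.approx(mismatch_sigma_ln(P), rel=0.05)

    def test_large_area_kills_the_variance(self):
        big = ProcessParams(w=45e-6, l=45e-6)  # 1000x linear sizing
        samples = sample_mismatch_synapses(500, big, seed=0)
        w1 = np.array([s.w1 for s in samples])
        assert np.allclose(w1, big.r1, rtol=5e-2)  # sigma shrinks 1000-fold

    def test_sigma_scales_as_inverse_sqrt_area(self):
        sigmas = []
        for mult in (1, 2, 4, 8):
            p = ProcessParams(w=45e-9 * mult, l=45e-9 * mult)
            sigmas.append(mismatch_sigma_ln(p))
        for i, mult in enumerate((1, 2, 4, 8)):
            assert sigmas[i] == pytest.approx(sigmas[0] / mult)

    def test_magnitudes_fit_lognormal_distribution(self):
        """Goodness of fit of |w| = w1/2 against lognormal(ln r1 - ln 2,
        sigma^2) via Kolmogorov-Smirnov at alpha = 0.01."""
        samples = sample_mismatch_synapses(10_000, P, seed=7)
        w = np.array([s.w for s in samples])
        sigma = mismatch_sigma_ln(P)
        stat, pval = scipy.stats.kstest(
            np.log(w), scipy.stats.norm(loc=math.log(P.r1 / 2.0), scale=sigma).cdf
        )
        assert pval > 0.01

    def test_signs_are_balanced(self):
        samples = sample_mismatch_synapses(4000, P, seed=3)
        frac = np.mean([s.sign > 0 for s in samples])
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_w1_w2_strictly_positive(self):
        samples = sample_mismatch_synapses(2000, P, seed=1)
        assert all(s.w1 > 0 and s.w2 > 0 for s in samples)

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            ProcessParams(w=0.0)


class TestSynapseOutput:
    def test_unity_mirrors_at_balance_pass_half_imax(self):
        s = SynapseSample(w1=1.0, w2=1.0)
        out = synapse_output(P.i_max / 2, P.i_max / 2, s, P)
        assert out == pytest.approx(P.i_max / 2)

    def test_zero_bias_zero_differential_gives_zero(self):
        s = SynapseSample(w1=1.0, w2=0.5)  # b = w2 - w1/2 = 0
        assert s.b == pytest.approx(0.0)
        out = synapse_output(P.i_max / 2, P.i_max / 2, s, P)
        assert out == pytest.approx(0.0, abs=1e-21)

    def test_two_algebraic_forms_agree(self, rng):
        """i_s = w2 I - w1 ix_minus  ==  (ix+ - ix-) w1/2 + I b."""
        for _ in range(1000):
            s = SynapseSample(w1=rng.lognormal(0, 1), w2=rng.lognormal(0, 1))
            ix_minus = rng.uniform(0, P.i_max)
            ix_plus = P.i_max - ix_minus
            lhs = synapse_output(ix_plus, ix_minus, s, P)
            rhs = (ix_plus - ix_minus) * s.w1 / 2.0 + P.i_max * s.b
            assert lhs == pytest.approx(rhs, abs=1e-12 * P.i_max)

    def test_complementarity_contract_enforced(self):
        s = SynapseSample(w1=1.0, w2=1.0)
        with pytest.raises(ConfigurationError):
            synapse_output(P.i_max, P.i_max, s, P)


class TestBaselineArea:
    def test_never_below_two_amatch(self):
        for wres in (1.0, 0.5, 0.125, 0.01):
            for dist in ("uniform_pm1", "normal", "lognormal"):
                spec = BaselineWeightSpec(w_res=wres, distribution=dist)
                assert baseline_synapse_area(spec, P) >= 2.0 * P.a_match - 1e-30

    def test_unit_resolution_gives_exactly_two_amatch(self):
        spec = BaselineWeightSpec(w_res=1.0)
        assert baseline_synapse_area(spec, P) == pytest.approx(2.0 * P.a_match)

    def test_uniform_grid_matches_enumeration_oracle(self):
        """Brute-force oracle: enumerate every k, reduce k/gcd(1/w_res, k),
        average uniformly."""
        wres = 1.0 / 8.0
        expected = 2.0 * P.a_match * np.mean(
            [k / math.gcd(8, k) for k in range(1, 9)]
        )
        spec = BaselineWeightSpec(w_res=wres)
        assert baseline_synapse_area(spec, P) == pytest.approx(expected)

    def test_non_unit_fraction_resolution_rejected(self):
        with pytest.raises(ConfigurationError):
            BaselineWeightSpec(w_res=0.3)


class TestAreaReport:
    def test_amatch_default_is_20250_nm2(self):
        assert P.a_match == pytest.approx(20250e-18)

    def test_proposed_synapse_max_area_is_6_amatch(self):
        assert proposed_synapse_area(P) == pytest.approx(6.0 * P.a_match)

    def test_neuron_area_is_5_amatch(self):
        spec = TopologySpec(kind="hybrid", n=10)
        rep = area_report(spec, P)
        assert rep["neuron_each"] == pytest.approx(5.0 * P.a_match)

    def test_output_layer_area_formula(self):
        spec = TopologySpec(kind="hybrid", n=30, m=5)
        rep = area_report(spec, P)
        assert rep["output_layer"] == pytest.approx((30 * 5 + 9) * P.a_match)

    def test_total_sums_blocks(self):
        spec = TopologySpec(kind="one_way_ring", n=12)
        rep = area_report(spec, P)
        assert rep["total"] == pytest.approx(
            rep["neurons_total"] + rep["synapses_total"] + rep["output_layer"]
        )


class TestPowerReport:
    def test_zero_imax_means_zero_power(self):
        p0 = ProcessParams(i_max=1e-30, i_bias=1e-30)  # limit of vanishing currents
        rep = power_report(TopologySpec(kind="hybrid", n=10), p0)
        assert rep["total"] < 1e-25

    def test_single_neuron_power_is_imax_vdd(self):
        rep = power_report(TopologySpec(kind="one_way_ring", n=2), P)
        assert rep["neuron_each"] == pytest.approx(0.55e-9)

    def test_median_synapse_power_hand_value(self):
        # w1 = w2 = 1, eta = 0.5: 0.55 nW * (1 + 0.5 + 1 + 2) = 2.475 nW
        assert synapse_power(SynapseSample(1.0, 1.0), P) == pytest.approx(2.475e-9)

    def test_per_sample_mode_uses_each_draw(self):
        spec = TopologySpec(kind="one_way_ring", n=3)
        samples = sample_mismatch_synapses(6, P, seed=0)
        rep = power_report(spec, P, samples=samples, mode="per_sample")
        expected = sum(synapse_power(s, P) for s in samples[:6])
        assert rep["synapses_total"] == pytest.approx(expected)

    def test_median_power_affine_in_n_for_ring_and_hybrid(self):
        """Ring/hybrid totals are exactly affine in N (zero residual on a
        linear fit); the random topology grows quadratically."""
        sizes = np.array([10, 20, 40, 80])
        for kind in ("one_way_ring", "two_way_ring", "hybrid"):
            totals = np.array([
                power_report(TopologySpec(kind=kind, n=int(n)), P)["total"]
                for n in sizes
            ])
            coef = np.polyfit(sizes, totals, 1)
            resid = totals - np.polyval(coef, sizes)
            assert np.max(np.abs(resid)) < 1e-12 * totals.max()

    def test_random_power_is_quadratic_in_n(self):
        sizes = np.array([10, 20, 40, 80])
        totals = np.array([
            power_report(
                TopologySpec(kind="random", n=int(n), connectivity=0.5), P
            )["total"]
            for n in sizes
        ])
        lin = np.polyfit(sizes, totals, 1)
        assert np.max(np.abs(totals - np.polyval(lin, sizes))) > 1e-3 * totals.max()
        quad = np.polyfit(sizes, totals, 2)
        resid = totals - np.polyval(quad, sizes)
        assert np.max(np.abs(resid)) < 1e-12 * totals.max()

    def test_per_sample_requires_enough_samples(self):
        spec = TopologySpec(kind="hybrid", n=10)
        with pytest.raises(ConfigurationError):
            power_report(spec, P, samples=[], mode="per_sample")
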