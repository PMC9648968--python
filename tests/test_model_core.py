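"""Unit and property tests for the steady-state model distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from burstfish import (
    CountPMF,
    DEFAULT_GEOMETRY,
    GeneGeometry,
    MatureModelSpec,
    NascentModelSpec,
    RateParams,
    SignalBinPMF,
    convolve_pmf,
    delay_polII_pmf,
    derived_quantities,
    fano_factor,
    signal_bin_pmf,
    signal_conditional_bin_probs,
    signal_mean,
    telegraph_pmf,
)
from burstfish._exceptions import InvalidParameterError, UndefinedQuantityError


class TestTelegraphPMF:
    def test_always_on_limit_is_poisson(self):
        # sigma_off = 0: the gene never switches off, so counts are Poisson(rho/d)
        p = telegraph_pmf(MatureModelSpec(RateParams(1, 0, 5), d=1))
        ref = poisson.pmf(np.arange(len(p)), 5.0)
        assert abs(p[0] - np.exp(-5)) < 1e-8
        assert np.max(np.abs(p.probs - ref)) < 1e-8

    def test_zero_initiation_gives_point_mass_at_zero(self):
        p = telegraph_pmf(MatureModelSpec(RateParams(3, 2, 0), d=1))
        assert p[0] == 1.0 and len(p) == 1

    @pytest.mark.parametrize("rates", [(1, 1, 10), (5, 2, 60), (0.5, 4, 30)])
    def test_normalization_and_moments(self, rates):
        from burstfish import telegraph_moments

        spec = MatureModelSpec(RateParams(*rates), d=1)
        p = telegraph_pmf(spec)
        mean, var = telegraph_moments(spec)
        assert abs(p.probs.sum() - 1) < 1e-8
        assert abs(p.mean() - mean) < 1e-6 * max(1, mean)
        assert abs(p.variance() - var) < 1e-5 * max(1, var)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            telegraph_pmf(MatureModelSpec(RateParams(1, 1, 10), d=1), eps=2.0)
        with pytest.raises(InvalidParameterError):
            RateParams(-1, 1, 10)
        with pytest.raises(InvalidParameterError):
            RateParams(float("nan"), 1, 10)


class TestDelayPolIIPMF:
    def test_always_on_limit_is_poisson(self):
        p = delay_polII_pmf(NascentModelSpec(RateParams(1, 0, 4), tau=0.5))
        ref = poisson.pmf(np.arange(len(p)), 2.0)
        assert abs(p[0] - np.exp(-2)) < 1e-8
        assert np.max(np.abs(p.probs - ref)) < 1e-8

    @pytest.mark.parametrize(
        "rates,tau",
        [((1, 1, 4), 0.5), ((2, 3, 20), 0.5), ((7.5, 7.5, 50), 0.5), ((12, 3, 80), 0.785)],
    )
    def test_mean_identity(self, rates, tau):
        # E[k] = rho * tau * fON exactly (window-count of the modulated process)
        r = RateParams(*rates)
        p = delay_polII_pmf(NascentModelSpec(r, tau=tau))
        expect = r.rho * tau * r.fraction_on
        assert abs(p.mean() - expect) / expect < 1e-6

    def test_symmetric_switching_unit_mean(self):
        p = delay_polII_pmf(NascentModelSpec(RateParams(1, 1, 4), tau=0.5))
        assert abs(p.mean() - 1.0) < 1e-6


class TestSignalBins:
    def test_zero_and_one_polII(self):
        assert signal_conditional_bin_probs(0, DEFAULT_GEOMETRY).tolist() == [1.0]
        b1 = signal_conditional_bin_probs(1, DEFAULT_GEOMETRY)
        # one Pol II always emits signal in (0, 1]
        assert b1[0] == 0.0 and abs(b1[1] - 1.0) < 1e-12

    def test_two_polII_closed_form(self):
        g = DEFAULT_GEOMETRY
        b2 = signal_conditional_bin_probs(2, g)
        a = g.linear_fraction
        # both in the rising region and summing below 1: a^2 / 2
        assert abs(b2[1] - a * a / 2) < 1e-12
        assert abs(b2[2] - (1 - a * a / 2)) < 1e-12

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 20, 100])
    def test_rows_normalize(self, k):
        assert abs(signal_conditional_bin_probs(k, DEFAULT_GEOMETRY).sum() - 1) < 1e-10

    def test_negative_k_raises(self):
        with pytest.raises(InvalidParameterError):
            signal_conditional_bin_probs(-1, DEFAULT_GEOMETRY)

    def test_zero_initiation_all_mass_in_zero_bin(self):
        s = signal_bin_pmf(NascentModelSpec(RateParams(1, 1, 0), tau=0.5))
        assert s[0] == 1.0

    def test_continuous_signal_mean_identity(self):
        # Poisson limit: E[signal] = rho*tau * (L1/2 + L2) / L
        spec = NascentModelSpec(RateParams(1, 0, 4), tau=0.5)
        expect = 2.0 * (431.0 + 2200.0) / 3062.0
        assert abs(signal_mean(spec) - expect) / expect < 1e-6

    def test_signal_mean_identity_general(self):
        spec = NascentModelSpec(RateParams(2, 3, 20), tau=0.5)
        ek = delay_polII_pmf(spec).mean()
        expect = ek * spec.geometry.mean_signal_per_polII
        assert abs(signal_mean(spec) - expect) / expect < 1e-4


class TestConvolve:
    def test_delta_identity(self):
        d0 = CountPMF([1.0])
        out = convolve_pmf(d0, d0)
        assert out.probs.tolist() == [1.0]

    def test_bernoulli_square(self):
        p = CountPMF([0.5, 0.5])
        out = convolve_pmf(p, p)
        assert np.allclose(out.probs, [0.25, 0.5, 0.25])

    def test_poisson_additivity(self):
        lam = 3.0
        n = 40
        p = CountPMF(poisson.pmf(np.arange(n), lam))
        out = convolve_pmf(p, p)
        ref = poisson.pmf(np.arange(len(out)), 2 * lam)
        assert np.max(np.abs(out.probs - ref)) < 1e-8

    def test_mixed_kind_raises(self):
        with pytest.raises(InvalidParameterError):
            convolve_pmf(CountPMF([1.0]), SignalBinPMF([1.0]))

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_convolution_adds_means_and_conserves_mass(self, a, b):
        p = CountPMF(np.array(a) / np.sum(a))
        q = CountPMF(np.array(b) / np.sum(b))
        out = convolve_pmf(p, q)
        assert abs(out.probs.sum() - 1) < 1e-10
        assert abs(out.mean() - (p.mean() + q.mean())) < 1e-9


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "rates,fon,burst,eff",
        [((1, 1, 100), 0.5, 100.0, 50.0), ((3, 1, 40), 0.75, 40.0, 30.0), ((5, 10, 50), 1 / 3, 5.0, 50 / 3)],
    )
    def test_formulas(self, rates, fon, burst, eff):
        d = derived_quantities(RateParams(*rates))
        assert abs(d["fraction_on"] - fon) < 1e-12
        assert abs(d["burst_size"] - burst) < 1e-12
        assert abs(d["effective_rate"] - eff) < 1e-12

    def test_infinite_burst_flagged(self):
        d = derived_quantities(RateParams(1, 0, 10))
        assert d["burst_size_infinite"] and np.isinf(d["burst_size"])

    def test_frozen_promoter_raises(self):
        with pytest.raises(UndefinedQuantityError):
            derived_quantities(RateParams(0, 0, 10))


class TestFanoFactor:
    def test_poisson_is_one(self):
        p = CountPMF(poisson.pmf(np.arange(60), 7.0))
        assert abs(fano_factor(p) - 1.0) < 1e-6

    def test_point_mass_is_zero(self):
        p = CountPMF([0, 0, 0, 0, 0, 1.0])
        assert fano_factor(p) == 0.0

    def test_zero_mean_raises(self):
        with pytest.raises(UndefinedQuantityError):
            fano_factor(CountPMF([1.0]))

    def test_telegraph_super_poissonian(self):
        # bursty expression inflates variance over mean
        p = telegraph_pmf(MatureModelSpec(RateParams(1, 1, 10), d=1))
        assert abs(fano_factor(p) - (1 + 10 / 6)) < 1e-4


@given(
    st.floats(0.1, 100.0),
    st.floats(0.1, 100.0),
    st.floats(0.1, 200.0),
)
@settings(max_examples=25, deadline=None)
def test_pmf_normalization_property(son, soff, rho):
    p = telegraph_pmf(MatureModelSpec(RateParams(son, soff, rho), d=1))
    assert 1 - 1e-7 <= p.probs.sum() <= 1 + 1e-9
    s = signal_bin_pmf(NascentModelSpec(RateParams(son, soff, rho), tau=0.1))
    assert 1 - 1e-7 <= s.probs.sum() <= 1 + 1e-9


def test_pmf_serialization_roundtrip(tmp_path):
    p = telegraph_pmf(MatureModelSpec(RateParams(1, 1, 10), d=1))
    p.to_csv(tmp_path / "pmf.csv")
    import pandas as pd

    df = pd.read_csv(tmp_path / "pmf.csv")
    assert np.allclose(df["probability"], p.probs)
    env = p.to_json()
    import json

    obj = json.loads(env)
    assert obj["truncation"] == p.K and np.allclose(obj["probs"], p.probs)
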