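from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import gammaln, hyp2f1 as scipy_hyp2f1

from fmotif.corpus_io import ConsistencyError
from fmotif.distfit import (
    HyperPascal,
    InsufficientDataError,
    ZipfMandelbrot,
    _hp_expected_probs,
    fit_hyperpascal,
    fit_zm,
    goodness_of_fit,
    hp_pmf,
    hyp2f1_k1m,
    zm_pmf,
)
from fmotif.motif import FMotif, LengthSpectrum, rank_frequency_spectrum

a_vals = st.floats(min_value=0.0, max_value=3.0)
b_vals = st.floats(min_value=-0.99, max_value=40.0)
k_vals = st.floats(min_value=0.05, max_value=5.0)
m_vals = st.floats(min_value=0.05, max_value=5.0)
q_vals = st.floats(min_value=0.0, max_value=0.9)


class TestZMPmf:
    def test_single_class(self):
        assert zm_pmf(1.3, 2.0, 1) == pytest.approx([1.0])

    def test_harmonic_case(self):
        np.testing.assert_allclose(zm_pmf(1.0, 0.0, 3), [6 / 11, 3 / 11, 2 / 11])

    def test_uniform_limit(self):
        np.testing.assert_allclose(zm_pmf(0.0, 7.0, 4), [0.25] * 4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            zm_pmf(1.0, -1.0, 5)

    @given(a_vals, b_vals, st.integers(min_value=1, max_value=300))
    def test_valid_distribution(self, a, b, n):
        p = zm_pmf(a, b, n)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(min_value=0.1, max_value=3.0), b_vals)
    def test_strictly_decreasing_for_positive_a(self, a, b):
        p = zm_pmf(a, b, 50)
        assert np.all(np.diff(p) < 0)


class TestHyp2f1:
    def test_q_zero(self):
        assert hyp2f1_k1m(3.0, 0.7, 0.0) == 1.0

    def test_geometric_collapse(self):
        assert hyp2f1_k1m(2.0, 2.0, 0.5) == pytest.approx(2.0, rel=1e-12)

    def test_log_series(self):
        assert hyp2f1_k1m(1.0, 2.0, 0.5) == pytest.approx(2 * math.log(2), rel=1e-10)

    def test_divergence_domain_error(self):
        with pytest.raises(ValueError):
            hyp2f1_k1m(1.0, 1.0, 1.0)

    @given(k_vals, m_vals, q_vals)
    def test_matches_scipy_reference(self, k, m, q):
        ours = hyp2f1_k1m(k, m, q)
        ref = float(scipy_hyp2f1(k, 1.0, m, q))
        assert ours == pytest.approx(ref, rel=1e-8)


def hp_pmf_direct(k, m, q, x_max):
    """Independent evaluation via log binomial-coefficient ratios."""
    x = np.arange(x_max + 1)
    logc_top = gammaln(k + x) - gammaln(k) - gammaln(x + 1)
    logc_bot = gammaln(m + x) - gammaln(m) - gammaln(x + 1)
    p0 = 1.0 / float(scipy_hyp2f1(k, 1.0, m, q))
    return np.exp(logc_top - logc_bot + x * np.log(np.maximum(q, 1e-300))) * p0


class TestHPPmf:
    def test_point_mass_at_zero_when_q_tiny(self):
        y = hp_pmf(1.3, 0.4, 1e-12, 5)
        assert y[0] == pytest.approx(1.0, abs=1e-9)

    def test_geometric_when_k_equals_m(self):
        y = hp_pmf(2.0, 2.0, 0.5, 40)
        geo = 0.5 ** np.arange(41) * 0.5
        np.testing.assert_allclose(y, geo, atol=1e-12)

    @given(k_vals, m_vals, st.floats(min_value=0.01, max_value=0.7))
    def test_recurrence_matches_direct_binomials(self, k, m, q):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y = hp_pmf(k, m, q, 20)
        np.testing.assert_allclose(y, hp_pmf_direct(k, m, q, 20), rtol=1e-9)

    def test_truncation_warning(self):
        with pytest.warns(UserWarning, match="tail mass"):
            hp_pmf(2.0, 0.2, 0.6, 3)

    @given(k_vals, m_vals, st.floats(min_value=0.01, max_value=0.6))
    def test_mode_at_zero_when_ratio_below_one(self, k, m, q):
        if q * k / m <= 1.0:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                y = hp_pmf(k, m, q, 30)
            assert y[0] == pytest.approx(y.max())


class TestGoodnessOfFit:
    def test_exact_match(self):
        rep = goodness_of_fit([10, 5, 5], [0.5, 0.25, 0.25], 20, 1)
        assert rep.X2 == pytest.approx(0.0)
        assert rep.C == pytest.approx(0.0)
        assert rep.R2 == pytest.approx(1.0)

    def test_hand_computed_chisquare(self):
        rep = goodness_of_fit([12, 5, 3], [0.5, 0.25, 0.25], 20, 1)
        assert rep.X2 == pytest.approx(4 / 10 + 0 + 4 / 5)
        assert rep.C == pytest.approx(1.2 / 20)
        assert rep.pooled_classes == 3
        assert rep.df == 1

    def test_tail_pooling_to_expected_one(self):
        # last three classes have expected 0.4 each -> pooled into one class
        expected = np.array([0.4, 0.3, 0.18, 0.04, 0.04, 0.04])
        rep = goodness_of_fit([4, 3, 2, 0, 1, 0], expected, 10, 1)
        assert rep.pooled_classes == 4

    def test_length_mismatch(self):
        with pytest.raises(ConsistencyError):
            goodness_of_fit([1, 2], [0.5, 0.25, 0.25], 3, 1)


class TestZMFit:
    def test_noiseless_self_consistency(self):
        counts = 10_000 * zm_pmf(0.9, 5.0, 500)
        res = ZipfMandelbrot(counts).fit()
        assert res.params.a == pytest.approx(0.9, abs=1e-3)
        assert res.params.b == pytest.approx(5.0, abs=1e-2)
        assert res.report.converged

    def test_insufficient_classes(self):
        spec = rank_frequency_spectrum([FMotif((1,)), FMotif((2,)), FMotif((1,))])
        with pytest.raises(InsufficientDataError):
            fit_zm(spec)

    def test_refit_from_optimum_is_stable(self):
        counts = 5_000 * zm_pmf(1.1, 2.0, 200) + 1.0  # mild perturbation
        model = ZipfMandelbrot(counts)
        res1 = model.fit()
        x2_again = model.chisquare(res1.params.a, res1.params.b)
        assert abs(x2_again - res1.report.X2) < 1e-6

    def test_ml_flag(self):
        counts = np.round(8_000 * zm_pmf(1.0, 3.0, 300))
        res = ZipfMandelbrot(counts).fit(method="ml")
        assert res.params.a == pytest.approx(1.0, abs=0.05)

    def test_summary_mentions_parameters(self):
        counts = 10_000 * zm_pmf(0.9, 5.0, 100)
        text = ZipfMandelbrot(counts).fit().summary()
        assert "a (decay exponent)" in text and "X2" in text


class TestHPFit:
    def test_noiseless_self_consistency(self):
        probs = _hp_expected_probs(1.07, 0.18, 0.25, 12)
        res = HyperPascal(2_000 * probs).fit()
        assert res.params.k == pytest.approx(1.07, abs=1e-2)
        assert res.params.m == pytest.approx(0.18, abs=1e-2)
        assert res.params.q == pytest.approx(0.25, abs=1e-2)

    def test_sampled_fit_close_in_total_variation(self):
        from fmotif.synthetic import sample_hyperpascal

        draws = sample_hyperpascal(1.5, 0.25, 0.23, 5_000, seed=2)
        counts = np.bincount(draws)
        res = HyperPascal(counts).fit()
        fitted = _hp_expected_probs(res.params.k, res.params.m, res.params.q, len(counts))
        truth = _hp_expected_probs(1.5, 0.25, 0.23, len(counts))
        tvd = 0.5 * np.abs(fitted - truth).sum()
        assert tvd < 0.02

    def test_single_length_class_errors(self):
        with pytest.raises(InsufficientDataError):
            fit_hyperpascal(LengthSpectrum(counts={1: 500}))

    def test_p0_matches_hypergeometric_reciprocal(self):
        probs = _hp_expected_probs(1.07, 0.18, 0.25, 12)
        res = HyperPascal(2_000 * probs).fit()
        p = res.params
        assert p.p0 == pytest.approx(1.0 / hyp2f1_k1m(p.k, p.m, p.q), rel=1e-12)

    def test_missing_intermediate_lengths_are_zero_filled(self):
        ls = LengthSpectrum(counts={1: 500, 2: 200, 3: 80, 5: 10})
        model = HyperPascal.from_lengths(ls)
        assert list(model.counts) == [500, 200, 80, 0, 10]
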