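"""Beta-binomial pmf/tail correctness and maximum-likelihood fitting."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import comb

from mitocall import BetaBinomialModel, bbd_lower_tail, bbd_pmf, compute_qvalues
from mitocall.betabinom import MAX_PRECISION, _moment_init


def _pmf_by_quadrature(k, n, alpha, beta):
    """Numerical integration of the binomial pmf against the Beta density."""
    def integrand(p):
        return (
            comb(n, k, exact=True)
            * p**k
            * (1 - p) ** (n - k)
            * stats.beta.pdf(p, alpha, beta)
        )

    val, _ = integrate.quad(integrand, 0, 1, epsabs=1e-12, limit=200)
    return val


def _bh_bruteforce(pvals):
    """Step-up BH: sort, scale by m/rank, cumulative min from the right."""
    p = np.asarray(pvals, dtype=float)
    mtests = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * mtests / np.arange(1, mtests + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestPmf:
    def test_uniform_case(self):
        for k in range(5):
            assert bbd_pmf(k, 4, 1.0, 1.0) == pytest.approx(0.2, abs=1e-12)

    def test_matches_quadrature_on_grid(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 50:
            n = int(rng.integers(1, 60))
            k = int(rng.integers(0, n + 1))
            alpha = float(rng.uniform(0.2, 50))
            beta = float(rng.uniform(0.2, 50))
            assert bbd_pmf(k, n, alpha, beta) == pytest.approx(
                _pmf_by_quadrature(k, n, alpha, beta), abs=1e-8
            )
            checked += 1

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(1, 100))
            k = int(rng.integers(0, n + 1))
            a, b = rng.uniform(0.1, 200, 2)
            assert bbd_pmf(k, n, a, b) == pytest.approx(
                stats.betabinom.pmf(k, n, a, b), rel=1e-10, abs=1e-12
            )

    def test_zero_dispersion_limit_is_binomial(self):
        theta, s, n = 0.6, 1e6, 20
        for k in range(n + 1):
            assert bbd_pmf(k, n, theta * s, (1 - theta) * s) == pytest.approx(
                stats.binom.pmf(k, n, theta), abs=1e-4
            )

    def test_numerically_stable_at_extreme_sizes(self):
        val = bbd_pmf(99_000, 100_000, 9.9e5, 1e4)
        assert np.isfinite(val) and 0 < val < 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            bbd_pmf(1, 2, -1.0, 1.0)
        with pytest.raises(ValueError):
            bbd_pmf(3, 2, 1.0, 1.0)


class TestLowerTail:
    def test_full_tail_is_one(self):
        assert bbd_lower_tail(9, 9, 2.0, 3.0) == pytest.approx(1.0)

    def test_single_trial_closed_form(self):
        a, b = 3.0, 7.0
        assert bbd_lower_tail(0, 1, a, b) == pytest.approx(b / (a + b))

    def test_matches_bruteforce_pmf_sum(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(1, 50))
            m = int(rng.integers(0, n + 1))
            a, b = rng.uniform(0.2, 30, 2)
            brute = sum(bbd_pmf(k, n, a, b) for k in range(m + 1))
            assert bbd_lower_tail(m, n, a, b) == pytest.approx(brute, abs=1e-10)

    def test_nondecreasing_in_m(self):
        tails = bbd_lower_tail(np.arange(26), 25, 4.0, 2.0)
        assert (np.diff(tails) >= 0).all()

    def test_zero_depth_is_missing(self):
        assert np.isnan(bbd_lower_tail(np.array([0]), np.array([0]), 2.0, 2.0))[0]


class TestMLEFit:
    def test_recovers_simulation_parameters(self):
        theta, s = 0.5, 20.0
        th, ss = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = np.rint(rng.lognormal(2, 1, 5000)).astype(int)
            n = n[n > 0]
            pi = rng.beta(theta * s, (1 - theta) * s, size=n.size)
            m = rng.binomial(n, pi)
            fit = BetaBinomialModel(m, n).fit()
            th.append(fit.theta)
            ss.append(fit.precision)
        assert abs(np.median(th) - theta) < 0.02
        assert abs(np.median(ss) - s) / s < 0.2

    def test_pure_binomial_data_hits_precision_cap(self):
        rng = np.random.default_rng(3)
        n = np.rint(rng.lognormal(2.5, 0.8, 4000)).astype(int)
        n = n[n > 0]
        m = rng.binomial(n, 0.8)
        fit = BetaBinomialModel(m, n).fit()
        assert fit.theta == pytest.approx(0.8, abs=0.01)
        assert fit.at_cap
        assert fit.phi < 1e-6

    def test_fit_never_worse_than_moment_init(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = np.rint(rng.lognormal(2, 1, 400)).astype(int)
            n = n[n > 0]
            pi = rng.beta(5, 2, size=n.size)
            m = rng.binomial(n, pi)
            model = BetaBinomialModel(m, n)
            a0, b0 = _moment_init(model.m, model.n)
            a0 = np.clip(a0, 1e-8, MAX_PRECISION)
            b0 = np.clip(b0, 1e-8, MAX_PRECISION)
            assert model.fit().loglike_ >= model.loglike(a0, b0) - 1e-9

    def test_all_saturated_cells_capped_not_crashed(self):
        n = np.full(30, 25)
        fit = BetaBinomialModel(n, n).fit()
        assert np.isfinite(fit.alpha) and np.isfinite(fit.beta)
        assert fit.theta <= 1.0 - 1e-5  # error-rate floor keeps theta off 1

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            BetaBinomialModel([5], [5])


class TestQvalues:
    def test_single_pvalue_unchanged(self):
        assert compute_qvalues(np.array([0.01]))[0] == pytest.approx(0.01)

    def test_all_ones_stay_one(self):
        assert (compute_qvalues(np.ones(10)) == 1.0).all()

    def test_matches_bruteforce_bh(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=100)
        assert compute_qvalues(p) == pytest.approx(_bh_bruteforce(p), abs=1e-12)

    def test_q_at_least_p_and_order_preserved(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=50)
        q = compute_qvalues(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()  # q preserves the p ordering

    def test_nan_entries_stay_missing(self):
        p = np.array([0.01, np.nan, 0.5])
        q = compute_qvalues(p)
        assert np.isnan(q[1]) and np.isfinite(q[[0, 2]]).all()
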