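"""Beta-binomial null model of wild-type read counts.

Across cells of one locus, the WT heteroplasmy level is treated as a
beta-distributed random variable Pi ~ Beta(alpha, beta); the WT read
count of a cell with depth N is then X ~ BetaBinomial(N, alpha, beta).
The mean heteroplasmy is theta = alpha / (alpha + beta) and the
dispersion phi = 1 / (alpha + beta + 1): as the precision
s = alpha + beta grows (phi -> 0) the distribution collapses onto a plain
binomial with probability theta.

The null is fitted by maximum likelihood on preselected WT reference
cells only.  A cell whose WT count falls deep in the lower tail of the
fitted null — i.e. whose heteroplasmy is significantly *below* the locus
baseline (H1: pi_i < theta) — is evidence for a mutation at that locus
in that cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import betaln, gammaln

# precision cap: data with no detectable overdispersion drive s -> inf;
# the pmf at s = 1e8 is numerically binomial already
MAX_PRECISION = 1e8
MIN_PARAM = 1e-8
# residual per-base sequencing error floor: a null fitted on reference
# cells that happen to be all-pure would otherwise claim literally
# error-free sequencing and flag any cell with a single non-WT read
MAX_THETA = 1.0 - 1e-4


def bbd_logpmf(k, n, alpha: float, beta: float) -> np.ndarray:
    """Log beta-binomial pmf via log-beta functions.

    log C(n,k) + B(k+alpha, n-k+beta) - B(alpha, beta); stable for n up to
    1e5 and alpha+beta up to ~1e6.
    """
    if alpha <= 0 or beta <= 0 or not np.isfinite(alpha + beta):
        raise ValueError("alpha and beta must be positive and finite")
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if ((k < 0) | (k > n)).any():
        raise ValueError("need 0 <= k <= n")
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + alpha, n - k + beta)
        - betaln(alpha, beta)
    )


def bbd_pmf(k, n, alpha: float, beta: float) -> np.ndarray:
    """Beta-binomial probability mass P(X = k | n, alpha, beta)."""
    return np.exp(bbd_logpmf(k, n, alpha, beta))


def bbd_lower_tail(m, n, alpha: float, beta: float) -> np.ndarray:
    """Inclusive lower tail P(X <= m | n, alpha, beta).

    Computed by summing the pmf in log space from k = 0 to m.  NaN where
    ``n == 0``.  Non-decreasing in m at fixed (n, alpha, beta).
    """
    scalar = np.isscalar(m) and np.isscalar(n)
    m_b, n_b = np.broadcast_arrays(
        np.atleast_1d(np.asarray(m, dtype=float)),
        np.atleast_1d(np.asarray(n, dtype=float)),
    )
    out = np.full(m_b.shape, np.nan).ravel()
    mv = m_b.ravel()
    nv = n_b.ravel()
    valid = nv > 0
    if valid.any():
        mi = mv[valid].astype(np.int64)
        ni = nv[valid]
        ks = np.arange(int(mi.max()) + 1, dtype=float)
        # pmf matrix over k = 0..max(m); entries with k > n are never read
        # (m <= n), clip k to keep the pmf arguments in range
        kk = np.minimum(ks[None, :], ni[:, None])
        probs = np.exp(bbd_logpmf(kk, ni[:, None], alpha, beta))
        cdf = np.cumsum(probs, axis=1)
        out[valid] = np.minimum(cdf[np.arange(mi.size), mi], 1.0)
    out = out.reshape(m_b.shape)
    if scalar:
        return float(out.reshape(-1)[0])
    return out


def _moment_init(m: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) from per-cell WT allele frequencies."""
    waf = m / n
    mu = float(np.clip(waf.mean(), 1e-6, 1 - 1e-6))
    var = float(waf.var())
    # binomial sampling alone contributes mu(1-mu)*E[1/n]; excess is dispersion
    sampling = mu * (1 - mu) * float(np.mean(1.0 / n))
    excess = var - sampling
    if excess <= 0:
        s = MAX_PRECISION / 100.0
    else:
        s = max(mu * (1 - mu) / excess - 1.0, 1e-3)
    s = min(s, MAX_PRECISION)
    return mu * s, (1 - mu) * s


class BetaBinomialModel:
    """Beta-binomial model of WT counts m with depths n (MLE over alpha, beta).

    Cells with zero depth are excluded before fitting.
    """

    def __init__(self, m, n):
        m = np.asarray(m, dtype=float)
        n = np.asarray(n, dtype=float)
        if m.shape != n.shape:
            raise ValueError("m and n must have the same shape")
        if ((m < 0) | (m > n)).any():
            raise ValueError("need 0 <= m <= n")
        mask = n > 0
        self.m = m[mask]
        self.n = n[mask]
        if self.m.size < 2:
            raise ValueError("need at least 2 cells with positive depth")

    def loglike(self, alpha: float, beta: float) -> float:
        return float(bbd_logpmf(self.m, self.n, alpha, beta).sum())

    def fit(self, init: tuple[float, float] | None = None) -> "BetaBinomialResults":
        """Maximize the likelihood over (log alpha, log beta).

        Initialization by method of moments (or a user-supplied
        ``(alpha, beta)``), quasi-Newton optimization in log-parameter
        space, precision capped at 1e8 so zero-dispersion data terminate at
        a numerically-binomial fit instead of diverging.
        """
        if init is None:
            a0, b0 = _moment_init(self.m, self.n)
        else:
            a0, b0 = init
        a0 = float(np.clip(a0, MIN_PARAM, MAX_PRECISION))
        b0 = float(np.clip(b0, MIN_PARAM, MAX_PRECISION))
        x0 = np.log([a0, b0])
        ll_init = self.loglike(a0, b0)

        def negloglik(x: np.ndarray) -> float:
            a, b = np.exp(np.clip(x, np.log(MIN_PARAM), np.log(MAX_PRECISION)))
            return -self.loglike(a, b)

        res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 2000})
        a, b = np.exp(np.clip(res.x, np.log(MIN_PARAM), np.log(MAX_PRECISION)))
        ll = self.loglike(a, b)
        if ll < ll_init:  # never return worse than the starting point
            a, b, ll = a0, b0, ll_init
        converged = bool(res.success)
        # the binomial boundary (s -> inf) is a candidate the simplex only
        # approaches asymptotically; prefer it unless dispersion improves
        # the fit beyond sampling noise (~1 log-likelihood unit per extra
        # effective parameter, doubled for safety)
        theta_cap = float(np.clip(self.m.sum() / self.n.sum(), 1e-12, 1 - 1e-12))
        a_cap = theta_cap * MAX_PRECISION
        b_cap = (1.0 - theta_cap) * MAX_PRECISION
        ll_cap = self.loglike(a_cap, b_cap)
        if ll_cap >= ll - 2.0:
            a, b, ll = a_cap, b_cap, ll_cap
            converged = True
        if a / (a + b) > MAX_THETA:
            # error-rate floor: reference cells that happen to be all-pure
            # would otherwise yield a null claiming error-free sequencing.
            # The floored null is the binomial with the residual error rate
            # (a free 1-D search over the dispersion at fixed theta would
            # land on a degenerate U-shaped beta instead).
            a, b = MAX_THETA * MAX_PRECISION, (1.0 - MAX_THETA) * MAX_PRECISION
            ll = self.loglike(a, b)
        return BetaBinomialResults(
            model=self,
            alpha=float(a),
            beta=float(b),
            loglike_=ll,
            converged=converged,
            n_cells_used=int(self.m.size),
            at_cap=bool(a + b >= MAX_PRECISION * 0.99),
        )


@dataclass
class BetaBinomialResults:
    """Fitted beta-binomial null: (alpha, beta) plus derived (theta, phi)."""

    model: BetaBinomialModel | None
    alpha: float
    beta: float
    loglike_: float
    converged: bool
    n_cells_used: int
    at_cap: bool = False

    @property
    def theta(self) -> float:
        """Mean WT heteroplasmy alpha / (alpha + beta)."""
        return self.alpha / (self.alpha + self.beta)

    @property
    def phi(self) -> float:
        """Dispersion 1 / (alpha + beta + 1); 0 is the binomial limit."""
        return 1.0 / (self.alpha + self.beta + 1.0)

    @property
    def precision(self) -> float:
        """Precision s = alpha + beta."""
        return self.alpha + self.beta

    @property
    def params(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta,
                "theta": self.theta, "phi": self.phi}

    def lower_tail(self, m, n) -> np.ndarray:
        """P(X <= m | n) under the fitted null; the per-cell mutation p-value."""
        return bbd_lower_tail(m, n, self.alpha, self.beta)

    def summary(self) -> str:
        lines = [
            "Beta-binomial null (MLE)",
            "=" * 34,
            f"alpha     {self.alpha:14.6g}",
            f"beta      {self.beta:14.6g}",
            f"theta     {self.theta:14.6f}",
            f"phi       {self.phi:14.6g}",
            f"precision {self.precision:14.6g}" + ("  (at cap)" if self.at_cap else ""),
            f"loglike   {self.loglike_:14.4f}",
            f"cells used {self.n_cells_used}  converged={self.converged}",
        ]
        return "\n".join(lines)
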