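"""Two-component binomial mixture classifier for wild-type cell preselection.

At a locus, the WT read count of cell *i* is modelled as a mixture of two
binomials sharing the cell's depth N_i: a WT component with success
probability pi_W (near 1 for a clean locus) and weight theta_W, and a
mutant component with pi_M < pi_W and weight theta_M = 1 - theta_W.  The
model is fitted by EM; the lower-tail probability of each cell under the
WT component, Benjamini-Hochberg adjusted across cells of the locus, then
flags likely-mutant cells so they can be excluded before the beta-binomial
null is fitted (preventing the null from absorbing the mutants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

_EPS = 1e-12


class BinomialMixtureModel:
    """Two-component binomial mixture over (WT count, depth) pairs.

    Parameters
    ----------
    m : array-like of int
        WT allele read counts per cell.
    n : array-like of int
        Sequencing depths per cell; cells with ``n == 0`` are excluded from
        fitting (they carry no likelihood contribution).
    """

    def __init__(self, m, n):
        m = np.asarray(m, dtype=float)
        n = np.asarray(n, dtype=float)
        if m.shape != n.shape:
            raise ValueError("m and n must have the same shape")
        if ((m < 0) | (m > n)).any():
            raise ValueError("need 0 <= m <= n")
        self._mask = n > 0
        self.m = m[self._mask]
        self.n = n[self._mask]
        if self.m.size < 2:
            raise ValueError("need at least 2 cells with positive depth")
        from scipy.special import gammaln

        self._logC = (
            gammaln(self.n + 1) - gammaln(self.m + 1) - gammaln(self.n - self.m + 1)
        )

    # -- likelihood machinery ------------------------------------------
    def _component_logpmf(self, p: np.ndarray) -> np.ndarray:
        """log pmf of each observation under each component, shape (2, n).

        Hand-rolled (rather than scipy.stats.binom.logpmf) because EM calls
        this hundreds of times per locus; boundary probabilities 0 and 1
        are handled exactly.
        """
        out = np.empty((2, self.m.size))
        for c in range(2):
            pc = p[c]
            if pc <= 0.0:
                out[c] = np.where(self.m == 0, 0.0, -np.inf)
            elif pc >= 1.0:
                out[c] = np.where(self.m == self.n, 0.0, -np.inf)
            else:
                out[c] = (
                    self._logC
                    + self.m * np.log(pc)
                    + (self.n - self.m) * np.log1p(-pc)
                )
        return out

    def loglike(self, p: np.ndarray, w: np.ndarray) -> float:
        lp = self._component_logpmf(p) + np.log(np.maximum(w, _EPS))[:, None]
        norm = np.logaddexp(lp[0], lp[1])
        return float(norm[np.isfinite(norm)].sum())

    def fit(
        self,
        max_iter: int = 500,
        tol: float = 1e-8,
        init: tuple | None = None,
        min_separation: float = 0.05,
    ) -> "BinomialMixtureResults":
        """Fit by EM.

        Initialization: component probabilities at the 10th and 90th
        percentiles of the observed WT allele frequencies, equal weights;
        override with ``init=((p_lo, p_hi), (w_lo, w_hi))``.  Convergence
        when the relative log-likelihood change drops below ``tol``.

        ``min_separation`` only affects the ``separated`` flag (see below),
        never the reported parameter estimates.
        """
        waf = self.m / self.n
        if init is None:
            p = np.clip(np.percentile(waf, [10.0, 90.0]), _EPS, 1.0)
            # rare-component data leave both percentiles equal; spread the
            # low component to the observed minimum so EM can separate them
            if p[1] - p[0] < 1e-3:
                p[0] = np.clip(min(waf.min(), p[1] - 0.1), _EPS, 1.0)
            w = np.array([0.5, 0.5])
        else:
            p = np.clip(np.asarray(init[0], dtype=float), 0.0, 1.0)
            w = np.asarray(init[1], dtype=float)

        degenerate = np.allclose(waf, waf[0])
        ll_old = -np.inf
        trace = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E step: responsibilities
            lp = self._component_logpmf(p) + np.log(np.maximum(w, _EPS))[:, None]
            norm = np.logaddexp(lp[0], lp[1])
            with np.errstate(invalid="ignore"):
                r = np.exp(lp - norm[None, :])
            # cells with zero density under both components (e.g. m < n when
            # both probabilities hit 1): fall back to the prior weights
            dead = ~np.isfinite(norm)
            if dead.any():
                r[:, dead] = w[:, None]
            ll = float(norm[np.isfinite(norm)].sum())
            trace.append(ll)
            # M step
            w = r.mean(axis=1)
            denom = r @ self.n
            p = np.where(denom > 0, (r @ self.m) / np.maximum(denom, _EPS), p)
            if ll - ll_old <= tol * (abs(ll_old) + 1.0) and it > 1:
                converged = True
                break
            ll_old = ll

        # canonical labeling: WT component is the high-probability one
        order = np.argsort(p)[::-1]
        p, w = p[order], w[order]

        # support for two components.  On a clean locus EM happily carves
        # the m == N atom into its own pi = 1 component; classifying
        # against that boundary component would give every cell with a
        # single non-WT read a tail probability of exactly 0.  The fit is
        # only treated as a genuine two-population split when (a) the
        # mixture beats a single pooled binomial by a likelihood-ratio
        # test and (b) the component heteroplasmies differ by at least
        # ``min_separation`` — smaller shifts are indistinguishable from
        # continuous overdispersion at typical mtDNA depths.  Otherwise
        # the classifier falls back to the pooled pi.
        pooled_pi = float(self.m.sum() / self.n.sum())
        ll_pooled = float(stats.binom.logpmf(self.m, self.n, pooled_pi).sum())
        ll_final = self.loglike(p, w)
        lrt_stat = max(0.0, 2.0 * (ll_final - ll_pooled))
        separated = bool(
            lrt_stat > stats.chi2.ppf(0.95, df=2)
            and (p[0] - p[1]) >= min_separation
        )

        return BinomialMixtureResults(
            model=self,
            pi_wt=float(p[0]),
            pi_mut=float(p[1]),
            theta_wt=float(w[0]),
            theta_mut=float(w[1]),
            loglike_=ll_final,
            n_iter=it,
            converged=converged,
            degenerate=degenerate,
            loglike_trace=np.asarray(trace),
            pooled_pi=pooled_pi,
            lrt_stat=lrt_stat,
            separated=separated,
        )


@dataclass
class BinomialMixtureResults:
    """Fitted binomial mixture: (pi_W, pi_M, theta_W, theta_M)."""

    model: BinomialMixtureModel
    pi_wt: float
    pi_mut: float
    theta_wt: float
    theta_mut: float
    loglike_: float
    n_iter: int
    converged: bool
    degenerate: bool
    loglike_trace: np.ndarray
    pooled_pi: float = 1.0
    lrt_stat: float = 0.0
    separated: bool = True

    @property
    def params(self) -> dict:
        return {
            "pi_wt": self.pi_wt,
            "pi_mut": self.pi_mut,
            "theta_wt": self.theta_wt,
            "theta_mut": self.theta_mut,
        }

    @property
    def classifier_pi(self) -> float:
        """Success probability the classifier tail is evaluated under.

        The WT component's pi when the two-component fit is supported by
        the likelihood-ratio test, else the pooled single-binomial pi.
        """
        return self.pi_wt if self.separated else self.pooled_pi

    def tail_prob(self, m, n) -> np.ndarray:
        """Inclusive lower-tail probability P(X <= m | n, pi_W).

        This is the classifier statistic: a cell with few WT reads relative
        to the WT component has a small tail probability.  NaN where n == 0.
        """
        return p_bmd(m, n, self.classifier_pi)

    def posterior_mutant(self, m, n) -> np.ndarray:
        """Diagnostic: posterior probability of the mutant component."""
        m = np.asarray(m, dtype=float)
        n = np.asarray(n, dtype=float)
        p = np.array([self.pi_wt, self.pi_mut])
        w = np.array([self.theta_wt, self.theta_mut])
        lp = (
            stats.binom.logpmf(m[None, ...], n[None, ...], p.reshape(2, *[1] * m.ndim))
            + np.log(np.maximum(w, _EPS)).reshape(2, *[1] * m.ndim)
        )
        post = np.exp(lp[1] - logsumexp(lp, axis=0))
        return np.where(n > 0, post, np.nan)

    def summary(self) -> str:
        lines = [
            "Binomial mixture (EM)",
            "=" * 34,
            f"pi_WT     {self.pi_wt:12.6f}",
            f"pi_mut    {self.pi_mut:12.6f}",
            f"theta_WT  {self.theta_wt:12.6f}",
            f"theta_mut {self.theta_mut:12.6f}",
            f"loglike   {self.loglike_:12.4f}",
            f"iterations {self.n_iter}  converged={self.converged}"
            + ("  DEGENERATE" if self.degenerate else ""),
        ]
        return "\n".join(lines)


def p_bmd(m, n, pi_wt: float) -> np.ndarray:
    """Inclusive lower-tail binomial probability P(X <= m | n, pi_WT).

    NaN where ``n == 0`` (no reads, probability undefined).
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    p = stats.binom.cdf(m, np.maximum(n, 1), pi_wt)
    return np.where(n > 0, p, np.nan)


def select_wt_cells(
    pvals: np.ndarray,
    fdr_threshold: float = 0.05,
    enabled: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Select likely-WT reference cells at one locus.

    Benjamini-Hochberg adjusts the per-cell classifier tail probabilities
    across cells of the locus; cells with adjusted value *above* the
    threshold look consistent with the WT component and are kept for the
    beta-binomial fit.  Returns ``(selected mask, adjusted p-values)``;
    NaN p-values (zero-depth cells) are never selected.  With fewer than
    two selected cells the selection falls back to all finite-p cells
    (the downstream fit would be degenerate otherwise).
    """
    pvals = np.asarray(pvals, dtype=float)
    finite = np.isfinite(pvals)
    adjusted = np.full_like(pvals, np.nan)
    if finite.sum() == 0:
        return np.zeros(pvals.shape, dtype=bool), adjusted
    adjusted[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    if not enabled:
        return finite.copy(), adjusted
    selected = finite & (adjusted > fdr_threshold)
    if selected.sum() < 2:
        selected = finite.copy()
    return selected, adjusted
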