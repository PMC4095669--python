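"""Exact tail probabilities for over-representation testing.

The central quantity is the upper tail of the hypergeometric distribution,

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n),

the probability of drawing at least ``k`` successes in ``n`` draws without
replacement from a population of ``N`` items of which ``K`` are successes.
It is evaluated in log space from log-factorials so that values far below
the smallest normal float (the interesting ones, e.g. 1e-55) keep full
relative precision; the natural-log form is exposed alongside the linear
probability.

``fisher_onesided`` maps a one-sided Fisher exact test (enrichment
direction) onto the same tail, optionally with the EASE modification in
which one observed success is removed before testing - the conservative
convention popularised by the DAVID annotation server.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "hypergeometric_upper_tail",
    "log_hypergeometric_upper_tail",
    "fisher_onesided",
    "benjamini_hochberg",
]

# Cached table of log-factorials, grown on demand; _LOGFACT[i] = log(i!).
_LOGFACT = np.zeros(1)

# Smallest positive (subnormal) double: floor so probabilities stay in (0, 1].
_TINY = 5e-324


def _logfact(n: int) -> np.ndarray:
    global _LOGFACT
    if _LOGFACT.size <= n:
        m = max(n + 1, 2 * _LOGFACT.size)
        _LOGFACT = np.concatenate(
            ([0.0], np.cumsum(np.log(np.arange(1, m, dtype=float))))
        )
    return _LOGFACT


def _validate(k: int, n: int, K: int, N: int) -> None:
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v:
            raise ConfigurationError(f"{name} must be an integer, got {v!r}")
    if not 0 <= K <= N:
        raise ConfigurationError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ConfigurationError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ConfigurationError(
            f"require 0 <= k <= min(n, K), got k={k}, n={n}, K={K}"
        )


def log_hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Natural log of P(X >= k) for the hypergeometric distribution.

    Parameters follow the population/draw convention: ``N`` population size,
    ``K`` successes in the population, ``n`` draws, ``k`` observed successes.
    Returns 0.0 (log 1) when the event is certain.
    """
    _validate(k, n, K, N)
    k, n, K, N = int(k), int(n), int(K), int(N)
    # Support of X is [max(0, n-(N-K)), min(n, K)]; below the lower end the
    # tail is certain.
    lo = max(0, n - (N - K))
    if k <= lo:
        return 0.0
    hi = min(n, K)
    lf = _logfact(N)
    i = np.arange(k, hi + 1)
    log_terms = (
        lf[K] - lf[i] - lf[K - i]
        + lf[N - K] - lf[n - i] - lf[N - K - n + i]
        - (lf[N] - lf[n] - lf[N - n])
    )
    mx = float(log_terms.max())
    logp = mx + math.log(float(np.exp(log_terms - mx).sum()))
    return min(0.0, logp)


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k); in (0, 1].  Values below ~1e-308 underflow to the smallest
    subnormal float - use :func:`log_hypergeometric_upper_tail` when the
    magnitude itself matters."""
    p = math.exp(log_hypergeometric_upper_tail(k, n, K, N))
    return p if p > 0.0 else _TINY


def fisher_onesided(
    count: int,
    list_size: int,
    pop_hits: int,
    pop_size: int,
    ease: bool = False,
) -> float:
    """One-sided (enrichment) Fisher exact probability for a 2x2 table.

    ``count`` genes of a query list of ``list_size`` fall in a category with
    ``pop_hits`` members among ``pop_size`` population genes.  With
    ``ease=True`` one success is removed (floored at zero) before the tail
    is computed, giving the EASE score.
    """
    if not 0 <= count <= min(list_size, pop_hits):
        raise ConfigurationError(
            f"require 0 <= count <= min(list_size, pop_hits), got count={count},"
            f" list_size={list_size}, pop_hits={pop_hits}"
        )
    if not (pop_hits <= pop_size and list_size <= pop_size):
        raise ConfigurationError(
            f"require pop_hits <= pop_size and list_size <= pop_size, got"
            f" pop_hits={pop_hits}, list_size={list_size}, pop_size={pop_size}"
        )
    c = max(count - 1, 0) if ease else count
    return hypergeometric_upper_tail(c, list_size, pop_hits, pop_size)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR), preserving input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
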