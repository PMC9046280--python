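"""Shared statistical kernel: hypergeometric upper tail and BH adjustment.

The enrichment statistic used throughout the package is the cumulative
(upper-tail) hypergeometric probability P(X >= k) for X ~ Hypergeom(N, K, n):
the chance of drawing at least k marked items in n draws without replacement
from a population of N items of which K are marked. It is evaluated in log
space (log-gamma terms combined with logsumexp) so that extremely small
p-values keep full relative precision. Both the motif-enrichment and the
over-representation modules call this single implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import UsageError

__all__ = ["log_hypergeom_sf", "hypergeom_sf", "bh_adjust"]


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def log_hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Natural log of P(X >= k) for X ~ Hypergeom(N, K, n).

    Parameters follow the sampling description: population ``N`` with ``K``
    successes, ``n`` draws, observed successes ``k``. ``k <= 0`` gives exactly
    log(1) = 0 (the upper tail from zero is the whole distribution).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise UsageError(
            f"invalid hypergeometric parameters N={N}, K={K}, n={n}"
        )
    if k > min(n, K):
        return -math.inf
    lo = max(0, n - (N - K))
    if k <= lo:
        return 0.0
    i = np.arange(k, min(n, K) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(logsumexp(log_terms))


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k), the upper-tail cumulative hypergeometric probability."""
    return math.exp(log_hypergeom_sf(k, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
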