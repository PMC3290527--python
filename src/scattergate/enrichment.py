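"""Geneset overlap analysis for a polygon selection.

For a selection of ``n`` genes out of a universe of ``N``, and a geneset with
``K`` members inside that universe, the observed overlap ``k`` is assessed
with the one-sided upper hypergeometric tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

(equivalently a one-sided Fisher exact test).  The expected overlap is the
hypergeometric mean n*K/N.  Tail probabilities are accumulated in log space
(gammaln + logsumexp) so -log10(p) stays meaningful far past double-precision
underflow.  Benjamini-Hochberg q-values are computed over exactly the tested
sets.

The universe defaults to all gene ids present in the uploaded table: the
selection is drawn from plotted genes, so the table is the sampling frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .gating import Selection
from .io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "hypergeom_tail_p",
    "log_hypergeom_tail",
    "bh_fdr",
    "overlap_analysis",
]

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap statistics for one geneset against one selection."""

    geneset_name: str
    description: str
    universe_size: int  # N
    selection_size: int  # n
    geneset_size_in_universe: int  # K
    observed_overlap: int  # k
    expected_overlap: float  # n*K/N
    p_value: float
    neg_log10_p: float
    q_value: float = math.nan


def _check_params(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N):
        raise DomainError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise DomainError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise DomainError(f"need 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")


def _log_binom(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def log_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Natural log of P(X >= k) for X ~ Hypergeometric(N, K, n).

    Sums the pmf over the upper tail in log space; exact 0.0 (= log 1) when
    k is at or below the distribution's lower support bound.
    """
    _check_params(N, K, n, k)
    lo_support = max(0, n + K - N)
    if k <= lo_support:
        return 0.0
    j = np.arange(k, min(n, K) + 1)
    log_pmf = _log_binom(K, j) + _log_binom(N - K, n - j) - _log_binom(N, n)
    return float(logsumexp(log_pmf))


def hypergeom_tail_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k); 1.0 when k = 0."""
    return min(1.0, math.exp(log_hypergeom_tail(N, K, n, k)))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, monotone, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(~((p > 0) & (p <= 1))):
        raise DomainError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return [float(v) for v in q]


def overlap_analysis(
    selection: Selection | Iterable[str],
    collection: GeneSetCollection,
    universe: set[str],
    min_geneset_size: int = 5,
    max_geneset_size: int = 2000,
) -> list[EnrichmentResult]:
    """Test every geneset in ``collection`` against the selection.

    Geneset membership is restricted to the universe (K = |set ∩ universe|);
    sets with K outside [min_geneset_size, max_geneset_size] are skipped.
    Selection ids not in the universe are dropped with a warning.  Results are
    sorted by ascending p-value, ties broken by descending observed overlap
    then geneset name; q-values are computed over exactly the tested sets.
    """
    if not universe:
        raise DomainError("universe must be non-empty")
    ids = selection.gene_ids if isinstance(selection, Selection) else tuple(selection)
    selected = set(ids)
    dropped = selected - universe
    if dropped:
        logger.warning(
            "%d selected gene id(s) not in the universe were dropped", len(dropped)
        )
        selected &= universe
    N = len(universe)
    n = len(selected)
    if n == 0:
        logger.warning("empty selection: no genesets tested")
        return []

    results: list[EnrichmentResult] = []
    for geneset in collection:
        members = geneset.members & universe
        K = len(members)
        if K < min_geneset_size or K > max_geneset_size:
            continue
        k = len(members & selected)
        log_tail = log_hypergeom_tail(N, K, n, k)
        results.append(
            EnrichmentResult(
                geneset_name=geneset.name,
                description=geneset.description,
                universe_size=N,
                selection_size=n,
                geneset_size_in_universe=K,
                observed_overlap=k,
                expected_overlap=n * K / N,
                p_value=min(1.0, math.exp(log_tail)),
                neg_log10_p=max(0.0, -log_tail / _LN10),
            )
        )
    results.sort(key=lambda r: (r.p_value, -r.observed_overlap, r.geneset_name))
    qs = bh_fdr([r.p_value for r in results])
    results = [
        EnrichmentResult(**{**r.__dict__, "q_value": q}) for r, q in zip(results, qs)
    ]
    logger.info("tested %d geneset(s) against a selection of %d/%d genes", len(results), n, N)
    return results
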