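"""Cumulative hypergeometric overlap enrichment.

Tests whether an identified gene set overlaps a functional catalog more than
expected by chance: with a universe of N genes, m functional, n identified
and k in the overlap,

    P = 1 - sum_{i=0}^{k-1} C(m, i) C(N-m, n-i) / C(N, n)

i.e. the upper tail P(overlap >= k). Evaluated through the survival
function of the hypergeometric distribution, which is computed in log space
and safe at genome scale (N ~ 20000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp


@dataclass
class EnrichmentResult:
    N: int   # universe size
    m: int   # functional-set size
    n: int   # identified-set size
    k: int   # overlap
    p: float


def hypergeom_enrichment(universe, functional_set, identified_set) -> EnrichmentResult:
    """Upper-tail hypergeometric p for the overlap of two subsets of a universe."""
    universe = set(universe)
    functional = set(functional_set)
    identified = set(identified_set)
    bad = (functional | identified) - universe
    if bad:
        raise ValueError(f"sets not subsets of universe: {sorted(bad)[:10]}")
    if not identified:
        raise ValueError("identified set is empty")
    N, m, n = len(universe), len(functional), len(identified)
    k = len(functional & identified)
    # P(X >= k): log-space tail sum so extreme overlaps stay strictly
    # positive instead of underflowing to 0
    hi = min(m, n)
    if k <= max(0, m + n - N):
        p = 1.0
    else:
        support = np.arange(k, hi + 1)
        logp = logsumexp(stats.hypergeom.logpmf(support, N, m, n))
        p = float(np.exp(logp))
        p = max(p, np.nextafter(0.0, 1.0))
    return EnrichmentResult(N=N, m=m, n=n, k=k, p=min(p, 1.0))
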