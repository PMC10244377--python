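"""Hypergeometric set-overlap statistics for gene lists.

Given two gene lists drawn from a common finite background (for example,
a protein interactome and an independently derived RBP catalogue), the
overlap is scored two ways:

* the *representation factor*, observed overlap divided by the overlap
  expected under independence, k / (n1 * n2 / N); and
* an upper-tail hypergeometric p-value P(X >= k), summed in log space so
  that extreme significance (p far below 1e-12) is representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = ["OverlapResult", "hypergeometric_overlap", "hypergeom_sf"]


@dataclass
class OverlapResult:
    n1: int
    n2: int
    universe: int
    overlap: int
    expected: float
    representation_factor: float
    pvalue: float

    def as_dict(self) -> dict:
        return {
            "n1": self.n1,
            "n2": self.n2,
            "universe": self.universe,
            "overlap": self.overlap,
            "expected": self.expected,
            "representation_factor": self.representation_factor,
            "pvalue": self.pvalue,
        }


def hypergeom_sf(k: int, N: int, n1: int, n2: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeom(N, n1, n2).

    Summed as logsumexp over the exact log-pmf, so the result is accurate
    in the far tail where ``1 - cdf`` would round to zero.
    """
    if k <= max(0, n1 + n2 - N):
        return 1.0
    hi = min(n1, n2)
    if k > hi:
        return 0.0
    support = np.arange(k, hi + 1)
    logp = sps.hypergeom.logpmf(support, N, n1, n2)
    return float(min(1.0, np.exp(logsumexp(logp))))


def hypergeometric_overlap(set_a, set_b, universe) -> OverlapResult:
    """Overlap of two sets against an explicit background universe.

    Raises ``ValueError`` when either set contains elements outside the
    universe (listing the offenders) or the universe is empty.  The
    universe must be supplied by the caller: there is no defensible
    default background and the result is sensitive to it.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    a, b = set(set_a), set(set_b)
    stray = sorted((a | b) - uni)
    if stray:
        raise ValueError(f"elements outside universe: {stray[:10]}" +
                         (" ..." if len(stray) > 10 else ""))
    n1, n2, N = len(a), len(b), len(uni)
    k = len(a & b)
    expected = n1 * n2 / N
    rf = float("nan") if expected == 0 else k / expected
    return OverlapResult(
        n1=n1,
        n2=n2,
        universe=N,
        overlap=k,
        expected=expected,
        representation_factor=rf,
        pvalue=hypergeom_sf(k, N, n1, n2),
    )
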