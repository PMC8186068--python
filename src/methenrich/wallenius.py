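"""Wallenius' noncentral hypergeometric upper tail, plus a brute-force oracle.

Wallenius' distribution describes drawing ``n`` balls one at a time, without
replacement, from an urn of ``m1`` white and ``m2`` black balls where at
every draw each remaining white ball is ``odds`` times as likely to be taken
as each black ball.  At ``odds = 1`` it reduces to the central
hypergeometric distribution.

The production path (`wallenius_upper_tail`) evaluates the tail with
``scipy.stats.nchypergeom_wallenius`` (odds = 1 is routed to
``scipy.stats.hypergeom``, where the reduction is exact).  The oracle
(`wallenius_oracle`) enumerates every ordered draw sequence explicitly and
is the correctness anchor for the tests; it is feasible only for tiny urns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom, nchypergeom_wallenius


@dataclass(frozen=True)
class UrnSpec:
    """Urn parameters: ``m1`` white (genes in the set), ``m2`` black (rest of
    the array), ``n`` draws (significant genes), ``odds`` white:black weight
    ratio."""

    m1: int
    m2: int
    n: int
    odds: float

    def __post_init__(self):
        if self.m1 < 0 or self.m2 < 0:
            raise ValueError("m1 and m2 must be non-negative")
        if not 0 <= self.n <= self.m1 + self.m2:
            raise ValueError(f"n={self.n} outside [0, m1+m2={self.m1 + self.m2}]")
        if not self.odds > 0:
            raise ValueError("odds must be positive")


def wallenius_upper_tail(x: int, urn: UrnSpec) -> float:
    """Inclusive upper tail ``P(X >= x)`` of the Wallenius distribution.

    Returns 1 when ``x`` is at or below the guaranteed minimum number of
    white draws ``max(0, n - m2)``, and 0 when ``x`` exceeds the support
    maximum ``min(n, m1)``.
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    if x <= max(0, urn.n - urn.m2):
        return 1.0
    if x > min(urn.n, urn.m1):
        return 0.0
    M = urn.m1 + urn.m2
    if urn.odds == 1:
        p = hypergeom.sf(x - 1, M, urn.m1, urn.n)
    else:
        p = nchypergeom_wallenius.sf(x - 1, M, urn.m1, urn.n, urn.odds)
    return float(min(max(p, 0.0), 1.0))


def wallenius_upper_tail_many(x, m1, m2, n, odds) -> np.ndarray:
    """Vectorised `wallenius_upper_tail` over parallel parameter arrays.

    All arguments broadcast.  Used by the enrichment engine, which tests
    hundreds of gene sets against one universe at a time.
    """
    x, m1, m2, n, odds = np.broadcast_arrays(
        *(np.asarray(a) for a in (x, m1, m2, n, odds))
    )
    p = np.ones(x.shape, dtype=float)
    lo = np.maximum(0, n - m2)
    hi = np.minimum(n, m1)
    zero = x > hi
    interior = (x > lo) & ~zero
    M = m1 + m2
    central = interior & (odds == 1)
    if central.any():
        p[central] = hypergeom.sf(x[central] - 1, M[central], m1[central], n[central])
    noncentral = interior & (odds != 1)
    if noncentral.any():
        p[noncentral] = nchypergeom_wallenius.sf(
            x[noncentral] - 1, M[noncentral], m1[noncentral], n[noncentral], odds[noncentral]
        )
    p[zero] = 0.0
    return np.clip(p, 0.0, 1.0)


_ORACLE_MAX_BALLS = 12


def wallenius_oracle(x: int, urn: UrnSpec) -> float:
    """Exact tail probability by exhaustive enumeration of draw sequences.

    Every ordered white/black sequence of length ``n`` is walked; a
    sequence's probability is the product, draw by draw, of
    ``weight of the chosen colour / total remaining weight``.  Refuses urns
    with more than 12 balls.
    """
    if urn.m1 + urn.m2 > _ORACLE_MAX_BALLS:
        raise ValueError(f"oracle limited to urns with <= {_ORACLE_MAX_BALLS} balls")
    if x < 0:
        raise ValueError("x must be non-negative")

    total = 0.0
    # depth-first walk over ordered sequences: state = (whites left, blacks
    # left, whites drawn, probability of the path so far)
    stack = [(urn.m1, urn.m2, 0, 0, 1.0)]
    while stack:
        w_left, b_left, drawn, whites, prob = stack.pop()
        if drawn == urn.n:
            if whites >= x:
                total += prob
            continue
        denom = urn.odds * w_left + b_left
        if w_left > 0:
            stack.append(
                (w_left - 1, b_left, drawn + 1, whites + 1, prob * urn.odds * w_left / denom)
            )
        if b_left > 0:
            stack.append((w_left, b_left - 1, drawn + 1, whites, prob * b_left / denom))
    return total
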