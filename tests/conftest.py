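"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive each statistic from first principles
(exhaustive enumeration, exact rational arithmetic, plain-Python formula
evaluation) so that tests compare two independent routes to the same number.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20140626)


# ---------------------------------------------------------------------------
# zinc finger pattern oracle: exhaustive placement enumeration + greedy pick


def brute_force_fingers(
    seq: str,
    cys_gap=(2, 4),
    loop_gap=(11, 14),
    his_gap=(3, 5),
) -> list[tuple[int, int, int, int]]:
    """All pattern placements, then left-to-right greedy with lexicographic
    shortest-gap-first tie-breaking.  Returns 1-based (c1, c2, h1, h2)."""
    L = len(seq)
    cands = []
    for c1 in range(L):
        if seq[c1] != "C":
            continue
        for g1 in range(cys_gap[0], cys_gap[1] + 1):
            c2 = c1 + g1 + 1
            if c2 >= L or seq[c2] != "C":
                continue
            for g2 in range(loop_gap[0], loop_gap[1] + 1):
                h1 = c2 + g2 + 1
                if h1 >= L or seq[h1] != "H":
                    continue
                for g3 in range(his_gap[0], his_gap[1] + 1):
                    h2 = h1 + g3 + 1
                    if h2 >= L or seq[h2] != "H":
                        continue
                    cands.append((c1, g1, g2, g3, c2, h1, h2))
    cands.sort(key=lambda t: t[:4])
    chosen = []
    last_end = -1
    for c1, _g1, _g2, _g3, c2, h1, h2 in cands:
        if c1 > last_end:
            chosen.append((c1 + 1, c2 + 1, h1 + 1, h2 + 1))
            last_end = h2
    return chosen


# ---------------------------------------------------------------------------
# exact HWE enumeration oracle in exact rational arithmetic


@lru_cache(maxsize=None)
def _fact(k: int) -> int:
    return math.factorial(k)


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exact conditional HWE p-value from the full probability formula.

    P(h | n, na) = n! / (nAA! h! naa!) * 2^h * na! nb! / (2n)!  summed over
    all heterozygote counts h whose probability does not exceed the observed
    one.  Entirely Fraction-based.
    """
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_alt + n_het
    nb = 2 * n_hom_ref + n_het
    base = Fraction(_fact(na) * _fact(nb) * _fact(n), _fact(2 * n))

    def prob(h: int) -> Fraction:
        naa = (na - h) // 2
        nbb = (nb - h) // 2
        return base * 2**h / (_fact(naa) * _fact(h) * _fact(nbb))

    rare = min(na, nb)
    hets = range(rare % 2, rare + 1, 2)
    p_obs = prob(n_het)
    return sum(prob(h) for h in hets if prob(h) <= p_obs)


# ---------------------------------------------------------------------------
# Fisher exact 2x2 enumeration oracle


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exact hypergeometric enumeration (Fractions)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    denom = math.comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs)


# ---------------------------------------------------------------------------
# plain-Python KL formula oracle


def kl_oracle(r: np.ndarray, s: np.ndarray, pseudocount: float) -> float:
    """Summed KL by direct per-cell formula evaluation in plain Python."""
    r = np.asarray(r, float) + pseudocount
    s = np.asarray(s, float) + pseudocount
    r = r / r.sum(axis=0)
    s = s / s.sum(axis=0)
    total = 0.0
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            total += r[i, j] * math.log(r[i, j] / s[i, j])
            total += s[i, j] * math.log(s[i, j] / r[i, j])
    return total
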