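"""Independent oracles used by the test suite.

These are deliberately naive: arbitrary-precision or exact-rational direct
summation, brute-force re-counting — never the code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import mpmath as mp


def ac_two_sided_grid(x_max: int, y_max: int, n1: float, n2: float,
                      dps: int = 250) -> dict[tuple[int, int], float]:
    """Two-sided Audic-Claverie p for all 0<=x<=x_max, 0<=y<=y_max by direct
    arbitrary-precision summation of the conditional pmf recurrence."""
    with mp.workdps(dps):
        r = mp.mpf(n2) / mp.mpf(n1)
        q = r / (1 + r)
        out: dict[tuple[int, int], float] = {}
        for x in range(x_max + 1):
            pmf = (1 / (1 + r)) ** (x + 1)
            pmfs = [pmf]
            for k in range(1, y_max + 1):
                pmf = pmf * q * mp.mpf(x + k) / k
                pmfs.append(pmf)
            cum = mp.mpf(0)
            for y in range(y_max + 1):
                cum += pmfs[y]
                lower = cum
                upper = 1 - cum + pmfs[y]
                out[(x, y)] = float(min(1, 2 * min(lower, upper)))
        return out


def ac_two_sided_single(x: int, n1: float, y: int, n2: float,
                        dps: int = 250) -> float:
    return ac_two_sided_grid(x, y, n1, n2, dps=dps)[(x, y)]


def hypergeom_upper_tail_exact(N: int, n: int, M: int, m: int) -> Fraction:
    """P(X >= m) as an exact rational: 1 - sum_{i<m} C(M,i) C(N-M,n-i) / C(N,n)."""
    denom = comb(N, n)
    s = sum(comb(M, i) * comb(N - M, n - i) for i in range(m))
    return 1 - Fraction(s, denom)


def bh_stepup(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up q-values by the textbook definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


def classify_reads(reads, adaptors, tag_length=21) -> dict[str, int]:
    """One-pass independent re-count of the raw-read categories (singleton
    removal applied afterwards on the tally)."""
    from collections import Counter
    adaptors = set(adaptors)
    ledger = {"raw": 0, "clean": 0, "adaptor_only": 0, "containing_N": 0,
              "low_quality": 0, "singleton_removed": 0}
    tally = Counter()
    for r in reads:
        ledger["raw"] += 1
        if r == "" or r in adaptors:
            ledger["adaptor_only"] += 1
        elif "N" in r:
            ledger["containing_N"] += 1
        elif len(r) != tag_length or not r.startswith("CATG") \
                or set(r) - set("ACGT"):
            ledger["low_quality"] += 1
        else:
            tally[r] += 1
    for t, c in tally.items():
        if c == 1:
            ledger["singleton_removed"] += 1
        else:
            ledger["clean"] += c
    return ledger


def covered_fraction_bruteforce(length: int, starts, tag_length=21) -> float:
    mask = [False] * length
    for s in starts:
        for i in range(max(0, s), min(length, s + tag_length)):
            mask[i] = True
    return sum(mask) / length
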