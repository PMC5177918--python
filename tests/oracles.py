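"""Independent reference implementations used to check the package.

These deliberately use different algorithms from the implementation:
exact integer hypergeometric enumeration for Fisher's test, literal
step-up recursion for BH, exhaustive depth-first chain search for
collinearity, and containment-filtered clade enumeration for
species-specific clades.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_exact_oracle(a: int, b: int, c: int, d: int, sidedness: str) -> float:
    """Exact hypergeometric p for a 2x2 table via integer enumeration."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, k)
    lo, hi = max(0, k - r2), min(r1, k)
    weights = {x: comb(r1, x) * comb(r2, k - x) for x in range(lo, hi + 1)}
    obs = weights[a]
    if sidedness == "greater":
        num = sum(w for x, w in weights.items() if x >= a)
    elif sidedness == "less":
        num = sum(w for x, w in weights.items() if x <= a)
    else:  # two-sided: all tables no more probable than the observed one
        num = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(num, denom))


def bh_stepup_oracle(p_values: list[float]) -> list[float]:
    """Brute-force Benjamini-Hochberg: q_i = min_{p_(j) >= p_(i)} p_(j)*m/j."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        q_sorted[rank - 1] = running_min
    q = [0.0] * m
    for rank, i in enumerate(indexed, 1):
        q[i] = min(q_sorted[rank - 1], 1.0)
    return q


def exhaustive_longest_chain(
    anchors: list[tuple[int, int]], max_gap: int
) -> int:
    """Length of the longest chain monotone in A and in B (either direction),
    with rank gaps <= max_gap in both genomes, by exhaustive DFS."""

    best = 1 if anchors else 0

    def compatible(prev, nxt, direction):
        pa, pb = prev
        na, nb = nxt
        if na <= pa or direction * (nb - pb) <= 0:
            return False
        return na - pa - 1 <= max_gap and abs(nb - pb) - 1 <= max_gap

    def extend(chain_last, used_len, rest, direction):
        nonlocal best
        best = max(best, used_len)
        for i, a in enumerate(rest):
            if compatible(chain_last, a, direction):
                extend(a, used_len + 1, rest[i + 1 :], direction)

    srt = sorted(anchors)
    for direction in (1, -1):
        for i, a in enumerate(srt):
            extend(a, 1, srt[i + 1 :], direction)
    return best


def clades_oracle(
    clade_tipsets: list[frozenset[str]], tip_species: dict[str, str], min_size: int
) -> dict[str, int]:
    """Maximal monospecific clades by containment filtering over all clades."""
    mono = [
        c
        for c in clade_tipsets
        if len({tip_species[t] for t in c}) == 1
    ]
    maximal = [
        c
        for c in mono
        if len(c) >= min_size
        and not any(c < other for other in mono)
    ]
    counts: dict[str, int] = {}
    for c in maximal:
        sp = tip_species[next(iter(c))]
        counts[sp] = counts.get(sp, 0) + 1
    return counts
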