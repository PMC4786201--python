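"""Independent brute-force oracles shared across test modules."""

import math


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities not exceeding the observed table's, using
    exact integer arithmetic throughout.
    """
    m1, m2 = a + b, c + d
    k = a + c
    n = m1 + m2
    denom = math.comb(n, k)
    obs = math.comb(m1, a) * math.comb(m2, c)
    total = 0
    for a2 in range(max(0, k - m2), min(k, m1) + 1):
        w = math.comb(m1, a2) * math.comb(m2, k - a2)
        if w <= obs:
            total += w
    return total / denom
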