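"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each statistic from first principles (exact
rationals, explicit loops, all-pairs distances) and share no code with the
package implementations they check.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_oracle(table):
    """Exact-rational enumeration of the two-sided Fisher p-value."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)


def wc84_oracle(ns, ps, hs):
    """Direct transcription of the Weir-Cockerham (1984) variance
    components for r populations (sample sizes, allele frequencies,
    heterozygote frequencies). Returns (a, b, c)."""
    r = len(ns)
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def pi_oracle(hap, window_length):
    """All-pairs Hamming-distance nucleotide diversity."""
    n = hap.shape[1]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(hap[:, i] != hap[:, j]))
    return total / (n * (n - 1) / 2) / window_length


def tajima_oracle(hap):
    """Direct-constants Tajima's D on a haplotype matrix."""
    n = hap.shape[1]
    counts = hap.sum(axis=1)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    k = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            k += np.sum(hap[:, i] != hap[:, j])
    k /= n * (n - 1) / 2
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
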