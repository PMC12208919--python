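"""Independent brute-force oracles for small-sample checks.

These deliberately avoid the package's own code paths: diversity is
recomputed from first principles and rarefaction expectations are obtained
by exhaustive enumeration of subsample compositions weighted by their
multivariate hypergeometric probabilities (feasible for n <= ~12).
"""

from itertools import product
from math import comb, exp, log


def shannon_hill(counts):
    """Exponential of Shannon entropy, written independently."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    h = -sum((c / n) * log(c / n) for c in counts)
    return exp(h)


def exact_rarefied_shannon(counts, m):
    """Exact E[D1] over all without-replacement subsamples of size m."""
    counts = [int(c) for c in counts if c > 0]
    n = sum(counts)
    if not (0 < m <= n):
        raise ValueError("m out of range")
    total = comb(n, m)
    expectation = 0.0
    for ks in product(*[range(0, min(c, m) + 1) for c in counts]):
        if sum(ks) != m:
            continue
        weight = 1
        for c, k in zip(counts, ks):
            weight *= comb(c, k)
        expectation += (weight / total) * shannon_hill(ks)
    return expectation
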