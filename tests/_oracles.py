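"""Independent brute-force oracles used to pin expected values in tests.

All hypergeometric computations here use exact integer arithmetic
(math.comb) and are independent of the scipy routines the package calls.
"""

from math import comb


def hypergeom_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided conditional exact p for the 2x2 table [[a, b], [c, d]]:
    sum of probabilities of all tables with the same margins whose
    probability does not exceed the observed table's."""
    N = a + b + c + d
    K = a + c
    n = a + b

    def weight(x: int) -> int:
        return comb(n, x) * comb(N - n, K - x)

    w_obs = weight(a)
    lo = max(0, K - (N - n))
    hi = min(n, K)
    total = sum(w for x in range(lo, hi + 1) if (w := weight(x)) <= w_obs)
    return total / comb(N, K)


def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided enrichment p: P(X >= a) under the table's margins."""
    N = a + b + c + d
    K = a + c
    n = a + b
    hi = min(n, K)
    return sum(comb(n, x) * comb(N - n, K - x) for x in range(a, hi + 1)) / comb(N, K)


def flatten_by_sweep(exon_lists):
    """Brute-force counting-bin oracle: per-base sweep over all breakpoints."""
    bases = set()
    for exons in exon_lists:
        for s, e in exons:
            bases.update(range(s, e))
    if not bases:
        return []
    cuts = sorted({b for exons in exon_lists for iv in exons for b in iv})
    bins = []
    for lo, hi in zip(cuts, cuts[1:]):
        if all(p in bases for p in range(lo, hi)):
            bins.append((lo, hi))
    return bins


def moving_average(values, window: int):
    """Direct per-position truncated moving average (convolution oracle)."""
    if window % 2 == 0:
        window += 1
    half = window // 2
    out = []
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out
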