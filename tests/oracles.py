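"""Independent reference implementations used only to cross-check netrend.

These are deliberately naive (pure-Python loops, textbook formulas) and
share no code with the package paths they verify.
"""

import math

MISSING = -1


def pearson_r2_bruteforce(x, y):
    """Textbook Pearson r, then squared, over pairwise-complete entries.

    Returns (r2, n) or None when fewer than three complete pairs remain or
    a vector is constant among them.
    """
    pairs = [(a, b) for a, b in zip(x, y) if a != MISSING and b != MISSING]
    n = len(pairs)
    if n < 3:
        return None
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a, _ in pairs)
    syy = sum((b - my) ** 2 for _, b in pairs)
    if sxx == 0 or syy == 0:
        return None
    r = sxy / math.sqrt(sxx * syy)
    return r * r, n


def haplotype_r2_bruteforce(a, b):
    """Exhaustive 2x2 haplotype-frequency counting.

    r2 = (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B)) over haplotypes
    complete at both loci; returns (r2, n_individuals) or None.
    """
    pairs = [(u, v) for u, v in zip(a, b) if u != MISSING and v != MISSING]
    nh = len(pairs)
    if nh < 6:
        return None
    p_a = sum(u for u, _ in pairs) / nh
    p_b = sum(v for _, v in pairs) / nh
    p_ab = sum(1 for u, v in pairs if u == 1 and v == 1) / nh
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        return None
    return (p_ab - p_a * p_b) ** 2 / denom, nh // 2


def power_law_edge(min_d, max_d, tot_bins, x, i):
    """Bin edge i (0..tot_bins) of the power-law binning, recomputed from
    the defining formula."""
    return min_d + (max_d - min_d) * (i / tot_bins) ** x
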