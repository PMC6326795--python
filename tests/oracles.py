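"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: plain loops and exact
hypergeometric enumeration only.
"""

from math import comb


def brute_nearest(genes, pos, k):
    """Naive nearest-gene scan: (gene, distance) sorted by (distance, start, id)."""
    scored = []
    for g in genes:
        if g.start <= pos <= g.end:
            d = 0
        else:
            d = min(abs(pos - g.start), abs(pos - g.end))
        scored.append((g, d))
    scored.sort(key=lambda t: (t[1], t[0].start, t[0].gene_id))
    return scored[:k]


def brute_overlap(genes, start, end):
    """Naive closed-interval overlap scan."""
    return sorted(
        (g for g in genes if g.start <= end and start <= g.end),
        key=lambda g: (g.start, g.gene_id),
    )


def hypergeom_prob(a, row1, row2, col1, n):
    """Probability of table [[a, row1-a], [col1-a, ...]] under fixed margins."""
    return comb(row1, a) * comb(row2, col1 - a) / comb(n, col1)


def fisher_two_sided(table):
    """Two-sided Fisher p by exhaustive enumeration over fixed-margin tables.

    Sums the probabilities of all tables no more likely than the observed
    one (with a tiny relative slack against floating-point ties, as exact
    conditional tests conventionally do).
    """
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    p_obs = hypergeom_prob(a, row1, row2, col1, n)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = hypergeom_prob(x, row1, row2, col1, n)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)
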