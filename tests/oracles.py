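"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by the most literal route available
(exhaustive enumeration, replay, naive agglomeration) without touching the
package's implementation or the scipy shortcuts behind it.
"""

import itertools

import numpy as np


def binom_cdf_enumeration(k, n, p):
    """P(X <= k) by summing the probability of every 0/1 outcome string."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=n):
        if sum(outcome) <= k:
            total += (p ** sum(outcome)) * ((1 - p) ** (n - sum(outcome)))
    return total


def bh_brute_force(p_values, q):
    """BH step-up critical value by scanning every index explicitly."""
    p = sorted(p_values)
    m = len(p)
    best = 0.0
    for i in range(1, m + 1):
        if p[i - 1] <= (i / m) * q:
            best = p[i - 1]
    return best


def greedy_oracle(hits, e_cutoff=1e-20):
    """Replay of the one-to-one rule: repeatedly scan remaining sub-cutoff
    hits for the best (lowest E, highest bitscore, lexicographic IDs) and
    accept it when both endpoints are free."""
    remaining = [h for h in hits if h.e_value < e_cutoff]
    genes, proteins, out = set(), set(), {}
    while remaining:
        best = min(
            remaining,
            key=lambda h: (h.e_value, -h.bitscore, h.query_gene, h.subject_protein),
        )
        remaining.remove(best)
        if best.query_gene not in genes and best.subject_protein not in proteins:
            out[best.query_gene] = (best.subject_protein, best.e_value)
            genes.add(best.query_gene)
            proteins.add(best.subject_protein)
    return out


def upgma_oracle(dist):
    """Group-average agglomeration over explicit leaf lists; returns the
    sorted merge heights."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)
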