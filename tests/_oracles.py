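"""Independent brute-force reference implementations.

Each oracle computes its statistic by direct enumeration from first
principles (pairwise loops, textbook formulas, explicit haplotype
counting) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def pi_pairwise(haplotypes: np.ndarray, L: float) -> float:
    """Average pairwise difference per site by enumerating all pairs of
    haplotype rows (binary matrix, rows = chromosomes)."""
    n = haplotypes.shape[0]
    total = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int((haplotypes[i] != haplotypes[j]).sum())
        pairs += 1
    return total / pairs / L if pairs else 0.0


def pi_from_counts_missing(counts: np.ndarray, L: float) -> float:
    """Pi with missing data (-1) handled per variant: average pairwise
    allele difference among non-missing chromosomes, summed over
    variants.  ``counts`` is (variants, samples) diploid counts."""
    total = 0.0
    for row in counts:
        alleles = []
        for c in row:
            if c >= 0:
                alleles.extend([1] * int(c) + [0] * (2 - int(c)))
        n = len(alleles)
        if n < 2:
            continue
        k = sum(alleles)
        total += 2 * k * (n - k) / (n * (n - 1))
    return total / L


def watterson(S: int, n: int, L: float) -> float:
    a1 = sum(1.0 / i for i in range(1, n))
    return S / a1 / L if S else 0.0


def tajimas_d(haplotypes: np.ndarray) -> float | None:
    """Textbook Tajima's D from a binary haplotype matrix."""
    n, _ = haplotypes.shape
    counts = haplotypes.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0:
        return None
    pi_total = 0.0
    for i, j in itertools.combinations(range(n), 2):
        pi_total += int((haplotypes[i] != haplotypes[j]).sum())
    pi_total /= n * (n - 1) / 2
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def r2_haplotype_counting(a: np.ndarray, b: np.ndarray) -> float:
    """r^2 from explicit two-locus haplotype frequency counting."""
    n = len(a)
    pAB = sum(1 for x, y in zip(a, b) if x == 1 and y == 1) / n
    pA = sum(a) / n
    pB = sum(b) / n
    D = pAB - pA * pB
    return D * D / (pA * (1 - pA) * pB * (1 - pB))


def hudson_fst(k1, n1, k2, n2) -> tuple[float, float]:
    """Single-site Hudson numerator/denominator by direct arithmetic."""
    p1, p2 = k1 / n1, k2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def p_distance(ca: np.ndarray, cb: np.ndarray) -> float:
    """Diploid allele-sharing distance with missing (-1) removal."""
    tot, n = 0.0, 0
    for x, y in zip(ca, cb):
        if x >= 0 and y >= 0:
            tot += abs(int(x) - int(y)) / 2
            n += 1
    return tot / n


_CODE = {}


def _codon_table():
    global _CODE
    if not _CODE:
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        _CODE = {
            a + b + c: aas[16 * i + 4 * j + k]
            for i, a in enumerate(bases)
            for j, b in enumerate(bases)
            for k, c in enumerate(bases)
        }
    return _CODE


def ng86_sites(codon: str) -> tuple[float, float]:
    """Nei-Gojobori synonymous/nonsynonymous site fractions by
    enumerating all nine single-base changes against an independently
    hard-coded standard genetic code."""
    table = _codon_table()
    aa = table[codon]
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if table[alt] == aa:
                syn += 1
    return syn / 3, 3 - syn / 3


def nj_three_taxa(d_ab, d_ac, d_bc):
    """Closed-form branch lengths for the unique 3-taxon tree."""
    a = (d_ab + d_ac - d_bc) / 2
    b = (d_ab + d_bc - d_ac) / 2
    c = (d_ac + d_bc - d_ab) / 2
    return a, b, c


def additive_matrix_from_tree(adj: dict, leaves: list) -> np.ndarray:
    """Path-length distance matrix on a weighted tree given as an
    adjacency dict {node: [(nbr, w), ...]}."""
    import heapq

    D = np.zeros((len(leaves), len(leaves)))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, np.inf):
                continue
            for v, w in adj[u]:
                nd = d + w
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        for j, dst in enumerate(leaves):
            D[i, j] = dist[dst]
    return D
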