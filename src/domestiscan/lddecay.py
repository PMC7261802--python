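"""Pairwise r-squared linkage disequilibrium and its decay with
physical distance.

For phased haplotypes r^2 is the squared correlation of the 0/1 allele
indicators (equivalently D^2 / (pA qA pB qB)); when phase is not
available, genotype mode uses the squared Pearson correlation of the
diploid allele counts (the composite estimate), which agrees with the
phased value under Hardy-Weinberg proportions.

The single-number "decay distance" summary is the distance at which
the smoothed bin-mean curve first falls to half its maximum (or,
optionally, below a fixed threshold); the definition used is stamped
into every output because published decay values rarely state one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

__all__ = ["r2_pair", "LdDecayCurve", "decay_curve", "pairwise_r2"]


def r2_pair(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r^2 between two binary sites over jointly non-missing haplotypes.

    Entries < 0 are treated as missing.  Raises if either site is
    monomorphic after missing-data removal.
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic site after missing-data removal")
    pab = (a * b).mean()
    D = pab - pa * pb
    return float(D * D / (pa * (1 - pa) * pb * (1 - pb)))


def pairwise_r2(M: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between columns i and j of M
    (haplotype or genotype matrix, rows = chromosomes/samples), missing
    entries (< 0) handled pairwise."""
    out = np.empty(i.size, dtype=float)
    has_missing = (M < 0).any()
    if not has_missing:
        Mc = M - M.mean(axis=0, keepdims=True)
        ss = (Mc**2).sum(axis=0)
        cov = np.einsum("ni,ni->i", Mc[:, i], Mc[:, j])
        with np.errstate(invalid="ignore", divide="ignore"):
            out = cov**2 / (ss[i] * ss[j])
        out[(ss[i] == 0) | (ss[j] == 0)] = np.nan
        return out
    for t in range(i.size):
        a, b = M[:, i[t]].astype(float), M[:, j[t]].astype(float)
        ok = (a >= 0) & (b >= 0)
        a, b = a[ok], b[ok]
        if a.size < 2 or a.var() == 0 or b.var() == 0:
            out[t] = np.nan
            continue
        c = np.corrcoef(a, b)[0, 1]
        out[t] = c * c
    return out


@dataclass
class LdDecayCurve:
    bin_edges: np.ndarray  # bp, len = n_bins + 1
    mean_r2: np.ndarray  # NaN where empty
    pair_counts: np.ndarray
    decay_distance: Optional[float]  # bp; None when never crossing
    definition: str  # stamped definition of the decay summary
    n_pairs_used: int

    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def decay_curve(
    M: np.ndarray,
    positions: np.ndarray,
    max_dist: int = 500_000,
    bin_width: int = 1_000,
    mode: Literal["phased", "genotype"] = "phased",
    maf: float = 0.05,
    max_pairs: int = 2_000_000,
    seed: int = 0,
    decay_definition: Literal["half-max", "threshold"] = "half-max",
    threshold: float = 0.1,
) -> LdDecayCurve:
    """Mean r^2 in distance bins for all within-contig site pairs up to
    ``max_dist`` apart, plus the decay-distance summary.

    ``M`` is (chromosomes x variants) 0/1 for phased mode or
    (samples x variants) 0/1/2 for genotype mode, missing < 0.  Sites
    below the ``maf`` floor are excluded (rare variants make r^2
    unstable).  When the pair count exceeds ``max_pairs`` a uniform
    seeded subsample is scored instead.
    """
    M = np.asarray(M)
    positions = np.asarray(positions, dtype=np.int64)
    if M.shape[1] != positions.size:
        raise ValueError("matrix/positions length mismatch")
    ploidy = 1 if mode == "phased" else 2
    valid = M >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(valid, M, 0).sum(axis=0) / (ploidy * valid.sum(axis=0))
    keep = (freq >= maf) & (freq <= 1 - maf)
    M = M[:, keep]
    positions = positions[keep]
    n_sites = positions.size

    pairs_i, pairs_j = [], []
    hi = np.searchsorted(positions, positions + max_dist, side="right")
    for a in range(n_sites):
        if hi[a] > a + 1:
            j = np.arange(a + 1, hi[a])
            pairs_i.append(np.full(j.size, a))
            pairs_j.append(j)
    if not pairs_i:
        raise ValueError("no usable site pairs within max_dist")
    i = np.concatenate(pairs_i)
    j = np.concatenate(pairs_j)
    if i.size > max_pairs:
        sel = np.random.default_rng(seed).choice(i.size, size=max_pairs, replace=False)
        sel.sort()
        i, j = i[sel], j[sel]

    r2 = pairwise_r2(M, i, j)
    dist = positions[j] - positions[i]
    ok = ~np.isnan(r2)
    r2, dist = r2[ok], dist[ok]

    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width
    which = np.minimum(dist // bin_width, n_bins - 1).astype(int)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=r2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    decay, definition = _decay_distance(
        edges, means, decay_definition, threshold
    )
    return LdDecayCurve(
        bin_edges=edges,
        mean_r2=means,
        pair_counts=counts,
        decay_distance=decay,
        definition=definition,
        n_pairs_used=int(r2.size),
    )


def _decay_distance(edges, means, definition, threshold):
    """Distance where the monotone-smoothed curve first reaches the
    target level (half of max, or a fixed r^2)."""
    filled = np.asarray(means, dtype=float)
    have = ~np.isnan(filled)
    if not have.any():
        return None, definition
    # monotone non-increasing envelope over observed bins
    smooth = np.minimum.accumulate(np.where(have, filled, np.inf))
    smooth[~np.isfinite(smooth)] = np.nan
    if definition == "half-max":
        target = 0.5 * np.nanmax(smooth)
        label = "half-max of smoothed bin means"
    elif definition == "threshold":
        target = threshold
        label = f"smoothed bin mean r2 <= {threshold}"
    else:
        raise ValueError(f"unknown decay definition {definition!r}")
    centers = 0.5 * (edges[:-1] + edges[1:])
    below = np.nonzero(smooth <= target)[0]
    if below.size == 0:
        return None, label
    first = below[0]
    if first == 0:
        return float(centers[0]), label
    return float(centers[first]), label
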