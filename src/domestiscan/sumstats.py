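"""Within-population diversity: theta-pi, Watterson's theta-w,
Tajima's D, and segregating sites, per window and genome-wide.

All estimators are missing-data aware: the chromosome count n at each
variant is the number of non-missing alleles in the group, and the
k(n-k) heterozygosity terms use that per-variant n.  The normalizing
constants of Tajima's D, which need a single n, use the median
per-variant n across the window.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .popio import GenotypeMatrix, PopulationMap, Window, assign_to_windows

logger = logging.getLogger(__name__)

__all__ = [
    "harmonic",
    "theta_pi",
    "theta_w",
    "tajimas_d",
    "window_stats",
    "sliding_stats",
    "genome_wide_stats",
    "group_counts",
]


def harmonic(n: int, power: int = 1) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i (power=1) or a2 with 1/i^2 (power=2)."""
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


def theta_pi(k: np.ndarray, n: np.ndarray, L: float) -> float:
    """Per-site nucleotide diversity over a window.

    ``k`` is the derived/alternate allele count and ``n`` the number of
    non-missing chromosomes at each variant; pi is the mean pairwise
    difference sum_v 2 k (n - k) / (n (n - 1)) scaled by span ``L``.
    Variants with n < 2 are skipped (logged).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if L < 1:
        raise ValueError("window length must be >= 1")
    usable = n >= 2
    if not usable.all():
        logger.info("theta_pi: skipping %d variant(s) with n < 2", int((~usable).sum()))
    k, n = k[usable], n[usable]
    if k.size == 0:
        return 0.0
    return float(np.sum(2.0 * k * (n - k) / (n * (n - 1.0))) / L)


def theta_w(S: int, n: int, L: float) -> float:
    """Watterson's estimator S / (a1 * L) per site."""
    if n < 2:
        raise ValueError("theta_w requires n >= 2")
    if L < 1:
        raise ValueError("window length must be >= 1")
    if S == 0:
        return 0.0
    return float(S / (harmonic(n) * L))


def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of the D variance for sample size n chromosomes."""
    a1 = harmonic(n)
    a2 = harmonic(n, power=2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(k: np.ndarray, n: np.ndarray) -> Optional[float]:
    """Tajima's D for one window from per-variant allele counts.

    D = (pi_total - S/a1) / sqrt(e1 S + e2 S (S-1)) with pi_total the
    window *sum* of pairwise differences.  Returns None (absent) when
    S = 0, where the statistic is undefined.  The constants use the
    median per-variant chromosome count.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    usable = (n >= 2) & (k > 0) & (k < n)
    k, n = k[usable], n[usable]
    S = k.size
    if S == 0:
        return None
    n_med = int(np.median(n))
    if n_med < 2:
        return None
    pi_total = float(np.sum(2.0 * k * (n - k) / (n * (n - 1.0))))
    a1 = harmonic(n_med)
    e1, e2 = _tajima_constants(n_med)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return None
    return float((pi_total - S / a1) / np.sqrt(var))


def group_counts(G: GenotypeMatrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant (alt allele count, non-missing chromosome count) for
    the samples at column indices ``idx``."""
    sub = G.counts[:, idx]
    valid = sub >= 0
    n = 2 * valid.sum(axis=1)
    k = np.where(valid, sub, 0).sum(axis=1)
    return k.astype(np.int64), n.astype(np.int64)


def window_stats(k: np.ndarray, n: np.ndarray, L: float, min_n: int = 2) -> dict:
    """All diversity statistics for one window; counts k of n per variant."""
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    seg = (n >= max(min_n, 2)) & (k > 0) & (k < n)
    ks, ns = k[seg], n[seg]
    S = int(ks.size)
    pi = theta_pi(ks, ns, L) if S else 0.0
    n_med = int(np.median(ns)) if S else 0
    tw = theta_w(S, n_med, L) if S and n_med >= 2 else 0.0
    D = tajimas_d(ks, ns) if S else None
    return {
        "n_chrom": n_med,
        "S": S,
        "theta_pi": pi,
        "theta_w": tw,
        "tajimas_d": D,
        "length": L,
    }


def sliding_stats(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    windows: list[Window],
    groups: Optional[list[str]] = None,
    min_samples: int = 6,
) -> pd.DataFrame:
    """One row of diversity statistics per (window, group).

    Groups with fewer than ``min_samples`` samples get their SNP counts
    reported but theta/D left absent (NaN), mirroring how small panels
    are summarized in resequencing studies.
    """
    if not windows:
        raise ValueError("empty window set")
    groups = groups if groups is not None else popmap.groups
    by_window = assign_to_windows(G.positions, windows)
    rows = []
    for group in groups:
        idx = popmap.group_indices(G.samples, group)
        k_all, n_all = group_counts(G, idx)
        suppress = idx.size < min_samples
        for w, vidx in zip(windows, by_window):
            st = window_stats(k_all[vidx], n_all[vidx], w.end - w.start)
            row = {
                "contig": w.contig,
                "start": w.start,
                "end": w.end,
                "window": w.index,
                "group": group,
                "n_samples": idx.size,
                **st,
            }
            if suppress:
                row["theta_pi"] = np.nan
                row["theta_w"] = np.nan
                row["tajimas_d"] = np.nan
            rows.append(row)
    df = pd.DataFrame(rows)
    df["tajimas_d"] = df["tajimas_d"].astype(float)
    return df


def genome_wide_stats(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    total_length: int,
    groups: Optional[list[str]] = None,
    min_samples: int = 6,
) -> pd.DataFrame:
    """Genome-wide pooled summary per group (the whole-genome layout of
    a per-population diversity table: S, theta-pi, theta-w, D)."""
    groups = groups if groups is not None else popmap.groups
    rows = []
    for group in groups:
        idx = popmap.group_indices(G.samples, group)
        k, n = group_counts(G, idx)
        st = window_stats(k, n, total_length)
        if idx.size < min_samples:
            st["theta_pi"] = np.nan
            st["theta_w"] = np.nan
            st["tajimas_d"] = np.nan
        rows.append({"group": group, "n_samples": idx.size, **st})
    df = pd.DataFrame(rows)
    df["tajimas_d"] = df["tajimas_d"].astype(float)
    return df
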