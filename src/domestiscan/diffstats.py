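"""Between-population differentiation: FST tracks and the
wild/domesticated diversity-ratio track.

The default FST estimator is Hudson's (1992) with ratio-of-averages
window aggregation, which is robust to unequal sample sizes; a
Weir-Cockerham variant is available behind a flag for sensitivity
analysis.  Negative windowed values are reported as computed, not
clamped.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .popio import GenotypeMatrix, PopulationMap, Window, assign_to_windows
from .sumstats import group_counts

logger = logging.getLogger(__name__)

__all__ = [
    "hudson_fst_site",
    "weir_cockerham_site",
    "fst_windows",
    "fst_genome_wide",
    "pi_ratio",
]


def hudson_fst_site(k1, n1, k2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Hudson estimator numerator and denominator per site.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    Sites with n < 2 in either population yield NaN and should be
    excluded from window sums.
    """
    k1 = np.asarray(k1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = k1 / n1
        p2 = k2 / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return num, den


def weir_cockerham_site(k1, n1, k2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) two-population variance components.

    Returns (a, a+b+c) per site, so ratio-of-averages works the same
    way as for Hudson.  Chromosome counts n are haploid sample sizes.
    """
    k1 = np.asarray(k1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = k1 / n1, k2 / n2
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        # haploid allele-count formulation (no heterozygosity term)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        tot = a + b
    return np.where(ok, a, np.nan), np.where(ok, tot, np.nan)


_ESTIMATORS = {"hudson": hudson_fst_site, "weir-cockerham": weir_cockerham_site}


def _site_components(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    group_a: str,
    group_b: str,
    estimator: str,
) -> tuple[np.ndarray, np.ndarray]:
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown FST estimator {estimator!r}")
    ia = popmap.group_indices(G.samples, group_a)
    ib = popmap.group_indices(G.samples, group_b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both groups need at least 2 samples for FST")
    k1, n1 = group_counts(G, ia)
    k2, n2 = group_counts(G, ib)
    num, den = _ESTIMATORS[estimator](k1, n1, k2, n2)
    skipped = int(np.isnan(num).sum())
    if skipped:
        logger.info("fst: %d site(s) skipped (n < 2 in a population)", skipped)
    # monomorphic-overall sites contribute nothing; keep den>0 sites
    return num, den


def fst_windows(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    group_a: str,
    group_b: str,
    windows: list[Window],
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Windowed FST via ratio of averages (sum num / sum den)."""
    num, den = _site_components(G, popmap, group_a, group_b, estimator)
    by_window = assign_to_windows(G.positions, windows)
    rows = []
    for w, vidx in zip(windows, by_window):
        nv, dv = num[vidx], den[vidx]
        ok = ~np.isnan(nv) & (dv > 0)
        nsum, dsum = float(np.nansum(nv[ok])), float(np.nansum(dv[ok]))
        rows.append(
            {
                "contig": w.contig,
                "start": w.start,
                "end": w.end,
                "window": w.index,
                "fst": nsum / dsum if dsum > 0 else np.nan,
                "num_sum": nsum,
                "den_sum": dsum,
                "n_snps": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)


def fst_genome_wide(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    group_a: str,
    group_b: str,
    estimator: str = "hudson",
) -> float:
    """Genome-wide ratio-of-averages FST between two groups."""
    num, den = _site_components(G, popmap, group_a, group_b, estimator)
    ok = ~np.isnan(num) & (den > 0)
    if not ok.any():
        raise ValueError("no usable sites for genome-wide FST")
    return float(num[ok].sum() / den[ok].sum())


def pi_ratio(
    wild_stats: pd.DataFrame,
    dom_stats: pd.DataFrame,
    orientation: str = "wild/dom",
) -> pd.DataFrame:
    """Per-window diversity ratio between a wild and a domesticated
    group's window tables (as produced by ``sliding_stats`` for one
    group each).

    With the default orientation, larger values mean stronger diversity
    loss in the domesticate.  Windows where the denominator is 0 while
    the numerator is positive are flagged infinite and rank above every
    finite window in the outlier rule.
    """
    for col in ("window", "start", "end"):
        if not np.array_equal(wild_stats[col].values, dom_stats[col].values):
            raise ValueError("wild and domesticated tables use different windows")
    if orientation not in ("wild/dom", "dom/wild"):
        raise ValueError("orientation must be 'wild/dom' or 'dom/wild'")
    a = wild_stats["theta_pi"].values.astype(float)
    b = dom_stats["theta_pi"].values.astype(float)
    if orientation == "dom/wild":
        a, b = b, a
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b > 0, a / b, np.nan)
    infinite = (b == 0) & (a > 0)
    out = wild_stats[["contig", "start", "end", "window"]].copy()
    out["pi_wild"] = wild_stats["theta_pi"].values
    out["pi_dom"] = dom_stats["theta_pi"].values
    out["ratio"] = ratio
    out["infinite"] = infinite
    out.attrs["orientation"] = orientation
    return out
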