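"""Domestication-region calling by the joint top-5% outlier rule.

A window is called selected when its diversity statistic (by default
the wild/domesticated pi-ratio) is in the genome-wide top 5% AND at
least one top-5% XP-CLR grid point lies inside it.  Selected windows
within a merge gap collapse into regions, and regions are mapped to the
genes they overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .popio import GeneModel

logger = logging.getLogger(__name__)

__all__ = ["top_quantile_mask", "call_regions", "map_genes", "SelectedRegion"]


@dataclass
class SelectedRegion:
    contig: str
    start: int
    end: int
    windows: list[int]
    max_pi_ratio: float
    max_xpclr: float
    genes: list[str]


def top_quantile_mask(
    values: np.ndarray,
    q: float = 0.95,
    infinite: Optional[np.ndarray] = None,
    contigs: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Boolean mask of entries at or above the genome-wide ``q``
    quantile of the finite values; ties at the threshold are included,
    infinite-flagged entries are always included, NaN never.

    Passing ``contigs`` switches to a per-chromosome threshold (one
    quantile per contig) instead of one genome-wide distribution.
    """
    values = np.asarray(values, dtype=float)
    if infinite is None:
        infinite = np.zeros(values.shape, dtype=bool)
    infinite = np.asarray(infinite, dtype=bool)
    if contigs is not None:
        contigs = np.asarray(contigs)
        mask = np.zeros(values.shape, dtype=bool)
        for c in np.unique(contigs):
            sel = contigs == c
            mask[sel] = top_quantile_mask(values[sel], q, infinite[sel])
        return mask
    finite = np.isfinite(values) & ~infinite
    if finite.sum() < 20:
        raise ValueError(
            f"need >= 20 finite values for a top-quantile cut; have {int(finite.sum())}"
        )
    threshold = float(np.quantile(values[finite], q))
    vmax = float(values[finite].max())
    if threshold == float(values[finite].min()) == vmax:
        logger.warning("all values equal; the quantile mask selects everything")
    mask = np.zeros(values.shape, dtype=bool)
    mask[finite] = values[finite] >= threshold
    mask |= infinite
    return mask


def _nanmax2(a: float, b: float) -> float:
    vals = [v for v in (a, b) if not np.isnan(v)]
    return max(vals) if vals else np.nan


def call_regions(
    windows: pd.DataFrame,
    pi_mask: np.ndarray,
    xpclr_positions: np.ndarray,
    xpclr_mask: np.ndarray,
    merge_gap: int = 0,
    pi_values: Optional[np.ndarray] = None,
    xpclr_scores: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Intersect window and grid-point masks and merge into regions.

    ``windows`` needs contig/start/end/window columns on the same
    coordinate system as the 1-based ``xpclr_positions``.  A window is
    selected iff its own mask is true and at least one true grid point
    falls inside it; selected windows closer than ``merge_gap`` merge.
    """
    if len(pi_mask) != len(windows):
        raise ValueError("pi mask / window table length mismatch")
    if len(xpclr_positions) != len(xpclr_mask):
        raise ValueError("XP-CLR positions / mask length mismatch")
    xpos = np.asarray(xpclr_positions, dtype=np.int64) - 1  # to 0-based
    xmask = np.asarray(xpclr_mask, dtype=bool)
    xsel = np.sort(xpos[xmask])

    sel_rows = []
    for i, row in enumerate(windows.itertuples(index=False)):
        if not pi_mask[i]:
            continue
        lo = np.searchsorted(xsel, row.start)
        hi = np.searchsorted(xsel, row.end)
        if hi > lo:
            sel_rows.append(i)

    regions: list[dict] = []
    for i in sel_rows:
        w = windows.iloc[i]
        pi_v = float(pi_values[i]) if pi_values is not None else np.nan
        in_win = (
            (np.asarray(xpclr_positions) - 1 >= w.start)
            & (np.asarray(xpclr_positions) - 1 < w.end)
        )
        xp_v = (
            float(np.nanmax(np.asarray(xpclr_scores, dtype=float)[in_win]))
            if xpclr_scores is not None and in_win.any()
            else np.nan
        )
        if (
            regions
            and regions[-1]["contig"] == w.contig
            and w.start - regions[-1]["end"] <= merge_gap
        ):
            r = regions[-1]
            r["end"] = max(r["end"], int(w.end))
            r["windows"].append(int(w.window))
            r["max_pi_ratio"] = _nanmax2(r["max_pi_ratio"], pi_v)
            r["max_xpclr"] = _nanmax2(r["max_xpclr"], xp_v)
        else:
            regions.append(
                {
                    "contig": w.contig,
                    "start": int(w.start),
                    "end": int(w.end),
                    "windows": [int(w.window)],
                    "max_pi_ratio": pi_v,
                    "max_xpclr": xp_v,
                }
            )
    return pd.DataFrame(
        regions, columns=["contig", "start", "end", "windows", "max_pi_ratio", "max_xpclr"]
    )


def map_genes(
    regions: pd.DataFrame,
    genes: list[GeneModel],
    min_overlap_bp: int = 1,
) -> tuple[pd.DataFrame, list[str]]:
    """Overlap regions with gene spans (half-open coordinates).

    Returns the region table with a ``genes`` column added, plus the
    flat deduplicated candidate gene list.
    """
    out = regions.copy()
    per_region: list[list[str]] = []
    candidates: list[str] = []
    seen = set()
    for row in regions.itertuples(index=False):
        hits = [
            g.gene_id
            for g in genes
            if g.contig == row.contig
            and min(g.end, row.end) - max(g.start, row.start) >= min_overlap_bp
        ]
        per_region.append(hits)
        for gid in hits:
            if gid not in seen:
                seen.add(gid)
                candidates.append(gid)
    out["genes"] = per_region
    return out, candidates
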