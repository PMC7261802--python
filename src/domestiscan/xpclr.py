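"""Cross-population composite likelihood ratio (XP-CLR) sweep scan.

The scan contrasts two models for the derived-allele count k (out of n
chromosomes) in an object population given the allele frequency p1 in a
reference population:

* Neutral drift: p2 | p1 ~ Normal(p1, omega * p1 * (1 - p1)) truncated
  to (0, 1), with the escaped mass placed as point masses at 0 and 1;
  omega is the moment-estimated drift time (in 2N units) between the
  populations.

* Hard sweep at map distance r_dist (Morgans) from the site, with
  selection coefficient s: a linked lineage escapes the sweep with
  probability c = 1 - exp(-(r_dist / s) * ln(2 N s)) (star-like
  approximation).  With probability c the neutral frequency is kept;
  with probability 1 - c the site hitchhikes deterministically to
  fixation of its background, 1 with probability equal to its pre-sweep
  frequency and 0 otherwise.

Both are integrated over p2 with Gauss-Legendre nodes placed through
the probability transform of the truncated normal, then over the
binomial sampling of k.  The composite score at a grid position x is
2 * max_s sum_k w_k [ log L_sweep - log L_neutral ], with SNP weights
w_k down-weighting clusters of SNPs in high LD in the reference
population; the s grid includes 0 (defined as ratio 0), so scores are
never negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

from .lddecay import pairwise_r2
from .popio import GenotypeMatrix, PopulationMap
from .sumstats import group_counts

logger = logging.getLogger(__name__)

__all__ = [
    "XpclrConfig",
    "estimate_drift",
    "neutral_loglik",
    "sweep_loglik",
    "xpclr_scan",
]

_DEFAULT_S_GRID = (0.0, 0.0025, 0.005, 0.01, 0.025, 0.05, 0.1, 0.2)


@dataclass(frozen=True)
class XpclrConfig:
    """Scan geometry and model parameters.

    ``rec_rate_cm_per_mb`` converts physical to genetic distance with a
    single uniform rate (1 cM/Mb default); ``effective_size`` is the N
    in the escape probability; SNPs whose pairwise r^2 in the reference
    group exceeds ``r2_max`` share their weight.
    """

    grid_spacing: int = 2_000
    radius: int = 25_000
    s_grid: tuple[float, ...] = _DEFAULT_S_GRID
    effective_size: int = 1_000
    r2_max: float = 0.95
    ref_maf: float = 0.05
    rec_rate_cm_per_mb: float = 1.0
    n_nodes: int = 64
    max_snps_per_window: int = 200
    min_neutral_snps: int = 50
    # average both polarizations when ancestral states are unknown
    folded: bool = False

    def __post_init__(self):
        s = tuple(sorted(self.s_grid))
        if 0.0 not in s:
            raise ValueError("selection grid must contain 0")
        object.__setattr__(self, "s_grid", s)
        if self.radius <= 0 or self.grid_spacing <= 0:
            raise ValueError("radius and grid_spacing must be > 0")

    def usable_s(self) -> list[float]:
        """Positive grid values satisfying the sweep model's 2*N*s > 1;
        values outside it are skipped with a warning at scan time."""
        return [s for s in self.s_grid if s > 0 and 2 * self.effective_size * s > 1]

    @property
    def morgans_per_bp(self) -> float:
        return self.rec_rate_cm_per_mb * 1e-8


def estimate_drift(
    ref_k: np.ndarray,
    ref_n: np.ndarray,
    obj_k: np.ndarray,
    obj_n: np.ndarray,
    min_snps: int = 50,
) -> float:
    """Moment estimator of the drift parameter omega.

    omega = E[(p2 - p1)^2 / (p1 (1 - p1))] over SNPs segregating in the
    reference, with the binomial sampling variance of both sample
    frequencies subtracted (unbiased p(1-p) uses n/(n-1)) so that the
    estimate targets true drift, not sampling noise.  Clamped at 0.
    """
    ref_k = np.asarray(ref_k, dtype=float)
    ref_n = np.asarray(ref_n, dtype=float)
    obj_k = np.asarray(obj_k, dtype=float)
    obj_n = np.asarray(obj_n, dtype=float)
    ok = (ref_n >= 2) & (obj_n >= 2)
    p1 = np.where(ok, ref_k / np.maximum(ref_n, 1), 0.0)
    usable = ok & (p1 > 0) & (p1 < 1)
    if usable.sum() < min_snps:
        raise ValueError(
            f"need >= {min_snps} SNPs segregating in the reference to "
            f"estimate drift; have {int(usable.sum())}"
        )
    p1 = ref_k[usable] / ref_n[usable]
    p2 = obj_k[usable] / obj_n[usable]
    n1, n2 = ref_n[usable], obj_n[usable]
    var1 = p1 * (1 - p1) / (n1 - 1)
    var2 = p2 * (1 - p2) / (n2 - 1)
    het1 = p1 * (1 - p1) * n1 / (n1 - 1)  # unbiased p1(1-p1)
    num = (p1 - p2) ** 2 - var1 - var2
    omega = float(np.mean(num / het1))
    if omega < 0:
        logger.warning("drift estimate %.3g < 0; clamped to 0", omega)
        omega = 0.0
    return omega


def _freq_nodes(p1: float, omega: float, n_nodes: int) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Integration nodes for the truncated-normal drift density.

    Returns (x, w, m0, m1): node frequencies in (0,1), their weights
    (summing to the continuous mass 1 - m0 - m1), and the boundary
    point masses.  Nodes are Gauss-Legendre in the probability domain
    of the untruncated normal, so small omega (a near-point mass at p1)
    is integrated as accurately as large omega.
    """
    var = omega * p1 * (1 - p1)
    if var < 1e-12:
        return np.array([p1]), np.array([1.0]), 0.0, 0.0
    sigma = np.sqrt(var)
    lo = stats.norm.cdf(0.0, loc=p1, scale=sigma)
    hi = stats.norm.cdf(1.0, loc=p1, scale=sigma)
    m0, m1 = float(lo), float(1.0 - hi)
    z, gw = np.polynomial.legendre.leggauss(n_nodes)
    u = lo + (hi - lo) * (z + 1.0) / 2.0
    x = special.ndtri(u) * sigma + p1
    w = gw * (hi - lo) / 2.0
    x = np.clip(x, 1e-12, 1 - 1e-12)
    return x, w, m0, m1


def _site_pieces(k: int, n: int, p1: float, omega: float, n_nodes: int) -> dict:
    """Everything site-level the two likelihoods share."""
    x, w, m0, m1 = _freq_nodes(p1, omega, n_nodes)
    b = stats.binom.pmf(k, n, x)
    cont = float(np.dot(w, b))  # integral of Binom * density over (0,1)
    mu = float(np.dot(w, x) + m1)  # E[p2] including boundary masses
    return {
        "cont": cont,
        "m0": m0,
        "m1": m1,
        "mu": mu,
        "at0": 1.0 if k == 0 else 0.0,
        "atn": 1.0 if k == n else 0.0,
    }


_LOG_FLOOR = 1e-300


def neutral_loglik(k: int, n: int, p1: float, omega: float, n_nodes: int = 64) -> float:
    """log P(k | n, p1, omega) under pure drift."""
    if not (0 <= k <= n) or not (0.0 < p1 < 1.0) or omega < 0:
        raise ValueError("require 0 <= k <= n, 0 < p1 < 1, omega >= 0")
    pc = _site_pieces(k, n, p1, omega, n_nodes)
    p = pc["cont"] + pc["m0"] * pc["at0"] + pc["m1"] * pc["atn"]
    return float(np.log(max(p, _LOG_FLOOR)))


def escape_probability(r_dist: float, s: float, N: int) -> float:
    """Probability a lineage at map distance r_dist (Morgans) escapes a
    hard sweep of strength s: c = 1 - exp(-(r_dist/s) ln(2Ns))."""
    if s <= 0 or r_dist < 0:
        raise ValueError("require s > 0 and r_dist >= 0")
    if 2 * N * s <= 1:
        raise ValueError("sweep model requires 2*N*s > 1")
    c = 1.0 - np.exp(-(r_dist / s) * np.log(2 * N * s))
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"escape probability {c} outside [0, 1]")
    return float(c)


def sweep_loglik(
    k: int,
    n: int,
    p1: float,
    omega: float,
    s: float,
    r_dist: float,
    N: int,
    n_nodes: int = 64,
) -> float:
    """log P(k) under the sweep-transformed frequency distribution.

    The post-sweep distribution is the c-mixture: the neutral density
    scaled by c, plus boundary masses that absorb the hitchhiked
    fraction (1 - c) split between fixation (with probability equal to
    the pre-sweep mean frequency) and loss.
    """
    c = escape_probability(r_dist, s, N)
    pc = _site_pieces(k, n, p1, omega, n_nodes)
    m1s = c * pc["m1"] + (1 - c) * pc["mu"]
    m0s = c * pc["m0"] + (1 - c) * (1 - pc["mu"])
    p = c * pc["cont"] + m0s * pc["at0"] + m1s * pc["atn"]
    return float(np.log(max(p, _LOG_FLOOR)))


def _ld_weights(ref_matrix: np.ndarray, snp_idx: np.ndarray, r2_max: float) -> np.ndarray:
    """Weight 1/m for each SNP in a cluster of m mutually high-LD SNPs
    (pairwise r^2 > r2_max in the reference group)."""
    m = snp_idx.size
    if m <= 1:
        return np.ones(m)
    ii, jj = np.triu_indices(m, k=1)
    r2 = pairwise_r2(ref_matrix[:, snp_idx], ii, jj)
    counts = np.ones(m)
    hit = r2 > r2_max
    np.add.at(counts, ii[hit], 1)
    np.add.at(counts, jj[hit], 1)
    return 1.0 / counts


def xpclr_scan(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    ref_group: str,
    obj_group: str,
    cfg: XpclrConfig = XpclrConfig(),
    omega: Optional[float] = None,
    contig: Optional[str] = None,
    contig_length: Optional[int] = None,
) -> pd.DataFrame:
    """Scan a contig on a regular grid of putative sweep positions.

    Only SNPs segregating in the reference group (0 < p1 < 1) inform
    the likelihood.  Each grid point scores the SNPs within ``radius``;
    when more than ``max_snps_per_window`` fall inside, an evenly
    spaced deterministic subset is used.  Grid points with no SNPs are
    reported with a NaN score.
    """
    snp = G.snps()
    if contig is None:
        uniq = pd.unique(snp.contigs)
        if len(uniq) != 1:
            raise ValueError("multi-contig matrix: pass contig explicitly")
        contig = uniq[0]
    mask = snp.contigs == contig
    snp = snp.subset_variants(mask)
    ridx = popmap.group_indices(snp.samples, ref_group)
    oidx = popmap.group_indices(snp.samples, obj_group)
    rk, rn = group_counts(snp, ridx)
    ok_, on = group_counts(snp, oidx)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = rk / np.maximum(rn, 1)
    usable = (
        (rn >= 2)
        & (on >= 2)
        & (p1 >= max(cfg.ref_maf, 1e-9))
        & (p1 <= 1 - max(cfg.ref_maf, 1e-9))
    )
    if omega is None:
        omega = estimate_drift(rk, rn, ok_, on, min_snps=cfg.min_neutral_snps)
    pos = snp.positions[usable]
    p1u = p1[usable]
    ku = ok_[usable].astype(int)
    nu = on[usable].astype(int)
    ref_counts = np.where(
        snp.counts[usable][:, ridx] >= 0, snp.counts[usable][:, ridx], -1
    ).T  # samples x variants for LD weights

    # site-level precomputation (independent of grid position / s);
    # in folded mode both polarizations are averaged in probability
    n_sites = pos.size
    polarizations = [(ku, nu, p1u)]
    if cfg.folded:
        polarizations.append((nu - ku, nu, 1.0 - p1u))
    pieces = []
    for kk, nn, pp in polarizations:
        cont = np.empty(n_sites)
        m0 = np.empty(n_sites)
        m1 = np.empty(n_sites)
        mu = np.empty(n_sites)
        for v in range(n_sites):
            pc = _site_pieces(int(kk[v]), int(nn[v]), float(pp[v]), omega, cfg.n_nodes)
            cont[v], m0[v], m1[v], mu[v] = pc["cont"], pc["m0"], pc["m1"], pc["mu"]
        at0 = (kk == 0).astype(float)
        atn = (kk == nn).astype(float)
        pieces.append((cont, m0, m1, mu, at0, atn))
    neutral_p = np.mean(
        [c + m0_ * a0 + m1_ * an for c, m0_, m1_, mu_, a0, an in pieces], axis=0
    )
    neutral_ll = np.log(np.maximum(neutral_p, _LOG_FLOOR))

    if contig_length is None:
        contig_length = int(pos.max()) if n_sites else cfg.grid_spacing
    grid = np.arange(cfg.grid_spacing // 2, contig_length + 1, cfg.grid_spacing)
    rows = []
    s_values = cfg.usable_s()
    skipped = [s for s in cfg.s_grid if s > 0 and s not in s_values]
    if skipped:
        logger.warning(
            "s values %s skipped (2*N*s <= 1 at N=%d)", skipped, cfg.effective_size
        )
    for x in grid:
        lo = np.searchsorted(pos, x - cfg.radius)
        hi = np.searchsorted(pos, x + cfg.radius, side="right")
        idx = np.arange(lo, hi)
        if idx.size > cfg.max_snps_per_window:
            sel = np.linspace(0, idx.size - 1, cfg.max_snps_per_window).round().astype(int)
            idx = idx[np.unique(sel)]
        if idx.size == 0:
            rows.append(
                {"contig": contig, "position": int(x), "score": np.nan,
                 "best_s": np.nan, "n_snps": 0, "mean_weight": np.nan}
            )
            continue
        w = _ld_weights(ref_counts, idx, cfg.r2_max)
        r_dist = np.abs(pos[idx] - x) * cfg.morgans_per_bp
        best, best_s = 0.0, 0.0
        for s in s_values:
            c = 1.0 - np.exp(-(r_dist / s) * np.log(2 * cfg.effective_size * s))
            p = np.zeros(idx.size)
            for cont, m0, m1, mu, at0, atn in pieces:
                m1s = c * m1[idx] + (1 - c) * mu[idx]
                m0s = c * m0[idx] + (1 - c) * (1 - mu[idx])
                p += c * cont[idx] + m0s * at0[idx] + m1s * atn[idx]
            p /= len(pieces)
            ll = np.log(np.maximum(p, _LOG_FLOOR))
            ratio = float(np.dot(w, ll - neutral_ll[idx]))
            if ratio > best:
                best, best_s = ratio, s
        rows.append(
            {
                "contig": contig,
                "position": int(x),
                "score": 2.0 * best,
                "best_s": best_s,
                "n_snps": int(idx.size),
                "mean_weight": float(w.mean()),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["omega"] = omega
    df.attrs["config"] = cfg
    return df
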