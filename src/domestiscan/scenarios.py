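"""Canonical synthetic study conditions.

These presets define the conditions under which the pipeline's
statistical behaviour is demonstrated: neutral equilibrium panels for
estimator calibration, two-population splits for differentiation and
structure, and completed hard sweeps in a derived population for scan
power.  Effective sizes are illustrative round numbers (the organism's
true N_e is unknown); the per-site mutation rate is rescaled so that
theta = 4*N*mu holds the stated per-site diversity at desk-scale N.
"""

from __future__ import annotations

import numpy as np

from .simdata import SimulationConfig, SweepSpec

SCAN_WINDOW_SIZE = 20_000
SCAN_MERGE_GAP = 20_000
SWEEP_GENE = (488_500, 491_500)  # 3 kb gene centered on the swept site

__all__ = [
    "neutral_locus",
    "two_population_split",
    "sweep_scan_config",
    "SWEEP_POSITION",
    "SWEEP_S",
]

SWEEP_POSITION = 490_000
SWEEP_S = 0.1


def neutral_locus(
    seed: int,
    n_samples: int = 10,
    L: int = 10_000,
    theta: float = 0.005,
    N: int = 50,
    recombination_rate: float = 1e-6,
) -> SimulationConfig:
    """Constant-size neutral locus with per-site theta = 4*N*mu."""
    return SimulationConfig(
        diploid_size_per_epoch=((0, N),),
        sample_sizes=(n_samples,),
        sequence_length=L,
        mutation_rate=theta / (4 * N),
        recombination_rate=recombination_rate,
        seed=seed,
    )


def two_population_split(
    seed: int,
    split_generations: int,
    n_samples: int = 15,
    L: int = 50_000,
    theta: float = 0.005,
    N: int = 50,
    recombination_rate: float = 1e-6,
    missing_rate: float = 0.0,
) -> SimulationConfig:
    """A derived population splitting cleanly from a progenitor
    ``split_generations`` before present; no migration."""
    return SimulationConfig(
        diploid_size_per_epoch=((0, N),),
        n_populations=2,
        split_generations=(split_generations,),
        sample_sizes=(n_samples, n_samples),
        sequence_length=L,
        mutation_rate=theta / (4 * N),
        recombination_rate=recombination_rate,
        missing_rate=missing_rate,
        population_names=("wild", "dom"),
        seed=seed,
    )


def sweep_scan_config(
    seed: int,
    sweep: bool,
    L: int = 1_000_000,
    position: int = SWEEP_POSITION,
    s: float = SWEEP_S,
) -> SimulationConfig:
    """Scan-scale scenario: wild progenitor plus one domesticate, with
    an optional completed hard sweep in the domesticate.

    An ancestral population of 200 diploids expands to 500 at the
    split, 200 generations before present.  The swept allele is a rare
    standing variant (10% frequency, all copies on one haplotype
    background, so the sweep is hard) selected at s = 0.1 from the
    moment of the split; sweep panels are sampled the generation the
    allele fixes, as sweep-detection power studies do, so the sampled
    diversity deficit reflects the sweep rather than post-fixation
    mutation recovery at rescaled mutation rates.
    """
    return SimulationConfig(
        diploid_size_per_epoch=((201, 200), (200, 500)),
        n_populations=2,
        split_generations=(200,),
        sample_sizes=(40, 25),
        sequence_length=L,
        mutation_rate=6e-7,
        recombination_rate=1e-7,
        sweep=SweepSpec(
            population=1,
            position=position,
            s=s,
            generation=198,
            initial_frequency=0.1,
            sample_at_fixation=True,
        )
        if sweep
        else None,
        population_names=("wild", "dom"),
        seed=seed,
    )


def sweep_scan_xpclr_config():
    """XP-CLR settings matched to ``sweep_scan_config``: the scan is
    told the truth about the recombination rate (10 cM/Mb) and the
    domesticate's effective size, scans selection coefficients up to
    the simulated s, and down-weights reference-LD clusters."""
    from .xpclr import XpclrConfig

    return XpclrConfig(
        grid_spacing=5_000,
        radius=50_000,
        s_grid=(0.0, 0.025, 0.05, 0.1),
        effective_size=500,
        r2_max=0.7,
        ref_maf=0.05,
        rec_rate_cm_per_mb=10.0,
        max_snps_per_window=400,
    )


def sweep_scan_replicate(seed: int, sweep: bool) -> dict:
    """Run one full scan replicate: simulate, XP-CLR scan, windowed
    diversity ratio, and the joint top-5% region call.

    Returns the sweep outcome, the distance from the XP-CLR argmax to
    the (putative) swept site, and whether the planted 3 kb gene at the
    site is recovered by the intersection rule.
    """
    from . import domscan
    from .diffstats import pi_ratio
    from .popio import PopulationMap, genotype_matrix_from_panel, make_windows
    from .simdata import simulate_wf
    from .sumstats import sliding_stats
    from .xpclr import xpclr_scan

    cfg = sweep_scan_config(seed, sweep=sweep)
    panel, truth = simulate_wf(cfg)
    G = genotype_matrix_from_panel(panel)
    pm = PopulationMap(
        dict(zip(panel.sample_ids, panel.sample_populations)), ["wild", "dom"]
    )
    track = xpclr_scan(
        G, pm, "wild", "dom", sweep_scan_xpclr_config(),
        contig_length=cfg.sequence_length,
    )
    windows = make_windows(cfg.sequence_length, SCAN_WINDOW_SIZE, contig=cfg.contig)
    st = sliding_stats(G, pm, windows, min_samples=2)
    wild = st[st.group == "wild"].reset_index(drop=True)
    dom = st[st.group == "dom"].reset_index(drop=True)
    ratio = pi_ratio(wild, dom)
    pi_mask = domscan.top_quantile_mask(
        ratio["ratio"].values, 0.95, infinite=ratio["infinite"].values
    )
    scored = track.dropna(subset=["score"])
    xp_mask = domscan.top_quantile_mask(scored["score"].values, 0.95)
    regions = domscan.call_regions(
        ratio, pi_mask, scored["position"].values, xp_mask, merge_gap=SCAN_MERGE_GAP
    )
    gene_hit = any(
        min(r.end, SWEEP_GENE[1]) - max(r.start, SWEEP_GENE[0]) >= 1
        for r in regions.itertuples()
    )
    best = track.loc[track.score.idxmax()]
    return {
        "outcome": truth.sweep_outcome,
        "argmax_distance": abs(int(best.position) - SWEEP_POSITION),
        "gene_recovered": bool(gene_hit),
        "n_regions": int(len(regions)),
        "max_score": float(best.score),
    }
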