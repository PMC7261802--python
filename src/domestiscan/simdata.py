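"""Forward-in-time Wright–Fisher simulator with known ground truth.

Simulates a diploid panel under discrete non-overlapping generations:
binomial resampling of parents, per-site binary mutation (two alleles,
first mutation at a site wins), single-crossover-per-meiosis
recombination, clean population splits off a wild/progenitor lineage,
and an optional additive hard sweep.  Every run emits the parameters it
was given plus the realized sweep outcome, so downstream estimators can
be tested against truth.

The forward (rather than coalescent) construction makes bottlenecks and
hard sweeps exact by design: selection acts on realized genotypes, and
the sweep's fixation generation is observed, not assumed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SweepSpec",
    "SimulationConfig",
    "HaplotypePanel",
    "SimulationTruth",
    "simulate_wf",
    "write_vcf",
    "write_popmap",
    "write_truth",
    "GeneSpec",
    "make_toy_genes",
]


@dataclass(frozen=True)
class SweepSpec:
    """A hard selective sweep: an additive beneficial mutation.

    Fitness of genotypes 0/1/2 at the swept site is 1, 1+s/2, 1+s.
    With ``initial_frequency`` 0 the allele is introduced as a single
    new copy ``generation`` generations before present; a positive
    value introduces it at that frequency, modeling selection on a
    rare standing variant (the usual domestication scenario, which
    also makes fixation within a short domestication episode nearly
    certain).  If lost it is reintroduced the next generation
    (recurrent introduction), so a sweep given enough time completes.
    """

    population: int
    position: int  # 1-based bp
    s: float
    generation: int  # generations before present when introduced
    initial_frequency: float = 0.0
    # when True, the panel is sampled the generation the sweep fixes
    # (no post-fixation recovery), as in sweep-detection power studies
    sample_at_fixation: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one forward simulation.

    ``diploid_size_per_epoch`` is a list of ``(start_generation, N)``
    pairs, times in generations before present, most ancient first; the
    size applies to every population extant in that epoch.  Mutation and
    recombination rates are per base per generation (the study-scale
    point estimate for the crop is 1.0e-8 per nucleotide per generation
    with a 1-year generation time; synthetic scenarios rescale mu
    upward at small N to hold theta = 4*N*mu at a realistic per-site
    value).
    """

    diploid_size_per_epoch: tuple[tuple[int, int], ...]
    sample_sizes: tuple[int, ...]
    sequence_length: int
    mutation_rate: float
    recombination_rate: float = 0.0
    n_populations: int = 1
    split_generations: tuple[int, ...] = ()
    sweep: Optional[SweepSpec] = None
    missing_rate: float = 0.0
    seed: int = 0
    contig: str = "chr1"
    population_names: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "diploid_size_per_epoch", tuple(map(tuple, self.diploid_size_per_epoch))
        )
        object.__setattr__(self, "sample_sizes", tuple(self.sample_sizes))
        object.__setattr__(self, "split_generations", tuple(self.split_generations))
        names = tuple(self.population_names) or tuple(
            f"pop{i}" for i in range(self.n_populations)
        )
        object.__setattr__(self, "population_names", names)
        self._validate()

    def _validate(self) -> None:
        for rate, name in [
            (self.mutation_rate, "mutation_rate"),
            (self.recombination_rate, "recombination_rate"),
            (self.missing_rate, "missing_rate"),
        ]:
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if not self.diploid_size_per_epoch:
            raise ValueError("need at least one (start_generation, N) epoch")
        for _, n in self.diploid_size_per_epoch:
            if n < 1:
                raise ValueError("diploid size must be >= 1")
        if len(self.sample_sizes) != self.n_populations:
            raise ValueError("one sample size per population required")
        if len(self.split_generations) != self.n_populations - 1:
            raise ValueError("need n_populations - 1 split times")
        if list(self.split_generations) != sorted(self.split_generations, reverse=True) or len(
            set(self.split_generations)
        ) != len(self.split_generations):
            raise ValueError("split times must be strictly decreasing toward present")
        n_present = self.size_at(0)
        for i, ss in enumerate(self.sample_sizes):
            if ss > n_present:
                raise ValueError(
                    f"sample size {ss} for population {self.population_names[i]} "
                    f"exceeds {n_present} diploids (2N = {2 * n_present} haplotypes)"
                )
        if self.sweep is not None:
            if not (1 <= self.sweep.position <= self.sequence_length):
                raise ValueError(
                    f"sweep position {self.sweep.position} outside "
                    f"[1, {self.sequence_length}]"
                )
            if not (0 <= self.sweep.population < self.n_populations):
                raise ValueError("sweep population index out of range")
            if self.sweep.s <= 0:
                raise ValueError("selection coefficient must be > 0")
            if not (0.0 <= self.sweep.initial_frequency < 1.0):
                raise ValueError("sweep initial frequency must be in [0, 1)")

    def size_at(self, t: int) -> int:
        """Diploid size in force ``t`` generations before present."""
        n = self.diploid_size_per_epoch[0][1]
        for start, size in sorted(self.diploid_size_per_epoch, reverse=True):
            if t <= start:
                n = size
        return n


@dataclass
class HaplotypePanel:
    """Sampled phased haplotypes at segregating sites.

    ``haplotypes`` is (2 * n_samples, n_variants) with 0 = ancestral,
    1 = derived; rows 2i and 2i+1 belong to sample i.  ``missing`` marks
    diploid genotype calls masked post hoc (both alleles unknown).
    """

    contig: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    haplotypes: np.ndarray  # uint8 (2S, V)
    sample_ids: list[str]
    sample_populations: list[str]
    missing: np.ndarray  # bool (S, V)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.positions.size

    def allele_counts(self) -> np.ndarray:
        """Diploid derived-allele counts, (V, n_samples), -1 = missing."""
        counts = (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
        counts[self.missing] = -1
        return counts.T.copy()


@dataclass
class SimulationTruth:
    config: SimulationConfig
    sweep_fixation_generation: Optional[int]  # None when no sweep or lost
    expected_theta: dict[str, float] = field(default_factory=dict)  # per pop, 4*N*mu

    @property
    def sweep_outcome(self) -> str:
        if self.config.sweep is None:
            return "none"
        return "lost" if self.sweep_fixation_generation is None else "fixed"


class _State:
    """Mutable simulation state: one haplotype matrix per population over
    a shared, unsorted column (site) space."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        # columns: sorted prefix of length n_sorted + small unsorted
        # suffix of recent mutations, compacted during cleanup
        self.positions = np.empty(0, dtype=np.int64)
        self.n_sorted = 0
        self.pops: list[np.ndarray] = []  # each (2N, V) uint8
        self.site_used = np.zeros(cfg.sequence_length + 1, dtype=bool)
        self.sweep_col_pos = -1  # bp of the protected sweep site, if any
        if cfg.sweep is not None:
            self.site_used[cfg.sweep.position] = True

    # -- reproduction ---------------------------------------------------

    def _gametes(self, H: np.ndarray, n_offspring: int, weights: Optional[np.ndarray]) -> np.ndarray:
        rng = self.rng
        n_parents = H.shape[0] // 2
        if weights is None:
            parents = rng.integers(0, n_parents, size=2 * n_offspring)
        else:
            parents = rng.choice(n_parents, size=2 * n_offspring, p=weights)
        which = rng.integers(0, 2, size=2 * n_offspring)
        child = H[2 * parents + which]
        p_rec = min(1.0, self.cfg.recombination_rate * max(self.cfg.sequence_length - 1, 0))
        if p_rec > 0 and self.positions.size:
            rec = np.nonzero(rng.random(2 * n_offspring) < p_rec)[0]
            if rec.size:
                cuts = rng.integers(2, self.cfg.sequence_length + 1, size=rec.size)
                rows_b = 2 * parents[rec] + (1 - which[rec])
                ns = self.n_sorted
                # sorted prefix: the crossover is a contiguous slice
                cut_idx = np.searchsorted(self.positions[:ns], cuts)
                for g, rb, ci in zip(rec, rows_b, cut_idx):
                    if ci < ns:
                        child[g, ci:ns] = H[rb, ci:ns]
                # unsorted suffix of recent mutations: masked assignment
                if ns < self.positions.size:
                    tail = self.positions[ns:]
                    after = tail[None, :] >= cuts[:, None]
                    child[rec, ns:] = np.where(after, H[rows_b, ns:], child[rec, ns:])
        return child

    def reproduce(self, pop: int, n_next: int, sweep_s: float = 0.0) -> None:
        H = self.pops[pop]
        weights = None
        if sweep_s > 0.0 and self.sweep_col_pos >= 0:
            col = np.nonzero(self.positions == self.sweep_col_pos)[0]
            if col.size:
                g = H[0::2, col[0]].astype(np.float64) + H[1::2, col[0]]
                w = 1.0 + g * (sweep_s / 2.0)
                weights = w / w.sum()
        self.pops[pop] = self._gametes(H, n_next, weights)

    def found_population(self, source: int, n_new: int) -> None:
        self.pops.append(self._gametes(self.pops[source], n_new, None))

    # -- mutation -------------------------------------------------------

    def mutate(self) -> None:
        rng = self.rng
        L = self.cfg.sequence_length
        mu = self.cfg.mutation_rate
        if mu <= 0:
            return
        rows_per_pop = [H.shape[0] for H in self.pops]
        total_rows = sum(rows_per_pop)
        n_mut = rng.poisson(total_rows * L * mu)
        if n_mut == 0:
            return
        pos = rng.integers(1, L + 1, size=n_mut)
        # a site hit twice in one draw keeps only its first occurrence
        pos = np.unique(pos[~self.site_used[pos]])
        if pos.size == 0:
            return
        self.site_used[pos] = True
        rows = rng.integers(0, total_rows, size=pos.size)
        nc = self.positions.size
        final_col = nc + np.arange(pos.size)
        self.positions = np.concatenate([self.positions, pos])
        offsets = np.cumsum([0] + rows_per_pop)
        new_pops = []
        for p, H in enumerate(self.pops):
            H = np.concatenate(
                [H, np.zeros((H.shape[0], pos.size), dtype=np.uint8)], axis=1
            )
            mine = (rows >= offsets[p]) & (rows < offsets[p + 1])
            H[rows[mine] - offsets[p], final_col[mine]] = 1
            new_pops.append(H)
        self.pops = new_pops

    def introduce_sweep_allele(self) -> None:
        sweep = self.cfg.sweep
        H = self.pops[sweep.population]
        if self.sweep_col_pos < 0:
            self.positions = np.concatenate([self.positions, [sweep.position]])
            self.pops = [
                np.concatenate([P, np.zeros((P.shape[0], 1), dtype=np.uint8)], axis=1)
                for P in self.pops
            ]
            self.sweep_col_pos = sweep.position
            H = self.pops[sweep.population]
        j = np.nonzero(self.positions == sweep.position)[0][0]
        n_copies = max(1, round(sweep.initial_frequency * H.shape[0]))
        rows = self.rng.choice(H.shape[0], size=min(n_copies, H.shape[0]), replace=False)
        # all starting copies share one haplotype background, so the
        # sweep is hard: every swept lineage coalesces into the single
        # haplotype on which the beneficial allele arose
        H[rows] = H[rows[0]].copy()
        H[rows, j] = 1

    def sweep_freq(self) -> float:
        if self.sweep_col_pos < 0:
            return 0.0
        j = np.nonzero(self.positions == self.sweep_col_pos)[0]
        if j.size == 0:
            return 0.0
        H = self.pops[self.cfg.sweep.population]
        return float(H[:, j[0]].mean())

    # -- housekeeping ---------------------------------------------------

    def drop_monomorphic(self) -> None:
        if self.positions.size == 0:
            return
        total = sum(H.sum(axis=0, dtype=np.int64) for H in self.pops)
        n_rows = sum(H.shape[0] for H in self.pops)
        keep = (total > 0) & (total < n_rows)
        if self.sweep_col_pos >= 0:
            keep |= self.positions == self.sweep_col_pos
        # a site whose derived allele was *lost* can mutate again later
        # ("first mutation retained" applies per retained mutation); a
        # site fixed for the derived allele is retired.
        lost = ~keep & (total == 0)
        self.site_used[self.positions[lost]] = False
        idx = np.nonzero(keep)[0]
        suffix = self.positions.size - self.n_sorted
        resort = suffix > 512 or (suffix > 0 and (~keep[self.n_sorted :]).any())
        if resort:
            idx = idx[np.argsort(self.positions[idx], kind="stable")]
        elif keep.all():
            return
        self.positions = self.positions[idx]
        self.pops = [H[:, idx] for H in self.pops]
        if resort:
            self.n_sorted = self.positions.size
        else:
            self.n_sorted = int(keep[: self.n_sorted].sum())


def simulate_wf(config: SimulationConfig) -> tuple[HaplotypePanel, SimulationTruth]:
    """Run the forward simulation and sample a panel at the present.

    Burn-in lasts 8N generations before the most ancient configured
    event so initial monomorphism is forgotten (well beyond the expected
    TMRCA of 4N).  Monomorphic sites in the sampled panel are dropped.
    Identical config (including seed) gives identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    events = [t for t, _ in cfg.diploid_size_per_epoch] + list(cfg.split_generations)
    if cfg.sweep is not None:
        events.append(cfg.sweep.generation)
    t_oldest_event = max([t for t in events if t > 0], default=0)
    n0 = cfg.size_at(t_oldest_event + 1) if t_oldest_event else cfg.size_at(0)
    t_start = t_oldest_event + 8 * n0

    state = _State(cfg, rng)
    state.pops = [np.zeros((2 * n0, 0), dtype=np.uint8)]
    split_at = {t: k + 1 for k, t in enumerate(cfg.split_generations)}
    sweep = cfg.sweep
    sweep_active = False
    fixation_gen: Optional[int] = None

    t = t_start
    while t > 0:
        t -= 1
        n_next = cfg.size_at(t)
        for p in range(len(state.pops)):
            s_here = 0.0
            if sweep_active and sweep is not None and p == sweep.population and fixation_gen is None:
                s_here = sweep.s
            state.reproduce(p, n_next, sweep_s=s_here)
        if t in split_at:
            state.found_population(0, n_next)
        state.mutate()
        if sweep is not None and t == sweep.generation:
            if sweep.population >= len(state.pops):
                raise ValueError(
                    f"sweep population {sweep.population} does not exist at "
                    f"generation {t} (split later than sweep introduction)"
                )
            state.introduce_sweep_allele()
            sweep_active = True
        if sweep_active and fixation_gen is None:
            f = state.sweep_freq()
            if f >= 1.0:
                fixation_gen = t
                if sweep.sample_at_fixation:
                    break
            elif f <= 0.0:
                state.introduce_sweep_allele()  # recurrent reintroduction
        if t % 2 == 0:  # amortize column cleanup
            state.drop_monomorphic()

    # ---- sample the present generation --------------------------------
    sample_rows = []
    sample_ids: list[str] = []
    sample_pops: list[str] = []
    for p, ss in enumerate(cfg.sample_sizes):
        chosen = np.sort(rng.choice(state.pops[p].shape[0] // 2, size=ss, replace=False))
        for j, ind in enumerate(chosen):
            sample_rows.append(state.pops[p][2 * ind : 2 * ind + 2])
            sample_ids.append(f"{cfg.population_names[p]}_{j:03d}")
            sample_pops.append(cfg.population_names[p])
    if sample_rows:
        H = np.concatenate(sample_rows, axis=0)
    else:
        H = np.zeros((0, state.positions.size), dtype=np.uint8)
    counts = H.sum(axis=0)
    seg = (counts > 0) & (counts < H.shape[0])
    H = H[:, seg]
    positions = state.positions[seg]
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    H = np.ascontiguousarray(H[:, order])
    missing = rng.random((len(sample_ids), positions.size)) < cfg.missing_rate

    panel = HaplotypePanel(
        contig=cfg.contig,
        positions=positions,
        haplotypes=H,
        sample_ids=sample_ids,
        sample_populations=sample_pops,
        missing=missing,
    )
    expected_theta = {
        name: 4.0 * cfg.size_at(0) * cfg.mutation_rate for name in cfg.population_names
    }
    truth = SimulationTruth(
        config=cfg, sweep_fixation_generation=fixation_gen, expected_theta=expected_theta
    )
    return panel, truth


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------


_TRANSVERSION = {"A": "T", "T": "A", "C": "G", "G": "C"}


def write_vcf(panel: HaplotypePanel, path, reference: Optional[str] = None) -> None:
    """Write the panel as VCF 4.2 with phased GT; masked calls become ./.

    With a ``reference`` sequence for the contig, REF is the actual
    (ancestral) base at each position and ALT its transversion partner;
    without one, a fixed A>T placeholder pair is used.
    """
    if panel.n_variants == 0 and panel.n_samples == 0:
        raise ValueError("refusing to write an empty panel (no samples)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=domestiscan-simdata\n")
        fh.write(f"##contig=<ID={panel.contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        hap = panel.haplotypes
        for v in range(panel.n_variants):
            gts = []
            for s in range(panel.n_samples):
                if panel.missing[s, v]:
                    gts.append("./.")
                else:
                    gts.append(f"{hap[2 * s, v]}|{hap[2 * s + 1, v]}")
            if reference is not None:
                ref = reference[int(panel.positions[v]) - 1].upper()
                alt = _TRANSVERSION.get(ref, "T")
            else:
                ref, alt = "A", "T"
            fh.write(
                f"{panel.contig}\t{panel.positions[v]}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def write_popmap(panel: HaplotypePanel, path) -> None:
    """Sample→group TSV matching the panel's population labels."""
    with open(path, "w") as fh:
        for sid, pop in zip(panel.sample_ids, panel.sample_populations):
            fh.write(f"{sid}\t{pop}\n")


def write_truth(truth: SimulationTruth, path) -> None:
    """Truth sidecar TSV: config fields, sweep outcome, expected theta."""
    cfg = truth.config
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for f_ in dataclasses.fields(cfg):
            fh.write(f"{f_.name}\t{getattr(cfg, f_.name)}\n")
        fh.write(f"sweep_outcome\t{truth.sweep_outcome}\n")
        fh.write(f"sweep_fixation_generation\t{truth.sweep_fixation_generation}\n")
        for pop, theta in truth.expected_theta.items():
            fh.write(f"expected_theta_{pop}\t{theta}\n")


# ---------------------------------------------------------------------------
# toy gene models
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    contig: str
    start: int  # 0-based half-open genomic span
    end: int
    strand: str  # '+' or '-'


def make_toy_genes(
    contig_length: int,
    n_genes: int,
    cds_length: int,
    seed: int,
    gff_path,
    fasta_path,
    contig: str = "chr1",
) -> list[GeneSpec]:
    """Emit a toy single-exon gene set: GFF3 + reference FASTA.

    Genes are non-overlapping, alternate between strands, and carry
    random non-stop codons on the coding strand (so no internal stop in
    any frame-0 translation).  Coordinates in the GFF3 are 1-based
    inclusive as the format requires.
    """
    if cds_length % 3 != 0:
        raise ValueError("cds_length must be a multiple of 3")
    if n_genes * cds_length > contig_length:
        raise ValueError(
            f"cannot pack {n_genes} genes x {cds_length} bp into {contig_length} bp"
        )
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list(_BASES), size=contig_length)))

    # evenly spaced slots, jittered within the slack of each slot
    genes: list[GeneSpec] = []
    if n_genes > 0:
        slot = contig_length // n_genes
        slack = slot - cds_length
        for i in range(n_genes):
            offset = int(rng.integers(0, slack + 1)) if slack > 0 else 0
            start = i * slot + offset
            strand = "+" if i % 2 == 0 else "-"
            coding = "".join(
                _NONSTOP_CODONS[j]
                for j in rng.integers(0, len(_NONSTOP_CODONS), size=cds_length // 3)
            )
            genomic = coding if strand == "+" else _revcomp(coding)
            seq[start : start + cds_length] = list(genomic)
            genes.append(GeneSpec(f"gene{i + 1:04d}", contig, start, start + cds_length, strand))

    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {contig} 1 {contig_length}\n")
        for g in genes:
            s1, e1 = g.start + 1, g.end  # to 1-based inclusive
            fh.write(
                f"{contig}\tdomestiscan\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{contig}\tdomestiscan\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{contig}\tdomestiscan\tCDS\t{s1}\t{e1}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )
    with open(fasta_path, "w") as fh:
        fh.write(f">{contig}\n")
        s = "".join(seq)
        for i in range(0, len(s), 70):
            fh.write(s[i : i + 70] + "\n")
    return genes
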