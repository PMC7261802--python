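"""Readers, writers, and coordinate plumbing.

All internal coordinates are 0-based half-open; VCF and GFF3 (both
1-based) are converted at the file boundary.  The genotype matrix keeps
only biallelic records, with InDels length-classified so they can be
excluded from SNP statistics (the variant-calling convention upstream
of this pipeline retains indels up to 50 bp).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PopulationMap",
    "Window",
    "GeneModel",
    "read_vcf",
    "read_popmap",
    "read_gff",
    "read_fasta",
    "make_windows",
]


@dataclass
class GenotypeMatrix:
    """Biallelic variants x samples diploid allele-count matrix.

    ``counts[v, s]`` is the number of alternate alleles (0/1/2) carried
    by sample ``s`` at variant ``v``, or -1 for a missing call.  A call
    with one unknown allele is treated as fully missing.
    """

    contigs: np.ndarray  # str per variant
    positions: np.ndarray  # 1-based bp
    ref: np.ndarray
    alt: np.ndarray
    counts: np.ndarray  # int8 (V, S)
    vtype: np.ndarray  # 'snp' | 'indel'
    samples: list[str]

    @property
    def n_variants(self) -> int:
        return self.positions.size

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(
            self.contigs,
            self.positions,
            self.ref,
            self.alt,
            self.counts[:, idx],
            self.vtype,
            [self.samples[i] for i in idx],
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.contigs[mask],
            self.positions[mask],
            self.ref[mask],
            self.alt[mask],
            self.counts[mask],
            self.vtype[mask],
            list(self.samples),
        )

    def snps(self) -> "GenotypeMatrix":
        return self.subset_variants(self.vtype == "snp")

    def allele_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant (alt frequency, non-missing chromosome count),
        computed over non-missing calls only."""
        valid = self.counts >= 0
        n_chrom = 2 * valid.sum(axis=1)
        alt = np.where(valid, self.counts, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
        return freq, n_chrom


@dataclass
class PopulationMap:
    """Assignment of each sample to exactly one named group."""

    assignments: dict[str, str]
    groups: list[str]

    def samples_in(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}; have {self.groups}")
        return [s for s, g in self.assignments.items() if g == group]

    def group_indices(self, samples: list[str], group: str) -> np.ndarray:
        members = set(self.samples_in(group))
        idx = np.array([i for i, s in enumerate(samples) if s in members], dtype=int)
        if idx.size == 0:
            raise ValueError(f"group {group!r} has no samples in the genotype matrix")
        return idx


@dataclass(frozen=True)
class Window:
    contig: str
    start: int  # 0-based half-open
    end: int
    index: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty window [{self.start}, {self.end})")


@dataclass
class GeneModel:
    """A gene with one or more CDS intervals (0-based half-open).

    ``cds`` intervals are stored in genomic order; for minus-strand
    genes the coding sequence is the reverse complement read from the
    last interval backwards.
    """

    gene_id: str
    contig: str
    strand: str
    cds: list[tuple[int, int]]
    start: int = field(init=False)
    end: int = field(init=False)

    def __post_init__(self):
        self.cds = sorted(self.cds)
        self.start = min(s for s, _ in self.cds)
        self.end = max(e for _, e in self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def read_vcf(
    path,
    keep: Literal["snp", "indel", "all"] = "snp",
    max_indel_len: int = 50,
    max_missing: float = 0.5,
) -> GenotypeMatrix:
    """Load biallelic variants from a VCF into a genotype matrix.

    Multi-allelic records are dropped (not split), indels longer than
    ``max_indel_len`` are dropped, and variants missing in more than
    ``max_missing`` of samples are dropped.  Phased and unphased GT are
    both accepted; half-missing calls count as missing.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns (no GT data)")
    contigs, positions, refs, alts, vtypes, rows = [], [], [], [], [], []
    n_samples = len(samples)
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) == 1 and len(alt) == 1:
            vt = "snp"
        else:
            vt = "indel"
            if abs(len(alt) - len(ref)) > max_indel_len:
                continue
        if keep != "all" and vt != keep:
            continue
        gt = var.genotype.array()  # (S, ploidy+1), last col = phased flag
        a = gt[:, 0].astype(np.int16)
        b = gt[:, 1].astype(np.int16)
        row = np.where((a < 0) | (b < 0), -1, a + b).astype(np.int8)
        if (row < 0).sum() > max_missing * n_samples:
            continue
        contigs.append(var.CHROM)
        positions.append(var.POS)
        refs.append(ref)
        alts.append(alt)
        vtypes.append(vt)
        rows.append(row)
    counts = (
        np.vstack(rows) if rows else np.zeros((0, n_samples), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        contigs=np.array(contigs, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        counts=counts,
        vtype=np.array(vtypes, dtype=object),
        samples=samples,
    )
    for contig in pd.unique(gm.contigs):
        pos = gm.positions[gm.contigs == contig]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{path}: positions not strictly increasing on {contig}")
    return gm


def read_popmap(path) -> PopulationMap:
    """Read a sample<TAB>group map; duplicate samples are an error."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    dup = df["sample"][df["sample"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample(s) in population map: {sorted(set(dup))}")
    groups = list(pd.unique(df["group"]))
    return PopulationMap(dict(zip(df["sample"], df["group"])), groups)


def read_gff(path) -> list[GeneModel]:
    """Parse gene models (CDS intervals, strand) from GFF3.

    CDS features are grouped by their Parent attribute chain up to the
    gene (or by their own Parent when no gene feature exists).  Genes
    whose total CDS length is not a multiple of 3 are skipped with a
    warning.
    """
    parent_of: dict[str, str] = {}
    strand_of: dict[str, str] = {}
    contig_of: dict[str, str] = {}
    cds_by_parent: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns")
            contig, _, ftype, start, end, _, strand, _, attrs = parts
            if strand not in "+-.":
                raise ValueError(f"{path}:{ln}: unknown strand symbol {strand!r}")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            fid = attr.get("ID")
            parent = attr.get("Parent")
            if fid is not None and parent is not None:
                parent_of[fid] = parent
            if ftype == "CDS":
                key = parent if parent is not None else fid or f"cds_line{ln}"
                # GFF3 1-based inclusive -> 0-based half-open
                cds_by_parent.setdefault(key, []).append((int(start) - 1, int(end)))
                strand_of[key] = strand
                contig_of[key] = contig

    def root(fid: str) -> str:
        seen = set()
        while fid in parent_of and fid not in seen:
            seen.add(fid)
            fid = parent_of[fid]
        return fid

    genes: list[GeneModel] = []
    for key, intervals in cds_by_parent.items():
        gid = root(key)
        model = GeneModel(gid, contig_of[key], strand_of[key], intervals)
        if model.cds_length % 3 != 0:
            warnings.warn(
                f"gene {gid}: CDS length {model.cds_length} not a multiple of 3; skipped"
            )
            logger.warning("gene %s skipped: CDS length %d %% 3 != 0", gid, model.cds_length)
            continue
        genes.append(model)
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


def read_fasta(path) -> dict[str, str]:
    """Reference sequences keyed by contig name (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def genotype_matrix_from_panel(panel) -> GenotypeMatrix:
    """In-memory bridge from a simulated haplotype panel to the
    genotype-matrix container (all sites biallelic SNPs, REF=ancestral)."""
    counts = panel.allele_counts()
    n = panel.n_variants
    return GenotypeMatrix(
        contigs=np.array([panel.contig] * n, dtype=object),
        positions=panel.positions.astype(np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        counts=counts.astype(np.int8),
        vtype=np.array(["snp"] * n, dtype=object),
        samples=list(panel.sample_ids),
    )


def make_windows(contig_length: int, size: int, step: Optional[int] = None, contig: str = "chr1") -> list[Window]:
    """Tile [0, contig_length) with half-open windows of ``size`` every
    ``step`` bp; the final windows are truncated at the contig end."""
    if step is None:
        step = size
    if size < 1 or step < 1 or step > size:
        raise ValueError("require size >= 1 and 1 <= step <= size")
    if contig_length < 1:
        raise ValueError("contig_length must be >= 1")
    windows = []
    i = 0
    for start in range(0, contig_length, step):
        windows.append(Window(contig, start, min(start + size, contig_length), i))
        i += 1
    return windows


def assign_to_windows(positions: np.ndarray, windows: list[Window]) -> list[np.ndarray]:
    """Indices of variants (1-based bp positions) falling in each window."""
    pos0 = positions - 1  # to 0-based
    return [np.nonzero((pos0 >= w.start) & (pos0 < w.end))[0] for w in windows]
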