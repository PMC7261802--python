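"""Coding-context SNP classification and genic dN/dS summaries.

Synonymous/nonsynonymous opportunity is counted Nei-Gojobori style
(unweighted): for each reference codon the fraction of the 9 possible
single-base changes that preserve the amino acid gives its synonymous
site count (out of 3); changes creating a stop codon count as
nonsynonymous.  Observed SNPs are classified one at a time against the
reference codon background (no haplotype-aware multi-hit paths), and
per group dN/dS = (nonsyn SNPs / nonsyn sites) / (syn SNPs / syn
sites).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .popio import GeneModel, GenotypeMatrix, PopulationMap
from .sumstats import group_counts

logger = logging.getLogger(__name__)

__all__ = [
    "codon_site_fractions",
    "classify_snp",
    "classify_all",
    "gene_site_counts",
    "group_dnds",
]

_BASES = "ACGT"
_STOPS = set(standard_dna_table.stop_codons)
_CODE = dict(standard_dna_table.forward_table)  # codon -> amino acid
_COMP = str.maketrans("ACGT", "TGCA")


def _aa(codon: str) -> Optional[str]:
    """Amino acid for a codon, '*' for stop, None if ambiguous."""
    if codon in _STOPS:
        return "*"
    return _CODE.get(codon)


def codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one reference codon.

    Enumerates all 9 single-base changes; syn_sites is the synonymous
    fraction times 3, and syn + nonsyn = 3 exactly.  Stop-codon
    products count as nonsynonymous.  Raises on ambiguous bases or a
    reference stop codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if codon in _STOPS:
        raise ValueError(f"reference codon {codon} is a stop codon")
    aa0 = _aa(codon)
    syn = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if _aa(alt) == aa0:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def _coding_context(gene: GeneModel, refseq: str, pos0: int) -> Optional[tuple[int, int]]:
    """(cds_offset, codon_index*3+frame) in coding orientation for a
    genomic 0-based position, or None if the position is not in the
    gene's CDS."""
    offset = 0
    for s, e in gene.cds:
        if s <= pos0 < e:
            within = pos0 - s
            cds_off = offset + within
            if gene.strand == "-":
                cds_off = gene.cds_length - 1 - cds_off
            return cds_off, cds_off // 3
        offset += e - s
    return None


def _cds_sequence(gene: GeneModel, refseq: str) -> str:
    seq = "".join(refseq[s:e] for s, e in gene.cds)
    if gene.strand == "-":
        seq = seq.translate(_COMP)[::-1]
    return seq


def classify_snp(
    gene: GeneModel,
    refseq: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
) -> str:
    """'synonymous' | 'nonsynonymous' | 'noncoding' for one biallelic SNP.

    ``pos`` is 1-based genomic.  The reference allele must match the
    reference sequence (a mismatch signals the wrong FASTA).  On minus
    strand genes both alleles are complemented into coding orientation.
    """
    pos0 = pos - 1
    if refseq[pos0].upper() != ref_allele.upper():
        raise ValueError(
            f"reference mismatch at {gene.contig}:{pos}: FASTA has "
            f"{refseq[pos0]!r}, VCF REF is {ref_allele!r}"
        )
    ctx = _coding_context(gene, refseq, pos0)
    if ctx is None:
        return "noncoding"
    cds_off, codon_idx = ctx
    cds = _cds_sequence(gene, refseq)
    codon = cds[3 * codon_idx : 3 * codon_idx + 3].upper()
    frame = cds_off % 3
    alt = alt_allele.upper()
    if gene.strand == "-":
        alt = alt.translate(_COMP)
    new_codon = codon[:frame] + alt + codon[frame + 1 :]
    if any(b not in _BASES for b in codon + new_codon):
        logger.warning("ambiguous codon at %s:%d skipped", gene.contig, pos)
        return "noncoding"
    return "synonymous" if _aa(new_codon) == _aa(codon) else "nonsynonymous"


def classify_all(
    G: GenotypeMatrix,
    genes: list[GeneModel],
    reference: dict[str, str],
) -> np.ndarray:
    """Per-variant classification against the first overlapping gene:
    'synonymous' | 'nonsynonymous' | 'noncoding'."""
    out = np.full(G.n_variants, "noncoding", dtype=object)
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for v in range(G.n_variants):
        if G.vtype[v] != "snp":
            continue
        contig = G.contigs[v]
        pos0 = int(G.positions[v]) - 1
        for g in by_contig.get(contig, []):
            if g.start <= pos0 < g.end:
                cls = classify_snp(
                    g, reference[contig], int(G.positions[v]), G.ref[v], G.alt[v]
                )
                if cls != "noncoding":
                    out[v] = cls
                    break
    return out


def gene_site_counts(genes: Iterable[GeneModel], reference: dict[str, str]) -> tuple[float, float]:
    """Total (synonymous, nonsynonymous) site counts over all genes'
    reference CDS codons; stop and ambiguous codons are skipped."""
    syn_total = 0.0
    nonsyn_total = 0.0
    for g in genes:
        cds = _cds_sequence(g, reference[g.contig])
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3].upper()
            if codon in _STOPS or any(b not in _BASES for b in codon):
                logger.info("gene %s: codon %s skipped in site counting", g.gene_id, codon)
                continue
            s, n = codon_site_fractions(codon)
            syn_total += s
            nonsyn_total += n
    return syn_total, nonsyn_total


def group_dnds(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    genes: list[GeneModel],
    reference: dict[str, str],
    groups: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Per-group genic SNP counts and dN/dS.

    A SNP counts for a group when at least one alternate allele is
    present among the group's non-missing calls.  Two dN/dS variants
    are emitted: ``dnds_pooled`` from group-total counts over summed
    site fractions, and ``dnds_per_sample`` computed the same way from
    the average per-sample counts (both NaN when the group has no
    synonymous SNPs).
    """
    groups = groups if groups is not None else popmap.groups
    cls = classify_all(G, genes, reference)
    syn_sites, nonsyn_sites = gene_site_counts(genes, reference)
    is_syn = cls == "synonymous"
    is_non = cls == "nonsynonymous"
    rows = []
    for group in groups:
        idx = popmap.group_indices(G.samples, group)
        k, n = group_counts(G, idx)
        present = (k > 0) & (n >= 2)
        syn_snps = int((present & is_syn).sum())
        non_snps = int((present & is_non).sum())
        sub = G.counts[:, idx]
        carrier = sub > 0
        per_sample_syn = carrier[is_syn].sum(axis=0).mean() if idx.size else 0.0
        per_sample_non = carrier[is_non].sum(axis=0).mean() if idx.size else 0.0

        def _ratio(nonsyn, syn):
            if syn <= 0 or syn_sites <= 0 or nonsyn_sites <= 0:
                return np.nan
            return (nonsyn / nonsyn_sites) / (syn / syn_sites)

        rows.append(
            {
                "group": group,
                "n_samples": int(idx.size),
                "syn_snps": syn_snps,
                "nonsyn_snps": non_snps,
                "avg_syn_snps_per_sample": float(per_sample_syn),
                "avg_nonsyn_snps_per_sample": float(per_sample_non),
                "syn_sites": syn_sites,
                "nonsyn_sites": nonsyn_sites,
                "dnds_pooled": _ratio(non_snps, syn_snps),
                "dnds_per_sample": _ratio(per_sample_non, per_sample_syn),
            }
        )
    return pd.DataFrame(rows)
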