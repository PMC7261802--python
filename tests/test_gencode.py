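import numpy as np
import pytest

from domestiscan import gencode
from domestiscan.popio import GeneModel, GenotypeMatrix, PopulationMap

from _oracles import ng86_sites


def make_matrix(contig, positions, ref, alt, counts, samples):
    n = len(positions)
    return GenotypeMatrix(
        contigs=np.array([contig] * n, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        counts=np.array(counts, dtype=np.int8),
        vtype=np.array(["snp"] * n, dtype=object),
        samples=samples,
    )


class TestSiteFractions:
    def test_met_has_no_synonymous_sites(self):
        syn, nonsyn = gencode.codon_site_fractions("ATG")
        assert syn == 0.0
        assert nonsyn == 3.0

    def test_phe_has_one_third(self):
        syn, nonsyn = gencode.codon_site_fractions("TTT")
        assert syn == pytest.approx(1 / 3)
        assert nonsyn == pytest.approx(3 - 1 / 3)

    def test_all_codons_match_independent_code_table(self):
        bases = "ACGT"
        stops = {"TAA", "TAG", "TGA"}
        for a in bases:
            for b in bases:
                for c in bases:
                    codon = a + b + c
                    if codon in stops:
                        with pytest.raises(ValueError):
                            gencode.codon_site_fractions(codon)
                        continue
                    syn, nonsyn = gencode.codon_site_fractions(codon)
                    esyn, enonsyn = ng86_sites(codon)
                    assert syn == pytest.approx(esyn, abs=1e-12)
                    assert syn + nonsyn == pytest.approx(3.0, abs=1e-12)

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(ValueError, match="codon"):
            gencode.codon_site_fractions("ANT")


class TestClassifySnp:
    # forward gene covering 10..18 (1-based 11..19): codons TTT GCA AAA
    REF = "X" * 10 + "TTTGCAAAA" + "X" * 10
    GENE = GeneModel("g+", "chr1", "+", [(10, 19)])

    def test_third_position_synonymous(self):
        # TTT -> TTC at genomic pos 13 (1-based)
        assert gencode.classify_snp(self.GENE, self.REF, 13, "T", "C") == "synonymous"

    def test_first_position_nonsynonymous(self):
        assert gencode.classify_snp(self.GENE, self.REF, 11, "T", "A") == "nonsynonymous"

    def test_noncoding_outside_cds(self):
        assert gencode.classify_snp(self.GENE, self.REF, 5, "X", "A") == "noncoding"

    def test_reference_mismatch_reported(self):
        with pytest.raises(ValueError, match="chr1:13"):
            gencode.classify_snp(self.GENE, self.REF, 13, "G", "C")

    def test_minus_strand_synonymous_third_position(self):
        # coding TTT GCA AAA on the minus strand: genomic = revcomp
        coding = "TTTGCAAAA"
        genomic = coding.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        ref = "X" * 10 + genomic + "X" * 10
        gene = GeneModel("g-", "chr1", "-", [(10, 19)])
        # third codon position of codon 1 (TTT->TTC) is genomic offset 16
        # on the minus strand: genomic base A -> G complements to T -> C
        assert gencode.classify_snp(gene, ref, 17, "A", "G") == "synonymous"
        # first codon position of codon 1: genomic pos 19, T->A coding
        assert gencode.classify_snp(gene, ref, 19, "A", "T") == "nonsynonymous"

    def test_strand_symmetry_whole_locus(self, rng):
        """Reverse-complementing the locus and flipping gene strand
        leaves every classification unchanged."""
        from domestiscan.simdata import make_toy_genes
        import tempfile, os

        with tempfile.TemporaryDirectory() as td:
            genes = make_toy_genes(
                3_000, 4, 300, 7, os.path.join(td, "g.gff3"), os.path.join(td, "r.fa")
            )
            from domestiscan.popio import read_fasta, read_gff

            ref = read_fasta(os.path.join(td, "r.fa"))["chr1"]
            models = read_gff(os.path.join(td, "g.gff3"))
        comp = str.maketrans("ACGT", "TGCA")
        L = len(ref)
        rc_ref = ref.translate(comp)[::-1]
        for _ in range(40):
            g = models[int(rng.integers(len(models)))]
            pos = int(rng.integers(g.start, g.end)) + 1
            refb = ref[pos - 1]
            altb = rng.choice([b for b in "ACGT" if b != refb])
            cls = gencode.classify_snp(g, ref, pos, refb, altb)
            g_rc = GeneModel(
                g.gene_id, g.contig,
                "+" if g.strand == "-" else "-",
                [(L - e, L - s) for s, e in g.cds],
            )
            pos_rc = L - pos + 1
            cls_rc = gencode.classify_snp(
                g_rc, rc_ref, pos_rc, refb.translate(comp), altb.translate(comp)
            )
            assert cls == cls_rc


class TestGroupDnds:
    def _toy(self, tmp_path, n_genes=20, seed=0):
        from domestiscan.popio import read_fasta, read_gff
        from domestiscan.simdata import make_toy_genes

        make_toy_genes(
            n_genes * 400, n_genes, 300, seed, tmp_path / "g.gff3", tmp_path / "r.fa"
        )
        return read_gff(tmp_path / "g.gff3"), read_fasta(tmp_path / "r.fa")

    def test_no_genic_snps_absent_ratio(self, tmp_path):
        genes, ref = self._toy(tmp_path)
        G = make_matrix("chr1", [1], ["A"], ["T"], [[1, 1]], ["s1", "s2"])
        G.contigs[:] = "chrZ"  # off-contig
        pm = PopulationMap({"s1": "A", "s2": "A"}, ["A"])
        df = gencode.group_dnds(G, pm, genes, {"chrZ": "A" * 10, **ref})
        assert df.syn_snps.iloc[0] == 0
        assert np.isnan(df.dnds_pooled.iloc[0])

    def test_uniform_cds_mutation_neutral_ratio(self, tmp_path, rng):
        """SNPs placed uniformly at random in CDS with random alternate
        bases have dN/dS ~ 1 under NG86 normalization."""
        genes, ref = self._toy(tmp_path, n_genes=100, seed=1)
        seq = ref["chr1"]
        positions, refs, alts, counts = [], [], [], []
        taken = set()
        for g in genes:
            for _ in range(12):
                pos0 = int(rng.integers(g.start, g.end))
                if pos0 in taken:
                    continue
                taken.add(pos0)
                rb = seq[pos0]
                positions.append(pos0 + 1)
                refs.append(rb)
                alts.append(str(rng.choice([b for b in "ACGT" if b != rb])))
                counts.append([int(rng.integers(0, 3)) for _ in range(6)])
        order = np.argsort(positions)
        G = make_matrix(
            "chr1",
            [positions[i] for i in order],
            [refs[i] for i in order],
            [alts[i] for i in order],
            [counts[i] for i in order],
            [f"s{i}" for i in range(6)],
        )
        pm = PopulationMap({s: "A" for s in G.samples}, ["A"])
        df = gencode.group_dnds(G, pm, genes, ref)
        assert df.dnds_pooled.iloc[0] == pytest.approx(1.0, abs=0.15)

    def test_fourfold_only_mutation_gives_zero(self, tmp_path, rng):
        genes, ref = self._toy(tmp_path, n_genes=30, seed=2)
        seq = ref["chr1"]
        fourfold_prefix = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
        positions, refs, alts, counts = [], [], [], []
        for g in genes:
            cds = seq[g.start : g.end]
            if g.strand == "-":
                cds = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            for ci in range(0, len(cds), 3):
                codon = cds[ci : ci + 3]
                if codon[:2] in fourfold_prefix:
                    off = ci + 2  # third position, coding orientation
                    pos0 = (
                        g.start + off if g.strand == "+" else g.end - 1 - off
                    )
                    rb = seq[pos0]
                    positions.append(pos0 + 1)
                    refs.append(rb)
                    alts.append(str(rng.choice([b for b in "ACGT" if b != rb])))
                    counts.append([1, 1, 0, 0])
        order = np.argsort(positions)
        G = make_matrix(
            "chr1",
            [positions[i] for i in order],
            [refs[i] for i in order],
            [alts[i] for i in order],
            [counts[i] for i in order],
            ["s1", "s2", "s3", "s4"],
        )
        pm = PopulationMap({s: "A" for s in G.samples}, ["A"])
        df = gencode.group_dnds(G, pm, genes, ref)
        assert df.nonsyn_snps.iloc[0] == 0
        assert df.dnds_pooled.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_partition_every_genic_snp_counted_once(self, tmp_path, rng):
        genes, ref = self._toy(tmp_path, n_genes=10, seed=3)
        seq = ref["chr1"]
        pos0s = sorted(rng.choice(len(seq), size=200, replace=False))
        G = make_matrix(
            "chr1",
            [p + 1 for p in pos0s],
            [seq[p] for p in pos0s],
            [str(rng.choice([b for b in "ACGT" if b != seq[p]])) for p in pos0s],
            [[1, 1] for _ in pos0s],
            ["s1", "s2"],
        )
        cls = gencode.classify_all(G, genes, ref)
        genic = sum(
            1
            for p in pos0s
            if any(g.start <= p < g.end for g in genes)
        )
        assert ((cls == "synonymous") | (cls == "nonsynonymous")).sum() == genic
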