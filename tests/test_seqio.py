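"""Sequence/annotation I/O and preparation steps."""

import numpy as np
import pysam
import pytest

from lncdbs import seqio
from lncdbs.cohort import _write_gff3  # GFF writer used for round-trips
from lncdbs.seqio import (DuplicateContigError, GeneModel, GenomeAssembly,
                          RefMismatchError, apply_variants, assemble_lncrna,
                          extract_promoter, filter_by_n, load_genome,
                          n_fraction, read_gff, revcomp, write_genome)

from conftest import random_seq


def _write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestFasta:
    def test_round_trip_exact(self, tmp_path, rng):
        asm = GenomeAssembly({"c1": random_seq(rng, 313), "c2": "ACGTN" * 20})
        p = tmp_path / "g.fa"
        write_genome(asm, p)
        back = load_genome(p)
        assert back.contigs == asm.contigs

    def test_two_records_and_case(self, tmp_path):
        _write_fasta(tmp_path / "g.fa", [("a", "acgt"), ("b", "GGCC")])
        asm = load_genome(tmp_path / "g.fa")
        assert len(asm.contigs) == 2
        assert asm["a"] == "ACGT"

    def test_duplicate_header_rejected(self, tmp_path):
        _write_fasta(tmp_path / "g.fa", [("a", "ACGT"), ("a", "GGCC")])
        with pytest.raises(DuplicateContigError):
            load_genome(tmp_path / "g.fa")

    def test_invalid_characters(self, tmp_path):
        _write_fasta(tmp_path / "g.fa", [("a", "ACRT")])
        with pytest.raises(ValueError):
            load_genome(tmp_path / "g.fa")
        asm = load_genome(tmp_path / "g.fa", map_invalid_to_n=True)
        assert asm["a"] == "ACNT"


class TestPromoterWindow:
    def test_plus_strand_window_arithmetic(self, rng):
        asm = GenomeAssembly({"c": random_seq(rng, 10000)})
        gene = GeneModel("g", "c", "+", tss=4000)
        w = extract_promoter(gene, asm)
        assert (w.start, w.end) == (500, 5500)
        assert len(w) == 5000 and not w.truncated
        assert w.seq == asm["c"][500:5500]
        # 3500 bases before the TSS, then the TSS base itself
        assert w.seq[3500] == asm["c"][4000]

    def test_minus_strand_is_reverse_complement(self, rng):
        asm = GenomeAssembly({"c": random_seq(rng, 10000)})
        gene = GeneModel("g", "c", "-", tss=4000)
        w = extract_promoter(gene, asm)
        assert len(w) == 5000
        assert w.seq == revcomp(asm["c"][2501:7501])

    def test_upstream_clipping_flagged(self, rng):
        asm = GenomeAssembly({"c": random_seq(rng, 10000)})
        w = extract_promoter(GeneModel("g", "c", "+", tss=1000), asm)
        assert w.truncated and len(w) == 2500

    def test_strand_mirror_symmetry(self, rng):
        """Mirrored annotation on the reverse-complemented genome gives the
        same promoter sequence."""
        seq = random_seq(rng, 9000)
        tss = 4321
        fwd = extract_promoter(GeneModel("g", "c", "+", tss=tss),
                               GenomeAssembly({"c": seq}))
        mirrored = extract_promoter(
            GeneModel("g", "c", "-", tss=len(seq) - 1 - tss),
            GenomeAssembly({"c": revcomp(seq)}))
        assert fwd.seq == mirrored.seq

    def test_tss_outside_contig(self, rng):
        asm = GenomeAssembly({"c": random_seq(rng, 100)})
        with pytest.raises(ValueError):
            extract_promoter(GeneModel("g", "c", "+", tss=500), asm)


class TestLncrnaAssembly:
    def test_single_exon_plus(self, rng):
        seq = random_seq(rng, 500)
        asm = GenomeAssembly({"c": seq})
        g = GeneModel("l", "c", "+", tss=100, biotype="lncRNA",
                      exons=[(100, 220)])
        assert assemble_lncrna(g, asm).seq == seq[100:220]

    def test_two_exon_minus(self, rng):
        seq = random_seq(rng, 500)
        asm = GenomeAssembly({"c": seq})
        g = GeneModel("l", "c", "-", tss=399, biotype="lncRNA",
                      exons=[(100, 180), (250, 400)])
        assert assemble_lncrna(g, asm).seq == revcomp(seq[100:180] + seq[250:400])

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("l", "c", "+", tss=0, biotype="lncRNA",
                      exons=[(0, 100), (50, 150)])


def _make_vcf(path, contig_len, records):
    header = pysam.VariantHeader()
    header.contigs.add("c", length=contig_len)
    header.filters.add("LowQual", None, None, "low confidence")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("s1")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for pos1, ref, alt, filt, gt in records:
            rec = out.new_record(contig="c", start=pos1 - 1, stop=pos1,
                                 alleles=(ref, alt), filter=filt)
            rec.samples["s1"]["GT"] = gt
            out.write(rec)


class TestApplyVariants:
    @pytest.fixture()
    def asm(self, rng):
        seq = "A" * 50 + "C" * 50 + "G" * 50
        return GenomeAssembly({"c": seq})

    def test_empty_vcf_is_identity(self, asm, tmp_path):
        _make_vcf(tmp_path / "v.vcf", 150, [])
        assert apply_variants(asm, tmp_path / "v.vcf").contigs == asm.contigs

    def test_snv_substitution(self, asm, tmp_path):
        _make_vcf(tmp_path / "v.vcf", 150, [(100, "C", "G", "PASS", (1, 1))])
        out = apply_variants(asm, tmp_path / "v.vcf")
        assert out["c"][99] == "G"
        assert out["c"][:99] == asm["c"][:99]
        assert out["c"][100:] == asm["c"][100:]

    def test_non_pass_masks_with_n(self, asm, tmp_path):
        _make_vcf(tmp_path / "v.vcf", 150, [(7, "A", "G", "LowQual", (1, 1))])
        assert apply_variants(asm, tmp_path / "v.vcf")["c"][6] == "N"

    def test_missing_genotype_masks_with_n(self, asm, tmp_path):
        _make_vcf(tmp_path / "v.vcf", 150,
                  [(10, "A", "T", "PASS", (None, None))])
        assert apply_variants(asm, tmp_path / "v.vcf")["c"][9] == "N"

    def test_ref_mismatch_names_position(self, asm, tmp_path):
        _make_vcf(tmp_path / "v.vcf", 150, [(100, "T", "G", "PASS", (1, 1))])
        with pytest.raises(RefMismatchError, match="c:100"):
            apply_variants(asm, tmp_path / "v.vcf")

    def test_reapplication_is_idempotent(self, asm, tmp_path):
        _make_vcf(tmp_path / "v.vcf", 150, [(100, "C", "G", "PASS", (1, 1))])
        once = apply_variants(asm, tmp_path / "v.vcf")
        twice = apply_variants(once, tmp_path / "v.vcf")
        assert once.contigs == twice.contigs


class TestNFilters:
    @pytest.mark.parametrize("seq,expected", [
        ("AANNTTNN", 0.5), ("ACGTACGT", 0.0), ("NNNN", 1.0)])
    def test_n_fraction(self, seq, expected):
        assert n_fraction(seq) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            n_fraction("")

    def test_strict_threshold_semantics(self):
        at_threshold = "N" + "A" * 9        # exactly 10% N
        below = "N" * 29 + "A" * 71         # 29% N
        assert filter_by_n([at_threshold], 0.10) == []
        assert filter_by_n([below], 0.30) == [below]
        assert filter_by_n(["ACGT"], 0.10) == ["ACGT"]


class TestGff:
    def test_round_trip_gene_models(self, tmp_path, tiny_cohort):
        p = tmp_path / "t.gff3"
        contig_lens = {c: len(s) for c, s in
                       tiny_cohort.assemblies["horse"].contigs.items()}
        _write_gff3(p, tiny_cohort.genes, tiny_cohort.lncrna_genes, contig_lens)
        models = {g.gene_id: g for g in read_gff(p)}
        for g in tiny_cohort.genes:
            back = models[g.gene_id]
            assert (back.contig, back.strand, back.tss) == (
                g.contig, g.strand, g.tss)
            assert back.biotype == "coding"
        for g in tiny_cohort.lncrna_genes:
            back = models[g.gene_id]
            assert back.biotype == "lncRNA"
            assert back.exons == g.exons
            assert back.tss == g.tss
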