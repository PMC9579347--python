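"""Sequence and annotation I/O plus sequence-preparation steps.

This module covers the data-preparation layer of the pipeline: loading
genome assemblies from FASTA, reading gene models (protein-coding genes and
multi-exon lncRNA transcripts) from GFF3, building a per-sample consensus
from SNV calls with masking of low-confidence sites, extracting promoter
windows around transcription start sites, assembling spliced lncRNA
sequences, and the N-fraction filters used to discard unreliable
(ancient-DNA-style) sequences.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  GFF3 and VCF use 1-based
inclusive coordinates; conversion happens at the I/O boundary only.

The promoter window of a gene on the + strand is ``[tss - upstream,
tss + downstream)`` — i.e. ``upstream`` bases before the TSS, the TSS base
itself, and ``downstream - 1`` bases after it, 5,000 bp in total with the
defaults (3,500 up / 1,500 down).  On the − strand the window is mirrored
and the extracted sequence reverse-complemented, so the window always reads
5'→3' with respect to the gene.  Windows clipped at contig ends are flagged
``truncated`` rather than rejected: scaffold-level assemblies routinely
truncate promoter windows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class DuplicateContigError(ValueError):
    pass


class RefMismatchError(ValueError):
    pass


@dataclass
class GenomeAssembly:
    """Named contigs over {A,C,G,T,N}; one per species/sample."""

    contigs: dict[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        for cname, seq in self.contigs.items():
            if not cname:
                raise ValueError("empty contig name")
            if not seq:
                raise ValueError(f"empty sequence for contig {cname!r}")

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass
class GeneModel:
    """An annotated gene with TSS, strand and (for lncRNAs) exon structure.

    ``tss`` is the 0-based position of the transcription start: the gene
    start for + strand genes, the gene end − 1 for − strand genes.  Exons
    are 0-based half-open intervals in genomic order, sorted and
    non-overlapping.
    """

    gene_id: str
    contig: str
    strand: str
    tss: int
    biotype: str = "coding"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon ({s},{e}) in {self.gene_id}")
            if s < prev_end:
                raise ValueError(f"overlapping/unsorted exons in {self.gene_id}")
            prev_end = e


@dataclass
class PromoterWindow:
    gene_id: str
    contig: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str
    seq: str    # 5'->3' with respect to the gene
    truncated: bool = False

    @property
    def promoter_id(self) -> str:
        return self.gene_id

    @property
    def n_fraction(self) -> float:
        return n_fraction(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LncRNASequence:
    lncrna_id: str
    seq: str  # exon-assembled, strand-corrected, stored in DNA alphabet

    @property
    def n_fraction(self) -> float:
        return n_fraction(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


def load_genome(path: str | os.PathLike, name: str = "",
                map_invalid_to_n: bool = False) -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly`.

    Sequences are upper-cased.  Characters outside {A,C,G,T,N} either raise
    (default) or are mapped to N when ``map_invalid_to_n`` is set.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise DuplicateContigError(f"duplicate contig name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            if map_invalid_to_n:
                seq = "".join(c if c in VALID_BASES else "N" for c in seq)
            else:
                raise ValueError(
                    f"contig {rec.id!r} contains invalid characters {sorted(bad)}")
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeAssembly(contigs, name=name or os.path.basename(str(path)))


def write_genome(assembly: GenomeAssembly, path: str | os.PathLike,
                 width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=cname, description="")
               for cname, seq in assembly.contigs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models (genes + lncRNA transcripts with exons) from GFF3.

    For multi-transcript lncRNA genes the transcript with the largest exon
    sum defines the lncRNA sequence.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        strand = g.strand if g.strand in "+-" else "+"
        tss = (g.start - 1) if strand == "+" else (g.end - 1)
        biotype = g.attributes.get("gene_biotype", ["coding"])[0]
        biotype = "lncRNA" if biotype.lower() in ("lncrna", "lnc_rna") else "coding"
        exons: list[tuple[int, int]] = []
        if biotype == "lncRNA":
            best_sum = -1
            for t in db.children(g, level=1):
                t_exons = sorted((e.start - 1, e.end)
                                 for e in db.children(t, featuretype="exon"))
                exon_sum = sum(e - s for s, e in t_exons)
                if exon_sum > best_sum:
                    best_sum, exons = exon_sum, t_exons
        genes.append(GeneModel(gene_id=g.id, contig=g.seqid, strand=strand,
                               tss=tss, biotype=biotype, exons=exons))
    return genes


def apply_variants(assembly: GenomeAssembly,
                   vcf_path: str | os.PathLike) -> GenomeAssembly:
    """Substitute SNVs into an assembly, masking low-confidence sites with N.

    Rules (an explicit, minimal emulation of consensus building from an
    ancient-DNA variant call set):

    * only SNVs are accepted (REF and every ALT of length 1);
    * records whose FILTER is PASS or '.' substitute the first ALT;
    * records with any other FILTER, or with a missing genotype in the
      first sample, write N at the site;
    * the assembly base must equal REF — or already equal ALT, which makes
      re-application of the same call set a no-op (idempotent).
    """
    muts: dict[str, bytearray] = {c: bytearray(s, "ascii")
                                  for c, s in assembly.contigs.items()}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.chrom not in muts:
                raise KeyError(f"VCF contig {rec.chrom!r} absent from assembly")
            if rec.alts is None:
                continue
            if len(rec.ref) != 1 or any(len(a) != 1 for a in rec.alts):
                raise ValueError(
                    f"non-SNV record at {rec.chrom}:{rec.pos} (indels unsupported)")
            pos0 = rec.pos - 1
            arr = muts[rec.chrom]
            if pos0 < 0 or pos0 >= len(arr):
                raise IndexError(f"position {rec.pos} outside contig {rec.chrom}")
            alt = rec.alts[0].upper()
            cur = chr(arr[pos0])
            filters = list(rec.filter.keys())
            passing = (not filters) or filters == ["PASS"] or filters == ["."]
            gt_missing = False
            if rec.samples:
                gt = rec.samples[0].get("GT")
                gt_missing = gt is None or all(a is None for a in gt)
            if not passing or gt_missing:
                arr[pos0] = ord("N")
                continue
            if cur != rec.ref.upper() and cur != alt and cur != "N":
                raise RefMismatchError(
                    f"REF mismatch at {rec.chrom}:{rec.pos}: "
                    f"assembly has {cur}, VCF REF is {rec.ref}")
            arr[pos0] = ord(alt)
    return GenomeAssembly({c: a.decode("ascii") for c, a in muts.items()},
                          name=assembly.name)


def extract_promoter(gene: GeneModel, assembly: GenomeAssembly,
                     upstream: int = 3500, downstream: int = 1500) -> PromoterWindow:
    """Extract the promoter window around a gene's TSS.

    + strand: ``[tss - upstream, tss + downstream)``; − strand mirrored and
    reverse-complemented.  Windows clipped at contig boundaries are flagged
    ``truncated``.
    """
    if gene.contig not in assembly:
        raise KeyError(f"contig {gene.contig!r} not in assembly")
    contig_seq = assembly[gene.contig]
    if not (0 <= gene.tss < len(contig_seq)):
        raise ValueError(
            f"TSS {gene.tss} of {gene.gene_id} outside contig {gene.contig}")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream + 1, gene.tss + upstream + 1
    cstart, cend = max(0, start), min(len(contig_seq), end)
    seq = contig_seq[cstart:cend]
    if gene.strand == "-":
        seq = revcomp(seq)
    return PromoterWindow(gene_id=gene.gene_id, contig=gene.contig,
                          start=cstart, end=cend, strand=gene.strand, seq=seq,
                          truncated=(cstart != start or cend != end))


def promoter_rel_to_genomic(window: PromoterWindow, rel_start: int,
                            rel_end: int) -> tuple[int, int]:
    """Map a half-open interval in window coordinates to genomic coordinates."""
    if window.strand == "+":
        return window.start + rel_start, window.start + rel_end
    return window.end - rel_end, window.end - rel_start


def assemble_lncrna(gene: GeneModel, assembly: GenomeAssembly) -> LncRNASequence:
    """Concatenate exon slices 5'→3' into the spliced lncRNA sequence."""
    if gene.biotype != "lncRNA":
        raise ValueError(f"{gene.gene_id} is not annotated as lncRNA")
    if not gene.exons:
        raise ValueError(f"{gene.gene_id} has no exons")
    contig_seq = assembly[gene.contig]
    parts = []
    for s, e in gene.exons:
        if s < 0 or e > len(contig_seq):
            raise ValueError(f"exon ({s},{e}) outside contig {gene.contig}")
        parts.append(contig_seq[s:e])
    seq = "".join(parts)
    if gene.strand == "-":
        seq = revcomp(seq)
    return LncRNASequence(lncrna_id=gene.gene_id, seq=seq)


def n_fraction(seq: str) -> float:
    """Fraction of N bases; errors on empty input."""
    if not seq:
        raise ValueError("empty sequence")
    return seq.count("N") / len(seq)


def filter_by_n(records, threshold: float, strict: bool = True, key=None) -> list:
    """Retain records whose N fraction is below ``threshold``.

    The comparison is strict (``n_fraction < threshold``) by default: a
    record at exactly the threshold is dropped.  ``key`` extracts the N
    fraction; by default the record's ``n_fraction`` attribute is used, or
    the record itself is treated as a sequence string.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if key is None:
        key = lambda r: r.n_fraction if hasattr(r, "n_fraction") else n_fraction(r)
    if strict:
        return [r for r in records if key(r) < threshold]
    return [r for r in records if key(r) <= threshold]


def write_bed6(windows: list[PromoterWindow], path: str | os.PathLike,
               header_lines: list[str] | None = None) -> None:
    """Write promoter windows as BED6 (0-based half-open, like the internal
    convention)."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for w in windows:
            fh.write(f"{w.contig}\t{w.start}\t{w.end}\t{w.gene_id}\t0\t{w.strand}\n")


def write_fasta_records(records: dict[str, str], path: str | os.PathLike) -> None:
    """Write a mapping of id → sequence as FASTA."""
    seqs = [SeqRecord(Seq(s), id=rid, description="") for rid, s in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")
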