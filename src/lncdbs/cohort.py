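"""Synthetic multi-genome cohorts with planted triplex ground truth.

The generator emulates the structure of a comparative domestication
study without any downloads: several related genomes (a focal species
plus substitution-diverged relatives) share a common gene layout;
annotated lncRNAs carry triplex-forming segments (TFOs); gene promoters
carry planted triplex target sites (TTSs) derived from those TFOs at a
designed identity; a configurable fraction of planted sites is ablated in
non-focal species (making them focal-specific); and "ancient" copies of
the focal genome are produced as SNV call sets plus N-masked consensus
sequences.  Every planted site is recorded in a machine-readable truth
manifest so downstream stages can be scored against ground truth.

Design choices that matter for testing: background sequence is i.i.d.
uniform over {A,C,G,T}, which makes spurious >=50-bp, >=60%-identity
triplexes rare; genes are spaced further apart than the orthology flank
so each +/-flank search window contains exactly one promoter; planted
site sequences are built deterministically from the TFO (evenly spaced
mismatch positions), so the same (lncRNA, gene) site is identical across
species unless a per-species identity level or ablation says otherwise.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .seqio import GenomeAssembly, GeneModel, LncRNASequence, assemble_lncrna, revcomp
from .triplex import ALL_MOTIFS, MOTIF_ALPHABET, MOTIF_IMAGE, ORIENTATIONS, PAIRING

_BASES = "ACGTN"


class CohortSizingError(ValueError):
    """A contig or promoter cannot host the requested windows/sites."""


class PlantingError(ValueError):
    """Requested planted-site parameters are unsatisfiable."""


DEFAULT_SPECIES = ("horse", "donkey", "przewalski")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the cohort used throughout the analyses: three related
    species, 20 genes, 10 lncRNAs, 5-kb promoter windows, 120-bp planted
    sites (a realistic DBS length) at 85% designed identity, 30% of
    non-focal sites ablated, and
    ancient focal copies with 5% N-masking and a SNV divergence of 5e-4
    (the magnitude behind per-mille lncRNA distances between samples).
    """

    n_species: int = 3
    n_genes: int = 20
    n_lncrnas: int = 10
    promoter_len: int = 5000
    planted_site_len: int = 120
    planted_identity: float = 0.85
    ablation_rate: float = 0.3
    n_mask_rate: float = 0.05
    seed: int = 0
    # cohort structure beyond the minimal knobs
    targets_per_lncrna: int = 5
    lncrna_len: int = 500
    species_divergence: float = 0.02
    ablation_mode: str = "randomize"
    n_ancient: int = 3
    ancient_snv_rate: float = 5e-4
    ancient_lowq_rate: float = 0.05
    motifs: tuple[str, ...] = ALL_MOTIFS
    flank: int = 100_000
    n_ncds: int = 10
    # optional per-lncRNA affinity-ordering design: label -> fraction,
    # e.g. {"horse>donkey>przewalski": 0.6, "donkey>horse>przewalski": 0.4}.
    # Ranks are realized through planted-site length (affinity = length x
    # identity, and length is its dominant lever): the species ranked r in
    # a lncRNA's label gets sites truncated by r * rank_length_step bases.
    pattern_fractions: dict[str, float] | None = None
    rank_length_step: int = 20
    # give every lncRNA its own disjoint gene targets (one planted site per
    # promoter).  Purine-rich sites of different lncRNAs in one promoter
    # cross-react (any two same-motif sites match ~50% per position), which
    # is realistic but drowns designed affinity orderings; exclusive
    # targets remove that coupling for ordering-design cohorts.
    exclusive_gene_targets: bool = False

    def __post_init__(self) -> None:
        for name in ("planted_identity", "ablation_rate", "n_mask_rate",
                     "species_divergence"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.planted_site_len < 1:
            raise ValueError("planted_site_len must be >= 1")
        if self.n_species < 1 or self.n_genes < 1 or self.n_lncrnas < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.targets_per_lncrna > self.n_genes:
            raise ValueError("targets_per_lncrna exceeds n_genes")
        if (self.exclusive_gene_targets
                and self.n_lncrnas * self.targets_per_lncrna > self.n_genes):
            raise CohortSizingError(
                "exclusive_gene_targets needs n_genes >= "
                "n_lncrnas * targets_per_lncrna")
        if self.ablation_mode not in ("randomize", "shuffle"):
            raise ValueError(
                "cohort ablation_mode must be 'randomize' or 'shuffle' "
                "(deletion would shift manifest coordinates)")
        if self.lncrna_len < self.planted_site_len:
            raise CohortSizingError("lncrna_len too short for planted_site_len")

    @property
    def species(self) -> tuple[str, ...]:
        names = list(DEFAULT_SPECIES[: self.n_species])
        names += [f"species{i}" for i in range(len(names), self.n_species)]
        return tuple(names)

    @property
    def focal(self) -> str:
        return self.species[0]

    @property
    def upstream(self) -> int:
        return round(0.7 * self.promoter_len)

    @property
    def downstream(self) -> int:
        return self.promoter_len - self.upstream


@dataclass
class TruthRecord:
    """One planted TFO–TTS pair in one species."""

    lncrna_id: str
    gene_id: str
    species: str
    tfo_start: int  # spliced lncRNA coordinates, half-open
    tfo_end: int
    tts_start: int  # promoter-window coordinates, half-open
    tts_end: int
    genome_start: int  # genomic coordinates on the gene contig
    genome_end: int
    design_identity: float
    ablated: bool
    motif: str
    purine_strand: str  # window frame
    orientation: str


@dataclass
class AncientSample:
    name: str
    vcf_records: list[tuple[str, int, str, str, str]]  # contig, pos1, ref, alt, filter
    assembly: GenomeAssembly  # masked consensus


@dataclass
class Cohort:
    config: CohortConfig
    assemblies: dict[str, GenomeAssembly]          # per species
    genes: list[GeneModel]                         # shared layout (all species)
    lncrna_genes: list[GeneModel]                  # focal annotation
    lncrnas: dict[str, LncRNASequence]             # focal spliced sequences
    manifest: list[TruthRecord]
    ancient: list[AncientSample] = field(default_factory=list)
    ncds_genes: list[str] = field(default_factory=list)
    pattern_labels: dict[str, str] = field(default_factory=dict)  # lncrna -> label

    @property
    def species(self) -> tuple[str, ...]:
        return self.config.species

    @property
    def focal(self) -> str:
        return self.config.focal

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.manifest])


# ---------------------------------------------------------------------------
# primitive planting operations


def design_tts(tfo_seq: str, motif: str, target_identity: float,
               orientation: str = "parallel") -> str:
    """Purine-strand TTS sequence realizing ``target_identity`` vs a TFO.

    Matching positions carry the motif's pairing image of the TFO base;
    mismatch positions (evenly spaced, deterministic) carry a base that
    does not pair.  The realized identity is within one base-worth of the
    target.  For antiparallel motifs the returned purine-strand sequence
    is reversed so that the TFO read 5'→3' pairs against it read 3'→5'.
    """
    if motif not in PAIRING:
        raise ValueError(f"unknown motif {motif!r}")
    if orientation not in ORIENTATIONS[motif]:
        raise ValueError(f"orientation {orientation!r} invalid for motif {motif!r}")
    L = len(tfo_seq)
    if L < 1:
        raise PlantingError("empty TFO")
    n_match = round(target_identity * L)
    if not (0 <= n_match <= L):
        raise PlantingError(
            f"identity {target_identity} unrealizable for length {L}")
    bad = set(tfo_seq) - set(MOTIF_ALPHABET[motif])
    if bad:
        raise PlantingError(
            f"TFO letters {sorted(bad)} cannot pair under motif {motif!r}")
    n_mis = L - n_match
    mis_positions = {int(k * L / n_mis) for k in range(n_mis)} if n_mis else set()
    image = MOTIF_IMAGE[motif]
    pairs = PAIRING[motif]
    site = []
    for i, rb in enumerate(tfo_seq):
        if i in mis_positions:
            candidates = [b for b in "ACGT" if (rb, b) not in pairs]
            site.append(candidates[i % len(candidates)])
        else:
            site.append(image[rb])
    seq = "".join(site)
    return seq[::-1] if orientation == "antiparallel" else seq


def plant_triplex_site(promoter_seq: str, tfo_seq: str, motif: str,
                       target_identity: float, position: int,
                       purine_strand: str = "+",
                       orientation: str | None = None) -> str:
    """Embed a TTS for ``tfo_seq`` into a promoter sequence.

    The site is placed at ``position`` (window coordinates); when the
    designated purine strand is '-', the reverse complement of the
    purine-strand sequence is written into the forward window.  Bases
    outside the site are unchanged.
    """
    if orientation is None:
        orientation = ORIENTATIONS[motif][0]
    site = design_tts(tfo_seq, motif, target_identity, orientation)
    L = len(site)
    if position < 0 or position + L > len(promoter_seq):
        raise ValueError(
            f"site [{position}, {position + L}) outside promoter of length "
            f"{len(promoter_seq)}")
    ins = site if purine_strand == "+" else revcomp(site)
    return promoter_seq[:position] + ins + promoter_seq[position + L:]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def mask_ancient(seq: str, n_mask_rate: float, seed) -> str:
    """Replace an i.i.d. fraction of bases with N (length preserved)."""
    if not (0 <= n_mask_rate <= 1):
        raise ValueError("n_mask_rate must be in [0, 1]")
    if n_mask_rate == 0:
        return seq
    rng = _as_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    arr[rng.random(len(arr)) < n_mask_rate] = ord("N")
    return arr.tobytes().decode("ascii")


def ablate_site(seq: str, interval: tuple[int, int], mode: str, seed) -> str:
    """Remove a planted site: delete it, shuffle it in place (preserving
    length and base composition), or replace it with random bases."""
    s, e = interval
    if not (0 <= s < e <= len(seq)):
        raise ValueError(f"interval {interval} out of bounds")
    rng = _as_rng(seed)
    if mode == "delete":
        return seq[:s] + seq[e:]
    if mode == "shuffle":
        chars = list(seq[s:e])
        rng.shuffle(chars)
        return seq[:s] + "".join(chars) + seq[e:]
    if mode == "randomize":
        repl = "".join("ACGT"[i] for i in rng.integers(0, 4, e - s))
        return seq[:s] + repl + seq[e:]
    raise ValueError(f"unknown ablation mode {mode!r}")


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def site_recovered(record: TruthRecord, intervals: list[tuple[int, int]],
                   min_frac: float = 0.5) -> bool:
    """Does any predicted TTS/DBS interval (window coordinates) cover at
    least ``min_frac`` of the planted site?"""
    truth = (record.tts_start, record.tts_end)
    tlen = truth[1] - truth[0]
    return any(interval_overlap(truth, iv) >= min_frac * tlen for iv in intervals)


# ---------------------------------------------------------------------------
# cohort generation

GENE_CONTIG = "chr1"
LNC_CONTIG = "chrL"


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    tbl = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        tbl[ord(b)] = i
    return tbl[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def _spliced_writeback(gene: GeneModel, contig: np.ndarray, spliced: str) -> None:
    """Write a spliced (strand-corrected) sequence back into genomic exons."""
    genomic = spliced if gene.strand == "+" else revcomp(spliced)
    off = 0
    for s, e in gene.exons:
        contig[s:e] = _encode(genomic[off:off + (e - s)])
        off += e - s


def _window_bounds(tss: int, strand: str, upstream: int, downstream: int
                   ) -> tuple[int, int]:
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream + 1, tss + upstream + 1


def _write_window_site(contig: np.ndarray, gene: GeneModel, upstream: int,
                       downstream: int, rel: int, ins_window: str) -> tuple[int, int]:
    """Write a window-frame segment into the genome; return genomic interval."""
    ws, we = _window_bounds(gene.tss, gene.strand, upstream, downstream)
    L = len(ins_window)
    if gene.strand == "+":
        gs, ge = ws + rel, ws + rel + L
        contig[gs:ge] = _encode(ins_window)
    else:
        gs, ge = we - rel - L, we - rel
        contig[gs:ge] = _encode(revcomp(ins_window))
    return gs, ge


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    up, down = config.upstream, config.downstream
    site_len = config.planted_site_len

    # --- layout ------------------------------------------------------------
    margin = config.promoter_len + 1000
    gene_spacing = 2 * config.flank + 2 * config.promoter_len
    chr1_len = 2 * margin + config.n_genes * gene_spacing
    genes: list[GeneModel] = []
    for g in range(config.n_genes):
        tss = margin + g * gene_spacing
        strand = "+" if rng.random() < 0.7 else "-"
        genes.append(GeneModel(gene_id=f"gene{g:03d}", contig=GENE_CONTIG,
                               strand=strand, tss=tss, biotype="coding"))

    intron = 150
    lnc_spacing = config.lncrna_len + intron + 2000
    chrl_len = 2000 + config.n_lncrnas * lnc_spacing
    lnc_genes: list[GeneModel] = []
    for i in range(config.n_lncrnas):
        start = 1000 + i * lnc_spacing
        e1 = max(1, int(0.6 * config.lncrna_len))
        e2 = config.lncrna_len - e1
        exons = [(start, start + e1)]
        if e2 > 0:
            exons.append((start + e1 + intron, start + e1 + intron + e2))
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(gene_id=f"lnc{i:03d}", contig=LNC_CONTIG, strand=strand,
                         tss=(start if strand == "+" else exons[-1][1] - 1),
                         biotype="lncRNA", exons=exons)
        lnc_genes.append(gene)

    # spacing between planted sites in one promoter must exceed the reach
    # of maximal-window extension through background (~(id-0.6)/0.475 * L
    # per side), or neighbouring sites chain into one merged DBS
    slot_width = site_len + 200
    max_slots = (config.promoter_len - 400) // slot_width
    if max_slots < 1:
        raise CohortSizingError("promoter_len too short to host planted sites")

    # --- focal genome with TFOs --------------------------------------------
    focal_chr1 = _random_codes(rng, chr1_len)
    focal_chrl = _random_codes(rng, chrl_len)
    focal_asm = {GENE_CONTIG: focal_chr1, LNC_CONTIG: focal_chrl}

    tfo_info: dict[str, tuple[str, int, str]] = {}  # lncrna -> (motif, offset, seq)
    for gene in lnc_genes:
        motif = str(rng.choice(list(config.motifs)))
        off = int(rng.integers(0, config.lncrna_len - site_len + 1))
        alphabet = MOTIF_ALPHABET[motif]
        tfo_seq = "".join(str(rng.choice(list(alphabet)))
                          for _ in range(site_len))
        spliced = _decode(np.concatenate(
            [focal_chrl[s:e] for s, e in gene.exons]))
        if gene.strand == "-":
            spliced = revcomp(spliced)
        spliced = spliced[:off] + tfo_seq + spliced[off + site_len:]
        _spliced_writeback(gene, focal_chrl, spliced)
        tfo_info[gene.gene_id] = (motif, off, tfo_seq)

    # --- diverged relatives -------------------------------------------------
    species_arrays: dict[str, dict[str, np.ndarray]] = {
        config.focal: focal_asm}
    for sp in config.species[1:]:
        asm = {}
        for cname, arr in focal_asm.items():
            a = arr.copy()
            hit = rng.random(len(a)) < config.species_divergence
            idx = np.nonzero(hit)[0]
            a[idx] = (a[idx] + rng.integers(1, 4, len(idx), dtype=np.uint8)) % 4
            asm[cname] = a
        species_arrays[sp] = asm

    # --- affinity-pattern design -------------------------------------------
    pattern_labels: dict[str, str] = {}
    rank_of: dict[str, dict[str, int]] = {}
    if config.pattern_fractions:
        labels = list(config.pattern_fractions)
        for lab in labels:
            parts = tuple(lab.split(">"))
            if sorted(parts) != sorted(config.species):
                raise ValueError(f"pattern label {lab!r} must order all species")
            rank_of[lab] = {sp: r for r, sp in enumerate(parts)}
        counts = [int(round(config.pattern_fractions[lab] * config.n_lncrnas))
                  for lab in labels]
        while sum(counts) > config.n_lncrnas:
            counts[int(np.argmax(counts))] -= 1
        while sum(counts) < config.n_lncrnas:
            counts[int(np.argmin(counts))] += 1
        pool = [lab for lab, c in zip(labels, counts) for _ in range(c)]
        pool = [pool[i] for i in rng.permutation(len(pool))]
        for gene, lab in zip(lnc_genes, pool):
            pattern_labels[gene.gene_id] = lab
        rank_lens = tuple(site_len - config.rank_length_step * r
                          for r in range(config.n_species))
        if min(rank_lens) < 50:
            raise PlantingError(
                "rank-truncated site lengths fall below the 50-bp "
                "triplex detection floor")
    else:
        rank_lens = (site_len,) * config.n_species

    def site_len_for(lnc_id: str, sp: str) -> int:
        if pattern_labels:
            return rank_lens[rank_of[pattern_labels[lnc_id]][sp]]
        return site_len

    # --- plant target sites --------------------------------------------------
    manifest: list[TruthRecord] = []
    slot_counter: dict[str, int] = {g.gene_id: 0 for g in genes}
    for li, lnc_gene in enumerate(lnc_genes):
        lnc_id = lnc_gene.gene_id
        motif, tfo_off, tfo_seq = tfo_info[lnc_id]
        if config.exclusive_gene_targets:
            t = config.targets_per_lncrna
            target_idx = list(range(li * t, (li + 1) * t))
        else:
            target_idx = sorted(rng.choice(config.n_genes,
                                           size=config.targets_per_lncrna,
                                           replace=False).tolist())
        for gi in target_idx:
            gene = genes[gi]
            slot = slot_counter[gene.gene_id]
            if slot >= max_slots:
                raise CohortSizingError(
                    f"promoter of {gene.gene_id} cannot host another site")
            slot_counter[gene.gene_id] += 1
            rel = 200 + slot * slot_width
            w_strand = "+" if rng.random() < 0.5 else "-"
            orient_opts = ORIENTATIONS[motif]
            orientation = (orient_opts[0] if len(orient_opts) == 1
                           else str(rng.choice(list(orient_opts))))
            for sp in config.species:
                sp_len = site_len_for(lnc_id, sp)
                site = design_tts(tfo_seq[:sp_len], motif,
                                  config.planted_identity, orientation)
                ins_window = site if w_strand == "+" else revcomp(site)
                gs, ge = _write_window_site(
                    species_arrays[sp][GENE_CONTIG], gene, up, down, rel,
                    ins_window)
                manifest.append(TruthRecord(
                    lncrna_id=lnc_id, gene_id=gene.gene_id, species=sp,
                    tfo_start=tfo_off, tfo_end=tfo_off + sp_len,
                    tts_start=rel, tts_end=rel + sp_len,
                    genome_start=gs, genome_end=ge,
                    design_identity=config.planted_identity, ablated=False,
                    motif=motif, purine_strand=w_strand,
                    orientation=orientation))

    # --- ablation in non-focal species ---------------------------------------
    for rec in manifest:
        if rec.species == config.focal:
            continue
        if rng.random() < config.ablation_rate:
            arr = species_arrays[rec.species][GENE_CONTIG]
            seg = _decode(arr[rec.genome_start:rec.genome_end])
            seg = ablate_site(seg, (0, len(seg)), config.ablation_mode, rng)
            arr[rec.genome_start:rec.genome_end] = _encode(seg)
            rec.ablated = True

    assemblies = {sp: GenomeAssembly({c: _decode(a) for c, a in arrs.items()},
                                     name=sp)
                  for sp, arrs in species_arrays.items()}

    # --- ancient copies of the focal genome ----------------------------------
    ancient: list[AncientSample] = []
    for k in range(config.n_ancient):
        name = f"ancient{k + 1}"
        vcf_records: list[tuple[str, int, str, str, str]] = []
        contigs: dict[str, str] = {}
        for cname, arr in species_arrays[config.focal].items():
            a = arr.copy()
            idx = np.nonzero(rng.random(len(a)) < config.ancient_snv_rate)[0]
            for pos in idx:
                ref = _BASES[a[pos]]
                alt_code = (a[pos] + rng.integers(1, 4)) % 4
                alt = _BASES[alt_code]
                lowq = rng.random() < config.ancient_lowq_rate
                vcf_records.append((cname, int(pos) + 1, ref, alt,
                                    "LowQual" if lowq else "PASS"))
                a[pos] = 4 if lowq else alt_code
            contigs[cname] = mask_ancient(_decode(a), config.n_mask_rate, rng)
        ancient.append(AncientSample(
            name=name, vcf_records=vcf_records,
            assembly=GenomeAssembly(contigs, name=name)))

    # --- focal spliced lncRNA sequences --------------------------------------
    lncrnas = {g.gene_id: assemble_lncrna(g, assemblies[config.focal])
               for g in lnc_genes}

    ncds_n = min(config.n_ncds, config.n_genes)
    ncds_idx = sorted(rng.choice(config.n_genes, size=ncds_n,
                                 replace=False).tolist())
    ncds_genes = [genes[i].gene_id for i in ncds_idx]

    return Cohort(config=config, assemblies=assemblies, genes=genes,
                  lncrna_genes=lnc_genes, lncrnas=lncrnas, manifest=manifest,
                  ancient=ancient, ncds_genes=ncds_genes,
                  pattern_labels=pattern_labels)


# ---------------------------------------------------------------------------
# serialization


def _write_gff3(path, genes: list[GeneModel], lncrna_genes: list[GeneModel],
                contig_lens: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cname, clen in contig_lens.items():
            fh.write(f"##sequence-region {cname} 1 {clen}\n")
        for g in genes:
            start1, end1 = g.tss + 1, g.tss + 2000
            if g.strand == "-":
                start1, end1 = g.tss - 1999 + 1, g.tss + 1
            fh.write(f"{g.contig}\t.\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id};gene_biotype=protein_coding\n")
        for g in lncrna_genes:
            gstart = min(s for s, _ in g.exons) + 1
            gend = max(e for _, e in g.exons)
            common = f"\t{gstart}\t{gend}\t.\t{g.strand}\t.\t"
            fh.write(f"{g.contig}\t.\tgene{common}"
                     f"ID={g.gene_id};gene_biotype=lncRNA\n")
            tid = f"{g.gene_id}.t1"
            fh.write(f"{g.contig}\t.\tlnc_RNA{common}ID={tid};Parent={g.gene_id}\n")
            for j, (s, e) in enumerate(g.exons):
                fh.write(f"{g.contig}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={tid}.e{j + 1};Parent={tid}\n")


def _write_vcf(path, sample: AncientSample, contig_lens: dict[str, int]) -> None:
    header = pysam.VariantHeader()
    for cname, clen in contig_lens.items():
        header.contigs.add(cname, length=clen)
    header.filters.add("LowQual", None, None, "Low-confidence ancient call")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample.name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for cname, pos1, ref, alt, filt in sample.vcf_records:
            rec = out.new_record(contig=cname, start=pos1 - 1, stop=pos1,
                                 alleles=(ref, alt), filter=filt)
            rec.samples[sample.name]["GT"] = (1, 1)
            out.write(rec)


def write_cohort(cohort: Cohort, outdir: str | os.PathLike) -> dict[str, str]:
    """Write FASTA/GFF3/VCF/TSV artifacts for a cohort; returns the paths."""
    from .seqio import write_genome

    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    cfg = cohort.config
    paths: dict[str, str] = {}
    contig_lens = {c: len(s) for c, s in
                   cohort.assemblies[cohort.focal].contigs.items()}

    for sp, asm in cohort.assemblies.items():
        p = os.path.join(outdir, f"{sp}.fa")
        write_genome(asm, p)
        paths[f"fasta:{sp}"] = p
        gp = os.path.join(outdir, f"{sp}.gff3")
        _write_gff3(gp, cohort.genes,
                    cohort.lncrna_genes if sp == cohort.focal else [],
                    contig_lens)
        paths[f"gff:{sp}"] = gp
    for anc in cohort.ancient:
        p = os.path.join(outdir, f"{anc.name}.fa")
        write_genome(anc.assembly, p)
        paths[f"fasta:{anc.name}"] = p
        vp = os.path.join(outdir, f"{anc.name}.vcf")
        _write_vcf(vp, anc, contig_lens)
        paths[f"vcf:{anc.name}"] = vp

    mp = os.path.join(outdir, "truth_manifest.tsv")
    cohort.manifest_frame().to_csv(mp, sep="\t", index=False)
    paths["manifest"] = mp

    gl = os.path.join(outdir, "genes.txt")
    with open(gl, "w") as fh:
        fh.writelines(f"{g.gene_id}\n" for g in cohort.genes)
    paths["genes"] = gl
    nl = os.path.join(outdir, "ncds_genes.txt")
    with open(nl, "w") as fh:
        fh.writelines(f"{gid}\n" for gid in cohort.ncds_genes)
    paths["ncds_genes"] = nl

    cp = os.path.join(outdir, "cohort_config.json")
    cfgdict = dataclasses.asdict(cfg)
    cfgdict["motifs"] = list(cfg.motifs)
    with open(cp, "w") as fh:
        json.dump(cfgdict, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["config"] = cp
    return paths
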