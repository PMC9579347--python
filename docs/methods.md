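# Methods

`lncdbs` models one regulatory mechanism: a long noncoding RNA binds
double-stranded DNA in the major groove by forming an RNA:DNA:DNA triplex,
and recruitment of chromatin modifiers to such binding sites regulates the
nearby gene.  The package predicts these sites in gene promoters, scores
them, and compares the per-genome site repertoires of related species —
including low-quality, N-masked "ancient" consensus copies of one genome.

## Triplex model

A triplex pairs a segment of the RNA (the triplex-forming oligonucleotide,
TFO) with the purine-rich strand of a DNA duplex segment (the
triplex-targeting site, TTS).  We use the canonical Hoogsteen /
reverse-Hoogsteen codes:

| motif       | third-strand orientation | pairs (RNA · duplex purine base) |
|-------------|--------------------------|----------------------------------|
| pyrimidine  | parallel                 | T·A, C·G                         |
| purine      | antiparallel             | A·A, G·G                         |
| mixed GT    | both                     | G·G, T·A                         |

N never pairs, so N-masked consensus positions silently lose triplexes —
the same direction in which the explicit N-fraction prefilters act.

Matching is **ungapped**: a candidate is a diagonal window of the RNA x DNA
match matrix for one (duplex strand, motif, orientation) combination.  A
window qualifies when its length is ≥ `min_length` (default 50 bp) and its
identity — pairing positions / window length — is ≥ `min_identity`
(default 0.60, inclusive).  Gapped triplex alignment exists in the
literature; we chose ungapped scanning because it admits an exact
definition of the reported set and therefore an exact brute-force oracle.
This is a documented simplification, not an approximation of a particular
gapped tool.

**Maximality.**  Qualifying windows are heavily nested and overlapping.
On each diagonal, overlap-connected groups of qualifying windows are
reduced to a single representative: the longest window, ties broken by
higher identity, then smaller start.  This makes the output set
well-defined, deterministic, and checkable.

**Engine vs oracle.**  The production scanner shears the match matrix so
diagonals become columns, computes prefix scores (match `1 − min_identity`,
mismatch `−min_identity`; a window qualifies iff its score sum ≥ 0), and
uses a vectorized prefix-min bound to reject diagonals that cannot contain
a qualifying window; survivors are enumerated exhaustively with integer
match counts, so float rounding can only cost wasted work, never a missed
or spurious window (the quick-reject slack of 0.05 is orders of magnitude
above float32 prefix-sum error).  The oracle (`lncdbs.oracle`) enumerates
every window of every diagonal in plain Python with its own independent
reduction and is guarded to ≤ 2,000 nt.  Equivalence of the two on seeded
random-plus-planted instances is part of the test suite.

## Sites, domains, and the best-DBD rule

Overlapping TTSs (single-linkage, overlap ≥ 1 bp, across motifs and
strands) merge into a **DBS** (DNA-binding site); overlapping TFOs merge
into a **DBD** (DNA-binding domain) on the RNA.  When a lncRNA has several
DBDs, only the DBSs reached by the *best* DBD — the one whose members
touch the most distinct DBSs — are analyzed further; ties go to the
smaller RNA start coordinate for determinism.

**Binding affinity** of a DBS is `length x mean member identity`, with
identity as a fraction: a 100-bp site averaging 60% identity scores 60.
Filters are strict: DBSs are retained at affinity > 60; the
nuclear-lncRNA prefilter passes a lncRNA only with > 2,000 raw TTSs
(pre-merge triplexes, the unit a genome-wide screen reports) across the
promoter set, so a count of exactly 2,000 fails.  The TTS cutoff is a
genome-scale quantity (tens of thousands of promoters); desk-scale
synthetic cohorts can never reach it, so the pipeline exposes it as a
configuration threshold and the analysis drivers set it to the cohort's
scale.  Whether the affinity filter applies to the ancient-sample group is
exposed as a flag (`affinity_filter_ancient`, default off): low-quality
consensus sequences already lose triplexes to N-masking, and the
chronological comparison is about quality tiers rather than regulation
strength.

A useful consequence of the maximality rule: a reported window extends
until identity would drop below the floor, so a single-member DBS has
affinity ≈ its match count.  Affinity is therefore driven primarily by
site length, which is also the lever the synthetic generator uses to
design affinity orderings (below).

## Sequence preparation

* Promoter window: 3,500 bp upstream through 1,500 bp downstream of the
  TSS.  On the + strand this is `[tss − 3500, tss + 1500)` (0-based,
  half-open): 3,500 bases, the TSS base, and 1,499 following bases — 5,000
  total.  Published descriptions of such windows rarely say whether the
  TSS base counts; this convention fixes the length at exactly 5,000 and
  is applied mirror-symmetrically (with reverse complement) on the −
  strand.  Windows clipped at contig ends are flagged, not dropped —
  scaffold-level assemblies truncate windows in practice.
* lncRNA sequences are exon concatenations, strand-corrected, stored in
  the DNA alphabet.  For multi-transcript genes the transcript with the
  largest exon sum is used.
* Consensus from SNV calls: PASS (or unfiltered) single-nucleotide records
  substitute their ALT; records with any other FILTER or a missing
  genotype write N — an explicit, minimal emulation of masking
  low-confidence positions in an ancient-DNA consensus.  Re-applying the
  same call set is a no-op.
* N filters are strict: lncRNAs are kept at N-fraction < 0.10, promoter
  windows at < 0.30.

## Cross-genome comparisons

* **Homolog search** (lncRNA → other genome) and **DBS orthology** (DBS
  sequence → ±100 kb of the orthologous gene's TSS) use local alignment
  (match +1, mismatch −1, gap open −2, gap extend −0.5) behind an exact
  k-mer seeding step (k = 16 genome-wide, k = 12 within orthology
  windows); only regions around seed clusters are aligned, which makes
  genome-scale targets tractable without changing what a hit means.  A
  hit requires identity ≥ 0.8 over the aligned (non-gap) columns and
  query coverage ≥ 0.5; identity excludes gap columns so that an
  alignment bridging an intron judges its aligned blocks, while gap costs
  still decide which alignment wins.  Both strands are searched.  A DBS
  with no hit is species-specific; a gene absent from the target
  annotation yields a distinct `unmapped` status.
* **Affinity orderings**: per lncRNA, the mean affinity of retained DBSs
  per species defines a strict descending label (e.g.
  `horse>donkey>przewalski`); any adjacent pair within `tie_tol`
  (default 0, i.e. only exact ties) gives a tie label.  lncRNAs with no
  retained DBS in some species are excluded from classification and
  tallied with the reason.
* **Distances**: p-distance (mismatches / aligned non-gap, non-N columns)
  over a pairwise global alignment.  The argument pair is canonicalized
  (sorted) before aligning so co-optimal alignments cannot break exact
  symmetry.  Between samples, the reported distance is the mean of
  per-lncRNA distances over the shared lncRNA set.

## Synthetic cohorts

The generator builds the study conditions end to end: a focal genome with
i.i.d. uniform background (spurious ≥ 50 bp, ≥ 60% windows are rare, so
recovery tests are clean); related species as substitution-diverged copies
(default 2% — enough to be non-trivial for the homolog search, close
enough that orthologous context aligns); genes spaced farther apart than
the orthology flank so each ±flank window contains exactly one promoter;
lncRNAs as two-exon genes whose spliced sequence carries a TFO drawn from
the motif's pairing alphabet; and planted TTSs built deterministically
from the TFO (evenly spaced mismatch positions), so the same site is
identical across species unless the design says otherwise.  Defaults:
3 species, 20 genes, 10 lncRNAs, 5-kb promoters, 120-bp sites (a realistic
DBS length that clears the affinity filter at the default 85% designed
identity), ablation rate 0.3, N-mask rate 0.05, three ancient copies at
SNV rate 5x10⁻⁴ (the magnitude that yields per-mille lncRNA distances
between samples) with 5% of calls flagged low-quality.

Within a promoter, planted sites sit ≥ 200 bp apart: maximal windows
extend roughly `(identity − 0.6)/0.475 x length` per side through
background, and closer slots would chain neighbouring sites into one
merged DBS.  Ablation in non-focal species replaces the site in place
(`randomize` by default, `shuffle` available; `delete` exists as a
primitive but is rejected inside cohorts because it would shift the
coordinates of every later manifest record).

Affinity-ordering cohorts assign each lncRNA a designed species ordering
and truncate its planted sites by 20 bp per rank.  Length is the robust
lever: designed *identity* gaps compress, because maximal-window extension
rises with identity and cancels much of the intended affinity difference.
These cohorts also use exclusive gene targets (one planted site per
promoter): purine-rich sites of two lncRNAs sharing a motif match each
other at ~50% per position, and such cross-reactive DBSs — realistic as
they are — drown a designed ordering in correlated noise.

What the generator does **not** emulate: phylogenetic correlation
structure, indels, sequencing-read noise, deamination damage patterns, GC
heterogeneity, repeats.  Tests passing on these cohorts show the machinery
is correct and calibrated at desk scale, not that real genomes would yield
any particular counts.

## Numerical and degenerate-input choices

Strict vs inclusive boundaries follow the stated rules exactly (identity
≥ 0.60 inclusive; affinity > 60, TTS count > 2000, N fractions < 0.10 /
< 0.30 strict).  Window qualification uses integer match counts against
`min_identity x length − 1e−9`, so 30/50 qualifies and float noise cannot
flip a boundary.  Empty inputs: an empty triplex list merges to an empty
DBS list; a lncRNA with no DBDs is dropped with a reason; an empty
orthology direction is flagged rather than divided by zero; empty samples
appear in summaries with an explicit flag.

## Problem sizes

The bundled analyses and tests run cohorts of 3 genomes with 12–45 genes,
8–15 lncRNAs (~500 nt), 1.5–5 kb promoters and a 20–100 kb orthology
flank — sizes chosen so a full run is minutes on one core while every
stage still operates at its intended signal-to-noise.  The engine scans a
500 x 5,000 pair in ~0.25 s; the exhaustive oracle is only ever applied at
its ≤ 2,000 nt guard.

## Known limitations

* Ungapped matching understates triplexes interrupted by bulges.
* The GT motif is scanned in both orientations; if a downstream
  application requires a single orientation convention it must filter.
* The seeded homolog search can miss homologs that share no exact k-mer
  (k = 16 ≈ 20% divergence for uniform substitutions); at the divergences
  simulated here the miss probability is negligible.
* `resume` reloads the expensive scan stage from its table; cheap
  extraction stages are recomputed deterministically.
* Orthology windows are clipped at contig ends; on very short scaffolds a
  "species-specific" call can reflect assembly truncation rather than
  sequence loss, which is why `unmapped` is kept separate from `no-hit`.
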