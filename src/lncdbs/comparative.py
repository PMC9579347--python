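"""Cross-genome comparisons of lncRNA DNA-binding repertoires.

Four questions, each mirrored in one operation family:

* Does a lncRNA have a detectable homolog in another genome?
  (:func:`find_lncrna_homolog` — seeded local alignment search.)
* Is a DBS conserved near the orthologous gene, or species-specific?
  (:func:`dbs_orthology` — search the DBS sequence within +/-flank of the
  target gene's TSS; no detectable counterpart means species-specific.)
* How do per-lncRNA mean binding affinities order across species?
  (:func:`classify_affinity_pattern` / :func:`pattern_proportions`.)
* How many lncRNAs/DBSs does each candidate gene attract per species?
  (:func:`per_gene_dbs_counts`.)

Plus :func:`pairwise_distance`: p-distance over a pairwise global
alignment, for lncRNA divergence between samples.

Alignment is done with Biopython's PairwiseAligner (affine gaps, match
+1, mismatch -1, gap open -2, gap extend -0.5).  Genome-scale targets are
made tractable by an exact k-mer seeding step: only regions around seed
hits are aligned.  Thresholds (identity >= 0.8 of aligned columns, query
coverage >= 0.5) are exposed as arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .scoring import binding_affinity
from .seqio import GeneModel, GenomeAssembly, revcomp
from .triplex import DBS

TIE_LABEL = "tie/incomparable"


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -0.5
    return a


def _global_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -0.5
    return a


def _alignment_stats(aln) -> tuple[int, int, int, int, int]:
    """(matches, columns, query_span, target_start, target_end) of a local
    alignment.

    ``columns`` counts aligned (non-gap) columns only, so an alignment that
    bridges an intron-sized gap is judged by the quality of its aligned
    blocks; gaps still cost alignment score, which decides which alignment
    is returned.
    """
    tblocks, qblocks = aln.aligned
    tseq, qseq = aln.sequences
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        columns += te - ts
        for k in range(te - ts):
            if tseq[ts + k] == qseq[qs + k] and tseq[ts + k] != "N":
                matches += 1
    qspan = qblocks[-1][1] - qblocks[0][0] if len(qblocks) else 0
    return matches, columns, qspan, int(tblocks[0][0]), int(tblocks[-1][1])


class KmerIndex:
    """Exact k-mer position index of a target sequence (seeding step)."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append(i)
        self._index = index

    def hits(self, query: str) -> list[tuple[int, int]]:
        """(query_pos, target_pos) exact k-mer matches."""
        out = []
        k = self.k
        for i in range(len(query) - k + 1):
            for j in self._index.get(query[i:i + k], ()):
                out.append((i, j))
        return out


@dataclass
class AlignmentHit:
    identity: float
    coverage: float
    target_start: int
    target_end: int
    strand: str
    score: float


def _seeded_best_hit(query: str, index: KmerIndex,
                     aligner: Align.PairwiseAligner,
                     band: int = 24) -> AlignmentHit | None:
    """Best local alignment of query (either strand) around seed clusters."""
    target = index.seq
    best: AlignmentHit | None = None
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        hits = index.hits(q)
        if not hits:
            continue
        # cluster seeds by diagonal
        hits.sort(key=lambda h: (h[1] - h[0], h[1]))
        clusters: list[list[tuple[int, int]]] = []
        for h in hits:
            d = h[1] - h[0]
            if clusters and d - (clusters[-1][-1][1] - clusters[-1][-1][0]) <= band:
                clusters[-1].append(h)
            else:
                clusters.append([h])
        for cl in clusters:
            lo = max(0, min(t for _, t in cl) - len(q) - band)
            hi = min(len(target), max(t for _, t in cl) + len(q) + index.k + band)
            region = target[lo:hi]
            alns = aligner.align(region, q)
            if not len(alns):
                continue
            aln = alns[0]
            matches, columns, qspan, ts, te = _alignment_stats(aln)
            if columns == 0:
                continue
            hit = AlignmentHit(identity=matches / columns,
                               coverage=qspan / len(q),
                               target_start=lo + ts, target_end=lo + te,
                               strand=strand, score=float(aln.score))
            if best is None or hit.score > best.score:
                best = hit
    return best


@dataclass
class HomologHit:
    contig: str
    start: int
    end: int
    strand: str
    seq: str  # oriented like the query
    identity: float
    coverage: float


def find_lncrna_homolog(query, target: GenomeAssembly,
                        min_identity: float = 0.8, min_coverage: float = 0.5,
                        k: int = 16,
                        indexes: dict[str, KmerIndex] | None = None
                        ) -> HomologHit | None:
    """Best homolog of a lncRNA in another genome, or None.

    A hit requires alignment identity >= ``min_identity`` over the aligned
    columns and query coverage >= ``min_coverage``.  Prebuilt
    :class:`KmerIndex` objects may be passed to amortize indexing across
    queries.
    """
    qseq = query if isinstance(query, str) else query.seq
    if len(qseq) < 50:
        raise ValueError("query must be >= 50 nt")
    aligner = _local_aligner()
    best: tuple[float, HomologHit] | None = None
    for cname, cseq in target.contigs.items():
        idx = (indexes or {}).get(cname) or KmerIndex(cseq, k)
        hit = _seeded_best_hit(qseq, idx, aligner)
        if hit is None:
            continue
        if hit.identity >= min_identity and hit.coverage >= min_coverage:
            seq = cseq[hit.target_start:hit.target_end]
            if hit.strand == "-":
                seq = revcomp(seq)
            hom = HomologHit(contig=cname, start=hit.target_start,
                             end=hit.target_end, strand=hit.strand, seq=seq,
                             identity=hit.identity, coverage=hit.coverage)
            if best is None or hit.score > best[0]:
                best = (hit.score, hom)
    return best[1] if best else None


@dataclass
class OrthologyCall:
    dbs_id: str
    target_species: str
    status: str  # 'hit' | 'no-hit' | 'unmapped'
    identity: float | None = None
    coverage: float | None = None
    target_interval: tuple[int, int] | None = None


def dbs_orthology(dbs_seq: str, dbs_id: str, target_gene: GeneModel | None,
                  target: GenomeAssembly, target_species: str = "",
                  flank: int = 100_000, min_identity: float = 0.8,
                  min_coverage: float = 0.5, k: int = 12,
                  window_index: KmerIndex | None = None) -> OrthologyCall:
    """Search a DBS sequence within +/-``flank`` of the orthologous gene's TSS.

    No detectable counterpart means the DBS is specific to the source
    species.  A gene missing from the target annotation yields status
    ``unmapped`` (distinct from ``no-hit``).
    """
    if target_gene is None:
        return OrthologyCall(dbs_id=dbs_id, target_species=target_species,
                             status="unmapped")
    if window_index is None:
        window_index = orthology_window_index(target_gene, target, flank, k)
    hit = _seeded_best_hit(dbs_seq, window_index, _local_aligner())
    if hit and hit.identity >= min_identity and hit.coverage >= min_coverage:
        return OrthologyCall(dbs_id=dbs_id, target_species=target_species,
                             status="hit", identity=hit.identity,
                             coverage=hit.coverage,
                             target_interval=(hit.target_start, hit.target_end))
    return OrthologyCall(dbs_id=dbs_id, target_species=target_species,
                         status="no-hit")


def orthology_window_index(target_gene: GeneModel, target: GenomeAssembly,
                           flank: int = 100_000, k: int = 12) -> KmerIndex:
    """Index of the +/-flank window around a gene's TSS (clipped at ends)."""
    cseq = target[target_gene.contig]
    lo = max(0, target_gene.tss - flank)
    hi = min(len(cseq), target_gene.tss + flank + 1)
    return KmerIndex(cseq[lo:hi], k)


def orthology_table(calls_by_direction: dict[tuple[str, str],
                                             list[OrthologyCall]]) -> pd.DataFrame:
    """Hit/no-hit counts and percentages per ordered species pair."""
    rows = []
    for (src, tgt), calls in calls_by_direction.items():
        mapped = [c for c in calls if c.status != "unmapped"]
        n = len(mapped)
        hits = sum(c.status == "hit" for c in mapped)
        rows.append({
            "source": src, "target": tgt, "n_dbs": n, "hits": hits,
            "no_hits": n - hits,
            "hit_pct": round(100 * hits / n, 1) if n else 0.0,
            "no_hit_pct": round(100 * (n - hits) / n, 1) if n else 0.0,
            "unmapped": len(calls) - n,
            "empty": n == 0,
        })
    return pd.DataFrame(rows)


@dataclass
class AffinityPattern:
    lncrna_id: str
    means: dict[str, float]
    label: str


def classify_affinity_pattern(means: dict[str, float], tie_tol: float = 0.0,
                              lncrna_id: str = "") -> AffinityPattern:
    """Label the strict descending species ordering of mean affinities.

    Any adjacent pair closer than ``tie_tol`` (or exactly equal at the
    default tie_tol=0) yields the tie label instead of an ordering.
    """
    if len(means) < 2:
        raise ValueError("need mean affinities for >= 2 species")
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    for (_, a), (_, b) in zip(ranked, ranked[1:]):
        if a - b <= tie_tol:
            return AffinityPattern(lncrna_id=lncrna_id, means=dict(means),
                                   label=TIE_LABEL)
    label = ">".join(sp for sp, _ in ranked)
    return AffinityPattern(lncrna_id=lncrna_id, means=dict(means), label=label)


def mean_affinity_by_species(dbs_by_species: dict[str, list[DBS]]
                             ) -> dict[str, dict[str, float]]:
    """Per-lncRNA per-species mean DBS affinity (species absent when the
    lncRNA has no retained DBS there)."""
    out: dict[str, dict[str, float]] = {}
    for sp, dbss in dbs_by_species.items():
        per_lnc: dict[str, list[float]] = {}
        for d in dbss:
            per_lnc.setdefault(d.lncrna_id, []).append(binding_affinity(d))
        for lnc, vals in per_lnc.items():
            out.setdefault(lnc, {})[sp] = sum(vals) / len(vals)
    return out


def classify_patterns(dbs_by_species: dict[str, list[DBS]],
                      tie_tol: float = 0.0
                      ) -> tuple[list[AffinityPattern], dict[str, str]]:
    """Classify every lncRNA with DBSs in all species; report exclusions.

    Returns (patterns, excluded) where ``excluded`` maps lncRNA id to the
    reason it was not classified (inactive in some species).
    """
    species = sorted(dbs_by_species)
    means = mean_affinity_by_species(dbs_by_species)
    patterns: list[AffinityPattern] = []
    excluded: dict[str, str] = {}
    for lnc in sorted(means):
        missing = [sp for sp in species if sp not in means[lnc]]
        if missing:
            excluded[lnc] = "inactive in " + ",".join(missing)
        else:
            patterns.append(classify_affinity_pattern(means[lnc], tie_tol, lnc))
    return patterns, excluded


def pattern_proportions(patterns: list[AffinityPattern]) -> dict[str, float]:
    """Proportion of each ordering label over classified lncRNAs (sums to 1)."""
    if not patterns:
        raise ValueError("no classified lncRNAs")
    counts: dict[str, int] = {}
    for p in patterns:
        counts[p.label] = counts.get(p.label, 0) + 1
    n = len(patterns)
    return {label: c / n for label, c in sorted(counts.items())}


def per_gene_dbs_counts(dbs_by_species: dict[str, list[DBS]],
                        gene_list: list[str],
                        known_genes: set[str] | None = None) -> pd.DataFrame:
    """Per gene, per species: distinct lncRNAs with >=1 retained DBS and
    total DBS count (DBS promoter ids are gene ids)."""
    if not gene_list:
        raise ValueError("gene list is empty")
    if known_genes is not None:
        unknown = [g for g in gene_list if g not in known_genes]
        if unknown:
            raise KeyError(f"unknown gene ids: {unknown}")
    rows = []
    for gene in gene_list:
        for sp, dbss in dbs_by_species.items():
            here = [d for d in dbss if d.promoter_id == gene]
            rows.append({"gene_id": gene, "species": sp,
                         "lncrna_count": len({d.lncrna_id for d in here}),
                         "dbs_count": len(here)})
    return pd.DataFrame(rows)


def pairwise_distance(seq_a: str, seq_b: str) -> float:
    """p-distance over a pairwise global alignment.

    Mismatches divided by aligned non-gap columns, ignoring columns where
    either base is N.  The argument order is canonicalized before aligning
    so the result is exactly symmetric.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if seq_a == seq_b:
        return 0.0
    a, b = sorted((seq_a, seq_b))
    aln = _global_aligner().align(a, b)[0]
    ablocks, bblocks = aln.aligned
    mismatches = 0
    columns = 0
    for (as_, ae), (bs, _) in zip(ablocks, bblocks):
        for kk in range(ae - as_):
            ca, cb = a[as_ + kk], b[bs + kk]
            if ca == "N" or cb == "N":
                continue
            columns += 1
            if ca != cb:
                mismatches += 1
    if columns == 0:
        return 0.0
    return mismatches / columns


def distance_matrix(seqs: dict[str, str]) -> pd.DataFrame:
    """Symmetric zero-diagonal matrix of pairwise p-distances."""
    ids = list(seqs)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, x in enumerate(ids):
        for y in ids[i + 1:]:
            d = pairwise_distance(seqs[x], seqs[y])
            mat.loc[x, y] = d
            mat.loc[y, x] = d
    return mat
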