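"""RNA:DNA triplex prediction between lncRNAs and promoter windows.

A lncRNA segment (triplex-forming oligonucleotide, TFO) can occupy the
major groove of duplex DNA and hydrogen-bond to the purine-rich strand of a
triplex-targeting site (TTS).  Prediction here is ungapped diagonal
matching under the canonical Hoogsteen / reverse-Hoogsteen pairing codes:

* pyrimidine motif (third strand parallel to the purine strand):
  T·A-T and C·G-C, i.e. RNA T pairs with duplex A, RNA C with duplex G;
* purine motif (antiparallel): A·A-T and G·G-C;
* mixed GT motif: G·G-C and T·A-T, scanned in both orientations.

N never pairs, so N-masked (ancient-consensus-style) windows naturally
lose triplexes.

A reported triplex is a maximal qualifying window: among all diagonal
windows with ``identity >= min_identity`` and ``length >= min_length``,
overlapping windows on the same diagonal/motif/strand/orientation are
reduced to the longest one (ties: highest identity, then smallest start).

Overlapping TTSs on a promoter merge into a DNA-binding site (DBS);
overlapping TFOs on the lncRNA merge into a DNA-binding domain (DBD).
When a lncRNA has several DBDs, downstream analyses keep only the best
DBD — the one whose members reach the most distinct DBSs.

The scanning core is exact, not heuristic: a per-diagonal prefix-score
bound first rejects diagonals that cannot contain a qualifying window,
and surviving diagonals are enumerated exhaustively.  Its output is
checked against an independent brute-force oracle (:mod:`lncdbs.oracle`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean

import numpy as np

from .seqio import revcomp

MOTIF_PYRIMIDINE = "pyrimidine"
MOTIF_PURINE = "purine"
MOTIF_GT = "gt"
ALL_MOTIFS = (MOTIF_PYRIMIDINE, MOTIF_PURINE, MOTIF_GT)

# (third-strand base, duplex purine-strand base) pairs that bond, per motif
PAIRING: dict[str, frozenset[tuple[str, str]]] = {
    MOTIF_PYRIMIDINE: frozenset({("T", "A"), ("C", "G")}),
    MOTIF_PURINE: frozenset({("A", "A"), ("G", "G")}),
    MOTIF_GT: frozenset({("G", "G"), ("T", "A")}),
}

# orientation of the third strand relative to the purine strand, per motif
ORIENTATIONS: dict[str, tuple[str, ...]] = {
    MOTIF_PYRIMIDINE: ("parallel",),
    MOTIF_PURINE: ("antiparallel",),
    MOTIF_GT: ("parallel", "antiparallel"),
}

# Letters a TFO may use and still be able to pair under a motif.
MOTIF_ALPHABET = {m: tuple(sorted({t for t, _ in PAIRING[m]})) for m in ALL_MOTIFS}
# Deterministic image of a pairing third-strand letter on the purine strand.
MOTIF_IMAGE = {m: dict(PAIRING[m]) for m in ALL_MOTIFS}

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _codes(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pair_table(motif: str) -> np.ndarray:
    if motif not in PAIRING:
        raise ValueError(f"unknown motif {motif!r}")
    table = np.zeros((5, 5), dtype=bool)
    for rna, dna in PAIRING[motif]:
        table["ACGTN".index(rna), "ACGTN".index(dna)] = True
    return table


def pairing_match(rna_base: str, purine_strand_base: str, motif: str) -> bool:
    """Does an RNA base bond to a duplex purine-strand base under a motif?

    N never matches.
    """
    if motif not in PAIRING:
        raise ValueError(f"unknown motif {motif!r}")
    return (rna_base, purine_strand_base) in PAIRING[motif]


@dataclass(frozen=True)
class TriplexParams:
    min_identity: float = 0.60
    min_length: int = 50
    motifs: tuple[str, ...] = ALL_MOTIFS
    merge_overlap: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        for m in self.motifs:
            if m not in PAIRING:
                raise ValueError(f"unknown motif {m!r}")


@dataclass(frozen=True)
class Triplex:
    """One TFO(RNA)–TTS(DNA) ungapped match.

    Intervals are 0-based half-open: ``tfo`` on the lncRNA sequence,
    ``tts`` on the promoter window (forward window coordinates regardless
    of which duplex strand is the purine strand).
    """

    lncrna_id: str
    promoter_id: str
    tfo_start: int
    tfo_end: int
    tts_start: int
    tts_end: int
    purine_strand: str  # which promoter-window strand is purine: '+' or '-'
    motif: str
    orientation: str
    matches: int

    @property
    def length(self) -> int:
        return self.tts_end - self.tts_start

    @property
    def identity(self) -> float:
        return self.matches / self.length

    def key(self) -> tuple:
        return (self.tts_start, self.tts_end, self.tfo_start, self.tfo_end,
                self.purine_strand, self.motif, self.orientation, self.matches)


def _reduce_windows(wins: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Reduce overlapping qualifying windows on one diagonal to the best one
    per overlap cluster (longest, then highest identity, then smallest start).

    Windows are (start, length, matches) tuples in diagonal coordinates.
    """
    if not wins:
        return []
    wins = sorted(wins, key=lambda w: (w[0], w[1]))
    clusters: list[list[tuple[int, int, int]]] = []
    cur = [wins[0]]
    cur_end = wins[0][0] + wins[0][1]
    for w in wins[1:]:
        if w[0] < cur_end:
            cur.append(w)
            cur_end = max(cur_end, w[0] + w[1])
        else:
            clusters.append(cur)
            cur = [w]
            cur_end = w[0] + w[1]
    clusters.append(cur)
    return [max(c, key=lambda w: (w[1], w[2] / w[1], -w[0])) for c in clusters]


def _enumerate_windows(m: np.ndarray, min_length: int,
                       min_identity: float) -> list[tuple[int, int, int]]:
    """All qualifying (start, length, matches) windows of a 0/1 match array."""
    n = len(m)
    pref = np.concatenate(([0], np.cumsum(m, dtype=np.int64)))
    # crop to positions that can start/end a qualifying window: with
    # Q[i] = matches[0:i] - min_identity*i, window (s, e] qualifies iff
    # Q[e] >= Q[s] and e - s >= min_length
    q = pref - min_identity * np.arange(n + 1)
    prefmin = np.minimum.accumulate(q)
    valid_e = np.nonzero(q[min_length:] >= prefmin[:-min_length] - 1e-9)[0]
    if len(valid_e) == 0:
        return []
    sufmax = np.maximum.accumulate(q[::-1])[::-1]
    valid_s = np.nonzero(sufmax[min_length:] >= q[:-min_length] - 1e-9)[0]
    lo = int(valid_s.min())
    hi = int(valid_e.max()) + min_length
    sub = pref[lo:hi + 1]
    k = len(sub)
    length = np.arange(k)[None, :] - np.arange(k)[:, None]
    matches = sub[None, :] - sub[:, None]
    ok = (length >= min_length) & (matches >= min_identity * length - 1e-9)
    ss, ee = np.nonzero(ok)
    return [(lo + int(s), int(e - s), int(sub[e] - sub[s]))
            for s, e in zip(ss, ee)]


class _ScanWorkspace:
    """Reusable float32 buffers for one (lncRNA length, promoter length)."""

    def __init__(self, a: int, b: int):
        ncols = a + b - 1
        self.D = np.empty((a, ncols), dtype=np.float32)
        self.P = np.empty((a + 1, ncols), dtype=np.float32)
        self.runmin = np.empty_like(self.P)
        itemsize = self.D.itemsize
        # strided view V with V[i, j] = D[i, j - i + a - 1]: writing the
        # score matrix into V shears it so each diagonal becomes a column
        self.V = np.lib.stride_tricks.as_strided(
            self.D.reshape(-1)[a - 1:], shape=(a, b),
            strides=((ncols - 1) * itemsize, itemsize))


# quick-reject slack: float32 prefix sums carry rounding error well below
# this; diagonals flagged spuriously are re-checked exactly and discarded
_REJECT_SLACK = 0.05


def _scan_oriented(rcodes: np.ndarray, dcodes: np.ndarray, table: np.ndarray,
                   min_length: int, min_identity: float,
                   ws: "_ScanWorkspace | None" = None
                   ) -> list[tuple[int, int, int, int]]:
    """Maximal qualifying windows of one oriented scan.

    Returns (rna_start, dna_start, length, matches) in the oriented
    coordinate frames.  Exact: a prefix-score bound (match scores
    ``1 - min_identity``, mismatch ``-min_identity``; a window qualifies
    iff its score sum is >= 0 and its length >= min_length) rejects
    diagonals that cannot contain a qualifying window, and the survivors
    are enumerated exhaustively with integer match counts.
    """
    a, b = len(rcodes), len(dcodes)
    if a < min_length or b < min_length:
        return []
    if ws is None:
        ws = _ScanWorkspace(a, b)
    score_table = np.where(table, 1.0 - min_identity, -min_identity
                           ).astype(np.float32)
    ws.D.fill(np.float32(-min_identity))
    np.copyto(ws.V, score_table[rcodes[:, None], dcodes[None, :]])
    P = ws.P
    P[0] = 0.0
    np.cumsum(ws.D, axis=0, out=P[1:])
    nmin = a + 1 - min_length
    runmin = ws.runmin[:nmin]
    np.minimum.accumulate(P[:nmin], axis=0, out=runmin)
    best = np.max(P[min_length:] - runmin, axis=0)
    out: list[tuple[int, int, int, int]] = []
    for col in np.nonzero(best >= -_REJECT_SLACK)[0]:
        d = int(col) - (a - 1)  # diagonal offset j - i
        i0 = max(0, -d)
        j0 = i0 + d
        n = min(a - i0, b - j0)
        if n < min_length:
            continue
        idx = np.arange(n)
        m = table[rcodes[i0 + idx], dcodes[j0 + idx]].astype(np.int8)
        for s, length, matches in _reduce_windows(
                _enumerate_windows(m, min_length, min_identity)):
            out.append((i0 + s, j0 + s, length, matches))
    return out


def _seq_of(obj) -> str:
    return obj if isinstance(obj, str) else obj.seq


def _id_of(obj, fallback: str) -> str:
    for attr in ("lncrna_id", "promoter_id", "gene_id"):
        if hasattr(obj, attr):
            return getattr(obj, attr)
    return fallback


def find_triplexes(lncrna, promoter, params: TriplexParams = TriplexParams(),
                   lncrna_id: str | None = None,
                   promoter_id: str | None = None) -> list[Triplex]:
    """Predict all maximal TFO–TTS matches between a lncRNA and a promoter.

    Both promoter-window strands are considered as purine-strand
    candidates; each enabled motif is scanned in its orientation sense
    (pyrimidine parallel, purine antiparallel, GT both).  Coordinates in
    the output are always on the forward frames of the input sequences.
    """
    rna_seq = _seq_of(lncrna)
    dna_seq = _seq_of(promoter)
    rid = lncrna_id or _id_of(lncrna, "lncrna")
    pid = promoter_id or _id_of(promoter, "promoter")
    if not rna_seq or not dna_seq:
        raise ValueError("empty sequence")
    a, b = len(rna_seq), len(dna_seq)
    rcodes_f = _codes(rna_seq)
    ws = (_ScanWorkspace(a, b)
          if a >= params.min_length and b >= params.min_length else None)
    results: list[Triplex] = []
    for strand in "+-":
        dcodes = _codes(dna_seq) if strand == "+" else _codes(revcomp(dna_seq))
        for motif in params.motifs:
            table = _pair_table(motif)
            for orientation in ORIENTATIONS[motif]:
                rcodes = rcodes_f if orientation == "parallel" else (
                    np.ascontiguousarray(rcodes_f[::-1]))
                for i, j, L, mt in _scan_oriented(
                        rcodes, dcodes, table, params.min_length,
                        params.min_identity, ws):
                    if orientation == "parallel":
                        tfo = (i, i + L)
                    else:
                        tfo = (a - i - L, a - i)
                    if strand == "+":
                        tts = (j, j + L)
                    else:
                        tts = (b - j - L, b - j)
                    results.append(Triplex(
                        lncrna_id=rid, promoter_id=pid,
                        tfo_start=tfo[0], tfo_end=tfo[1],
                        tts_start=tts[0], tts_end=tts[1],
                        purine_strand=strand, motif=motif,
                        orientation=orientation, matches=mt))
    results.sort(key=Triplex.key)
    return results


@dataclass
class DBS:
    """A DNA-binding site: single-linkage union of overlapping TTSs."""

    promoter_id: str
    lncrna_id: str
    start: int
    end: int
    members: list[Triplex] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mean_identity(self) -> float:
        return mean(t.identity for t in self.members)


@dataclass
class DBD:
    """A DNA-binding domain: single-linkage union of overlapping TFOs."""

    lncrna_id: str
    start: int
    end: int
    members: list[Triplex] = field(default_factory=list)
    dbs_count: int = 0


def merge_tts_to_dbs(triplexes: list[Triplex], merge_overlap: int = 1) -> list[DBS]:
    """Merge overlapping TTSs of one lncRNA–promoter pair into DBSs.

    Single-linkage on TTS intervals with overlap >= ``merge_overlap``
    bases (across motifs and strands); every triplex belongs to exactly
    one DBS and the resulting DBS intervals are pairwise disjoint.
    """
    if not triplexes:
        return []
    rids = {t.lncrna_id for t in triplexes}
    pids = {t.promoter_id for t in triplexes}
    if len(rids) != 1 or len(pids) != 1:
        raise ValueError("merge_tts_to_dbs expects one lncRNA-promoter pair")
    ts = sorted(triplexes, key=lambda t: (t.tts_start, t.tts_end))
    out: list[DBS] = []
    cur = DBS(promoter_id=ts[0].promoter_id, lncrna_id=ts[0].lncrna_id,
              start=ts[0].tts_start, end=ts[0].tts_end, members=[ts[0]])
    for t in ts[1:]:
        if cur.end - t.tts_start >= merge_overlap:
            cur.members.append(t)
            cur.end = max(cur.end, t.tts_end)
        else:
            out.append(cur)
            cur = DBS(promoter_id=t.promoter_id, lncrna_id=t.lncrna_id,
                      start=t.tts_start, end=t.tts_end, members=[t])
    out.append(cur)
    return out


def dbs_for_lncrna(triplexes: list[Triplex], merge_overlap: int = 1
                   ) -> dict[str, list[DBS]]:
    """Per-promoter DBS lists for all triplexes of one lncRNA."""
    by_prom: dict[str, list[Triplex]] = {}
    for t in triplexes:
        by_prom.setdefault(t.promoter_id, []).append(t)
    return {pid: merge_tts_to_dbs(ts, merge_overlap)
            for pid, ts in sorted(by_prom.items())}


def merge_tfo_to_dbd(triplexes: list[Triplex], merge_overlap: int = 1) -> list[DBD]:
    """Merge overlapping TFOs of one lncRNA (across promoters) into DBDs.

    ``dbs_count`` of each DBD is the number of distinct DBSs reached by
    its member triplexes, where DBSs are the per-promoter merges of *all*
    the lncRNA's triplexes.
    """
    if not triplexes:
        return []
    if len({t.lncrna_id for t in triplexes}) != 1:
        raise ValueError("merge_tfo_to_dbd expects triplexes of one lncRNA")
    dbs_map = dbs_for_lncrna(triplexes, merge_overlap)
    dbs_of: dict[tuple, tuple[str, int]] = {}
    for pid, dbss in dbs_map.items():
        for i, dbs in enumerate(dbss):
            for t in dbs.members:
                dbs_of[(t.promoter_id,) + t.key()] = (pid, i)
    ts = sorted(triplexes, key=lambda t: (t.tfo_start, t.tfo_end))
    out: list[DBD] = []
    cur = DBD(lncrna_id=ts[0].lncrna_id, start=ts[0].tfo_start,
              end=ts[0].tfo_end, members=[ts[0]])
    for t in ts[1:]:
        if cur.end - t.tfo_start >= merge_overlap:
            cur.members.append(t)
            cur.end = max(cur.end, t.tfo_end)
        else:
            out.append(cur)
            cur = DBD(lncrna_id=t.lncrna_id, start=t.tfo_start,
                      end=t.tfo_end, members=[t])
    out.append(cur)
    for dbd in out:
        dbd.dbs_count = len({dbs_of[(t.promoter_id,) + t.key()]
                             for t in dbd.members})
    return out


def select_best_dbd(dbds: list[DBD]) -> DBD | None:
    """The DBD with the most DBSs (ties: smallest RNA start coordinate)."""
    if not dbds:
        return None
    return max(dbds, key=lambda d: (d.dbs_count, -d.start))


def best_dbd_dbs(triplexes: list[Triplex], merge_overlap: int = 1
                 ) -> tuple[DBD | None, list[DBS]]:
    """Apply the best-DBD rule to one lncRNA's triplexes.

    Returns the best DBD and the DBSs reached by its member triplexes —
    the only DBSs carried into downstream analyses.
    """
    dbds = merge_tfo_to_dbd(triplexes, merge_overlap)
    best = select_best_dbd(dbds)
    if best is None:
        return None, []
    member_keys = {(t.promoter_id,) + t.key() for t in best.members}
    kept: list[DBS] = []
    for pid, dbss in dbs_for_lncrna(triplexes, merge_overlap).items():
        for dbs in dbss:
            if any((t.promoter_id,) + t.key() in member_keys for t in dbs.members):
                kept.append(dbs)
    return best, kept
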