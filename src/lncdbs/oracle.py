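"""Brute-force reference implementation of the triplex scan.

Enumerates every diagonal window of every length >= ``min_length`` on
every strand/motif/orientation combination, in plain Python, and applies
the same maximality reduction as the engine (longest window per overlap
cluster on a diagonal; ties broken by identity, then smallest start).

This is deliberately naive and shares no scanning code with
:func:`lncdbs.triplex.find_triplexes`; equivalence of the two on random
and planted instances is a core correctness check.  A size guard keeps
accidental use on large sequences from running forever.
"""

from __future__ import annotations

from .seqio import revcomp
from .triplex import ORIENTATIONS, PAIRING, Triplex, TriplexParams

MAX_ORACLE_LEN = 2000


def oracle_find_triplexes(lncrna, promoter,
                          params: TriplexParams = TriplexParams(),
                          lncrna_id: str | None = None,
                          promoter_id: str | None = None) -> list[Triplex]:
    rna_seq = lncrna if isinstance(lncrna, str) else lncrna.seq
    dna_seq = promoter if isinstance(promoter, str) else promoter.seq
    rid = lncrna_id or getattr(lncrna, "lncrna_id", "lncrna")
    pid = promoter_id or getattr(promoter, "promoter_id", "promoter")
    if len(rna_seq) > MAX_ORACLE_LEN or len(dna_seq) > MAX_ORACLE_LEN:
        raise ValueError(f"oracle guard: sequences must be <= {MAX_ORACLE_LEN} nt")
    a, b = len(rna_seq), len(dna_seq)
    min_len, min_id = params.min_length, params.min_identity
    results: list[Triplex] = []
    for strand in "+-":
        dna = dna_seq if strand == "+" else revcomp(dna_seq)
        for motif in params.motifs:
            pairs = PAIRING[motif]
            for orientation in ORIENTATIONS[motif]:
                rna = rna_seq if orientation == "parallel" else rna_seq[::-1]
                for d in range(-(a - 1), b):
                    i0 = max(0, -d)
                    j0 = i0 + d
                    n = min(a - i0, b - j0)
                    if n < min_len:
                        continue
                    match = [1 if (rna[i0 + t], dna[j0 + t]) in pairs else 0
                             for t in range(n)]
                    pref = [0]
                    acc = 0
                    for x in match:
                        acc += x
                        pref.append(acc)
                    wins = []
                    for length in range(min_len, n + 1):
                        need = min_id * length - 1e-9
                        for s in range(n - length + 1):
                            mt = pref[s + length] - pref[s]
                            if mt >= need:
                                wins.append((s, length, mt))
                    for s, length, mt in _pick_maximal(wins):
                        i, j = i0 + s, j0 + s
                        if orientation == "parallel":
                            tfo = (i, i + length)
                        else:
                            tfo = (a - i - length, a - i)
                        if strand == "+":
                            tts = (j, j + length)
                        else:
                            tts = (b - j - length, b - j)
                        results.append(Triplex(
                            lncrna_id=rid, promoter_id=pid,
                            tfo_start=tfo[0], tfo_end=tfo[1],
                            tts_start=tts[0], tts_end=tts[1],
                            purine_strand=strand, motif=motif,
                            orientation=orientation, matches=mt))
    results.sort(key=Triplex.key)
    return results


def _pick_maximal(wins):
    """Reduce qualifying windows on one diagonal: per overlap-connected
    group keep the longest (ties: highest identity, then smallest start).

    Written independently of the engine's reduction: groups are built by
    repeated expansion instead of a sorted sweep.
    """
    chosen = []
    remaining = list(wins)
    while remaining:
        seed = remaining.pop()
        group = [seed]
        lo, hi = seed[0], seed[0] + seed[1]
        changed = True
        while changed:
            changed = False
            still = []
            for w in remaining:
                if w[0] < hi and w[0] + w[1] > lo:
                    group.append(w)
                    lo = min(lo, w[0])
                    hi = max(hi, w[0] + w[1])
                    changed = True
                else:
                    still.append(w)
            remaining = still
        best = group[0]
        for w in group[1:]:
            if (w[1], w[2] / w[1], -w[0]) > (best[1], best[2] / best[1], -best[0]):
                best = w
        chosen.append(best)
    chosen.sort()
    return chosen
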