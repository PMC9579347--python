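"""Triplex engine: pairing codes, scanning, merging, best-DBD rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncdbs.cohort import design_tts, plant_triplex_site
from lncdbs.seqio import revcomp
from lncdbs.triplex import (ALL_MOTIFS, MOTIF_ALPHABET, ORIENTATIONS, DBS,
                            Triplex, TriplexParams, best_dbd_dbs,
                            find_triplexes, merge_tfo_to_dbd,
                            merge_tts_to_dbs, pairing_match, select_best_dbd)

from conftest import random_seq


class TestPairing:
    @pytest.mark.parametrize("rna,dna,motif,expected", [
        ("T", "A", "pyrimidine", True), ("C", "G", "pyrimidine", True),
        ("A", "A", "pyrimidine", False), ("G", "A", "purine", False),
        ("A", "A", "purine", True), ("G", "G", "purine", True),
        ("G", "G", "gt", True), ("T", "A", "gt", True),
        ("C", "G", "gt", False),
    ])
    def test_code_table(self, rna, dna, motif, expected):
        assert pairing_match(rna, dna, motif) is expected

    @pytest.mark.parametrize("motif", ALL_MOTIFS)
    def test_n_never_matches(self, motif):
        for b in "ACGTN":
            assert not pairing_match(b, "N", motif)
            assert not pairing_match("N", b, motif)

    def test_unknown_motif_rejected(self):
        with pytest.raises(ValueError):
            pairing_match("T", "A", "hoogsteen-zeta")


def _planted_pair(rng, motif, site_len, identity, strand="+",
                  orientation=None):
    """A lncRNA carrying a TFO and a random-background promoter carrying
    the matching planted TTS."""
    orientation = orientation or ORIENTATIONS[motif][0]
    tfo = "".join(np.array(MOTIF_ALPHABET[motif])[
        rng.integers(0, len(MOTIF_ALPHABET[motif]), site_len)])
    lnc = random_seq(rng, 40) + tfo + random_seq(rng, 40)
    prom = plant_triplex_site(random_seq(rng, 600), tfo, motif, identity,
                              250, purine_strand=strand,
                              orientation=orientation)
    return lnc, prom, (40, 40 + site_len), (250, 250 + site_len)


class TestFindTriplexes:
    @pytest.mark.parametrize("motif", ALL_MOTIFS)
    def test_perfect_site_reported_at_full_identity(self, rng, motif):
        """A perfect TFO-TTS pair with no flanking sequence is reported as
        one full-length window at identity 1.0 (flanked sites are instead
        absorbed into longer maximal windows whose identity sits at the
        floor, which the recovery tests cover)."""
        alphabet = MOTIF_ALPHABET[motif]
        tfo = "".join(np.array(alphabet)[
            rng.integers(0, len(alphabet), 60)])
        site = design_tts(tfo, motif, 1.0, ORIENTATIONS[motif][0])
        found = find_triplexes(tfo, site, TriplexParams(motifs=(motif,)))
        full = [t for t in found
                if (t.tts_start, t.tts_end) == (0, 60) and t.identity == 1.0]
        assert len(full) >= 1
        assert full[0].length == 60

    def test_planted_site_overlapped_by_a_maximal_window(self, rng):
        lnc, prom, _, tts_iv = _planted_pair(rng, "pyrimidine", 60, 1.0)
        found = find_triplexes(lnc, prom,
                               TriplexParams(motifs=("pyrimidine",)))
        assert any(min(t.tts_end, tts_iv[1]) - max(t.tts_start, tts_iv[0])
                   >= 30 for t in found)

    def test_below_min_length_site_not_reported(self, rng):
        """A 49-bp perfect pair cannot satisfy the 50-bp floor; the same
        pair at 50 bp is reported."""
        params = TriplexParams(motifs=("pyrimidine",))
        tfo49 = "".join(np.array(list("TC"))[rng.integers(0, 2, 49)])
        assert find_triplexes(tfo49, design_tts(tfo49, "pyrimidine", 1.0),
                              params) == []
        tfo50 = tfo49 + "T"
        assert find_triplexes(tfo50, design_tts(tfo50, "pyrimidine", 1.0),
                              params) != []

    def test_all_outputs_respect_thresholds(self, rng):
        params = TriplexParams()
        for _ in range(5):
            motif = str(rng.choice(list(ALL_MOTIFS)))
            lnc, prom, _, _ = _planted_pair(
                rng, motif, 70, float(rng.uniform(0.6, 1.0)))
            for t in find_triplexes(lnc, prom, params):
                assert t.identity >= params.min_identity
                assert t.length >= params.min_length
                assert t.length == t.tfo_end - t.tfo_start

    def test_strand_symmetry(self, rng):
        """Reverse-complementing the promoter flips strand labels but yields
        an isomorphic triplex set."""
        lnc, prom, _, _ = _planted_pair(rng, "purine", 80, 0.9)
        fwd = find_triplexes(lnc, prom)
        rev = find_triplexes(lnc, revcomp(prom))
        b = len(prom)
        mapped = {(b - t.tts_end, b - t.tts_start, t.tfo_start, t.tfo_end,
                   "-" if t.purine_strand == "+" else "+", t.motif,
                   t.orientation, t.matches) for t in rev}
        original = {(t.tts_start, t.tts_end, t.tfo_start, t.tfo_end,
                     t.purine_strand, t.motif, t.orientation, t.matches)
                    for t in fwd}
        assert mapped == original

    def test_monotone_in_thresholds(self, rng):
        lnc, prom, _, _ = _planted_pair(rng, "gt", 70, 0.8)
        base = len(find_triplexes(lnc, prom, TriplexParams()))
        for min_id, min_len in [(0.65, 50), (0.60, 60), (0.70, 70)]:
            stricter = len(find_triplexes(
                lnc, prom, TriplexParams(min_identity=min_id,
                                         min_length=min_len)))
            assert stricter <= base


def _mk(tts, tfo=(0, 60), matches=None, lnc="l1", prom="p1"):
    length = tts[1] - tts[0]
    return Triplex(lncrna_id=lnc, promoter_id=prom, tfo_start=tfo[0],
                   tfo_end=tfo[1], tts_start=tts[0], tts_end=tts[1],
                   purine_strand="+", motif="pyrimidine",
                   orientation="parallel",
                   matches=matches if matches is not None else length)


class TestMergeDbs:
    def test_overlapping_tts_union(self):
        dbss = merge_tts_to_dbs([_mk((100, 160)), _mk((150, 210))])
        assert len(dbss) == 1
        assert (dbss[0].start, dbss[0].end, dbss[0].length) == (100, 210, 110)

    def test_disjoint_tts_stay_separate(self):
        dbss = merge_tts_to_dbs([_mk((100, 160)), _mk((300, 360))])
        assert len(dbss) == 2
        assert sum(len(d.members) for d in dbss) == 2

    def test_mean_identity_is_arithmetic_mean(self):
        a = _mk((100, 200), matches=60)   # identity 0.6
        b = _mk((150, 250), matches=70)   # identity 0.7
        dbss = merge_tts_to_dbs([a, b])
        assert dbss[0].mean_identity == pytest.approx(0.65)

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            merge_tts_to_dbs([_mk((0, 60)), _mk((0, 60), prom="p2")])

    @given(st.permutations(range(5)))
    @settings(max_examples=20, deadline=None)
    def test_merge_order_independent(self, order):
        ts = [_mk((100, 160)), _mk((150, 210)), _mk((400, 470)),
              _mk((460, 520)), _mk((900, 960))]
        base = [(d.start, d.end, len(d.members)) for d in merge_tts_to_dbs(ts)]
        permuted = [(d.start, d.end, len(d.members))
                    for d in merge_tts_to_dbs([ts[i] for i in order])]
        assert base == permuted

    def test_merge_idempotent_intervals_disjoint(self, rng):
        ts = [_mk((int(s), int(s) + int(l)))
              for s, l in zip(rng.integers(0, 2000, 30),
                              rng.integers(50, 200, 30))]
        dbss = merge_tts_to_dbs(ts)
        spans = sorted((d.start, d.end) for d in dbss)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # pairwise disjoint
        assert sum(len(d.members) for d in dbss) == len(ts)


class TestDbdAndBestRule:
    def test_single_triplex_single_dbd(self):
        dbds = merge_tfo_to_dbd([_mk((100, 160))])
        assert len(dbds) == 1 and dbds[0].dbs_count == 1

    def test_overlapping_tfos_two_promoters(self):
        ts = [_mk((100, 160), tfo=(0, 60), prom="p1"),
              _mk((500, 560), tfo=(30, 90), prom="p2")]
        dbds = merge_tfo_to_dbd(ts)
        assert len(dbds) == 1 and dbds[0].dbs_count == 2

    def test_disjoint_tfo_clusters(self):
        ts = [_mk((100, 160), tfo=(0, 60)), _mk((300, 360), tfo=(200, 260))]
        assert len(merge_tfo_to_dbd(ts)) == 2

    def test_best_dbd_has_most_dbs(self):
        # three TFO clusters reaching 3, 7 and 2 distinct DBSs
        ts = []
        mkseg = {0: (0, 60), 1: (200, 260), 2: (400, 460)}
        for cluster, n in [(0, 3), (1, 7), (2, 2)]:
            for k in range(n):
                ts.append(_mk((1000 * cluster + 300 * k,
                               1000 * cluster + 300 * k + 60),
                              tfo=mkseg[cluster], prom=f"p{cluster}_{k}"))
        dbds = merge_tfo_to_dbd(ts)
        best = select_best_dbd(dbds)
        assert best.dbs_count == 7 and best.start == 200

    def test_single_dbd_selected(self):
        dbds = merge_tfo_to_dbd([_mk((0, 60))])
        assert select_best_dbd(dbds) is dbds[0]

    def test_tie_broken_by_smaller_rna_start(self):
        ts = [_mk((0, 60), tfo=(200, 260), prom="pA"),
              _mk((0, 60), tfo=(0, 60), prom="pB")]
        best = select_best_dbd(merge_tfo_to_dbd(ts))
        assert best.start == 0

    def test_empty_input(self):
        assert select_best_dbd([]) is None
        assert best_dbd_dbs([]) == (None, [])

    def test_best_dbd_dbs_returns_only_member_dbs(self):
        ts = [_mk((100, 160), tfo=(0, 60), prom="p1"),
              _mk((100, 160), tfo=(0, 60), prom="p2"),
              _mk((500, 560), tfo=(200, 260), prom="p1")]
        best, dbss = best_dbd_dbs(ts)
        assert best.dbs_count == 2
        assert {(d.promoter_id, d.start) for d in dbss} == {
            ("p1", 100), ("p2", 100)}
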