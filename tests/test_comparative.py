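"""Cross-genome comparisons: homologs, orthology, patterns, distances."""

import numpy as np
import pytest

from lncdbs.comparative import (TIE_LABEL, classify_affinity_pattern,
                                dbs_orthology, distance_matrix,
                                find_lncrna_homolog, orthology_table,
                                OrthologyCall, pairwise_distance,
                                pattern_proportions, per_gene_dbs_counts)
from lncdbs.cohort import ablate_site
from lncdbs.seqio import GeneModel, GenomeAssembly, revcomp
from lncdbs.triplex import DBS, Triplex

from conftest import random_seq


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = "ACGT"[(("ACGT".index(out[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


class TestHomologSearch:
    def test_verbatim_copy_found_perfectly(self, rng):
        query = random_seq(rng, 400)
        target = GenomeAssembly(
            {"c": random_seq(rng, 8000) + query + random_seq(rng, 8000)})
        hit = find_lncrna_homolog(query, target)
        assert hit is not None
        assert hit.identity == pytest.approx(1.0)
        assert hit.coverage == pytest.approx(1.0)
        assert hit.seq == query

    def test_random_target_yields_none(self, rng):
        query = random_seq(rng, 500)
        target = GenomeAssembly({"c": random_seq(rng, 20000)})
        assert find_lncrna_homolog(query, target) is None

    def test_ten_percent_substitutions_still_found(self, rng):
        query = random_seq(rng, 400)
        mutated = _mutate(rng, query, 0.10)
        target = GenomeAssembly(
            {"c": random_seq(rng, 5000) + mutated + random_seq(rng, 5000)})
        hit = find_lncrna_homolog(query, target)
        assert hit is not None and hit.identity >= 0.8

    def test_reverse_strand_copy_found(self, rng):
        query = random_seq(rng, 300)
        target = GenomeAssembly(
            {"c": random_seq(rng, 4000) + revcomp(query)
             + random_seq(rng, 4000)})
        hit = find_lncrna_homolog(query, target)
        assert hit is not None and hit.strand == "-"
        assert hit.seq == query

    def test_short_query_rejected(self, rng):
        with pytest.raises(ValueError):
            find_lncrna_homolog("ACGT", GenomeAssembly({"c": "ACGT" * 100}))


class TestDbsOrthology:
    @pytest.fixture()
    def planted_target(self, rng):
        dbs_seq = random_seq(rng, 120)
        flanks = random_seq(rng, 30000), random_seq(rng, 30000)
        contig = flanks[0] + dbs_seq + flanks[1]
        gene = GeneModel("g1", "c", "+", tss=30060)
        return dbs_seq, gene, GenomeAssembly({"c": contig})

    def test_unchanged_site_is_hit(self, planted_target):
        dbs_seq, gene, asm = planted_target
        call = dbs_orthology(dbs_seq, "d1", gene, asm, flank=31000)
        assert call.status == "hit" and call.identity == pytest.approx(1.0)

    def test_shuffled_site_is_no_hit(self, planted_target, rng):
        dbs_seq, gene, asm = planted_target
        contig = asm["c"]
        shuffled = ablate_site(contig, (30000, 30120), "shuffle", 9)
        call = dbs_orthology(dbs_seq, "d1", gene,
                             GenomeAssembly({"c": shuffled}), flank=31000)
        assert call.status == "no-hit"

    def test_missing_gene_is_unmapped(self, planted_target):
        dbs_seq, _, asm = planted_target
        call = dbs_orthology(dbs_seq, "d1", None, asm)
        assert call.status == "unmapped"

    def test_every_call_gets_exactly_one_status(self, planted_target, rng):
        dbs_seq, gene, asm = planted_target
        calls = [dbs_orthology(dbs_seq, "d1", gene, asm, flank=31000),
                 dbs_orthology(random_seq(rng, 120), "d2", gene, asm,
                               flank=31000),
                 dbs_orthology(dbs_seq, "d3", None, asm)]
        statuses = [c.status for c in calls]
        assert all(s in ("hit", "no-hit", "unmapped") for s in statuses)
        assert len(calls) == 3


class TestOrthologyTable:
    def test_counts_and_percentages(self):
        calls = [OrthologyCall("d", "t", "hit")] * 7 + \
                [OrthologyCall("d", "t", "no-hit")] * 3
        df = orthology_table({("a", "b"): calls})
        row = df.iloc[0]
        assert (row["hits"], row["no_hits"]) == (7, 3)
        assert row["hit_pct"] == 70.0 and row["no_hit_pct"] == 30.0
        assert row["hit_pct"] + row["no_hit_pct"] == pytest.approx(100.0)

    def test_empty_direction_flagged(self):
        df = orthology_table({("a", "b"): []})
        assert bool(df.iloc[0]["empty"]) is True


class TestAffinityPatterns:
    def test_strict_descending_label(self):
        p = classify_affinity_pattern({"H": 101.0, "D": 100.0, "P": 87.0})
        assert p.label == "H>D>P"

    def test_tie_within_tolerance(self):
        p = classify_affinity_pattern({"H": 90.0, "D": 90.0, "P": 80.0},
                                      tie_tol=0.5)
        assert p.label == TIE_LABEL

    def test_exact_tie_at_zero_tolerance(self):
        p = classify_affinity_pattern({"H": 90.0, "D": 90.0, "P": 80.0})
        assert p.label == TIE_LABEL

    def test_fewer_than_two_species_rejected(self):
        with pytest.raises(ValueError):
            classify_affinity_pattern({"H": 90.0})

    def test_proportions_sum_to_one(self):
        patterns = [classify_affinity_pattern(m) for m in (
            {"H": 3.0, "D": 2.0, "P": 1.0},
            {"H": 3.0, "D": 2.0, "P": 1.0},
            {"D": 3.0, "H": 2.0, "P": 1.0})]
        props = pattern_proportions(patterns)
        assert sum(props.values()) == pytest.approx(1.0)
        assert props["H>D>P"] == pytest.approx(2 / 3)

    def test_single_lncrna_is_hundred_percent(self):
        props = pattern_proportions(
            [classify_affinity_pattern({"H": 2.0, "D": 1.0})])
        assert props == {"H>D": 1.0}


def _dbs(lnc, prom, start=0, length=100, ident=0.8):
    t = Triplex(lncrna_id=lnc, promoter_id=prom, tfo_start=0, tfo_end=length,
                tts_start=start, tts_end=start + length, purine_strand="+",
                motif="pyrimidine", orientation="parallel",
                matches=round(ident * length))
    return DBS(promoter_id=prom, lncrna_id=lnc, start=start,
               end=start + length, members=[t])


class TestPerGeneCounts:
    def test_single_gene_counts(self):
        dbss = {"H": [_dbs("l1", "g1"), _dbs("l1", "g1", start=300),
                      _dbs("l1", "g1", start=600)]}
        df = per_gene_dbs_counts(dbss, ["g1"])
        row = df.iloc[0]
        assert (row["lncrna_count"], row["dbs_count"]) == (1, 3)

    def test_zero_dbs_gene_row_present(self):
        df = per_gene_dbs_counts({"H": [_dbs("l1", "g1")]}, ["g1", "g2"])
        g2 = df[df["gene_id"] == "g2"].iloc[0]
        assert (g2["lncrna_count"], g2["dbs_count"]) == (0, 0)

    def test_totals_conserved(self):
        dbss = {"H": [_dbs("l1", "g1"), _dbs("l2", "g2"),
                      _dbs("l2", "g2", start=300)]}
        df = per_gene_dbs_counts(dbss, ["g1", "g2"])
        assert df["dbs_count"].sum() == 3

    def test_unknown_gene_id_listed_in_error(self):
        with pytest.raises(KeyError, match="gX"):
            per_gene_dbs_counts({"H": []}, ["gX"], known_genes={"g1"})


class TestPairwiseDistance:
    def test_identical_sequences_distance_zero(self, rng):
        seq = random_seq(rng, 800)
        assert pairwise_distance(seq, seq) == 0.0

    def test_single_substitution_in_thousand(self, rng):
        a = random_seq(rng, 1000)
        b = a[:500] + ("A" if a[500] != "A" else "C") + a[501:]
        assert pairwise_distance(a, b) == pytest.approx(0.001)

    def test_symmetry_and_range(self, rng):
        for _ in range(5):
            a = random_seq(rng, 300)
            b = _mutate(rng, a, float(rng.uniform(0, 0.2)))
            dab, dba = pairwise_distance(a, b), pairwise_distance(b, a)
            assert dab == dba
            assert 0.0 <= dab <= 1.0

    def test_n_columns_excluded(self):
        a = "ACGT" * 100
        b = "N" * 4 + a[4:]
        assert pairwise_distance(a, b) == 0.0

    def test_matrix_symmetric_zero_diagonal(self, rng):
        seqs = {f"s{i}": random_seq(rng, 200) for i in range(4)}
        mat = distance_matrix(seqs)
        assert (mat.values.diagonal() == 0).all()
        assert np.allclose(mat.values, mat.values.T)
        assert ((mat.values >= 0) & (mat.values <= 1)).all()
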