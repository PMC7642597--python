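"""Hit-table dialect, ranking, the voting rule, locus calling, translated search."""

import itertools

import numpy as np
import pytest

from chuvee.screen import (HomologyHit, ProductClass, Strategy, SubjectRecord,
                           call_eves, naive_translated_search, parse_hit_table,
                           rank_hits, vote_eve, write_hit_table)
from chuvee.seqio import Contig
from conftest import random_dna
from oracles import oracle_rank, oracle_vote


def _hit(subject="s1", query="q1", evalue=1e-10, bitscore=100.0,
         s_start=1, s_end=300, strategy=Strategy.VIRUS_GENOME_TBLASTX):
    return HomologyHit(query, subject, 35.0, 100, 60, 0, 1, 100,
                       s_start, s_end, evalue, bitscore, strategy)


def _subjects(flags):
    return {f"s{i}": SubjectRecord(f"s{i}", viral,
                                   ProductClass.GLY if viral else ProductClass.OTHER)
            for i, viral in enumerate(flags)}


class TestParse:
    def test_minus_strand_encoded_by_coordinate_order(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q\ts\t40.0\t100\t60\t0\t1\t100\t900\t601\t1e-20\t120\n")
        (hit,) = parse_hit_table(p, Strategy.KNOWN_EVE_BLASTN)
        assert hit.subject_interval == (600, 900, "-")

    def test_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("# header\nq\ts\t40.0\t100\t60\t0\t1\t100\t1\t300\t1e-20\t120\n")
        assert len(parse_hit_table(p, Strategy.KNOWN_EVE_BLASTN)) == 1

    def test_wrong_column_count_reports_line_number(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q\ts\t40.0\n")
        with pytest.raises(ValueError, match=":1"):
            parse_hit_table(p, Strategy.KNOWN_EVE_BLASTN)

    def test_round_trip(self, tmp_path):
        hits = [_hit(evalue=1e-8), _hit(subject="s2", s_start=500, s_end=201)]
        p = tmp_path / "h.tsv"
        write_hit_table(hits, p)
        back = parse_hit_table(p, Strategy.VIRUS_GENOME_TBLASTX)
        assert [(h.subject_id, h.s_start, h.s_end) for h in back] == \
            [(h.subject_id, h.s_start, h.s_end) for h in hits]


class TestRank:
    def test_evalue_then_bitscore(self):
        hits = [_hit(subject="a", evalue=1e-5), _hit(subject="b", evalue=1e-50)]
        assert [h.subject_id for h in rank_hits(hits)] == ["b", "a"]
        hits = [_hit(subject="a", evalue=1e-9, bitscore=100),
                _hit(subject="b", evalue=1e-9, bitscore=200)]
        assert [h.subject_id for h in rank_hits(hits)] == ["b", "a"]

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            rank_hits([_hit(query="q1"), _hit(query="q2")])

    def test_matches_sort_oracle_on_random_sets(self, rng):
        for _ in range(200):
            rows = [(10.0 ** -rng.integers(0, 30), float(rng.integers(40, 400)),
                     f"s{rng.integers(0, 8)}") for _ in range(int(rng.integers(1, 12)))]
            hits = [_hit(subject=s, evalue=e, bitscore=b) for e, b, s in rows]
            got = [(h.evalue, h.bitscore, h.subject_id) for h in rank_hits(hits)]
            assert got == oracle_rank(rows)


class TestVote:
    """The annotation rule: top hit decides when <= 4 matches; otherwise at
    least three of the five best subjects must be viral."""

    def test_three_of_five_accepts(self):
        flags = [True, True, True, False, False]
        is_eve, _ = vote_eve([_hit(subject=f"s{i}") for i in range(5)],
                             _subjects(flags))
        assert is_eve

    def test_two_of_five_rejects(self):
        flags = [True, True, False, False, False]
        is_eve, _ = vote_eve([_hit(subject=f"s{i}") for i in range(5)],
                             _subjects(flags))
        assert not is_eve

    def test_few_hits_with_nonviral_best_rejects(self):
        flags = [False, True, True]
        is_eve, _ = vote_eve([_hit(subject=f"s{i}") for i in range(3)],
                             _subjects(flags))
        assert not is_eve

    def test_no_hits(self):
        is_eve, evidence = vote_eve([], {})
        assert not is_eve and evidence["reason"] == "no hits"

    def test_multiple_hsps_to_one_subject_count_once(self):
        # four HSPs but only two distinct subjects: the <=4 branch applies
        hits = [_hit(subject="s0", evalue=1e-30), _hit(subject="s0", evalue=1e-20),
                _hit(subject="s1", evalue=1e-10), _hit(subject="s1", evalue=1e-9)]
        is_eve, evidence = vote_eve(hits, _subjects([True, False]))
        assert is_eve and evidence["n_subjects"] == 2

    def test_exhaustive_patterns_match_rule_oracle(self):
        for n in range(0, 7):
            for flags in itertools.product([True, False], repeat=n):
                hits = [_hit(subject=f"s{i}", evalue=10.0 ** -(30 - i))
                        for i in range(n)]
                is_eve, _ = vote_eve(hits, _subjects(list(flags)))
                assert is_eve == oracle_vote(list(flags)), flags


class TestCallEves:
    def _tables(self, contig_len=30_000):
        rngl = np.random.default_rng(5)
        contig = Contig("c1", random_dna(rngl, contig_len))
        subjects = {
            "virus_gly": SubjectRecord("virus_gly", True, ProductClass.GLY),
            "known_gly": SubjectRecord("known_gly", True, ProductClass.GLY),
            "virus_np": SubjectRecord("virus_np", True, ProductClass.NP),
        }
        return contig, subjects

    def test_overlapping_hits_from_both_strategies_merge_to_one_call(self):
        contig, subjects = self._tables()
        tables = {
            Strategy.VIRUS_GENOME_TBLASTX: [_hit(
                subject="c1", query="virus_gly", s_start=12_001, s_end=12_900)],
            Strategy.KNOWN_EVE_BLASTN: [HomologyHit(
                "known_gly", "c1", 90.0, 800, 10, 0, 1, 800, 12_101, 12_800,
                1e-50, 700, Strategy.KNOWN_EVE_BLASTN)],
        }
        calls = call_eves(tables, subjects, [contig])
        assert len(calls) == 1
        call = calls[0]
        assert call.strategies == {Strategy.VIRUS_GENOME_TBLASTX,
                                   Strategy.KNOWN_EVE_BLASTN}
        assert (call.locus.start, call.locus.end) == (12_000, 12_900)
        assert call.product_class is ProductClass.GLY

    def test_isolated_np_hit_passes_small_count_rule(self):
        contig, subjects = self._tables()
        tables = {Strategy.VIRUS_GENOME_TBLASTX: [_hit(
            subject="c1", query="virus_np", s_start=5_001, s_end=5_400)]}
        calls = call_eves(tables, subjects, [contig])
        assert len(calls) == 1 and calls[0].product_class is ProductClass.NP

    def test_opposite_strand_hits_stay_separate(self):
        contig, subjects = self._tables()
        tables = {Strategy.VIRUS_GENOME_TBLASTX: [
            _hit(subject="c1", query="virus_gly", s_start=12_001, s_end=12_900),
            _hit(subject="c1", query="virus_np", s_start=12_800, s_end=12_100),
        ]}
        calls = call_eves(tables, subjects, [contig])
        assert len(calls) == 2
        assert {c.locus.strand for c in calls} == {"+", "-"}

    def test_unknown_contig_rejected(self):
        contig, subjects = self._tables()
        tables = {Strategy.VIRUS_GENOME_TBLASTX: [_hit(
            subject="nope", query="virus_gly")]}
        with pytest.raises(KeyError, match="nope"):
            call_eves(tables, subjects, [contig])

    def test_merging_is_contractive(self):
        # union of both strategies never yields more loci than the sum of
        # the strategies run separately
        contig, subjects = self._tables()
        t1 = [_hit(subject="c1", query="virus_gly", s_start=1_001, s_end=1_900),
              _hit(subject="c1", query="virus_gly", s_start=9_001, s_end=9_400)]
        t2 = [HomologyHit("known_gly", "c1", 90.0, 800, 10, 0, 1, 800,
                          1_101, 1_800, 1e-50, 700, Strategy.KNOWN_EVE_BLASTN)]
        both = call_eves({Strategy.VIRUS_GENOME_TBLASTX: t1,
                          Strategy.KNOWN_EVE_BLASTN: t2}, subjects, [contig])
        sep = call_eves({Strategy.VIRUS_GENOME_TBLASTX: t1}, subjects, [contig]) \
            + call_eves({Strategy.KNOWN_EVE_BLASTN: t2}, subjects, [contig])
        assert len(both) <= len(sep)

    def test_mock_tables_row_count_matches_generator(self, small_sim):
        virus_rows = small_sim.hit_tables[Strategy.VIRUS_GENOME_TBLASTX]
        n_eve_components = sum(
            1 for t in small_sim.truth for c in t.components
            if c in ("GLY", "RDRP_EVE", "NP_EVE"))
        assert len(virus_rows) == n_eve_components


class TestNaiveTranslatedSearch:
    def test_planted_peptide_recovered_with_high_coverage(self, rng):
        from chuvee.simulate import _backtranslate, _random_peptide
        pep = _random_peptide(rng, 120)
        block = _backtranslate(rng, pep)
        seq = random_dna(rng, 3_000) + block + random_dna(rng, 3_000)
        hits = naive_translated_search([Contig("c", seq)], {"prot": pep})
        covering = [h for h in hits if h.query_id == "prot"
                    and (h.q_end - h.q_start + 1) >= 0.9 * len(pep)]
        assert covering, "planted peptide not recovered"

    def test_minus_strand_coordinates_recover_the_locus(self, rng):
        from chuvee.simulate import _backtranslate, _random_peptide
        from chuvee.seqio import revcomp
        pep = _random_peptide(rng, 100)
        block = _backtranslate(rng, pep)
        seq = random_dna(rng, 2_000) + revcomp(block) + random_dna(rng, 2_000)
        hits = naive_translated_search([Contig("c", seq)], {"prot": pep})
        best = max(hits, key=lambda h: h.bitscore)
        start, end, strand = best.subject_interval
        assert strand == "-"
        assert start >= 1_900 and end <= 2_400

    def test_shuffled_genome_yields_no_hits(self, rng):
        from chuvee.simulate import _random_peptide
        prots = {f"p{i}": _random_peptide(rng, 300) for i in range(3)}
        seq = random_dna(rng, 20_000)
        assert naive_translated_search([Contig("c", seq)], prots) == []

    def test_contains_gapless_smith_waterman_optimum_on_tiny_case(self, rng):
        """The ungapped seed-and-extend must find the optimal local alignment
        (gap-free Smith-Waterman) of an exact planted peptide."""
        from Bio import Align
        from Bio.Align import substitution_matrices
        from chuvee.simulate import _backtranslate, _random_peptide
        from chuvee.seqio import translate
        pep = _random_peptide(rng, 60)
        block = _backtranslate(rng, pep)
        seq = random_dna(rng, 900) + block + random_dna(rng, 900)
        contig = Contig("c", seq)
        hits = naive_translated_search([contig], {"prot": pep}, min_score=40)
        best_hit = max(h.bitscore for h in hits)
        aligner = Align.PairwiseAligner(mode="local")
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -1_000  # forbid gaps: pure ungapped optimum
        aligner.extend_gap_score = -1_000
        sw_best = 0
        for frame in range(3):
            for s in (seq, __import__("chuvee.seqio", fromlist=["revcomp"]).revcomp(seq)):
                p = translate(s[frame:])  # '*' is in the BLOSUM62 alphabet
                sw_best = max(sw_best, aligner.score(pep, p))
        # same raw score implies the same optimal ungapped segment was found
        from chuvee.screen import _bitscore
        assert best_hit == pytest.approx(round(_bitscore(int(sw_best)), 1))
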