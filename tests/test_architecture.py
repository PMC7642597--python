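"""Domain scanning, direct-repeat LTR pairs, classification, solo LTRs, expansion."""

import itertools

import numpy as np
import pytest

from chuvee.architecture import (Category, ClassifiedLocus, Domain, LtrPair,
                                 PAO_DOMAINS, classify_locus, classify_window,
                                 detect_solo_ltrs, expand_homologs,
                                 find_ltr_pairs, ingest_domain_table,
                                 scan_domains)
from chuvee.screen import EveCall, HomologyHit, ProductClass, Strategy
from chuvee.seqio import Contig, Interval, revcomp
from conftest import random_dna
from oracles import oracle_direct_repeats


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[(("ACGT".index(out[i])) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)


def _resolve(cands):
    """Overlap resolution rule applied to oracle candidates."""
    scored = sorted(cands, key=lambda c: (-(c[4] / 100 * (c[1] - c[0])), c[0],
                                          c[2] - c[0]))
    kept = []
    for c in scored:
        ivs = [(c[0], c[1]), (c[2], c[3])]
        clash = any(a < k_b and b > k_a
                    for (a, b) in ivs
                    for k in kept for (k_a, k_b) in [(k[0], k[1]), (k[2], k[3])])
        if not clash:
            kept.append(c)
    return sorted((c[0], c[1], c[2], c[3]) for c in kept)


class TestFindLtrPairs:
    def test_planted_identical_repeat_found_at_exact_coordinates(self, rng):
        ltr = random_dna(rng, 600)
        win = random_dna(rng, 3_000) + ltr + random_dna(rng, 4_000) + ltr \
            + random_dna(rng, 3_000)
        (pair,) = find_ltr_pairs(win)
        assert pair.identity == 100.0
        assert (pair.left.start, pair.left.end) == (3_000, 3_600)
        assert (pair.right.start, pair.right.end) == (7_600, 8_200)

    def test_diverged_copies_found_with_reduced_identity(self, rng):
        ltr = random_dna(rng, 670)
        win = random_dna(rng, 2_000) + _mutate(rng, ltr, 0.05) \
            + random_dna(rng, 3_000) + _mutate(rng, ltr, 0.05) \
            + random_dna(rng, 2_000)
        (pair,) = find_ltr_pairs(win)
        assert pair.identity >= 85.0
        assert abs(pair.left.start - 2_000) < 30

    def test_close_repeats_below_min_separation_rejected(self, rng):
        ltr = random_dna(rng, 300)
        win = random_dna(rng, 1_500) + ltr + random_dna(rng, 200) + ltr \
            + random_dna(rng, 1_500)
        assert find_ltr_pairs(win) == []

    @pytest.mark.parametrize("divergence", [0.0, 0.04, 0.1])
    def test_equals_bruteforce_direct_repeat_oracle(self, rng, divergence):
        for _ in range(3):
            length = int(rng.integers(100, 901))
            sep = int(rng.integers(1_000, 3_000))
            ltr = random_dna(rng, length)
            win = (random_dna(rng, 500) + _mutate(rng, ltr, divergence)
                   + random_dna(rng, sep) + _mutate(rng, ltr, divergence)
                   + random_dna(rng, 500))
            got = sorted((p.left.start, p.left.end, p.right.start, p.right.end)
                         for p in find_ltr_pairs(win))
            expected = _resolve(oracle_direct_repeats(win))
            assert got == expected

    def test_n_positions_never_match(self):
        win = ("ACGT" * 300) + "N" * 2_000 + ("ACGT" * 300)
        # periodic sequence matches itself, but every candidate involving N
        # must exclude the N run from its matches
        for pair in find_ltr_pairs(win, min_sep=1_000, max_sep=4_000):
            left = win[pair.left.start:pair.left.end]
            right = win[pair.right.start:pair.right.end]
            matches = sum(1 for a, b in zip(left, right) if a == b and a != "N")
            assert matches / len(left) * 100 == pytest.approx(pair.identity)


class TestScanDomains:
    def test_planted_body_recovered_in_order(self, small_sim):
        truth = next(t for t in small_sim.truth
                     if t.category is Category.PAO_COMPLETE)
        contig = next(c for c in small_sim.contigs
                      if c.id == t.interval.contig_id) \
            if (t := truth) else None
        window = Interval(contig.id, max(0, truth.interval.start - 1_000),
                          truth.interval.end + 1_000)
        found = scan_domains(contig, window, small_sim.family.domain_peptides)
        labels = [d.domain.value for d in found]
        expected = list(PAO_DOMAINS) if truth.strand == "+" \
            else list(PAO_DOMAINS)[::-1]
        assert labels == expected

    def test_random_background_is_empty(self, rng):
        from chuvee.simulate import _random_peptide
        refs = {name: _random_peptide(rng, 200) for name in PAO_DOMAINS}
        contig = Contig("c", random_dna(rng, 20_000))
        assert scan_domains(contig, Interval("c", 0, 20_000), refs) == []

    def test_external_table_equivalent_to_scan(self, small_sim, tmp_path):
        truth = next(t for t in small_sim.truth
                     if t.category is Category.PAO_COMPLETE)
        contig = next(c for c in small_sim.contigs
                      if c.id == truth.interval.contig_id)
        window = Interval(contig.id, max(0, truth.interval.start - 1_000),
                          truth.interval.end + 1_000)
        scanned = scan_domains(contig, window, small_sim.family.domain_peptides)
        # write the scan as a CDD-style table keyed to window-frame ORFs
        rows = []
        for d in scanned:
            if d.interval.strand == "+":
                orf_start, orf_end = d.interval.start, d.interval.end
            else:
                orf_start, orf_end = d.interval.start, d.interval.end
            aa_len = (d.interval.end - d.interval.start) // 3
            rows.append(f"{contig.id}:{orf_start}-{orf_end}:{d.interval.strand}"
                        f"\t{d.domain.value}\t1\t{aa_len}\t{d.score}\t1e-20")
        p = tmp_path / "cdd.tsv"
        p.write_text("\n".join(rows) + "\n")
        ingested = ingest_domain_table(p, {contig.id})
        assert {(d.domain.value, d.interval.start, d.interval.end)
                for d in ingested} == \
            {(d.domain.value, d.interval.start, d.interval.end)
             for d in scanned}


def _pair(contig="c", left=(1_000, 1_600), right=(6_000, 6_600), identity=99.0):
    return LtrPair(Interval(contig, *left), Interval(contig, *right), identity,
                   Interval(contig, left[1], right[0]))


def _gly_eve(contig="c", start=3_000, end=3_900, product=ProductClass.GLY):
    hit = HomologyHit("virus_gly", contig, 35.0, 300, 10, 0, 1, 300,
                      start + 1, end, 1e-20, 200.0)
    return EveCall(Interval(contig, start, end), product, hit, 1, 1,
                   {Strategy.VIRUS_GENOME_TBLASTX})


class TestClassifyLocus:
    def test_both_ltrs_all_domains_internal_gly_is_complete_anakin(self):
        cat, _ = classify_locus(_gly_eve(), frozenset(PAO_DOMAINS), [_pair()])
        assert cat is Category.ANAKIN_COMPLETE

    def test_both_ltrs_partial_domains_gly_is_defective_2ltr(self):
        cat, _ = classify_locus(_gly_eve(), frozenset({"RT", "RH", "INT"}),
                                [_pair()])
        assert cat is Category.ANAKIN_DEFECTIVE_2LTR

    def test_gly_with_domains_but_no_pair_is_defective(self):
        cat, _ = classify_locus(_gly_eve(), frozenset({"RT", "RH"}), [])
        assert cat is Category.ANAKIN_DEFECTIVE

    def test_bare_gly_is_solo(self):
        cat, _ = classify_locus(_gly_eve(), frozenset(), [])
        assert cat is Category.SOLO_GLY

    def test_pao_without_gly(self):
        cat, _ = classify_locus(None, frozenset(PAO_DOMAINS), [_pair()])
        assert cat is Category.PAO_COMPLETE
        cat, _ = classify_locus(None, frozenset({"RT", "RH"}), [])
        assert cat is Category.PAO_DEFECTIVE

    def test_lone_ltr_is_solo_ltr(self):
        cat, _ = classify_locus(None, frozenset(), [], n_single_ltrs=1)
        assert cat is Category.SOLO_LTR

    def test_rdrp_and_np_products_classified_by_product(self):
        cat, _ = classify_locus(_gly_eve(product=ProductClass.RDRP),
                                frozenset(PAO_DOMAINS), [_pair()])
        assert cat is Category.RDRP_EVE
        cat, _ = classify_locus(_gly_eve(product=ProductClass.NP),
                                frozenset(), [])
        assert cat is Category.NP_EVE

    def test_totality_over_evidence_space(self):
        """Every (LTR count) x (domain subset) x (GLY state) combination maps
        to exactly one category, and the architecture categories of the
        summary scheme are all reachable."""
        seen = set()
        for n_ltr in (0, 1, 2):
            pairs = [_pair()] if n_ltr == 2 else []
            singles = 1 if n_ltr == 1 else 0
            for r in range(6):
                for domset in itertools.combinations(PAO_DOMAINS, r):
                    for gly_state in ("inside", "outside", "absent"):
                        if gly_state == "absent":
                            eve = None
                        elif gly_state == "inside":
                            eve = _gly_eve(start=3_000, end=3_900)
                        else:
                            eve = _gly_eve(start=8_000, end=8_900)
                        cat, _ = classify_locus(eve, frozenset(domset), pairs,
                                                n_single_ltrs=singles)
                        assert cat is not None
                        seen.add(cat)
        expected = {Category.ANAKIN_COMPLETE, Category.ANAKIN_DEFECTIVE_2LTR,
                    Category.ANAKIN_DEFECTIVE, Category.SOLO_GLY,
                    Category.PAO_COMPLETE, Category.PAO_DEFECTIVE_2LTR,
                    Category.PAO_DEFECTIVE, Category.SOLO_LTR, Category.NONE}
        assert seen == expected


class TestSoloLtrsAndExpansion:
    def test_planted_solo_ltr_detected_from_library(self, small_sim):
        family = small_sim.family
        found = detect_solo_ltrs(small_sim.contigs, {"ltr": family.ltr},
                                 family.domain_peptides)
        solo_truth = [t for t in small_sim.truth
                      if t.category is Category.SOLO_LTR]
        assert len(found) == len(solo_truth)
        for t in solo_truth:
            assert any(f.locus.overlap(t.interval) >=
                       0.5 * len(t.interval) for f in found)

    def test_element_ltrs_rejected_as_solo(self, small_sim):
        # the LTRs of full elements have domains in their windows, so the
        # detected solo set contains no locus near a complete element
        family = small_sim.family
        found = detect_solo_ltrs(small_sim.contigs, {"ltr": family.ltr},
                                 family.domain_peptides)
        completes = [t for t in small_sim.truth
                     if t.category in (Category.ANAKIN_COMPLETE,
                                       Category.PAO_COMPLETE)]
        for f in found:
            for t in completes:
                assert f.locus.overlap(t.interval) == 0

    def test_empty_library_warns_and_returns_nothing(self, small_sim):
        with pytest.warns(UserWarning):
            assert detect_solo_ltrs(small_sim.contigs, {},
                                    small_sim.family.domain_peptides) == []

    def test_expansion_recovers_pao_copies_and_is_idempotent(self, small_sim):
        family = small_sim.family
        anakin = next(t for t in small_sim.truth
                      if t.category is Category.ANAKIN_COMPLETE)
        contig = next(c for c in small_sim.contigs
                      if c.id == anakin.interval.contig_id)
        query = contig.seq[anakin.interval.start:anakin.interval.end]
        expanded = expand_homologs({"q": query}, small_sim.contigs,
                                   family.domain_peptides)
        pao_truth = [t for t in small_sim.truth
                     if t.category in (Category.PAO_COMPLETE,
                                       Category.PAO_DEFECTIVE,
                                       Category.PAO_DEFECTIVE_2LTR)]
        for t in pao_truth:
            assert any(l.locus.overlap(t.interval) >=
                       0.5 * min(len(l.locus), len(t.interval))
                       for l in expanded), t.element_id
        # fixed point: a second expansion over its own output adds nothing
        again = expand_homologs({"q": query}, small_sim.contigs,
                                family.domain_peptides, existing=expanded)
        assert again == []

    def test_no_complete_elements_no_expansion(self, small_sim):
        assert expand_homologs({}, small_sim.contigs,
                               small_sim.family.domain_peptides) == []
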