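import itertools

import pytest

from phyloprimer import iupac, ispcr, simulate
from phyloprimer.motifs import MotifOccurrence, MotifSet, discover_motifs
from phyloprimer.primers import (
    CodingPair,
    DesignConfig,
    NoPrimer,
    build_block,
    choose_primer_window,
    degenerate_consensus,
    design_report,
    enumerate_pairs,
    map_motif_to_cds,
    pair_records,
    wallace_tm_range,
)
from phyloprimer.seqalign import SequenceRecord


def _coding_pair(pid, protein, cds):
    return CodingPair(
        pid, SequenceRecord(pid, protein), SequenceRecord(pid, cds, "dna")
    )


def _truth_occs(truth, motif_index):
    m = truth["motifs"][motif_index]
    return [
        MotifOccurrence(sid, o["start"], o["site"], 1.0)
        for sid, o in sorted(m["occurrences"].items())
    ]


class TestCodingPair:
    def test_mismatched_cds_rejected(self):
        with pytest.raises(ValueError, match="translate"):
            _coding_pair("x", "MK", "ATGAAC")  # AAC = N, not K

    def test_pair_records_by_id(self, family6):
        prot, cds, _ = family6
        pairs = pair_records(prot, cds)
        assert [p.id for p in pairs] == [p.id for p in prot]

    def test_missing_cds_reported(self, family6):
        prot, cds, _ = family6
        with pytest.raises(ValueError, match="sp05"):
            pair_records(prot, cds[:-1])


class TestMapMotifToCds:
    def test_coordinate_arithmetic(self):
        cp = _coding_pair("x", "M" + "K" * 15, "ATG" + "AAA" * 15)
        occ = MotifOccurrence("x", 10, "KKKKKK", 1.0)
        assert map_motif_to_cds(occ, cp) == (30, 48)

    def test_boundary_at_zero(self):
        cp = _coding_pair("x", "MKTAYI", "ATGAAAACCGCATACATA")
        occ = MotifOccurrence("x", 0, "MKTAYI", 1.0)
        assert map_motif_to_cds(occ, cp) == (0, 18)

    def test_mapped_interval_translates_to_site(self, family6):
        from phyloprimer.seqalign import translate_cds

        prot, cds, truth = family6
        pairs = {p.id: p for p in pair_records(prot, cds)}
        for mi in range(3):
            for occ in _truth_occs(truth, mi):
                cp = pairs[occ.seq_id]
                s, e = map_motif_to_cds(occ, cp)
                assert translate_cds(cp.cds.residues[s:e]) == occ.site

    def test_id_mismatch_rejected(self):
        cp = _coding_pair("x", "MK", "ATGAAA")
        with pytest.raises(ValueError, match="id"):
            map_motif_to_cds(MotifOccurrence("y", 0, "MK", 1.0), cp)


class TestBuildBlock:
    def test_union_column_sets(self):
        cps = [
            _coding_pair("a", "AA", "GCAGCA"),
            _coding_pair("b", "AA", "GCGGCA"),
        ]
        occs = [MotifOccurrence(x, 0, "AA", 1.0) for x in "ab"]
        block = build_block(occs, cps)
        assert block.column_sets[0] == frozenset("G")
        assert block.column_sets[1] == frozenset("C")
        assert block.column_sets[2] == frozenset("AG")
        assert block.column_sets[5] == frozenset("A")

    def test_wobble_only_at_third_codon_positions(self, family6):
        prot, cds, truth = family6
        pairs = pair_records(prot, cds)
        for mi in range(3):
            block = build_block(_truth_occs(truth, mi), pairs)
            for col, bases in enumerate(block.column_sets):
                if col % 3 != 2:
                    assert len(bases) == 1, (mi, col, bases)

    def test_single_species_rejected(self):
        cps = [_coding_pair("a", "AA", "GCAGCA")]
        with pytest.raises(ValueError, match="2 species"):
            build_block([MotifOccurrence("a", 0, "AA", 1.0)], cps)

    def test_differing_widths_rejected(self, family6):
        prot, cds, truth = family6
        pairs = pair_records(prot, cds)
        occs = _truth_occs(truth, 0)[:1] + _truth_occs(truth, 1)[1:]
        with pytest.raises(ValueError, match="width"):
            build_block(occs, pairs)


class TestDegenerateConsensus:
    def test_simple_sets(self):
        block = build_block(
            [MotifOccurrence(x, 0, "AA", 1.0) for x in "ab"],
            [_coding_pair("a", "AA", "GCAGCT"), _coding_pair("b", "AA", "GCGGCC")],
        )
        assert degenerate_consensus(block) == "GCRGCY"

    def test_all_fifteen_subsets_against_lookup_oracle(self):
        # oracle: independent mapping of each non-empty subset
        oracle = {}
        for r in range(1, 5):
            for combo in itertools.combinations("ACGT", r):
                expanded = {
                    code
                    for code, bases in iupac.CODE_TO_BASES.items()
                    if bases == frozenset(combo)
                }
                oracle[frozenset(combo)] = expanded.pop()
        assert len(oracle) == 15
        for subset, code in oracle.items():
            assert iupac.consensus_code(subset) == code

    def test_consensus_expansion_idempotent(self, family6):
        # build a block from all expansions of a consensus -> same consensus
        prot, cds, truth = family6
        pairs = pair_records(prot, cds)
        block = build_block(_truth_occs(truth, 0), pairs)
        consensus = degenerate_consensus(block)
        protein_site = truth["motifs"][0]["occurrences"]["sp00"]["site"]
        expansions = iupac.expand(consensus)
        cps = [
            _coding_pair(f"e{i}", protein_site, exp)
            for i, exp in enumerate(expansions)
        ]
        occs = [
            MotifOccurrence(f"e{i}", 0, protein_site, 1.0)
            for i in range(len(expansions))
        ]
        block2 = build_block(occs, cps)
        assert degenerate_consensus(block2) == consensus


class TestChoosePrimerWindow:
    def test_clean_consensus_leftmost_window(self):
        consensus = "ATGCATGCATGCATGCATGC"  # 20 nt, no degeneracy, 50% GC
        primer = choose_primer_window(consensus, "forward")
        assert primer.iupac == consensus[:18]
        assert primer.degeneracy == 1
        assert primer.window == (0, 18)

    def test_all_n_consensus_yields_no_primer(self):
        result = choose_primer_window("N" * 20, "forward")
        assert isinstance(result, NoPrimer)
        assert result.reasons["degeneracy"] > 0 or result.reasons["three_prime"] > 0

    def test_three_prime_rule_excludes_terminal_degeneracy(self):
        # Y at position 5 and R at position 19 (0-based) in a 20-nt consensus
        consensus = list("ATGCATGCATGCATGCATGC")
        consensus[5] = "Y"
        consensus[19] = "R"
        consensus = "".join(consensus)
        # brute-force oracle over all windows with the same rules
        cfg = DesignConfig()
        feasible = []
        for L in range(cfg.len_min, cfg.len_max + 1):
            for s in range(len(consensus) - L + 1):
                w = consensus[s : s + L]
                if any(len(iupac.CODE_TO_BASES[c]) > 1 for c in w[-2:]):
                    continue
                if iupac.degeneracy(w) > cfg.degeneracy_cap:
                    continue
                lo, hi = wallace_tm_range(w)
                if lo < cfg.tm_min or hi > cfg.tm_max:
                    continue
                feasible.append((iupac.degeneracy(w), hi - lo, s, L))
        primer = choose_primer_window(consensus, "forward")
        assert feasible, "oracle found no window but implementation must agree"
        best = min(feasible)
        assert (primer.degeneracy, primer.tm_range_c[1] - primer.tm_range_c[0],
                primer.window[0], len(primer)) == best
        # position 19 cannot sit in the last two bases of the chosen window
        assert not any(
            len(iupac.CODE_TO_BASES[c]) > 1 for c in primer.iupac[-2:]
        )

    def test_reverse_primer_is_revcomp_of_window(self):
        consensus = "ATGCATGCATGCATGCATGC"
        primer = choose_primer_window(consensus, "reverse")
        s, e = primer.window
        assert primer.iupac == iupac.revcomp(consensus[s:e])

    def test_short_consensus_no_primer(self):
        assert isinstance(choose_primer_window("ATGC", "forward"), NoPrimer)


@pytest.fixture(scope="module")
def designed(family6):
    prot, cds, _ = family6
    pairs = pair_records(prot, cds)
    found = discover_motifs(prot, n_motifs=3, rng_seed=1)
    return found, pairs, enumerate_pairs(found, pairs, "sp00")


class TestEnumeratePairs:
    def test_amplicons_match_hand_coordinates(self, designed):
        found, pairs, pps = designed
        ref = next(cp for cp in pairs if cp.id == "sp00")
        occ_start = {}
        for rank, (model, occs) in enumerate(found):
            occ = next(o for o in occs if o.seq_id == "sp00")
            occ_start[rank] = 3 * occ.start
        for pp in pps:
            fwd_5p = occ_start[pp.fwd.motif_rank] + pp.fwd.window[0]
            rev_5p = occ_start[pp.rev.motif_rank] + pp.rev.window[1] - 1
            assert pp.amplicon_bp["sp00"] == rev_5p - fwd_5p + 1

    def test_amplicon_bounds_and_footprints(self, designed):
        _, _, pps = designed
        cfg = DesignConfig()
        for pp in pps:
            amp = pp.amplicon_bp["sp00"]
            assert cfg.amp_min <= amp <= cfg.amp_max
            assert amp >= len(pp.fwd) + len(pp.rev)

    def test_exclusive_amplicon_range_empty_with_diagnostic(self, family6):
        prot, cds, _ = family6
        pairs = pair_records(prot, cds)
        found = discover_motifs(prot, n_motifs=3, rng_seed=1)
        cfg = DesignConfig(amp_min=1, amp_max=2)
        assert enumerate_pairs(found, pairs, "sp00", cfg) == []

    def test_top_pair_amplifies_every_template(self, designed, family6):
        _, cds, _ = family6
        _, pairs, pps = designed
        assert pps, "no primer pair designed on the fixture family"
        top = pps[0]
        for cp in pairs:
            amps = ispcr.predict_amplicons(top.fwd, top.rev, cp.cds, max_mismatch=0)
            assert any(
                a.length_bp == top.amplicon_bp["sp00"] for a in amps
            ), cp.id

    def test_every_block_sequence_matches_primer_exactly(self, designed):
        found, pairs, pps = designed
        top = pps[0]
        for primer in (top.fwd, top.rev):
            model, occs = found.motifs[primer.motif_rank]
            block = build_block(occs, pairs, motif_rank=primer.motif_rank)
            s, e = primer.window
            for sid, sub in block.substrings.items():
                window = sub[s:e]
                target = window if primer.direction == "forward" else iupac.revcomp(window)
                assert all(
                    b in iupac.CODE_TO_BASES[c]
                    for c, b in zip(primer.iupac, target)
                ), (sid, primer.iupac, target)

    def test_unknown_reference_rejected(self, family6):
        prot, cds, _ = family6
        pairs = pair_records(prot, cds)
        with pytest.raises(ValueError, match="reference"):
            enumerate_pairs(MotifSet([]), pairs, "nope")


class TestDesignReport:
    def test_empty_input_header_only(self):
        table = design_report([])
        assert table.empty
        assert list(table.columns)[:4] == [
            "gene_name", "primer", "sequence_5to3", "amplicon_bp",
        ]

    def test_row_count_two_per_pair(self, family6):
        prot, cds, _ = family6
        pairs = pair_records(prot, cds)
        found = discover_motifs(prot, n_motifs=3, rng_seed=1)
        pps = enumerate_pairs(found, pairs, "sp00")
        table = design_report(pps, gene_name="FAM")
        assert len(table) == 2 * len(pps)

    def test_degenerate_codes_rendered_verbatim(self):
        # the published FDS forward primer carries a W ambiguity code
        from phyloprimer.primers import DegeneratePrimer

        fwd = DegeneratePrimer("CATCGCCGCATTGTWCAG", "forward", 0, (0, 18))
        rev = DegeneratePrimer("CAATCTTTTCRGGCTCACC", "reverse", 1, (0, 19))
        from phyloprimer.primers import PrimerPair

        table = design_report([PrimerPair(fwd, rev, {"ref": 187}, 0.0)], "FDS")
        assert table.loc[0, "sequence_5to3"] == "CATCGCCGCATTGTWCAG"
        assert table.loc[0, "primer"] == "FDSFwd"
        assert table.loc[0, "amplicon_bp"] == 187
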