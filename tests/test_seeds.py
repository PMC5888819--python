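"""Seed extraction, UTR scanning vs a naive oracle, interaction calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mirpair as mp
from mirpair.errors import AlphabetError, SpecError
from mirpair.seeds import SeedMatch, seed_site


def naive_scan(utr: str, site: str):
    """O(n*m) reference scan used as the independent oracle."""
    return [i for i in range(len(utr) - len(site) + 1)
            if utr[i:i + len(site)] == site]


class TestExtractSeeds:
    def test_positional_definition(self):
        ss = mp.extract_seeds("x", "ACGUACGUACGU")
        assert {(L, s) for L, s, _p in ss.seeds} == {
            (6, "CGUACG"), (7, "CGUACGU"), (8, "CGUACGUA")}
        assert all(p == 2 for _L, _s, p in ss.seeds)

    def test_short_mature_truncates_the_set(self):
        ss = mp.extract_seeds("x", "ACGUACGU")  # length 8
        assert [L for L, _s, _p in ss.seeds] == [6, 7]

    def test_lowercase_and_dna_input_normalized(self):
        ss = mp.extract_seeds("x", "acgtacgtacgt")
        assert ss.seeds[0][1] == "CGUACG"

    def test_alphabet_error(self):
        with pytest.raises(AlphabetError):
            mp.extract_seeds("x", "ACGUXCGUACGU")


class TestScanUtr:
    def test_empty_utr_no_matches(self):
        ss = mp.extract_seeds("x", "ACGUACGUACGU")
        assert mp.scan_utr("", ss) == []

    def test_constructed_site_at_offset_ten(self):
        seed6 = "CGUACG"  # site is its DNA reverse complement
        site = seed_site(seed6)
        utr = "T" * 10 + site + "T" * 10
        ss = mp.extract_seeds("x", "ACGUACG")  # only the 6-mer+7-mer seeds
        hits = [m for m in mp.scan_utr(utr, ss, "g") if m.seed_length == 6]
        assert hits == [SeedMatch("x", "g", 6, 10, 16)]

    def test_n_never_matches(self):
        seed6 = "CGUACG"
        site = seed_site(seed6)
        utr = site.replace(site[2], "N", 1)
        ss = mp.extract_seeds("x", "ACGUACG")
        assert all(m.seed_length != 6 for m in mp.scan_utr(utr, ss, "g"))

    def test_empty_seed_set_rejected(self):
        ss = mp.extract_seeds("x", "ACGUAC")  # too short for any seed
        with pytest.raises(SpecError):
            mp.scan_utr("ACGT", ss)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_naive_oracle_on_random_cases(self, data):
        mature = data.draw(st.text(alphabet="ACGU", min_size=9, max_size=23))
        utr = data.draw(st.text(alphabet="ACGTN", min_size=0, max_size=300))
        ss = mp.extract_seeds("m", mature)
        got = {(m.seed_length, m.utr_start) for m in mp.scan_utr(utr, ss, "g")}
        want = {(L, i) for L, s, _p in ss.seeds
                for i in naive_scan(utr, seed_site(s))}
        assert got == want

    def test_overlapping_occurrences_all_reported(self):
        # seed whose site is 'AAAAAA'; a run of 8 A's has 3 overlapping sites
        seed6 = "UUUUUU"
        assert seed_site(seed6) == "AAAAAA"
        ss = mp.extract_seeds("m", "GUUUUUUG")
        hits = [m for m in mp.scan_utr("AAAAAAAA", ss, "g") if m.seed_length == 6]
        assert [m.utr_start for m in hits] == [0, 1, 2]

    def test_longer_seed_match_implies_shorter_at_offset(self, small_study):
        # seeds share start position 2, so the site of the L-mer contains the
        # site of the (L-1)-mer shifted by one
        ss = mp.extract_seeds("mir-0001", small_study.mature_seqs["mir-0001"])
        matches = mp.scan_utr(small_study.utrs["GENE0003"], ss, "GENE0003")
        by_len = {L: {m.utr_start for m in matches if m.seed_length == L}
                  for L in (6, 7, 8)}
        assert {p + 1 for p in by_len[7]} <= by_len[6]
        assert {p + 1 for p in by_len[8]} <= by_len[7]


class TestClassifyInteraction:
    def test_seed_match_and_negative_slope_is_direct(self):
        match = SeedMatch("hsa-miR-17-5p", "PDGFRA", 7, 100, 107)
        call = mp.classify_interaction("PDGFRA", "hsa-miR-17-5p", -0.28, [match])
        assert call.call == "direct" and call.has_seed_match

    def test_no_match_is_indirect_whatever_the_slope(self):
        call = mp.classify_interaction("MYC", "hsa-miR-17-5p", 0.35, [])
        assert call.call == "indirect" and not call.has_seed_match

    def test_match_with_positive_slope_is_indirect(self):
        match = SeedMatch("m", "g", 6, 0, 6)
        assert mp.classify_interaction("g", "m", 0.2, [match]).call == "indirect"


class TestSummarize:
    def test_reference_replay_for_mir150(self, reference_tables):
        t3 = reference_tables.table3
        calls = [mp.classify_interaction(r.gene, r.mirna, r.beta,
                                         [SeedMatch(r.mirna, r.gene, 6, 0, 6)]
                                         if r.seed_match else [])
                 for r in t3.itertuples()]
        summary = mp.summarize_by_mirna(calls)
        entry = summary["hsa-miR-150-5p"]
        assert len(entry["with_match"]) == 3
        assert len(entry["without_match"]) == 4
        assert entry["n_associations"] == 7
        total_direct = sum(c.call == "direct" for c in calls)
        assert total_direct == 13

    def test_single_call(self):
        call = mp.classify_interaction("g", "m", -1.0, [])
        assert mp.summarize_by_mirna([call]) == {
            "m": {"with_match": [], "without_match": ["g"],
                  "n_associations": 1}}

    def test_empty_input(self):
        assert mp.summarize_by_mirna([]) == {}
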