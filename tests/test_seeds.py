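"""Seed derivation, site scanning and UTR density statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _support import brute_force_sites
from ripseed.seeds import (
    GeneUtrSummary,
    MirnaFamily,
    density_comparison,
    derive_seed,
    find_seed_sites,
    gene_summary,
)

rna = st.text(alphabet="ACGU", min_size=1, max_size=200)
mature = st.text(alphabet="ACGU", min_size=8, max_size=24)


class TestDeriveSeed:
    def test_let7(self):
        assert derive_seed("UGAGGUAGUAGGUUGUAUAGUU") == "GAGGUAG"

    def test_minimal_length_and_t_normalisation(self):
        assert derive_seed("UAAAAAAA") == "AAAAAAA"
        assert derive_seed("TGAGGTAGTAGGTTGTATAGTT") == "GAGGUAG"

    def test_too_short_is_an_error(self):
        with pytest.raises(ValueError, match="8 nt"):
            derive_seed("UGAGGUA")

    def test_family_members_must_share_seed(self):
        with pytest.raises(ValueError, match="share"):
            MirnaFamily(
                "bad",
                ("a", "b"),
                ("UGAGGUAGUAGGUUGUAUAGUU", "UCCCUGAGACCUCAAGUGUGA"),
            )


class TestFindSeedSites:
    def test_single_8mer(self, let7_family):
        sites = find_seed_sites("AAACUACCUCAAA", let7_family)
        assert [(s.start, s.end, s.site_type) for s in sites] == [(3, 11, "8mer")]

    def test_7mer_m8_and_7mer_a1(self, let7_family):
        # rc(seed) = CUACCUC; no trailing A -> 7mer-m8
        (m8_site,) = find_seed_sites("GGCUACCUCGG", let7_family)
        assert (m8_site.start, m8_site.end, m8_site.site_type) == (2, 9, "7mer-m8")
        # rc(seed 2-7) + A = UACCUCA with a non-C before -> 7mer-A1
        (a1_site,) = find_seed_sites("GUACCUCAG", let7_family)
        assert (a1_site.start, a1_site.end, a1_site.site_type) == (1, 8, "7mer-A1")

    def test_no_sites_in_mismatching_sequence(self, let7_family):
        assert find_seed_sites("GGGGGGG", let7_family) == []

    def test_bad_character_error_names_position(self, let7_family):
        with pytest.raises(ValueError, match="position 4"):
            find_seed_sites("ACGU!ACGU", let7_family)

    def test_empty_family_iteration_yields_nothing(self):
        from ripseed.seeds import scan_utrs

        assert scan_utrs({"x": "ACGUACGU"}, []) == []

    @settings(derandomize=True, max_examples=300)
    @given(utr=rna, seq=mature)
    def test_matches_brute_force_window_scan(self, utr, seq):
        fam = MirnaFamily("f", ("m",), (seq,))
        got = {(s.start, s.end, s.site_type) for s in find_seed_sites(utr, fam)}
        assert got == brute_force_sites(utr, fam.seed7)

    @settings(derandomize=True, max_examples=100)
    @given(utr=rna, seq=mature)
    def test_invariant_under_t_u_representation(self, utr, seq):
        fam = MirnaFamily("f", ("m",), (seq,))
        dna = utr.replace("U", "T")
        assert find_seed_sites(utr, fam) == find_seed_sites(dna, fam)


class TestGeneSummary:
    def test_single_isoform_density(self):
        s = gene_summary("g", [3], [600])
        assert s == GeneUtrSummary("g", 3.0, 600.0, 5.0)

    def test_even_isoform_count_uses_mean_of_middle_two(self):
        s = gene_summary("g", [2, 4], [500, 1500])
        assert (s.median_sites, s.median_length, s.density_per_kb) == (3.0, 1000.0, 3.0)

    def test_zero_sites_gives_zero_density(self):
        assert gene_summary("g", [0, 0, 0], [100, 200, 300]).density_per_kb == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            gene_summary("g", [], [])
        with pytest.raises(ValueError):
            gene_summary("g", [1], [0])
        with pytest.raises(ValueError):
            gene_summary("g", [1, 2], [10])

    @settings(derandomize=True, max_examples=50)
    @given(
        counts=st.lists(st.integers(0, 20), min_size=1, max_size=6),
        lengths=st.lists(st.integers(10, 2000), min_size=1, max_size=6),
    )
    def test_duplicating_all_isoforms_leaves_density_unchanged(self, counts, lengths):
        n = min(len(counts), len(lengths))
        counts, lengths = counts[:n], lengths[:n]
        once = gene_summary("g", counts, lengths)
        twice = gene_summary("g", counts * 2, lengths * 2)
        assert twice.density_per_kb == pytest.approx(once.density_per_kb)
        assert twice.median_sites == pytest.approx(once.median_sites)


class TestDensityComparison:
    summaries = {
        "a": GeneUtrSummary("a", 2, 200, 10.0),
        "b": GeneUtrSummary("b", 1, 200, 5.0),
        "c": GeneUtrSummary("c", 0, 200, 0.0),
    }

    def test_identical_sets_give_fold_one(self):
        cmp = density_comparison({"a", "b"}, {"a", "b"}, self.summaries, {"a", "b", "c"})
        assert cmp.fold_change == pytest.approx(1.0)

    def test_expression_filter_applies_before_averaging(self):
        cmp = density_comparison({"a", "c"}, {"a", "b", "c"}, self.summaries, {"a", "b"})
        assert cmp.mean_density_targets == pytest.approx(10.0)
        assert cmp.mean_density_background == pytest.approx(7.5)

    def test_empty_filtered_target_set_is_an_error(self):
        with pytest.raises(ValueError, match="target"):
            density_comparison({"a"}, {"b"}, self.summaries, {"b"})
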