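"""Encoding, tallies, widespread fractions, and site-list subsetting."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import geovar as gv
from geovar.geocode import CodeTally

from conftest import brute_force_code


class TestEncode:
    def test_rare_in_one_region_only(self):
        cfg = gv.EncodingConfig(threshold=0.05)
        assert gv.encode_variant((0, 0, 0.01, 0, 0), cfg) == "uuRuu"

    def test_common_everywhere(self):
        cfg = gv.EncodingConfig(threshold=0.05)
        assert gv.encode_variant((0.3, 0.25, 0.4, 0.2, 0.35), cfg) == "CCCCC"

    def test_boundary_is_strictly_greater(self):
        cfg = gv.EncodingConfig(threshold=0.05)
        assert gv.encode_variant((0.05, 0.050001, 0, 0, 0), cfg) == "RCuuu"

    def test_boundary_exact_on_counts(self):
        # 1/20 == threshold exactly -> R, even where floats would wobble
        ac = np.array([[1, 2, 0]])
        an = np.array([[20, 20, 20]])
        assert gv.encode_counts(ac, an, Fraction(1, 20))[0] == "RCu"

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gv.encode_variant((0, 0, 0))

    def test_possible_code_count(self):
        assert gv.count_possible_codes(5) == 242
        assert gv.count_possible_codes(1) == 2
        assert gv.count_possible_codes(26) == 3**26 - 1
        with pytest.raises(ValueError):
            gv.count_possible_codes(0)

    def test_vectorised_equals_scalar_oracle(self, sim_table):
        table, _ = sim_table
        codes = gv.encode_table(table)
        freqs = table.freqs
        expected = [brute_force_code(freqs[i]) for i in range(len(table))]
        assert list(codes) == expected


class TestTally:
    def test_counts_and_proportions(self):
        tally = CodeTally.from_codes(["Ruuuu", "Ruuuu", "CCCCC"])
        assert tally.counts == {"Ruuuu": 2, "CCCCC": 1}
        assert tally.proportions["Ruuuu"] == pytest.approx(2 / 3)
        assert tally.rank_order == ["Ruuuu", "CCCCC"]

    def test_rank_ties_break_lexicographically(self):
        tally = CodeTally({"uR": 5, "Ru": 5, "CC": 7})
        assert tally.rank_order == ["CC", "Ru", "uR"]

    def test_tally_matches_per_variant_encoding(self, sim_table):
        table, truth = sim_table
        tally = gv.tally_codes(table)
        from collections import Counter

        assert tally.counts == dict(Counter(truth["true_code"]))
        assert tally.total == len(table)

    def test_drop_singletons(self, sim_table):
        table, _ = sim_table
        n_singletons = int(table.singleton_mask().sum())
        assert n_singletons > 0
        tally = gv.tally_codes(table, drop_singletons=True)
        assert tally.total == len(table) - n_singletons

    def test_all_singletons_dropped_is_error(self):
        spec = gv.SimSpec(n_variants=30, weights={"private_singleton": 1.0}, seed=1)
        table, _ = gv.simulate_table(spec)
        with pytest.raises(ValueError, match="no variants left"):
            gv.tally_codes(table, drop_singletons=True)

    def test_conservation_across_thresholds_and_filters(self, sim_table):
        table, _ = sim_table
        n_non_singleton = len(table) - int(table.singleton_mask().sum())
        for thr in ("0.01", "0.05", "0.25", "0.5"):
            cfg = gv.EncodingConfig(threshold=thr)
            assert gv.tally_codes(table, cfg).total == len(table)
            assert gv.tally_codes(table, cfg, drop_singletons=True).total == n_non_singleton

    def test_proportions_sum_to_one(self, sim_table):
        table, _ = sim_table
        assert sum(gv.tally_codes(table).proportions.values()) == pytest.approx(1.0)


class TestThresholdMonotonicity:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_threshold_only_moves_c_to_r(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 30, 4
        an = np.full((n, k), 40)
        ac = rng.integers(0, 21, size=(n, k))
        ac[ac.sum(axis=1) == 0, 0] = 1
        low = gv.encode_counts(ac, an, Fraction(1, 100))
        high = gv.encode_counts(ac, an, Fraction(1, 2))
        for lo, hi in zip(low, high):
            for a, b in zip(lo, hi):
                assert (a == b) or (a == "C" and b == "R")

    def test_tiny_threshold_makes_everything_common(self):
        ac = np.array([[1, 0, 39]])
        an = np.array([[40, 40, 40]])
        assert gv.encode_counts(ac, an, Fraction(1, 10**9))[0] == "CuC"


class TestPermutationEquivariance:
    def test_group_permutation_permutes_letters(self, sim_table):
        table, _ = sim_table
        perm = [4, 2, 0, 3, 1]
        permuted = gv.FrequencyTable(
            table.variants,
            table.ac[:, perm],
            table.an[:, perm],
            [table.group_order[i] for i in perm],
        )
        codes = gv.encode_table(table)
        codes_p = gv.encode_table(permuted)
        for c, cp in zip(codes, codes_p):
            assert cp == "".join(c[i] for i in perm)


class TestWidespreadFraction:
    def test_constructed_example(self):
        tally = CodeTally({"CCCCC": 63, "Cuuuu": 37})
        assert gv.widespread_fraction(tally, "common_in_any") == pytest.approx(0.63)

    def test_no_common_variant_is_error(self):
        tally = CodeTally({"RRRRR": 10})
        with pytest.raises(ValueError, match="denominator"):
            gv.widespread_fraction(tally, "common_in_any")

    def test_restricted_group_scope(self):
        # common outside group 0 only for the uCCCC code
        tally = CodeTally({"CCCCC": 50, "Cuuuu": 30, "uCCCC": 20})
        frac = gv.widespread_fraction(tally, "common_in_any_of",
                                      qualifying_groups=[1, 2, 3, 4])
        assert frac == pytest.approx(50 / 70)

    def test_matches_brute_force_recount(self, sim_table):
        table, _ = sim_table
        codes = gv.encode_table(table)
        tally = gv.tally_codes(table)
        num = sum(1 for c in codes if "u" not in c)
        den = sum(1 for c in codes if "C" in c)
        assert gv.widespread_fraction(tally, "common_in_any") == pytest.approx(num / den)


class TestSubsetToSites:
    def test_subset_preserves_order(self, sim_table):
        table, _ = sim_table
        wanted = [("1", 3), ("1", 7)]
        sub = gv.subset_to_sites(table, wanted)
        assert list(sub.variants["pos"]) == [3, 7]

    def test_absent_sites_silently_skipped(self, sim_table):
        table, _ = sim_table
        sub = gv.subset_to_sites(table, [("1", 3), ("99", 12345)])
        assert len(sub) == 1

    def test_positions_are_one_based(self, sim_table, tmp_path):
        table, _ = sim_table
        # BED is 0-based half-open: interval [2,3) covers 1-based position 3
        bed = tmp_path / "sites.bed"
        bed.write_text("1\t2\t3\n")
        sites = gv.read_site_list(bed)
        assert list(sites["pos"]) == [3]
        assert len(gv.subset_to_sites(table, sites)) == 1
        # off-by-one probe: 0-based positions as 1-based list miss every site
        probe = pd.DataFrame({"chrom": ["1"], "pos": [0]})
        assert len(gv.subset_to_sites(table, probe)) == 0

    def test_allele_aware_matching(self, sim_table):
        table, _ = sim_table
        v = table.variants.iloc[0]
        good = pd.DataFrame({"chrom": [v.chrom], "pos": [v.pos],
                             "ref": [v.ref], "alt": [v.alt]})
        swapped = pd.DataFrame({"chrom": [v.chrom], "pos": [v.pos],
                                "ref": [v.alt], "alt": [v.ref]})
        assert len(gv.subset_to_sites(table, good, match_alleles=True)) == 1
        assert len(gv.subset_to_sites(table, swapped, match_alleles=True)) == 0
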