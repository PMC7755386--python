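"""Panel reading, VCF -> frequency-table conversion, and polarization rules."""

import numpy as np
import pandas as pd
import pytest

import geovar as gv
from geovar.simdata import write_vcf


def make_panel(samples, groups):
    return pd.DataFrame({"sample": samples, "pop": groups, "group": groups})


class TestReadPanel:
    def test_counts_and_first_appearance_order(self):
        g = gv.read_panel(make_panel(["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"]))
        assert g.group_order == ("A", "B")
        assert g.n_diploid == {"A": 2, "B": 2}

    def test_explicit_order_overrides(self):
        g = gv.read_panel(
            make_panel(["s1", "s2"], ["B", "A"]), group_order=["A", "B"]
        )
        assert g.group_order == ("A", "B")

    def test_duplicate_sample_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gv.read_panel(make_panel(["s1", "s1"], ["A", "B"]))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gv.GroupingScheme(("s1",), {"s1": "A"}, ("A", "B"))

    def test_five_region_example_sizes(self):
        g = gv.example_grouping()
        assert g.n_diploid == {"AFR": 504, "EUR": 404, "SAS": 489, "EAS": 504, "AMR": 603}
        assert g.group_order == ("AFR", "EUR", "SAS", "EAS", "AMR")


class TestVcfToFreqTable:
    @pytest.fixture()
    def toy(self, tmp_path):
        samples = ["a1", "a2", "b1", "b2"]
        panel = make_panel(samples, ["A", "A", "B", "B"])
        grouping = gv.read_panel(panel)
        return tmp_path, samples, grouping

    def _write(self, path, rows, samples, ancestral=None):
        meta = pd.DataFrame(
            [(r[0], r[1], r[2], r[3]) for r in rows],
            columns=["chrom", "pos", "ref", "alt"],
        )
        write_vcf(path, meta, [r[4] for r in rows], samples, ancestral=ancestral)

    def test_single_copy_in_one_group(self, toy):
        tmp, samples, grouping = toy
        self._write(tmp / "t.vcf",
                    [("1", 1, "A", "G", ["0/1", "0/0", "0/0", "0/0"])], samples)
        t = gv.vcf_to_freq_table(tmp / "t.vcf", grouping)
        v = t.record(0)
        assert v.allele_counts == {"A": 1, "B": 0}
        assert v.global_freq == pytest.approx(1 / 8)
        assert v.tracked_allele == "G"

    def test_minor_polarization_flips_common_alt(self, toy):
        tmp, samples, grouping = toy
        # ALT at 6/8 = 0.75 -> REF is minor
        self._write(tmp / "t.vcf",
                    [("1", 5, "A", "G", ["1/1", "1/1", "0/1", "0/1"])], samples)
        t = gv.vcf_to_freq_table(tmp / "t.vcf", grouping)
        v = t.record(0)
        assert v.tracked_allele == "A"
        assert v.global_freq == pytest.approx(0.25)

    def test_tie_at_half_tracks_alt(self, toy):
        tmp, samples, grouping = toy
        self._write(tmp / "t.vcf",
                    [("1", 7, "A", "G", ["1/1", "0/0", "0/1", "0/1"])], samples)
        t = gv.vcf_to_freq_table(tmp / "t.vcf", grouping)
        assert t.record(0).tracked_allele == "G"
        assert t.record(0).global_freq == pytest.approx(0.5)

    def test_derived_polarization_keeps_common_derived(self, toy):
        tmp, samples, grouping = toy
        self._write(tmp / "t.vcf",
                    [("1", 9, "A", "G", ["1/1", "1/1", "0/1", "0/1"])],
                    samples, ancestral=["A"])
        t = gv.vcf_to_freq_table(tmp / "t.vcf", grouping, polarization="derived")
        v = t.record(0)
        assert v.tracked_allele == "G"
        assert v.global_freq == pytest.approx(0.75)

    def test_derived_without_ancestral_is_skipped(self, toy):
        tmp, samples, grouping = toy
        self._write(tmp / "t.vcf",
                    [("1", 9, "A", "G", ["1/1", "1/1", "0/1", "0/1"]),
                     ("1", 10, "A", "G", ["0/1", "0/0", "0/0", "0/0"])],
                    samples, ancestral=["T", "A"])  # first AA matches neither allele
        t = gv.vcf_to_freq_table(tmp / "t.vcf", grouping, polarization="derived")
        assert len(t) == 1 and t.record(0).pos == 10

    def test_missing_genotypes_shrink_chrom_counts(self, toy):
        tmp, samples, grouping = toy
        self._write(tmp / "t.vcf",
                    [("1", 3, "A", "G", ["0/1", "./.", "0/0", "0/0"])], samples)
        t = gv.vcf_to_freq_table(tmp / "t.vcf", grouping)
        v = t.record(0)
        assert v.chrom_counts == {"A": 2, "B": 4}
        assert v.allele_counts == {"A": 1, "B": 0}

    def test_non_snv_and_multiallelic_skipped(self, toy):
        tmp, samples, grouping = toy
        self._write(tmp / "t.vcf",
                    [("1", 1, "AT", "A", ["0/1", "0/0", "0/0", "0/0"]),
                     ("1", 2, "A", "G", ["0/1", "0/0", "0/0", "0/0"])], samples)
        t = gv.vcf_to_freq_table(tmp / "t.vcf", grouping)
        assert len(t) == 1 and t.record(0).pos == 2

    def test_vcf_sample_missing_from_panel_errors(self, toy, tmp_path):
        tmp, samples, _ = toy
        small = gv.read_panel(make_panel(["a1", "a2"], ["A", "A"]))
        self._write(tmp / "t.vcf",
                    [("1", 1, "A", "G", ["0/1", "0/0", "0/0", "0/0"])], samples)
        with pytest.raises(ValueError, match="missing from the grouping"):
            gv.vcf_to_freq_table(tmp / "t.vcf", small)


class TestInvariants:
    def test_tsv_round_trip(self, sim_table, tmp_path):
        table, _ = sim_table
        path = tmp_path / "ft.tsv"
        table.to_tsv(path)
        back = gv.FrequencyTable.from_tsv(path)
        assert back.group_order == table.group_order
        assert np.array_equal(back.ac, table.ac)
        assert np.array_equal(back.an, table.an)
        assert np.allclose(back.freqs, table.freqs)

    def test_sample_permutation_invariance(self, sim_vcf_dir, sim_freq_table, tmp_path):
        vcf_lines = open(sim_vcf_dir["vcf"]).read().splitlines()
        header = [l for l in vcf_lines if l.startswith("##")]
        cols = vcf_lines[len(header)].split("\t")
        body = [l.split("\t") for l in vcf_lines[len(header) + 1:]]
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cols) - 9)
        new_cols = cols[:9] + [cols[9 + i] for i in perm]
        new_body = ["\t".join(r[:9] + [r[9 + i] for i in perm]) for r in body]
        shuf = tmp_path / "shuffled.vcf"
        shuf.write_text("\n".join(header + ["\t".join(new_cols)] + new_body) + "\n")
        grouping = gv.read_panel(sim_vcf_dir["panel"])
        t2 = gv.vcf_to_freq_table(shuf, grouping)
        assert np.array_equal(t2.ac, sim_freq_table.ac)
        assert np.array_equal(t2.an, sim_freq_table.an)

    def test_minor_polarization_idempotent_and_bounded(self, sim_freq_table):
        assert np.all(sim_freq_table.global_freq <= 0.5)
        # re-polarizing a minor-polarized table changes nothing: every
        # tracked count is already the smaller one
        gc = sim_freq_table.global_count
        total = sim_freq_table.an.sum(axis=1)
        assert np.all(2 * gc <= total)

    def test_group_frequencies_aggregate_to_global(self, sim_freq_table):
        t = sim_freq_table
        recon = (t.freqs * t.an).sum(axis=1) / t.an.sum(axis=1)
        assert np.allclose(recon, t.global_freq)


class TestSingleton:
    def test_definition_is_count_based(self, sim_table):
        table, _ = sim_table
        for i in range(50):
            v = table.record(i)
            assert gv.is_singleton(v) == (v.global_count == 1)

    def test_count_two_in_one_individual_not_singleton(self):
        v = gv.VariantRecord("1", 1, "A", "G", "G",
                             {"A": 2, "B": 0}, {"A": 4, "B": 4})
        assert not gv.is_singleton(v)

    def test_zero_count_rejected(self):
        v = gv.VariantRecord("1", 1, "A", "G", "G",
                             {"A": 0, "B": 0}, {"A": 4, "B": 4})
        with pytest.raises(ValueError):
            gv.is_singleton(v)
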