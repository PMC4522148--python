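"""LOH calling, typing, locus profiles, candidate regions, territory."""

import numpy as np
import pandas as pd
import pytest

from lohsel import landscape
from lohsel.landscape import ThresholdSet


def track(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "major_cn", "minor_cn"])


def loci_table(rows):
    return pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"])


class TestCallLoh:
    def test_minor_below_half_is_loh(self):
        segs = landscape.call_loh(track([("s1", "chr1", 0, 0.5, 0.4)]))
        assert segs.iloc[0]["loh"]
        assert segs.iloc[0]["loh_type"] == "CNL"  # total 0.9 < 1.5

    def test_allelic_imbalance_excluded(self):
        segs = landscape.call_loh(track([("s1", "chr1", 0, 1.4, 0.6)]))
        assert not segs.iloc[0]["loh"]
        assert segs.iloc[0]["loh_type"] == "none"

    def test_boundary_minor_half_not_loh(self):
        segs = landscape.call_loh(track([("s1", "chr1", 0, 1.5, 0.5)]))
        assert not segs.iloc[0]["loh"]

    def test_cnn_typing_of_neutral_loh(self):
        segs = landscape.call_loh(track([("s1", "chr1", 0, 1.7, 0.2)]))
        assert segs.iloc[0]["loh"]
        assert segs.iloc[0]["loh_type"] == "CNN"

    def test_adjacent_same_state_positions_merge(self):
        t = track(
            [
                ("s1", "chr1", 0, 1.0, 0.1),
                ("s1", "chr1", 10, 1.1, 0.2),
                ("s1", "chr1", 20, 1.0, 0.9),
                ("s1", "chr1", 30, 1.0, 0.1),
            ]
        )
        segs = landscape.call_loh(t)
        assert len(segs) == 3
        assert list(segs["loh"]) == [True, False, True]
        # half-open, boundary at the first probe of the next run
        assert list(segs["start"]) == [0, 20, 30]
        assert list(segs["end"]) == [20, 30, 40]

    def test_segments_partition_without_overlap(self, default_segments):
        for (_, _), grp in default_segments.groupby(["sample", "chrom"]):
            grp = grp.sort_values("start")
            assert (grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1]).all()

    def test_unsorted_track_rejected(self):
        t = track([("s1", "chr1", 10, 1.0, 0.1), ("s1", "chr1", 0, 1.0, 0.1)])
        with pytest.raises(landscape.InputError):
            landscape.call_loh(t)

    def test_recovers_simulated_truth(self, default_cohort, default_segments):
        states, _ = landscape.locus_state_matrix(default_segments, default_cohort.loci)
        truth = np.where(default_cohort.truth_states == 3, 1, default_cohort.truth_states)
        assert (states == truth).mean() > 0.99


class TestClassifyLohType:
    @pytest.mark.parametrize("total,expected", [(1.0, "CNL"), (2.0, "CNN"), (1.5, "CNN")])
    def test_total_copy_boundary(self, total, expected):
        seg = {"loh": True, "total_cn": total}
        assert landscape.classify_loh_type(seg) == expected

    def test_non_loh_segment_is_logic_error(self):
        with pytest.raises(ValueError):
            landscape.classify_loh_type({"loh": False, "total_cn": 1.0})


def _segments_for_profile(n_cnl, n_cnn, n_none):
    rows = []
    i = 0
    for count, loh, typ, total in (
        (n_cnl, True, "CNL", 1.0),
        (n_cnn, True, "CNN", 2.0),
        (n_none, False, "none", 2.0),
    ):
        for _ in range(count):
            rows.append((f"s{i}", "chr1", 0, 100, total, 0.1 if loh else 1.0, loh, typ))
            i += 1
    return pd.DataFrame(rows, columns=landscape.SEGMENT_COLUMNS)


class TestLocusProfiles:
    loci = loci_table([("g1", "chr1", 0, 100)])

    def test_seven_of_ten_cnl_is_enriched(self):
        prof = landscape.locus_profiles(_segments_for_profile(7, 3, 0), self.loci)
        assert prof.iloc[0]["enrichment_class"] == "CNL-enriched"  # 0.7 > 2/3

    def test_six_of_ten_cnl_is_neither(self):
        prof = landscape.locus_profiles(_segments_for_profile(6, 4, 0), self.loci)
        assert prof.iloc[0]["enrichment_class"] == "neither"  # 0.6 <= 2/3

    def test_low_frequency_is_insufficient(self):
        prof = landscape.locus_profiles(_segments_for_profile(3, 0, 17), self.loci)
        assert prof.iloc[0]["loh_frequency"] == pytest.approx(0.15)
        assert prof.iloc[0]["enrichment_class"] == "insufficient"

    def test_no_informative_samples_marked_insufficient(self):
        other = _segments_for_profile(2, 0, 0)
        loci2 = loci_table([("g1", "chr1", 0, 100), ("g2", "chr2", 0, 100)])
        prof = landscape.locus_profiles(other, loci2)
        assert prof.set_index("locus_id").loc["g2", "enrichment_class"] == "insufficient"


class TestCandidateRegions:
    loci = loci_table([("g1", "chr1", 0, 100)])

    def _profiles(self, freq):
        return pd.DataFrame(
            {
                "locus_id": ["g1"],
                "chrom": ["chr1"],
                "n_informative": [20],
                "n_loh": [int(freq * 20)],
                "loh_frequency": [freq],
                "cnl_share_of_loh": [0.5],
                "enrichment_class": ["neither"],
            }
        )

    def test_overall_frequency_selects(self):
        out = landscape.select_candidate_regions(
            self._profiles(0.40), self.loci, _segments_for_profile(0, 0, 2)
        )
        assert out.iloc[0]["selected"]
        assert out.iloc[0]["reason"] == "overall_frequency"

    def test_below_threshold_not_selected(self):
        out = landscape.select_candidate_regions(
            self._profiles(0.30), self.loci, _segments_for_profile(0, 0, 2)
        )
        assert not out.iloc[0]["selected"]

    def test_subtype_frequency_selects(self):
        out = landscape.select_candidate_regions(
            self._profiles(0.30),
            self.loci,
            _segments_for_profile(0, 0, 2),
            subtype_profiles={"clear_cell": self._profiles(0.44)},
        )
        assert out.iloc[0]["selected"]
        assert out.iloc[0]["reason"] == "subtype_frequency:clear_cell"

    def test_recurrent_homozygous_deletion_selects(self):
        homdel = pd.DataFrame(
            [
                ("s1", "chr1", 0, 100, 0.2, 0.05, True, "CNL"),
                ("s2", "chr1", 0, 100, 0.3, 0.05, True, "CNL"),
            ],
            columns=landscape.SEGMENT_COLUMNS,
        )
        out = landscape.select_candidate_regions(self._profiles(0.10), self.loci, homdel)
        assert out.iloc[0]["selected"]
        assert out.iloc[0]["reason"] == "recurrent_homozygous_deletion"

    def test_single_sample_deletion_does_not_select(self):
        homdel = pd.DataFrame(
            [("s1", "chr1", 0, 100, 0.2, 0.05, True, "CNL")],
            columns=landscape.SEGMENT_COLUMNS,
        )
        out = landscape.select_candidate_regions(self._profiles(0.10), self.loci, homdel)
        assert not out.iloc[0]["selected"]


class TestTerritoryFractions:
    loci = loci_table([("g1", "chr1", 0, 100), ("g2", "chr1", 100, 200), ("g3", "chr2", 0, 100)])

    def test_no_loh(self):
        segs = pd.DataFrame(
            [("s1", "chr1", 0, 200, 2.0, 1.0, False, "none")],
            columns=landscape.SEGMENT_COLUMNS,
        )
        assert landscape.sample_territory_fractions(segs, self.loci) == (0.0, 0.0, 0.0)

    def test_whole_territory_cnl(self):
        segs = pd.DataFrame(
            [
                ("s1", "chr1", 0, 200, 1.0, 0.1, True, "CNL"),
                ("s1", "chr2", 0, 100, 1.0, 0.1, True, "CNL"),
            ],
            columns=landscape.SEGMENT_COLUMNS,
        )
        assert landscape.sample_territory_fractions(segs, self.loci) == (1.0, 1.0, 0.0)

    def test_one_gene_of_three_in_cnn(self):
        segs = pd.DataFrame(
            [("s1", "chr2", 0, 100, 2.0, 0.1, True, "CNN")],
            columns=landscape.SEGMENT_COLUMNS,
        )
        overall, cnl, cnn = landscape.sample_territory_fractions(segs, self.loci)
        assert (overall, cnl, cnn) == (pytest.approx(1 / 3), 0.0, pytest.approx(1 / 3))

    def test_overall_is_exact_sum_of_types(self, default_cohort, default_segments):
        table = landscape.territory_table(default_segments, default_cohort.loci)
        assert np.allclose(table["frac_loh"], table["frac_cnl"] + table["frac_cnn"])


class TestRoundTrip:
    def test_segment_table_io(self, default_segments, tmp_path):
        path = tmp_path / "segments.tsv"
        landscape.write_segments(default_segments, path)
        back = landscape.read_segments(path)
        pd.testing.assert_frame_equal(
            back, default_segments.sort_values(["sample", "chrom", "start"]).reset_index(drop=True)
        )

    def test_loci_bed_io(self, default_cohort, tmp_path):
        path = tmp_path / "loci.bed"
        landscape.write_loci_bed(default_cohort.loci, path)
        back = landscape.read_loci_bed(path)
        pd.testing.assert_frame_equal(
            back, default_cohort.loci[["chrom", "start", "end", "locus_id"]]
        )
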