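"""Somatic filtering, classification, biallelic status, gene screen."""

import numpy as np
import pandas as pd
import pytest

from lohsel import landscape, screen, stats


def call(**kw):
    base = dict(called_in_normal=False, n_alt_count=0, t_fwd_count=4, t_rev_count=3)
    base.update(kw)
    return base


class TestSomaticFilter:
    def test_clean_call_accepted(self):
        assert screen.somatic_filter(call()) == (True, "pass")

    def test_two_normal_reads_rejected(self):
        assert screen.somatic_filter(call(n_alt_count=2)) == (False, "normal_support")

    def test_unidirectional_rejected(self):
        assert screen.somatic_filter(call(t_fwd_count=5, t_rev_count=0)) == (
            False,
            "unidirectional",
        )

    def test_germline_call_rejected(self):
        assert screen.somatic_filter(call(called_in_normal=True))[1] == "germline_call"

    def test_vectorised_filter_matches_scalar_and_is_idempotent(self):
        df = pd.DataFrame(
            [
                call(),
                call(n_alt_count=3),
                call(t_rev_count=0),
                call(called_in_normal=True),
                call(n_alt_count=1),
            ]
        )
        out = screen.filter_calls(df)
        expect = [screen.somatic_filter(r) for r in df.to_dict("records")]
        assert list(out["accepted"]) == [e[0] for e in expect]
        assert list(out["reason"]) == [e[1] for e in expect]
        again = screen.filter_calls(df.iloc[::-1].reset_index(drop=True))
        assert list(again["accepted"]) == [e[0] for e in expect[::-1]]


class TestClassify:
    @pytest.mark.parametrize(
        "conseq,expected",
        [
            ("nonsense", "deleterious"),
            ("frameshift", "deleterious"),
            ("essential_splice", "deleterious"),
            ("missense", "non_synonymous_other"),
            ("inframe_indel", "non_synonymous_other"),
            ("synonymous", "synonymous"),
        ],
    )
    def test_consequence_mapping(self, conseq, expected):
        assert screen.classify_mutation(conseq) == expected

    def test_unknown_tag(self):
        with pytest.raises(ValueError):
            screen.classify_mutation("startgain")


LOCI = pd.DataFrame(
    {"locus_id": ["gA", "gB"], "chrom": ["chr1", "chr1"], "start": [0, 100], "end": [100, 200]}
)


def seg(sample, start, end, total, loh, typ):
    return (sample, "chr1", start, end, total, 0.1 if loh else 1.0, loh, typ)


def mut(sample, gene, pos, klass="non_synonymous_other", in_loh=False, loh_type="none"):
    return {
        "sample": sample,
        "gene": gene,
        "chrom": "chr1",
        "pos": pos,
        "class": klass,
        "in_loh": in_loh,
        "loh_type": loh_type,
    }


class TestBiallelicStatus:
    def test_mutation_in_loh_is_two_hit(self):
        muts = pd.DataFrame([mut("s1", "gA", 10, in_loh=True, loh_type="CNN")])
        segs = pd.DataFrame([seg("s1", 0, 100, 2.0, True, "CNN")], columns=landscape.SEGMENT_COLUMNS)
        assert screen.biallelic_status("gA", "s1", muts, segs, LOCI) == "biallelic_mut_loh"

    def test_single_mutation_without_loh_is_monoallelic(self):
        muts = pd.DataFrame([mut("s1", "gA", 10)])
        segs = pd.DataFrame([seg("s1", 0, 200, 2.0, False, "none")], columns=landscape.SEGMENT_COLUMNS)
        assert screen.biallelic_status("gA", "s1", muts, segs, LOCI) == "monoallelic"

    def test_homozygous_deletion_without_point_mutation(self):
        muts = pd.DataFrame([], columns=list(mut("s", "g", 0)))
        segs = pd.DataFrame([seg("s1", 0, 100, 0.2, True, "CNL")], columns=landscape.SEGMENT_COLUMNS)
        assert screen.biallelic_status("gA", "s1", muts, segs, LOCI) == "biallelic_homdel"

    def test_two_distinct_mutations(self):
        muts = pd.DataFrame([mut("s1", "gA", 10), mut("s1", "gA", 55)])
        segs = pd.DataFrame([seg("s1", 0, 200, 2.0, False, "none")], columns=landscape.SEGMENT_COLUMNS)
        assert screen.biallelic_status("gA", "s1", muts, segs, LOCI) == "biallelic_two_mut"

    def test_unmutated(self):
        muts = pd.DataFrame([], columns=list(mut("s", "g", 0)))
        segs = pd.DataFrame([seg("s1", 0, 200, 2.0, False, "none")], columns=landscape.SEGMENT_COLUMNS)
        assert screen.biallelic_status("gA", "s1", muts, segs, LOCI) == "unmutated"


class TestRecurrenceTest:
    def test_zero_count_is_one(self):
        assert screen.gene_recurrence_test(0, 1000, 1e-6, 50) == 1.0

    def test_count_at_expectation_not_small(self):
        # expectation = 1e-4 * 1000 * 50 = 5
        assert screen.gene_recurrence_test(5, 1000, 1e-4, 50) >= 0.5

    def test_monotone_decreasing_in_count(self):
        ps = [screen.gene_recurrence_test(k, 1000, 1e-4, 50) for k in range(0, 30)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


class TestBiallelicBands:
    def _screen_one_gene(self, n_samples, n_biallelic):
        """Gene mutated in n_samples, first n_biallelic carriers in CNN-LOH."""
        muts, segs = [], []
        for i in range(n_samples):
            loh = i < n_biallelic
            muts.append(mut(f"s{i}", "gA", 10, "deleterious" if i % 2 else "synonymous",
                            in_loh=loh, loh_type="CNN" if loh else "none"))
            segs.append(seg(f"s{i}", 0, 200, 2.0, loh, "CNN" if loh else "none"))
        out = screen.screen_genes(
            pd.DataFrame(muts), pd.DataFrame(segs, columns=landscape.SEGMENT_COLUMNS), LOCI
        )
        return out.iloc[0]

    def test_all_five_biallelic_is_gt80(self):
        assert self._screen_one_gene(5, 5)["biallelic_band"] == "gt80"

    def test_exactly_080_falls_in_lower_band(self):
        assert self._screen_one_gene(5, 4)["biallelic_band"] == "band60_80"

    def test_two_of_two(self):
        assert self._screen_one_gene(2, 2)["biallelic_band"] == "two_of_two"

    def test_below_band(self):
        assert self._screen_one_gene(5, 2)["biallelic_band"] == "below"


class TestDeleteriousMajority:
    def _gene_with_classes(self, classes):
        muts = [
            mut(f"s{i}", "gA", 10 + i, klass) for i, klass in enumerate(classes)
        ]
        segs = [seg(f"s{i}", 0, 200, 2.0, False, "none") for i in range(len(classes))]
        out = screen.screen_genes(
            pd.DataFrame(muts), pd.DataFrame(segs, columns=landscape.SEGMENT_COLUMNS), LOCI
        )
        return bool(out.iloc[0]["deleterious_majority"])

    def test_exactly_half_is_not_majority(self):
        assert not self._gene_with_classes(
            ["deleterious", "deleterious", "non_synonymous_other", "synonymous"]
        )

    def test_three_of_four_is_majority(self):
        assert self._gene_with_classes(
            ["deleterious", "deleterious", "deleterious", "synonymous"]
        )


class TestWildtypeLohRates:
    def test_published_fractions_reproduce(self):
        rows = []
        # non-synonymous: 134/381 in LOH; synonymous: 47/139
        for i in range(381):
            rows.append(mut(f"s{i%40}", "gA", i, "non_synonymous_other", in_loh=i < 134))
        for i in range(139):
            rows.append(mut(f"s{i%40}", "gB", 1000 + i, "synonymous", in_loh=i < 47))
        table, res = screen.wildtype_loh_rates(pd.DataFrame(rows))
        t = table.set_index("class")
        assert round(100 * t.loc["non_synonymous", "fraction"], 1) == 35.2
        assert round(100 * t.loc["synonymous", "fraction"], 1) == 33.8
        assert res.p_value > 0.05  # no significant difference between classes

    def test_identical_classes_give_p_one(self):
        rows = [
            mut("s1", "gA", 10 * j + i, k, in_loh=i < 5)
            for j, k in enumerate(["synonymous", "non_synonymous_other"])
            for i in range(10)
        ]
        table, res = screen.wildtype_loh_rates(pd.DataFrame(rows))
        t = table.set_index("class")
        assert t.loc["non_synonymous", "fraction"] == t.loc["synonymous", "fraction"]
        assert res.p_value == pytest.approx(1.0)

    def test_all_in_loh_is_degenerate_no_test(self):
        rows = [mut("s1", "gA", i, k, in_loh=True)
                for i, k in enumerate(["synonymous", "non_synonymous_other"] * 5)]
        table, res = screen.wildtype_loh_rates(pd.DataFrame(rows))
        assert table.set_index("class").loc["non_synonymous", "fraction"] == 1.0
        assert res is None  # zero margin: no chi-squared defined

    def test_biallelic_counts_bounded_by_carriers(self, strong_results):
        scr = strong_results["screen"]
        assert (scr["n_biallelic"] <= scr["n_mutated_samples"]).all()

    def test_planted_two_hit_gene_flagged_by_all_filters(self, strong_cohort, strong_results):
        gene = strong_cohort.loci.iloc[strong_cohort.config.two_hit_locus]["locus_id"]
        row = strong_results["screen"].set_index("gene").loc[gene]
        assert {"recurrence", "biallelic", "deleterious"} <= set(row["flags"].split(","))


class TestMafRoundTrip:
    def test_accepted_mutations_roundtrip(self, strong_results, tmp_path):
        muts = strong_results["mutations"]
        path = tmp_path / "m.maf"
        screen.write_maf(muts, path)
        back = screen.read_maf(path)
        for col in ("sample", "gene", "pos", "consequence", "class"):
            assert list(back[col]) == list(muts[col])
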