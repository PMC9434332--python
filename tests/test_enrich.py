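"""Contingency building, Fisher test, multiple-testing correction, ranking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_stepup, bonferroni, hypergeom_tail_exact, naive_overlap_hits
from ciscross.annotation import PromoterSet, build_promoters
from ciscross.enrich import (
    ContingencyTable,
    adjust_pvalues,
    ciscross_light,
    compare_regulator_lists,
    fisher_enrichment_p,
    gene_to_tf_table,
    promoter_hits,
    run_ciscross_main,
)
from ciscross.intervals import Interval
from ciscross.peaks import PeakCollection, PeakSet


def promoter_set(proms: dict) -> PromoterSet:
    d = {gid: Interval(c, s, e, name=gid, strand="+") for gid, (c, s, e) in proms.items()}
    return PromoterSet(length=500, promoters=d, universe=set(d))


class TestPromoterHits:
    def test_half_open_overlap_semantics(self):
        ps = promoter_set({"G1": ("c", 500, 1000)})
        assert promoter_hits(PeakSet("x", [Interval("c", 999, 1200)]), ps) == {"G1"}
        assert promoter_hits(PeakSet("x", [Interval("c", 1000, 1200)]), ps) == set()
        assert promoter_hits(PeakSet("x", [Interval("c", 300, 500)]), ps) == set()

    def test_matches_naive_all_pairs_scan(self):
        rng = np.random.default_rng(2)
        proms = {f"G{i}": ("c1" if i % 2 else "c2", int(s), int(s) + 400)
                 for i, s in enumerate(rng.integers(0, 50_000, 150))}
        peaks = [Interval("c1" if int(x) % 3 else "c2", int(s), int(s + l))
                 for x, s, l in zip(rng.integers(0, 3, 400),
                                    rng.integers(0, 50_200, 400),
                                    rng.integers(20, 300, 400))]
        ps = promoter_set(proms)
        assert promoter_hits(PeakSet("x", peaks), ps) == naive_overlap_hits(
            dict(ps.promoters), peaks)


class TestFisher:
    def test_zero_hits_gives_exactly_one(self):
        assert fisher_enrichment_p(ContingencyTable(0, 10, 5, 25)) == 1.0

    def test_all_foreground_hit_no_background_hit(self):
        # single arrangement out of C(10,5) equally likely ones
        p = fisher_enrichment_p(ContingencyTable(5, 0, 0, 5))
        assert p == pytest.approx(1 / 252, abs=1e-15)

    def test_matches_exact_enumeration_on_small_tables(self):
        for a, b, c, d in itertools.product(range(0, 7), repeat=4):
            expected = hypergeom_tail_exact(a, b, c, d)
            assert fisher_enrichment_p(ContingencyTable(a, b, c, d)) == pytest.approx(
                expected, abs=1e-12)

    def test_two_sided_option_matches_scipy(self):
        from scipy.stats import fisher_exact
        t = ContingencyTable(8, 2, 3, 9)
        assert fisher_enrichment_p(t, alternative="two-sided") == pytest.approx(
            fisher_exact([[8, 2], [3, 9]], "two-sided")[1])


class TestAdjustPvalues:
    def test_worked_examples(self):
        assert adjust_pvalues([0.03], "BH") == pytest.approx([0.03])
        assert adjust_pvalues([0.03], "bonferroni") == pytest.approx([0.03])
        assert adjust_pvalues([0.01, 0.02, 0.03], "BH") == pytest.approx([0.03, 0.03, 0.03])
        assert adjust_pvalues([0.01, 0.5], "bonferroni") == pytest.approx([0.02, 1.0])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False), min_size=1, max_size=40))
    def test_bh_never_below_raw_and_bonferroni_dominates(self, pvals):
        bh = adjust_pvalues(pvals, "BH")
        bonf = adjust_pvalues(pvals, "bonferroni")
        assert np.all(bh >= np.asarray(pvals) - 1e-15)
        assert np.all(bonf >= bh - 1e-12)
        assert np.all(bh <= 1.0) and np.all(bonf <= 1.0)

    def test_bh_invariant_under_permutation(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, 30)
        perm = rng.permutation(30)
        assert adjust_pvalues(p[perm], "BH") == pytest.approx(adjust_pvalues(p, "BH")[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5])


class TestRunMain:
    def test_planted_regulator_ranks_first(self, small_fixture):
        proms = build_promoters(small_fixture.annotation, small_fixture.spec.promoter_length)
        res = run_ciscross_main(small_fixture.foreground, proms, small_fixture.collection)
        assert res[0].peak_set_name in small_fixture.truth
        assert res[0].rank == 1 and res[0].p_adj < 0.05
        assert [r.rank for r in res] == list(range(1, len(small_fixture.collection) + 1))

    def test_degenerate_collection_with_no_hits(self):
        ps = promoter_set({"G1": ("c", 100, 200), "G2": ("c", 400, 500), "G3": ("c", 800, 900)})
        coll = PeakCollection("t")
        coll.add(PeakSet("empty", [Interval("c", 5000, 5100)]))
        res = run_ciscross_main(["G1"], ps, coll)
        assert res[0].p_raw == 1.0 and res[0].p_adj == 1.0 and res[0].rank == 1
        assert res[0].table == ContingencyTable(0, 1, 0, 2)

    def test_output_invariant_to_peak_set_order(self, small_fixture):
        proms = build_promoters(small_fixture.annotation, small_fixture.spec.promoter_length)
        coll = small_fixture.collection
        res1 = run_ciscross_main(small_fixture.foreground, proms, coll)
        shuffled = PeakCollection(coll.version_label)
        for name in sorted(coll.peak_sets, reverse=True):
            shuffled.add(coll.peak_sets[name])
        res2 = run_ciscross_main(small_fixture.foreground, proms, shuffled)
        key = lambda res: {r.peak_set_name: (r.p_raw, r.p_adj, r.rank) for r in res}
        assert key(res1) == key(res2)

    def test_foreground_size_constant_and_null_set_harmless(self, small_fixture):
        proms = build_promoters(small_fixture.annotation, small_fixture.spec.promoter_length)
        res = run_ciscross_main(small_fixture.foreground, proms, small_fixture.collection)
        fg_sizes = {r.table.a + r.table.b for r in res}
        assert len(fg_sizes) == 1
        # adding a peak set that can hit nothing never improves another set's raw p
        plus = PeakCollection("t2")
        for s in small_fixture.collection:
            plus.add(s)
        plus.add(PeakSet("nowhere", [Interval("ChrNope", 0, 100)]))
        res2 = run_ciscross_main(small_fixture.foreground, proms, plus)
        raw1 = {r.peak_set_name: r.p_raw for r in res}
        raw2 = {r.peak_set_name: r.p_raw for r in res2}
        assert all(raw2[n] == raw1[n] for n in raw1)
        assert raw2["nowhere"] == 1.0

    def test_unknown_ids_dropped_with_warning_and_all_unknown_errors(self, small_fixture, caplog):
        import logging
        proms = build_promoters(small_fixture.annotation, small_fixture.spec.promoter_length)
        genes = small_fixture.foreground + ["NOT_A_GENE"]
        with caplog.at_level(logging.WARNING, logger="ciscross"):
            res = run_ciscross_main(genes, proms, small_fixture.collection)
        assert any("NOT_A_GENE" in r.message for r in caplog.records)
        assert res[0].table.a + res[0].table.b == len(small_fixture.foreground)
        with pytest.raises(ValueError, match="NOPE"):
            run_ciscross_main(["NOPE"], proms, small_fixture.collection)

    def test_foreground_covering_universe_errors(self):
        ps = promoter_set({"G1": ("c", 100, 200), "G2": ("c", 400, 500)})
        coll = PeakCollection("t")
        coll.add(PeakSet("s", [Interval("c", 100, 150)]))
        with pytest.raises(ValueError, match="universe"):
            run_ciscross_main(["G1", "G2"], ps, coll)

    def test_duplicate_and_case_variant_input_ids_collapse(self):
        ps = promoter_set({"G1": ("c", 100, 200), "G2": ("c", 400, 500), "G3": ("c", 800, 900)})
        coll = PeakCollection("t")
        coll.add(PeakSet("s", [Interval("c", 150, 160)]))
        res = run_ciscross_main(["g1", "G1 ", "G1"], ps, coll)
        assert res[0].table == ContingencyTable(1, 0, 0, 2)


class TestLightMode:
    def test_enumerates_every_overlapping_peak(self):
        ps = promoter_set({"G1": ("c", 500, 1000), "G2": ("c", 2000, 2500)})
        coll = PeakCollection("t")
        coll.add(PeakSet("s1", [Interval("c", 600, 650), Interval("c", 900, 1100),
                                Interval("c", 3000, 3100)], tf_id="TFA"))
        coll.add(PeakSet("s2", [Interval("c", 400, 501)], tf_id="TFB"))
        table = ciscross_light("G1", ps, coll)
        assert len(table) == 3
        assert sorted(table.peak_set) == ["s1", "s1", "s2"]
        assert set(table.columns) == {"peak_set", "tf_id", "chrom", "start", "end"}

    def test_unknown_gene_errors_naming_the_id(self, small_fixture):
        proms = build_promoters(small_fixture.annotation, 500)
        with pytest.raises(KeyError, match="ATXGX"):
            ciscross_light("ATXGX", proms, small_fixture.collection)

    def test_consistent_with_promoter_hits(self, small_fixture):
        proms = build_promoters(small_fixture.annotation, small_fixture.spec.promoter_length)
        rng = np.random.default_rng(4)
        genes = rng.choice(sorted(proms.universe), size=30, replace=False)
        hits_by_set = {ps.name: promoter_hits(ps, proms) for ps in small_fixture.collection}
        for gid in genes:
            light = ciscross_light(gid, proms, small_fixture.collection)
            light_sets = set(light.peak_set)
            for name, hits in hits_by_set.items():
                assert (gid in hits) == (name in light_sets)

    def test_gene_to_tf_counts_match_light_rows(self, small_fixture):
        proms = build_promoters(small_fixture.annotation, small_fixture.spec.promoter_length)
        genes = small_fixture.foreground
        table = gene_to_tf_table(genes, proms, small_fixture.collection)
        for row in table.itertuples(index=False):
            light = ciscross_light(row.gene, proms, small_fixture.collection)
            assert (light.peak_set == row.peak_set).sum() == row.n_peaks_in_promoter


class TestCompareRegulatorLists:
    def r(self, name, p_adj):
        from ciscross.enrich import EnrichmentResult
        return EnrichmentResult(name, "", "", ContingencyTable(1, 1, 1, 1),
                                p_adj, p_adj, 1, set())

    def test_identity_disjoint_and_partial(self):
        a = [self.r(n, 0.01) for n in "xyz"]
        b = [self.r(n, 0.01) for n in "yzw"]
        assert compare_regulator_lists(a, a).percent == 100.0
        assert compare_regulator_lists(a, b).percent == pytest.approx(50.0)  # 2 shared / 4 union
        c = [self.r(n, 0.01) for n in "uv"]
        assert compare_regulator_lists(a, c).percent == 0.0

    def test_both_empty_flagged_as_identical(self):
        a = [self.r("x", 0.9)]
        out = compare_regulator_lists(a, a)
        assert out.percent == 100.0 and out.both_empty
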