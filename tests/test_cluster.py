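"""The clustering statistic: gaps, sweep counts, null, groupings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gencluster import (ClusterParams, GeneList, GeneRecord, GenomeAnnotation,
                        SimConfig, ValidationError, bh_adjust,
                        cluster_groupings, count_clustered_genes,
                        count_clustered_pairs, enrichment, fdr_over_lists,
                        gene_gap, null_distribution, plant_clustered_list)
from gencluster.synthetic import simulate_genome

from _oracles import (brute_force_clustered_genes, brute_force_components,
                      brute_force_pairs)
from conftest import random_sublist


class TestGeneGap:
    def test_intervening_bases(self):
        a = GeneRecord("A", "chr2L", 1000, 3000)
        b = GeneRecord("B", "chr2L", 12500, 14000)
        assert gene_gap(a, b) == 9499
        assert gene_gap(b, a) == 9499

    def test_overlap_gives_zero(self):
        a = GeneRecord("A", "chr2L", 1000, 3000)
        b = GeneRecord("B", "chr2L", 2500, 4000)
        assert gene_gap(a, b) == 0

    def test_touching_gives_zero(self):
        a = GeneRecord("A", "chr2L", 1000, 3000)
        b = GeneRecord("B", "chr2L", 3001, 4000)
        assert gene_gap(a, b) == 0

    def test_cross_chromosome_undefined(self):
        a = GeneRecord("A", "chr2L", 1000, 3000)
        d = GeneRecord("D", "chr3R", 1000, 3000)
        assert gene_gap(a, d) is None


class TestCounts:
    def test_three_gene_example(self, toy_annotation, toy_list):
        params = ClusterParams(window=10_000)
        # A-B and B-C are 9,499 bp apart; A-C is 20,499; D elsewhere
        assert count_clustered_pairs(toy_list, toy_annotation, params) == 2
        assert count_clustered_genes(toy_list, toy_annotation, params) == 3

    def test_single_gene_no_pairs(self, toy_annotation):
        gl = GeneList("one", "all", ("A",))
        assert count_clustered_pairs(gl, toy_annotation) == 0

    def test_two_overlapping_genes(self):
        ann = GenomeAnnotation([GeneRecord("A", "c", 100, 500),
                                GeneRecord("B", "c", 300, 900)])
        gl = GeneList("b", "all", ("A", "B"))
        assert count_clustered_pairs(gl, ann) == 1
        assert count_clustered_genes(gl, ann) == 2

    def test_unknown_ids_dropped_with_warning(self, toy_annotation, caplog):
        gl = GeneList("x", "all", ("A", "B", "ghost"))
        with caplog.at_level("WARNING"):
            assert count_clustered_pairs(gl, toy_annotation) == 1
        assert "dropped 1" in caplog.text

    def test_order_independence(self, small_genome):
        rng = np.random.default_rng(31)
        gl = random_sublist(small_genome, 60, rng)
        shuffled = GeneList("s", "all",
                            tuple(rng.permutation(np.array(gl.ids, dtype=object))))
        assert count_clustered_pairs(gl, small_genome) == \
            count_clustered_pairs(shuffled, small_genome)

    def test_sweep_equals_brute_force_randomized(self, small_genome):
        rng = np.random.default_rng(32)
        for _ in range(150):
            size = int(rng.integers(2, 120))
            window = int(rng.choice([0, 500, 5_000, 10_000, 50_000]))
            gl = random_sublist(small_genome, size, rng)
            records = [small_genome.get(g) for g in gl.ids]
            params = ClusterParams(window=window)
            assert count_clustered_pairs(gl, small_genome, params) == \
                brute_force_pairs(records, window)
            assert count_clustered_genes(gl, small_genome, params) == \
                brute_force_clustered_genes(records, window)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_sweep_equals_brute_force_adversarial(self, data):
        """Small adversarial interval sets, including ties and containment."""
        n = data.draw(st.integers(2, 12))
        records = []
        for i in range(n):
            chrom = data.draw(st.sampled_from(["c1", "c2"]))
            start = data.draw(st.integers(1, 300))
            end = start + data.draw(st.integers(0, 300))
            records.append(GeneRecord(f"g{i}", chrom, start, end))
        window = data.draw(st.integers(0, 200))
        ann = GenomeAnnotation(records)
        gl = GeneList("h", "all", tuple(r.gene_id for r in records))
        params = ClusterParams(window=window)
        assert count_clustered_pairs(gl, ann, params) == \
            brute_force_pairs(records, window)
        assert count_clustered_genes(gl, ann, params) == \
            brute_force_clustered_genes(records, window)

    def test_adding_a_gene_never_decreases_counts(self, small_genome):
        rng = np.random.default_rng(33)
        for _ in range(20):
            gl = random_sublist(small_genome, 40, rng)
            extra = next(g for g in small_genome.ids if g not in gl)
            bigger = GeneList("b", "all", gl.ids + (extra,))
            for counter in (count_clustered_pairs, count_clustered_genes):
                assert counter(bigger, small_genome) >= \
                    counter(gl, small_genome)


class TestNullDistribution:
    def test_exhaustive_list_has_zero_sd(self, small_genome):
        params = ClusterParams(n_random=20, seed=41)
        null = null_distribution(len(small_genome), small_genome, params)
        assert null.std() == 0

    def test_list_of_one_scores_zero(self, small_genome):
        null = null_distribution(1, small_genome,
                                 ClusterParams(n_random=50, seed=42))
        assert (null == 0).all()

    def test_oversized_list_rejected(self, small_genome):
        with pytest.raises(ValidationError):
            null_distribution(len(small_genome) + 1, small_genome)

    def test_deterministic_under_seed(self, small_genome):
        params = ClusterParams(n_random=50, seed=43)
        a = null_distribution(30, small_genome, params)
        b = null_distribution(30, small_genome, params)
        assert (a == b).all()

    def test_null_mean_matches_large_resample_oracle(self, small_genome):
        """Mean of 500 sweep-scored draws agrees with the mean of 10,000
        independently brute-force-scored draws of the same size."""
        rng = np.random.default_rng(44)
        df = small_genome.to_frame()
        chroms = df["chrom"].to_numpy(dtype=object)
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        window = 10_000

        def brute(idx):
            c, s, e = chroms[idx], starts[idx], ends[idx]
            same = c[:, None] == c[None, :]
            i_earlier = s[:, None] <= s[None, :]
            gap = np.where(i_earlier, s[None, :] - e[:, None] - 1,
                           s[:, None] - e[None, :] - 1)
            hit = same & (np.maximum(gap, 0) <= window)
            np.fill_diagonal(hit, False)
            return hit.sum() // 2

        scores = np.array([brute(rng.choice(len(df), 50, replace=False))
                           for _ in range(10_000)])
        params = ClusterParams(n_random=500, seed=45)
        null = null_distribution(50, small_genome, params)
        # compare means allowing for both samples' Monte-Carlo error
        se = np.hypot(null.std(ddof=1) / np.sqrt(null.size),
                      scores.std(ddof=1) / np.sqrt(scores.size))
        assert abs(null.mean() - scores.mean()) < 3.5 * se


class TestEnrichment:
    def test_ratio_arithmetic_and_p_floor(self, small_genome):
        rng = np.random.default_rng(46)
        gl = random_sublist(small_genome, 40, rng)
        res = enrichment(gl, small_genome,
                         ClusterParams(n_random=100, seed=47))
        if res.null_mean > 0:
            assert res.ratio == pytest.approx(res.observed / res.null_mean)
        assert res.p_emp >= 1 / 101

    def test_observed_zero_gives_p_one(self, toy_annotation):
        gl = GeneList("far", "all", ("A", "C"))  # 20,499 bp apart
        res = enrichment(gl, toy_annotation,
                         ClusterParams(n_random=30, seed=48))
        assert res.observed == 0
        assert res.p_emp == 1.0

    def test_empty_list_reports_na_ratio(self, toy_annotation, caplog):
        gl = GeneList("none", "all", ())
        with caplog.at_level("WARNING"):
            res = enrichment(gl, toy_annotation,
                             ClusterParams(n_random=10, seed=49))
        assert res.observed == 0 and res.ratio is None

    def test_planted_list_strongly_enriched(self, small_genome):
        gl, _ = plant_clustered_list(small_genome, 6, 4, 0, seed=50)
        res = enrichment(gl, small_genome,
                         ClusterParams(n_random=200, seed=51))
        assert res.ratio is not None and res.ratio > 5
        assert res.p_emp == 1 / 201


class TestFdrOverLists:
    def test_single_result_fdr_equals_p(self, small_genome):
        rng = np.random.default_rng(52)
        res = enrichment(random_sublist(small_genome, 20, rng), small_genome,
                         ClusterParams(n_random=50, seed=53))
        (out,) = fdr_over_lists([res])
        assert out.fdr == pytest.approx(out.p_emp)

    def test_matches_bh_adjust(self, small_genome):
        rng = np.random.default_rng(54)
        results = [enrichment(random_sublist(small_genome, s, rng),
                              small_genome, ClusterParams(n_random=50, seed=55 + s))
                   for s in (10, 25, 40, 80)]
        out = fdr_over_lists(results)
        expected = bh_adjust([r.p_emp for r in results])
        np.testing.assert_allclose([r.fdr for r in out], expected)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            fdr_over_lists([])


class TestGroupings:
    def test_transitive_chain_is_one_component(self):
        # A-B and B-C clustered, A-C not: one component of three genes
        ann = GenomeAnnotation([GeneRecord("A", "c", 1000, 2000),
                                GeneRecord("B", "c", 8000, 9000),
                                GeneRecord("C", "c", 15000, 16000)])
        gl = GeneList("chain", "all", ("A", "B", "C"))
        grouping = cluster_groupings(gl, ann, ClusterParams(window=6000))
        assert grouping.components == (("A", "B", "C"),)

    def test_no_pairs_gives_empty_grouping(self, toy_annotation):
        gl = GeneList("far", "all", ("A", "C", "D"))
        grouping = cluster_groupings(gl, toy_annotation)
        assert grouping.components == ()

    def test_matches_union_find_oracle(self, small_genome):
        rng = np.random.default_rng(56)
        for _ in range(40):
            gl = random_sublist(small_genome, int(rng.integers(2, 80)), rng)
            window = int(rng.choice([1_000, 10_000, 40_000]))
            grouping = cluster_groupings(gl, small_genome,
                                         ClusterParams(window=window))
            records = [small_genome.get(g) for g in gl.ids]
            expected = brute_force_components(records, window)
            got = sorted((frozenset(c) for c in grouping.components),
                         key=lambda s: sorted(s))
            assert got == expected

    def test_planted_clusters_recovered_exactly(self, small_genome):
        gl, truth = plant_clustered_list(small_genome, 5, 3, 0, seed=57)
        grouping = cluster_groupings(gl, small_genome)
        planted = {}
        for g, k in truth.planted_cluster_map.items():
            planted.setdefault(k, set()).add(g)
        assert sorted(map(frozenset, grouping.components),
                      key=sorted) == sorted(map(frozenset, planted.values()),
                                            key=sorted)

    def test_components_numbered_by_position(self, small_genome):
        gl, _ = plant_clustered_list(small_genome, 4, 3, 0, seed=58)
        grouping = cluster_groupings(gl, small_genome)
        keys = [(small_genome.get(c[0]).chrom, small_genome.get(c[0]).start)
                for c in grouping.components]
        assert keys == sorted(keys)
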