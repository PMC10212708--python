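"""Allelic status calling, aggregation, the status map, and the positional test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import xciprof as xp
from conftest import make_calls


class TestAggregation:
    def _records(self, spec):
        recs = []
        for i, (gene, n_ref, n_alt) in enumerate(spec):
            site = xp.SnpSite("chrX", 1000 + i * 100, "A", "G", gene)
            recs.append(xp.AlleleCountRecord(site, n_ref, n_alt))
        return recs

    def test_counts_summed_over_gene_sites(self):
        agg = xp.aggregate_site_counts_to_gene(
            self._records([("g1", 10, 0), ("g1", 8, 2), ("g2", 3, 3)])
        )
        assert tuple(agg.loc["g1"]) == (18, 2, 20)
        assert tuple(agg.loc["g2"]) == (3, 3, 6)

    def test_pooled_frequency_is_depth_weighted_mean(self):
        rng = np.random.default_rng(0)
        spec = [("g", int(a), int(b)) for a, b in rng.integers(1, 50, (10, 2))]
        agg = xp.aggregate_site_counts_to_gene(self._records(spec))
        pooled = agg.loc["g", "n_ref"] / agg.loc["g", "depth"]
        freqs = np.array([a / (a + b) for _, a, b in spec])
        weights = np.array([a + b for _, a, b in spec], dtype=float)
        assert pooled == pytest.approx(np.average(freqs, weights=weights))

    def test_error_records_excluded(self):
        recs = self._records([("g1", 5, 5)])
        recs.append(
            xp.AlleleCountRecord(xp.SnpSite("chr9", 1, "A", "G", "g2"),
                                 0, 0, status="missing_contig")
        )
        agg = xp.aggregate_site_counts_to_gene(recs)
        assert list(agg.index) == ["g1"]


class TestClassifyAllelicStatus:
    @pytest.mark.parametrize(
        "ref_freq,fpkm,depth,expected",
        [
            (0.50, 10, 100, "biallelic"),
            (0.90, 10, 100, "monoallelic"),
            (0.50, 0.5, 100, "not_expressed"),
            (0.249, 10, 100, "monoallelic"),
            (0.25, 10, 100, "biallelic"),
            (0.75, 10, 100, "biallelic"),
            (0.751, 10, 100, "monoallelic"),
            (0.50, 10, 9, "no_call"),
            (None, 10, 0, "no_call"),
            (None, 0.2, 0, "not_expressed"),  # expression rule takes precedence
        ],
    )
    def test_threshold_rules(self, ref_freq, fpkm, depth, expected):
        assert xp.classify_allelic_status(ref_freq, fpkm, depth) == expected

    @given(
        ref_freq=st.one_of(st.none(), st.floats(0, 1)),
        fpkm=st.floats(0, 1e4),
        depth=st.integers(0, 10_000),
    )
    @settings(deadline=None)
    def test_exhaustive_partition_and_symmetry(self, ref_freq, fpkm, depth):
        status = xp.classify_allelic_status(ref_freq, fpkm, depth)
        assert status in ("monoallelic", "biallelic", "not_expressed", "no_call")
        if ref_freq is not None:
            mirrored = xp.classify_allelic_status(1.0 - ref_freq, fpkm, depth)
            assert mirrored == status

    def test_biallelic_band_is_exactly_quarter_to_three_quarters(self):
        grid = np.round(np.arange(0, 1.0001, 0.001), 3)
        for f in grid:
            status = xp.classify_allelic_status(float(f), 10.0, 100)
            expected = "biallelic" if 0.25 <= f <= 0.75 else "monoallelic"
            assert status == expected, f


class TestClassifySample:
    def test_post_xci_clean_scenario_all_monoallelic(self):
        sc = xp.XCIScenario.preset("post_xci", seed=2, n_x_genes=30, n_chr1_genes=5,
                                   seq_error=0.0, allelic_dispersion_rho=0.0)
        genes, sites = xp.make_gene_and_snp_panel(sc)
        expr = xp.simulate_expression(sc, genes, "S")
        records = xp.simulate_allele_counts(sc, genes, sites, expr, "S")
        calls = xp.classify_sample(records, sites, expr, "S")
        informative = [c for c in calls if c.status in ("monoallelic", "biallelic")]
        assert informative
        assert all(c.status == "monoallelic" for c in informative)

    def test_pre_xci_deep_coverage_mostly_biallelic(self):
        # beta-binomial tail mass outside [0.25, 0.75] is negligible at this
        # depth and rho, so nearly every expressed informative gene is biallelic
        for seed in range(1, 11):
            sc = xp.XCIScenario.preset("pre_xci", seed=seed, n_x_genes=100,
                                       n_chr1_genes=5, mean_depth=200,
                                       allelic_dispersion_rho=0.01)
            genes, sites = xp.make_gene_and_snp_panel(sc)
            expr = xp.simulate_expression(sc, genes, "S")
            records = xp.simulate_allele_counts(sc, genes, sites, expr, "S")
            calls = xp.classify_sample(records, sites, expr, "S")
            informative = [c for c in calls if c.status in ("monoallelic", "biallelic")]
            frac_bi = np.mean([c.status == "biallelic" for c in informative])
            assert frac_bi >= 0.95

    def test_empty_counts_give_empty_output(self, toy_matrix):
        assert xp.classify_sample([], [], toy_matrix, "S1") == []

    def test_calls_ordered_by_position(self, simulated_bundle):
        genes, sites, expr, records = simulated_bundle
        calls = xp.classify_sample(records, sites, expr, "S1")
        keys = [(c.chrom, c.midpoint_coord) for c in calls]
        assert keys == sorted(keys)

    def test_gene_missing_from_expression_becomes_no_call(self, toy_matrix):
        site = xp.SnpSite("chrX", 500, "A", "G", "UNKNOWN")
        records = [xp.AlleleCountRecord(site, 40, 40)]
        [call] = xp.classify_sample(records, [site], toy_matrix, "S1")
        assert call.status == "no_call"

    def test_ref_alt_swap_leaves_statuses_unchanged(self, simulated_bundle):
        genes, sites, expr, records = simulated_bundle
        swapped = [
            xp.AlleleCountRecord(
                site=xp.SnpSite(r.site.chrom, r.site.pos, r.site.alt, r.site.ref,
                                r.site.gene_id),
                n_ref=r.n_alt, n_alt=r.n_ref, n_other=r.n_other,
                sample_id=r.sample_id)
            for r in records
        ]
        sites_swapped = [r.site for r in swapped]
        original = xp.classify_sample(records, sites, expr, "S1")
        mirrored = xp.classify_sample(swapped, sites_swapped, expr, "S1")
        assert [c.status for c in original] == [c.status for c in mirrored]


class TestChromosomeStatusMap:
    def test_tally_and_track(self):
        calls = make_calls([300, 100, 200], ["monoallelic", "biallelic", "not_expressed"])
        track, tally = xp.chromosome_status_map(calls)
        assert tally == {"monoallelic": 1, "biallelic": 1, "not_expressed": 1,
                         "no_call": 0}
        assert [c for c, _ in track] == [100, 200, 300]
        assert sum(tally.values()) == len(calls)

    def test_mixed_chromosomes_rejected(self):
        calls = make_calls([100], ["biallelic"]) + make_calls([100], ["biallelic"],
                                                             chrom="chr1")
        with pytest.raises(ValueError, match="multiple chromosomes"):
            xp.chromosome_status_map(calls)

    def test_escape_fraction_sets_expected_biallelic_tally(self):
        sc = xp.XCIScenario.preset("post_xci", seed=6, n_x_genes=200,
                                   n_chr1_genes=5, escape_fraction=0.1,
                                   mean_depth=200)
        genes, sites = xp.make_gene_and_snp_panel(sc)
        expr = xp.simulate_expression(sc, genes, "S")
        records = xp.simulate_allele_counts(sc, genes, sites, expr, "S")
        calls = xp.classify_sample(records, sites, expr, "S")
        _, tally = xp.chromosome_status_map(calls)
        # 20 escape genes expected; binomial-ish slack for low-expression dropouts
        assert 10 <= tally["biallelic"] <= 30


class TestPositionalBiasTest:
    def test_distal_clustering_detected(self):
        rng = np.random.default_rng(1)
        coords = np.sort(rng.uniform(0, 155e6, 100))
        statuses = ["biallelic"] * 90 + ["monoallelic"] * 10
        stat, p = xp.positional_bias_test(make_calls(coords, statuses),
                                          n_perm=999, seed=0)
        assert stat > 0
        assert p <= 0.01

    def test_null_labels_not_significant(self):
        rng = np.random.default_rng(2)
        coords = np.sort(rng.uniform(0, 155e6, 200))
        statuses = np.array(["biallelic"] * 200, dtype=object)
        statuses[rng.choice(200, 40, replace=False)] = "monoallelic"
        _, p = xp.positional_bias_test(make_calls(coords, statuses),
                                       n_perm=999, seed=3)
        assert p > 0.05

    def test_determinism_and_add_one_floor(self):
        coords = np.linspace(0, 1e6, 50)
        statuses = ["biallelic"] * 40 + ["monoallelic"] * 10
        calls = make_calls(coords, statuses)
        r1 = xp.positional_bias_test(calls, n_perm=199, seed=9)
        r2 = xp.positional_bias_test(calls, n_perm=199, seed=9)
        assert r1 == r2
        assert r1[1] >= 1 / 200

    def test_too_few_calls_is_informative_error(self):
        calls = make_calls([1, 2, 3], ["monoallelic", "biallelic", "biallelic"])
        with pytest.raises(ValueError, match="monoallelic"):
            xp.positional_bias_test(calls, n_perm=100)
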