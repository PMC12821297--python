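import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xsigmeta.clustering import spearman_matrix
from xsigmeta.enrichment import enrich_library
from xsigmeta.errors import ConfigurationError
from xsigmeta.normalization import build_matrix, impute
from xsigmeta.signature_io import write_collection
from xsigmeta.synthetic import (
    SyntheticConfig,
    SyntheticTruth,
    generate_collection,
    generate_gene_sets,
    generate_marker_data,
    generate_network,
)


def _null_config(seed=0, **kwargs):
    defaults = dict(
        n_datasets=10,
        n_genes=300,
        cluster_spec=[],
        n_template_genes=50,
        noise_sd=0.5,
        missing_rate_by_platform={"rnaseq": 0.0, "microarray": 0.0},
        n_consistent_genes=0,
        seed=seed,
    )
    defaults.update(kwargs)
    return SyntheticConfig(**defaults)


class TestGenerateCollection:
    def test_cluster_spec_exceeding_datasets_rejected(self):
        config = _null_config(cluster_spec=[("A", 11, 1.0)])
        with pytest.raises(ConfigurationError):
            generate_collection(config)

    def test_pure_noise_mean_offdiag_correlation_near_zero(self):
        collection, _ = generate_collection(_null_config(seed=3, n_genes=400))
        matrix = impute(build_matrix(collection, presence_threshold=None, top_k=400))
        corr = spearman_matrix(matrix).to_numpy()
        off = corr[np.triu_indices_from(corr, k=1)]
        se = off.std(ddof=1) / np.sqrt(off.size)
        assert abs(off.mean()) < 3 * se + 0.01

    def test_within_cluster_correlation_exceeds_between(self):
        config = _null_config(
            n_datasets=20,
            n_genes=400,
            cluster_spec=[("A", 10, 1.0), ("B", 10, 1.0)],
            n_template_genes=150,
            seed=1,
        )
        collection, truth = generate_collection(config)
        matrix = impute(build_matrix(collection, presence_threshold=None, top_k=400))
        corr = spearman_matrix(matrix)
        labels = {d: truth.cluster_assignment[d] for d in matrix.columns}
        within, between = [], []
        cols = list(matrix.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                (within if labels[a] == labels[b] else between).append(corr.loc[a, b])
        assert np.mean(within) > np.mean(between)

    def test_same_seed_identical_tables(self, tmp_path):
        config = _null_config(seed=9, cluster_spec=[("A", 4, 0.8)], n_consistent_genes=5)
        coll1, _ = generate_collection(config)
        coll2, _ = generate_collection(config)
        for did in coll1.tables:
            pd.testing.assert_frame_equal(coll1.tables[did].data, coll2.tables[did].data)
        # byte-identical on disk too
        write_collection(coll1, tmp_path / "a")
        write_collection(coll2, tmp_path / "b")
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_null_pvalues_uniform(self):
        collection, _ = generate_collection(_null_config(seed=5, n_genes=2000))
        for table in list(collection.tables.values())[:3]:
            ks = stats.kstest(table.data["pvalue"], "uniform")
            assert ks.pvalue > 0.01

    def test_bh_fdr_monotone_in_sorted_pvalues(self):
        collection, _ = generate_collection(_null_config(seed=6))
        table = next(iter(collection.tables.values()))
        ordered = table.data.sort_values("pvalue")
        fdrs = ordered["fdr"].to_numpy()
        assert (np.diff(fdrs) >= -1e-12).all()

    def test_platform_masking_drops_genes(self):
        config = _null_config(
            missing_rate_by_platform={"rnaseq": 0.0, "microarray": 0.3}
        )
        collection, _ = generate_collection(config)
        for did, table in collection.tables.items():
            platform = collection.metadata.set_index("dataset_id").loc[did, "platform"]
            if platform == "microarray":
                assert len(table) == 300 - round(0.3 * 300)
            else:
                assert len(table) == 300

    def test_consistent_genes_planted_in_90_percent(self):
        config = _null_config(n_consistent_genes=10, n_datasets=20, seed=2)
        collection, truth = generate_collection(config)
        assert len(truth.consistent_genes) == 10
        for gene, direction in truth.consistent_genes.items():
            signs = []
            for table in collection.tables.values():
                row = table.data[table.data["gene"] == gene]
                if len(row):
                    signs.append(np.sign(row["log2fc"].iloc[0]))
            want = 1.0 if direction == "up" else -1.0
            assert np.mean([s == want for s in signs]) >= 0.85

    def test_anticorrelated_clusters_via_negative_scale(self):
        config = _null_config(
            n_datasets=12,
            n_genes=300,
            cluster_spec=[("pos", 6, 1.0), ("neg", 6, -1.0)],
            n_template_genes=100,
            seed=8,
        )
        collection, truth = generate_collection(config)
        # same template support negated: cross-cluster correlation mildly
        # negative is only guaranteed when templates share support, so just
        # check generation succeeds and labels are recorded
        assert set(truth.cluster_assignment.values()) == {"pos", "neg"}


class TestGenerateGeneSets:
    def _truth(self, genes, n_consistent=40):
        return SyntheticTruth(
            cluster_assignment={},
            consistent_genes={g: "up" for g in genes[:n_consistent]},
        )

    def test_zero_enriched_fraction_chance_overlap(self):
        genes = [f"G{i:04d}" for i in range(500)]
        truth = self._truth(genes)
        library = generate_gene_sets(genes, 40, 25, 0.0, truth, seed=1)
        assert truth.enriched_sets == []
        overlaps = [
            len(set(s) & set(truth.consistent_genes)) for s in library.sets.values()
        ]
        # expected overlap 25 * 40/500 = 2; chance level, not systematic
        assert np.mean(overlaps) < 2 * 2.0

    def test_saturating_set_size(self):
        genes = [f"G{i:04d}" for i in range(100)]
        truth = self._truth(genes, n_consistent=10)
        library = generate_gene_sets(genes, 3, 100, 0.0, truth, seed=2)
        deg_list = genes[:30]
        for s in library.sets.values():
            assert len(set(s) & set(deg_list)) == len(deg_list)

    def test_set_size_exceeding_genes_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_gene_sets(["a"], 1, 2, 0.0, self._truth(["a"], 0), seed=0)

    def test_enriched_set_detected_by_ora(self):
        genes = [f"G{i:04d}" for i in range(800)]
        truth = self._truth(genes, n_consistent=50)
        library = generate_gene_sets(
            genes, 20, 50, 0.1, truth, seed=3, planted_fraction=0.8
        )
        assert len(truth.enriched_sets) == 2
        deg_list = list(truth.consistent_genes)
        results = enrich_library(deg_list, library, universe=genes)
        significant = {r.name for r in results if r.tier == "significant"}
        assert set(truth.enriched_sets) <= significant


class TestGenerateNetwork:
    def test_planted_hub_neighborhood_overlap(self):
        genes = [f"G{i:04d}" for i in range(1000)]
        deg_set = genes[:20]
        graph = generate_network(genes, 200, [("G0999", 10, 1.0)], deg_set, seed=4)
        neighbors = set(graph["G0999"])
        assert len(neighbors & set(deg_set)) == 10

    def test_no_edges_no_hubs_empty(self):
        graph = generate_network(["a", "b", "c"], 0, [], [], seed=0)
        assert graph.number_of_edges() == 0

    def test_duplicate_hub_rejected(self):
        genes = [f"G{i}" for i in range(50)]
        with pytest.raises(ConfigurationError):
            generate_network(genes, 10, [("G0", 5, 0.5), ("G0", 5, 0.5)], [], seed=0)

    def test_no_self_loops_or_duplicates(self):
        genes = [f"G{i}" for i in range(40)]
        graph = generate_network(genes, 100, [("G0", 10, 0.5)], genes[:15], seed=5)
        assert all(a != b for a, b in graph.edges)
        # nx.Graph cannot hold duplicate undirected edges; check count sanity
        assert graph.number_of_edges() >= 100

    def test_oversized_neighborhood_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_network(["a", "b"], 0, [("a", 5, 0.0)], [], seed=0)


class TestGenerateMarkerData:
    def test_null_effect_same_distribution(self):
        genes = [f"G{i:04d}" for i in range(200)]
        markers, models = generate_marker_data(
            genes, genome_length=50_000_000, trait_gene_set=genes[:50],
            effect=0.0, n_markers=4000, seed=6,
        )
        from xsigmeta.msea import map_markers

        scores = map_markers(markers, models)
        trait = scores[scores.index.isin(genes[:50])]
        rest = scores[~scores.index.isin(genes[:50])]
        assert stats.ks_2samp(trait, rest).pvalue > 0.01

    def test_intervals_non_overlapping_and_half_open(self):
        genes = ["a", "b", "c"]
        _, models = generate_marker_data(genes, genome_length=1_000_000, seed=0)
        ordered = models.sort_values("start")
        assert (ordered["start"] < ordered["end"]).all()
        assert (ordered["end"].to_numpy()[:-1] <= ordered["start"].to_numpy()[1:]).all()

    def test_genome_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_marker_data(["a", "b"], genome_length=1000, seed=0)

    def test_deterministic(self):
        genes = [f"G{i}" for i in range(50)]
        m1, g1 = generate_marker_data(genes, genome_length=20_000_000, seed=7)
        m2, g2 = generate_marker_data(genes, genome_length=20_000_000, seed=7)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(g1, g2)
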