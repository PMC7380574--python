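import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magderep.core_io import GeneClusterTable, MagderepError
from magderep.evaluate import (
    SubsampleExperimentConfig,
    completeness_experiment,
    coverage_dilution_sim,
    gene_cluster_retention,
    subsample_to_completeness,
    summarize_grid,
)

from conftest import make_genome, random_seq


class TestSubsampling:
    def test_fraction_one_keeps_everything(self):
        g = make_genome("g", *[random_seq(2000, i) for i in range(5)])
        assert subsample_to_completeness(g, 1.0, 0) == g

    def test_equal_contigs_exact_arithmetic(self):
        g = make_genome("g", *[random_seq(10_000, i) for i in range(10)])
        sub = subsample_to_completeness(g, 0.5, 1)
        assert len(sub.contigs) == 5
        assert sub.total_length == 50_000

    def test_single_contig_never_empty(self):
        g = make_genome("g", random_seq(5000, 2))
        sub = subsample_to_completeness(g, 0.1, 3)
        assert sub == g

    def test_retained_contigs_keep_original_order(self):
        g = make_genome("g", *[random_seq(3000, i) for i in range(8)])
        sub = subsample_to_completeness(g, 0.6, 4)
        original = [c for c, _ in g.contigs]
        kept = [c for c, _ in sub.contigs]
        assert kept == [c for c in original if c in set(kept)]

    def test_invalid_fraction_fatal(self):
        g = make_genome("g", random_seq(2000, 5))
        for f in (0.0, 1.5, -0.2):
            with pytest.raises(MagderepError):
                subsample_to_completeness(g, f, 0)

    def test_deterministic_per_seed(self):
        g = make_genome("g", *[random_seq(1000, i) for i in range(6)])
        assert subsample_to_completeness(g, 0.5, 7) == subsample_to_completeness(g, 0.5, 7)


class TestGeneClusterRetention:
    def test_keeping_everything_loses_nothing(self):
        t = GeneClusterTable.from_rows([("g1", "a"), ("g2", "b")])
        retained, lost, lost_ids = gene_cluster_retention(t, ["g1", "g2"])
        assert (retained, lost, lost_ids) == (2, 0, [])

    def test_unique_content_is_lost_with_its_carrier(self):
        rows = [("g1", "core"), ("g2", "core")] + [("g2", f"u{i}") for i in range(3)]
        t = GeneClusterTable.from_rows(rows)
        retained, lost, lost_ids = gene_cluster_retention(t, ["g1"])
        assert lost == 3
        assert lost_ids == ["u0", "u1", "u2"]

    def test_redundant_carrier_removal_is_free(self):
        rows = [(g, c) for g in ("g1", "g2") for c in ("a", "b", "c")]
        t = GeneClusterTable.from_rows(rows)
        assert gene_cluster_retention(t, ["g1"]) == (3, 0, [])

    def test_unknown_kept_genome_fatal(self):
        t = GeneClusterTable.from_rows([("g1", "a")])
        with pytest.raises(MagderepError, match="gx"):
            gene_cluster_retention(t, ["gx"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_retained_plus_lost_equals_universe(self, data):
        n_genomes = data.draw(st.integers(1, 6))
        n_clusters = data.draw(st.integers(1, 12))
        rows = data.draw(
            st.lists(
                st.tuples(
                    st.integers(0, n_genomes - 1), st.integers(0, n_clusters - 1)
                ),
                min_size=1,
                max_size=40,
            )
        )
        t = GeneClusterTable.from_rows((f"g{g}", f"c{c}") for g, c in rows)
        genome_ids = sorted(t.genome_ids)
        kept = data.draw(st.lists(st.sampled_from(genome_ids), unique=True))
        retained, lost, lost_ids = gene_cluster_retention(t, kept)
        assert retained + lost == len(t.universe)
        assert len(lost_ids) == lost


class TestCoverageDilution:
    def _source(self, seed=10):
        return make_genome("src", random_seq(20_000, seed), random_seq(20_000, seed + 1))

    def test_single_genome_database_receives_all_reads(self):
        src = self._source()
        df = coverage_dilution_sim([src], "src", n_reads=200, seed=1)
        assert df.set_index("genome_id").loc["src", "reads"] == 200

    def test_identical_copies_split_reads_roughly_evenly(self):
        src = self._source()
        copies = [make_genome(f"copy{i}", *[s for _, s in src.contigs]) for i in range(4)]
        df = coverage_dilution_sim(copies + [], "copy0", n_reads=800, seed=2)
        counts = df.set_index("genome_id")["reads"]
        assert counts.sum() == 800
        # each copy near 200: generous 5-sigma window of Binomial(800, 1/4)
        sigma = np.sqrt(800 * 0.25 * 0.75)
        assert all(abs(c - 200) <= 5 * sigma for c in counts)

    def test_unrelated_genome_attracts_no_reads(self):
        src = self._source()
        other = make_genome("other", random_seq(40_000, 99))
        df = coverage_dilution_sim([src, other], "src", n_reads=200, seed=3)
        counts = df.set_index("genome_id")["reads"]
        assert counts["other"] == 0
        assert counts["src"] == 200

    def test_mean_coverage_formula(self):
        src = self._source()
        df = coverage_dilution_sim([src], "src", n_reads=100, read_length=150, seed=4)
        row = df.set_index("genome_id").loc["src"]
        assert row["mean_coverage"] == pytest.approx(100 * 150 / src.total_length)

    def test_all_hits_mode_credits_every_copy(self):
        src = self._source()
        copies = [make_genome(f"c{i}", *[s for _, s in src.contigs]) for i in range(3)]
        df = coverage_dilution_sim(copies, "c0", n_reads=50, seed=5, report_all_hits=True)
        assert (df["reads"] == 50).all()

    def test_unknown_source_fatal(self):
        with pytest.raises(MagderepError, match="not in database"):
            coverage_dilution_sim([self._source()], "nope", n_reads=10, seed=0)


class TestCompletenessExperiment:
    def test_grid_shape_and_monotonicity_in_gamma(self):
        """10 near-identical genomes: lowering the coverage threshold can
        only merge more, so retained counts are non-increasing as gamma
        drops at fixed completeness."""
        seq_parts = [random_seq(6000, 40 + i) for i in range(5)]
        genomes = [
            make_genome(f"g{i}", *seq_parts) for i in range(4)
        ]
        from magderep.core_io import GenomeQuality

        qual = {g.genome_id: GenomeQuality(g.genome_id, 99, 0) for g in genomes}
        config = SubsampleExperimentConfig(
            completeness_grid=(0.5, 1.0),
            coverage_grid=(25.0, 75.0),
            replicates=2,
            seed=0,
        )
        grid = completeness_experiment(genomes, qual, config)
        assert len(grid) == 2 * 2 * 2
        summary = summarize_grid(grid)
        for f in (0.5, 1.0):
            sub = summary[summary.fraction == f].set_index("coverage_threshold")
            assert sub.loc[25.0, "mean_retained"] <= sub.loc[75.0, "mean_retained"]
        # complete identical genomes always collapse to one
        full = grid[(grid.fraction == 1.0)]
        assert (full.retained == 1).all()
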