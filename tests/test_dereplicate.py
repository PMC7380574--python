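import pytest

from magderep.ani import ANIResult
from magderep.core_io import GenomeQuality, MagderepError
from magderep.dereplicate import (
    DereplicationConfig,
    pair_redundant,
    fail_reason,
    read_report_tables,
    run_pipeline,
    secondary_clusters,
    select_representative,
    write_report_tables,
)
from conftest import make_genome, random_seq


def result(q, s, ani_qs, cov_q, ani_sq, cov_s):
    return ANIResult(q, s, ani_qs, cov_q, ani_sq, cov_s)


class TestPairRule:
    @pytest.mark.parametrize(
        "ani_qs,ani_sq,cov_q,cov_s,expected,reason",
        [
            (99.5, 99.4, 90, 88, True, "pass"),
            (99.5, 99.5, 90, 60, False, "coverage_below_threshold"),
            (98.9, 99.2, 90, 90, False, "ani_below_threshold"),
            (None, None, 0, 0, False, "no_alignment"),
        ],
    )
    def test_both_comparisons_required(self, ani_qs, ani_sq, cov_q, cov_s, expected, reason):
        r = result("a", "b", ani_qs, cov_q, ani_sq, cov_s)
        config = DereplicationConfig(ani_threshold=99.0, coverage_threshold=75.0)
        assert pair_redundant(r, config) is expected
        assert fail_reason(r, config) == reason


class TestSecondaryClusters:
    def setup_method(self):
        self.qual = {
            "a": GenomeQuality("a", 99, 0),
            "b": GenomeQuality("b", 95, 0),
            "c": GenomeQuality("c", 90, 0),
        }

    def chain_results(self):
        """Pass edges a-b and b-c only."""
        return [
            result("a", "b", 99.5, 90, 99.5, 90),
            result("a", "c", 98.0, 90, 98.0, 90),
            result("b", "c", 99.5, 90, 99.5, 90),
        ]

    def test_no_passing_pairs_all_singletons(self):
        results = [
            result(a, b, 95.0, 90, 95.0, 90)
            for a, b in [("a", "b"), ("a", "c"), ("b", "c")]
        ]
        assert secondary_clusters(["a", "b", "c"], results) == [["a"], ["b"], ["c"]]

    def test_connected_grouping_chains(self):
        groups = secondary_clusters(["a", "b", "c"], self.chain_results())
        assert groups == [["a", "b", "c"]]

    def test_complete_grouping_breaks_chain(self):
        groups = secondary_clusters(
            ["a", "b", "c"],
            self.chain_results(),
            DereplicationConfig(grouping="complete"),
            self.qual,
        )
        assert groups == [["a", "b"], ["c"]]

    def test_missing_pair_result_fatal(self):
        with pytest.raises(MagderepError, match="missing ANI result"):
            secondary_clusters(["a", "b", "c"], self.chain_results()[:2])


class TestRepresentativeSelection:
    def test_singleton_group(self):
        qual = {"x": GenomeQuality("x", 50, 10)}
        assert select_representative(["x"], qual) == "x"

    def test_dominant_genome_wins(self):
        qual = {
            "a": GenomeQuality("a", 100, 0),
            "b": GenomeQuality("b", 90, 0),
        }
        assert select_representative(["a", "b"], qual) == "a"

    def test_contamination_weight_flips_choice(self):
        """scores: 98 - 5*2 = 88 vs 92 - 0 = 92."""
        qual = {
            "a": GenomeQuality("a", 98, 2),
            "b": GenomeQuality("b", 92, 0),
        }
        assert select_representative(["a", "b"], qual) == "b"
        # with w=0 pure completeness wins the other way
        assert (
            select_representative(["a", "b"], qual, DereplicationConfig(score_weight=0))
            == "a"
        )

    def test_ties_broken_by_length_then_id(self):
        qual = {g: GenomeQuality(g, 90, 0) for g in ("a", "b")}
        genomes = {
            "a": make_genome("a", "ACGT" * 100),
            "b": make_genome("b", "ACGT" * 200),
        }
        assert select_representative(["a", "b"], qual, genomes=genomes) == "b"
        assert select_representative(["a", "b"], qual) == "a"

    def test_missing_quality_fatal(self):
        with pytest.raises(MagderepError, match="b"):
            select_representative(["a", "b"], {"a": GenomeQuality("a", 90, 0)})


class TestPipeline:
    def test_two_identical_genomes_keep_higher_score(self):
        seq = random_seq(30_600, 30)
        genomes = [make_genome("a", seq), make_genome("b", seq)]
        qual = {
            "a": GenomeQuality("a", 90, 0),
            "b": GenomeQuality("b", 99, 0),
        }
        report = run_pipeline(genomes, qual)
        assert report.representatives == ["b"]
        assert report.secondary_of["a"] == report.secondary_of["b"]

    def test_one_representative_per_secondary_cluster(self, small_mag_set):
        genomes, qual, _, _ = small_mag_set
        report = run_pipeline(genomes, qual)
        by_cluster = {}
        for g in report.genome_ids:
            by_cluster.setdefault(report.secondary_of[g], []).append(g)
        for members in by_cluster.values():
            assert sum(report.kept[g] for g in members) == 1
        assert len(report.representatives) == len(by_cluster)

    def test_removed_genomes_point_at_their_representative(self, small_mag_set):
        genomes, qual, _, _ = small_mag_set
        report = run_pipeline(genomes, qual)
        for g in report.genome_ids:
            rep = report.representative_of[g]
            assert report.kept[rep]
            assert report.secondary_of[rep] == report.secondary_of[g]

    def test_species_never_merged_across_boundary(self, small_mag_set):
        """Secondary clusters contain only conspecific genomes."""
        genomes, qual, _, truth = small_mag_set
        report = run_pipeline(genomes, qual)
        clusters = {}
        for g in report.genome_ids:
            clusters.setdefault(report.secondary_of[g], set()).add(truth.species_of[g])
        assert all(len(species) == 1 for species in clusters.values())

    def test_retention_monotone_in_thresholds(self, small_mag_set):
        genomes, qual, _, _ = small_mag_set
        counts_theta = []
        for theta in [98.0, 99.0, 99.8]:
            rep = run_pipeline(
                genomes, qual, derep_config=DereplicationConfig(ani_threshold=theta)
            )
            counts_theta.append(len(rep.representatives))
        assert counts_theta == sorted(counts_theta)
        counts_gamma = []
        for gamma in [25.0, 75.0, 95.0]:
            rep = run_pipeline(
                genomes, qual, derep_config=DereplicationConfig(coverage_threshold=gamma)
            )
            counts_gamma.append(len(rep.representatives))
        assert counts_gamma == sorted(counts_gamma)

    def test_dereplication_idempotent(self, small_mag_set):
        genomes, qual, _, _ = small_mag_set
        report = run_pipeline(genomes, qual)
        retained = [g for g in genomes if report.kept[g.genome_id]]
        report2 = run_pipeline(retained, qual)
        assert report2.representatives == report.representatives

    def test_report_round_trip(self, tmp_path, small_mag_set):
        genomes, qual, _, _ = small_mag_set
        report = run_pipeline(genomes, qual)
        write_report_tables(report, str(tmp_path))
        assert read_report_tables(str(tmp_path)) == report

    def test_missing_quality_row_fatal(self):
        seq = random_seq(10_200, 31)
        genomes = [make_genome("a", seq), make_genome("b", seq)]
        with pytest.raises(MagderepError, match="b"):
            run_pipeline(genomes, {"a": GenomeQuality("a", 90, 0)})
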