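"""Redundancy decisions, representative selection, and the full pipeline.

A genome pair is *redundant* only when ANI meets the threshold in **both**
directions and alignment coverage meets its threshold in **both**
directions (defaults: ANI >= 99%, coverage >= 75%). Redundant pairs form
edges of a graph within each Mash pre-cluster; secondary clusters are its
connected components (or, optionally, greedily-built complete subgraphs),
and each secondary cluster keeps the member with the best quality score
completeness - w * contamination (w = 5 by default).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .ani import ANIConfig, ANIResult, pairwise_ani, read_ani_pairs, write_ani_pairs
from .core_io import GenomeQuality, GenomeRecord, MagderepError
from .precluster import PreclusterConfig, precluster
from .sketch import SketchParams

_GROUPINGS = ("connected", "complete")


@dataclass(frozen=True)
class DereplicationConfig:
    ani_threshold: float = 99.0  # percent, both directions
    coverage_threshold: float = 75.0  # percent, both directions
    grouping: str = "connected"
    score_weight: float = 5.0  # contamination multiplier in the quality score

    def __post_init__(self) -> None:
        if not 0 < self.ani_threshold <= 100:
            raise MagderepError("ani_threshold must be in (0, 100]")
        if not 0 < self.coverage_threshold <= 100:
            raise MagderepError("coverage_threshold must be in (0, 100]")
        if self.grouping not in _GROUPINGS:
            raise MagderepError(f"grouping must be one of {_GROUPINGS}")
        if self.score_weight < 0:
            raise MagderepError("score_weight must be >= 0")


@dataclass
class DereplicationReport:
    """Complete record of one dereplication run."""

    genome_ids: list[str]
    precluster_of: dict[str, int]
    secondary_of: dict[str, int]
    kept: dict[str, bool]
    representative_of: dict[str, str]
    score_of: dict[str, float]
    ani_results: list[ANIResult] = field(default_factory=list)

    @property
    def representatives(self) -> list[str]:
        return sorted(g for g in self.genome_ids if self.kept[g])

    def pair_status(self, config: DereplicationConfig) -> dict[tuple[str, str], tuple[bool, str]]:
        """Per compared pair: (passed, failing criterion or 'pass')."""
        return {
            (r.query_id, r.subject_id): (pair_redundant(r, config), fail_reason(r, config))
            for r in self.ani_results
        }


# ---------------------------------------------------------------------------
# Pair rule
# ---------------------------------------------------------------------------

def pair_redundant(r: ANIResult, config: DereplicationConfig | None = None) -> bool:
    """Both-comparisons rule: ANI and coverage must pass in both directions.

    Pairs with undefined ANI (no accepted fragments) are never redundant.
    """
    config = config or DereplicationConfig()
    if r.ani_qs is None or r.ani_sq is None:
        return False
    return (
        r.ani_qs >= config.ani_threshold
        and r.ani_sq >= config.ani_threshold
        and r.cov_q >= config.coverage_threshold
        and r.cov_s >= config.coverage_threshold
    )


def fail_reason(r: ANIResult, config: DereplicationConfig | None = None) -> str:
    config = config or DereplicationConfig()
    if r.ani_qs is None or r.ani_sq is None:
        return "no_alignment"
    if r.ani_qs < config.ani_threshold or r.ani_sq < config.ani_threshold:
        return "ani_below_threshold"
    if r.cov_q < config.coverage_threshold or r.cov_s < config.coverage_threshold:
        return "coverage_below_threshold"
    return "pass"


# ---------------------------------------------------------------------------
# Secondary clustering
# ---------------------------------------------------------------------------

def quality_score(
    q: GenomeQuality, config: DereplicationConfig | None = None
) -> float:
    config = config or DereplicationConfig()
    return q.completeness - config.score_weight * q.contamination


def secondary_clusters(
    cluster: Sequence[str],
    results: Sequence[ANIResult],
    config: DereplicationConfig | None = None,
    qualities: Mapping[str, GenomeQuality] | None = None,
) -> list[list[str]]:
    """Partition one pre-cluster into groups of mutually redundant genomes.

    grouping='connected': connected components of the passing-pair graph.
    grouping='complete': greedy maximal all-pairs-pass groups, seeded from
    the highest-quality unassigned genome (requires qualities).
    """
    config = config or DereplicationConfig()
    members = sorted(set(cluster))
    index = {(r.query_id, r.subject_id): r for r in results}
    index.update({(r.subject_id, r.query_id): r for r in results})

    def edge(a: str, b: str) -> bool:
        r = index.get((a, b))
        if r is None:
            raise MagderepError(f"missing ANI result for pair ({a!r}, {b!r})")
        return pair_redundant(r, config)

    if len(members) == 1:
        return [list(members)]

    if config.grouping == "connected":
        parent = {g: g for g in members}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if edge(a, b):
                    parent[find(a)] = find(b)
        groups: dict[str, list[str]] = {}
        for g in members:
            groups.setdefault(find(g), []).append(g)
        return sorted((sorted(v) for v in groups.values()), key=lambda v: v[0])

    # grouping == "complete"
    if qualities is None:
        raise MagderepError("grouping='complete' requires a quality table")
    order = sorted(
        members, key=lambda g: (-quality_score(qualities[g], config), g)
    )
    unassigned = list(order)
    out: list[list[str]] = []
    while unassigned:
        seed = unassigned.pop(0)
        group = [seed]
        rest: list[str] = []
        for g in unassigned:
            if all(edge(g, m) for m in group):
                group.append(g)
            else:
                rest.append(g)
        unassigned = rest
        out.append(sorted(group))
    return sorted(out, key=lambda v: v[0])


def select_representative(
    group: Sequence[str],
    qualities: Mapping[str, GenomeQuality],
    config: DereplicationConfig | None = None,
    genomes: Mapping[str, GenomeRecord] | None = None,
) -> str:
    """Highest quality-score member; ties broken by larger total length,
    then lexicographically smallest id."""
    config = config or DereplicationConfig()
    missing = [g for g in group if g not in qualities]
    if missing:
        raise MagderepError(f"no quality row for genome(s) {missing}")

    def key(g: str) -> tuple[float, int, str]:
        length = genomes[g].total_length if genomes else 0
        return (-quality_score(qualities[g], config), -length, g)

    return min(group, key=key)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    genomes: Sequence[GenomeRecord],
    qualities: Mapping[str, GenomeQuality],
    sketch_params: SketchParams | None = None,
    precluster_config: PreclusterConfig | None = None,
    ani_config: ANIConfig | None = None,
    derep_config: DereplicationConfig | None = None,
) -> DereplicationReport:
    """read -> sketch -> precluster -> within-cluster ANI -> secondary
    clusters -> representatives.

    Every stage is deterministic for fixed inputs and configuration, so two
    runs with the same inputs produce identical reports.
    """
    if not genomes:
        raise MagderepError("no genomes to dereplicate")
    derep_config = derep_config or DereplicationConfig()
    by_id = {g.genome_id: g for g in genomes}
    if len(by_id) != len(genomes):
        raise MagderepError("duplicate genome ids in input set")
    missing_q = sorted(set(by_id) - set(qualities))
    if missing_q:
        raise MagderepError(f"no quality row for genome(s) {missing_q}")

    try:
        preclusters = precluster(list(genomes), sketch_params, precluster_config)
    except MagderepError as exc:
        raise MagderepError(f"precluster stage: {exc}") from exc

    precluster_of: dict[str, int] = {}
    for lab, members in enumerate(preclusters, start=1):
        for g in members:
            precluster_of[g] = lab

    all_results: list[ANIResult] = []
    secondary_of: dict[str, int] = {}
    kept: dict[str, bool] = {}
    representative_of: dict[str, str] = {}
    next_label = 1
    for members in preclusters:
        if len(members) >= 2:
            try:
                results = pairwise_ani([by_id[g] for g in members], ani_config)
            except MagderepError as exc:
                raise MagderepError(f"ani stage: {exc}") from exc
            all_results.extend(results)
        else:
            results = []
        groups = secondary_clusters(members, results, derep_config, qualities)
        for group in groups:
            rep = select_representative(group, qualities, derep_config, by_id)
            for g in group:
                secondary_of[g] = next_label
                representative_of[g] = rep
                kept[g] = g == rep
            next_label += 1

    return DereplicationReport(
        genome_ids=sorted(by_id),
        precluster_of=precluster_of,
        secondary_of=secondary_of,
        kept=kept,
        representative_of=representative_of,
        score_of={
            g: quality_score(qualities[g], derep_config) for g in by_id
        },
        ani_results=all_results,
    )


# ---------------------------------------------------------------------------
# Report tables (clusters.tsv, ani_pairs.tsv, representatives.tsv)
# ---------------------------------------------------------------------------

_CLUSTER_COLUMNS = "genome_id\tprecluster\tsecondary_cluster\tkept\trepresentative\tscore"


def write_report_tables(report: DereplicationReport, outdir: str) -> list[str]:
    """Write clusters.tsv, ani_pairs.tsv and representatives.tsv; the trio
    round-trips losslessly through read_report_tables."""
    try:
        os.makedirs(outdir, exist_ok=True)
        clusters_path = os.path.join(outdir, "clusters.tsv")
        with open(clusters_path, "w") as fh:
            fh.write(_CLUSTER_COLUMNS + "\n")
            for g in report.genome_ids:
                fh.write(
                    f"{g}\t{report.precluster_of[g]}\t{report.secondary_of[g]}\t"
                    f"{int(report.kept[g])}\t{report.representative_of[g]}\t"
                    f"{report.score_of[g]!r}\n"
                )
        ani_path = os.path.join(outdir, "ani_pairs.tsv")
        write_ani_pairs(report.ani_results, ani_path)
        reps_path = os.path.join(outdir, "representatives.tsv")
        with open(reps_path, "w") as fh:
            for g in report.representatives:
                fh.write(g + "\n")
    except OSError as exc:
        raise MagderepError(f"cannot write report to {outdir!r}: {exc}") from exc
    return [clusters_path, ani_path, reps_path]


def read_report_tables(outdir: str) -> DereplicationReport:
    clusters_path = os.path.join(outdir, "clusters.tsv")
    genome_ids: list[str] = []
    precluster_of: dict[str, int] = {}
    secondary_of: dict[str, int] = {}
    kept: dict[str, bool] = {}
    representative_of: dict[str, str] = {}
    score_of: dict[str, float] = {}
    with open(clusters_path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _CLUSTER_COLUMNS:
            raise MagderepError(f"{clusters_path!r}: unexpected header")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            g, pre, sec, k, rep, score = line.rstrip("\n").split("\t")
            genome_ids.append(g)
            precluster_of[g] = int(pre)
            secondary_of[g] = int(sec)
            kept[g] = bool(int(k))
            representative_of[g] = rep
            score_of[g] = float(score)
    ani_results = read_ani_pairs(os.path.join(outdir, "ani_pairs.tsv"))
    return DereplicationReport(
        genome_ids=sorted(genome_ids),
        precluster_of=precluster_of,
        secondary_of=secondary_of,
        kept=kept,
        representative_of=representative_of,
        score_of=score_of,
        ani_results=ani_results,
    )
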