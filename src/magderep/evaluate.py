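"""Evaluation procedures for dereplication behaviour.

Three experiments, each an in-silico analogue of a question practitioners
face when pruning redundant MAGs:

* completeness robustness — artificially reduce every genome's completeness
  by random subsampling of contigs and count how many of the originals the
  pipeline still retains across a grid of completeness fractions and
  coverage thresholds (incomplete genomes share less aligned length, so low
  completeness blocks dereplication at high coverage thresholds);
* gene-cluster retention — how many pangenome gene clusters keep at least
  one carrier among the retained genomes;
* coverage dilution — when a read-mapping database contains redundant
  near-identical genomes, uniformly drawn reads scatter across them and
  each genome's apparent coverage drops by the redundancy factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ani import ANIConfig, align_fragment, pairwise_ani
from .core_io import GeneClusterTable, GenomeQuality, GenomeRecord, MagderepError
from .dereplicate import DereplicationConfig, secondary_clusters
from .precluster import PreclusterConfig, precluster
from .sketch import SketchParams


@dataclass(frozen=True)
class SubsampleExperimentConfig:
    completeness_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))
    coverage_grid: tuple[float, ...] = (10.0, 25.0, 50.0, 75.0)
    replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < f <= 1 for f in self.completeness_grid):
            raise MagderepError("completeness fractions must be in (0, 1]")
        if any(not 0 < g <= 100 for g in self.coverage_grid):
            raise MagderepError("coverage thresholds must be in (0, 100]")
        if self.replicates < 1:
            raise MagderepError("replicates must be >= 1")


def subsample_to_completeness(
    genome: GenomeRecord, fraction: float, seed
) -> GenomeRecord:
    """Randomly subsample contigs down to ~fraction of total length.

    Contigs are shuffled with the seeded generator and the longest prefix
    whose cumulative length stays within fraction * total_length is kept
    (never empty); the retained contigs keep their original order and
    sequences.
    """
    if not 0 < fraction <= 1:
        raise MagderepError(f"fraction must be in (0, 1], got {fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(genome.contigs)
    order = rng.permutation(n)
    budget = fraction * genome.total_length
    keep: set[int] = set()
    acc = 0
    for idx in order:
        clen = len(genome.contigs[int(idx)][1])
        if keep and acc + clen > budget:
            break
        keep.add(int(idx))
        acc += clen
    contigs = tuple(c for i, c in enumerate(genome.contigs) if i in keep)
    return GenomeRecord(genome.genome_id, contigs)


def completeness_experiment(
    genomes: Sequence[GenomeRecord],
    qualities: Mapping[str, GenomeQuality],
    config: SubsampleExperimentConfig | None = None,
    sketch_params: SketchParams | None = None,
    precluster_config: PreclusterConfig | None = None,
    ani_config: ANIConfig | None = None,
    derep_config: DereplicationConfig | None = None,
) -> pd.DataFrame:
    """Retained-genome counts over the completeness x coverage-threshold grid.

    For each replicate and completeness fraction, every genome is
    subsampled and the pipeline run once up to pairwise ANI; the redundancy
    rule is then applied at each coverage threshold of the grid (ANI and
    coverage values do not depend on the threshold, so upstream stages are
    shared across the gamma column). Returns a long-format DataFrame with
    columns fraction, coverage_threshold, replicate, retained, plus
    per-cell means when replicates > 1 in the companion summary.
    """
    if len(genomes) < 2:
        raise MagderepError("completeness experiment needs >= 2 genomes")
    config = config or SubsampleExperimentConfig()
    base = derep_config or DereplicationConfig()
    rows: list[tuple[float, float, int, int]] = []
    master = np.random.default_rng(config.seed)
    for rep in range(config.replicates):
        for fraction in config.completeness_grid:
            rng = np.random.default_rng(master.integers(0, 2**31))
            subs = [subsample_to_completeness(g, fraction, rng) for g in genomes]
            clusters = precluster(subs, sketch_params, precluster_config)
            by_id = {g.genome_id: g for g in subs}
            ani_by_cluster = [
                pairwise_ani([by_id[g] for g in members], ani_config)
                if len(members) >= 2
                else []
                for members in clusters
            ]
            for gamma in config.coverage_grid:
                cfg = replace(base, coverage_threshold=gamma)
                retained = 0
                for members, results in zip(clusters, ani_by_cluster):
                    retained += len(
                        secondary_clusters(members, results, cfg, qualities)
                    )
                rows.append((fraction, gamma, rep, retained))
    return pd.DataFrame(
        rows, columns=["fraction", "coverage_threshold", "replicate", "retained"]
    )


def summarize_grid(grid: pd.DataFrame) -> pd.DataFrame:
    """Mean retained count per (fraction, coverage_threshold) cell."""
    return (
        grid.groupby(["fraction", "coverage_threshold"], as_index=False)["retained"]
        .mean()
        .rename(columns={"retained": "mean_retained"})
    )


def gene_cluster_retention(
    table: GeneClusterTable, kept: Sequence[str]
) -> tuple[int, int, list[str]]:
    """Gene clusters retained by keeping only ``kept`` genomes.

    Returns (retained, lost, lost_ids); retained + lost equals the universe
    size by construction.
    """
    missing = sorted(set(kept) - table.genome_ids)
    if missing:
        raise MagderepError(f"kept genome(s) absent from gene-cluster table: {missing}")
    retained_set: set[str] = set()
    for g in kept:
        retained_set |= table.clusters_of(g)
    universe = table.universe
    lost_ids = sorted(universe - retained_set)
    return len(retained_set), len(lost_ids), lost_ids


# ---------------------------------------------------------------------------
# Read-coverage dilution under database redundancy
# ---------------------------------------------------------------------------

def coverage_dilution_sim(
    db: Sequence[GenomeRecord],
    source_id: str,
    n_reads: int = 4000,
    read_length: int = 150,
    seed: int = 0,
    report_all_hits: bool = False,
    ani_config: ANIConfig | None = None,
) -> pd.DataFrame:
    """Simulate mapping uniformly drawn (error-free, forward-strand) reads
    from ``source_id`` against a genome database.

    Each read is assigned to the database genome(s) containing its best
    match: exact substring containment first, else the fragment aligner
    scores candidates. Ties are broken uniformly at random (one random
    placement reported), or credited to every tying genome when
    ``report_all_hits`` is set. Returns a DataFrame with columns genome_id,
    reads, mean_coverage (= reads * read_length / genome length).
    """
    by_id = {g.genome_id: g for g in db}
    if source_id not in by_id:
        raise MagderepError(f"source genome {source_id!r} not in database")
    source = by_id[source_id]
    eligible = [
        (cid, seq) for cid, seq in source.contigs if len(seq) >= read_length
    ]
    if not eligible:
        raise MagderepError(
            f"no contig of {source_id!r} is at least read_length={read_length} bp"
        )
    rng = np.random.default_rng(seed)
    weights = np.array([len(s) - read_length + 1 for _, s in eligible], dtype=float)
    weights /= weights.sum()
    texts = {g.genome_id: "\x00".join(s for _, s in g.contigs) for g in db}
    ids = sorted(by_id)

    counts = {g: 0 for g in ids}
    unplaced = 0
    contig_draws = rng.choice(len(eligible), size=n_reads, p=weights)
    for ci in contig_draws:
        seq = eligible[int(ci)][1]
        pos = int(rng.integers(0, len(seq) - read_length + 1))
        read = seq[pos : pos + read_length]
        exact = [g for g in ids if read in texts[g]]
        if exact:
            best = exact
        else:
            cfg = ani_config or ANIConfig()
            scored: list[tuple[float, str]] = []
            for g in ids:
                hit = align_fragment(read, by_id[g], cfg)
                if hit is not None:
                    scored.append((hit.identity, g))
            if not scored:
                unplaced += 1
                continue
            top = max(s for s, _ in scored)
            best = [g for s, g in scored if s == top]
        if report_all_hits:
            for g in best:
                counts[g] += 1
        else:
            counts[best[int(rng.integers(0, len(best)))]] += 1
    if unplaced:
        warnings.warn(f"{unplaced} of {n_reads} reads could not be placed")
    return pd.DataFrame(
        {
            "genome_id": ids,
            "reads": [counts[g] for g in ids],
            "mean_coverage": [
                counts[g] * read_length / by_id[g].total_length for g in ids
            ],
        }
    )
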