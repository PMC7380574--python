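"""Synthetic conspecific-MAG sets with planted ground truth.

The generator emulates what independent assembly of the same community
produces: several species, each represented by multiple metagenome-assembled
genomes that share a diverged core sequence, carry genome-specific auxiliary
segments (registered as planted gene clusters), are fragmented into contigs,
and may be incomplete.

ANI targets are *pairwise*: ``within_ani`` is the identity two conspecific
MAGs realise against each other, not against their unobserved common
ancestor. Each branch therefore receives the substitution rate q solving

    (1 - q)^2 + q^2 / 3 = ANI / 100

(the left side is the per-site match probability of two sequences evolved
independently from one ancestor when a substituted base is drawn uniformly
from the three alternatives), so measured pairwise ANI hits the target in
expectation. Species ancestors are siblings from one root when
``between_ani`` >= 90 (so intermediate, species-boundary ANI regimes are
constructible); below 90 they are independent random sequences.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_io import (
    GeneClusterTable,
    GenomeQuality,
    GenomeRecord,
    MagderepError,
    write_fasta,
    write_gene_clusters,
    write_quality_table,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class SynthConfig:
    n_species: int = 3
    mags_per_species: int = 5
    genome_length: int = 200_000
    within_ani: float = 99.5  # target pairwise ANI among conspecific MAGs, %
    between_ani: float = 80.0  # target pairwise ANI between species, %
    indel_rate: float = 0.0005  # per base per branch
    mean_indel_len: float = 3.0
    n_contigs: int = 20
    aux_blocks_per_genome: int = 5
    aux_block_len: int = 2000
    completeness_range: Optional[tuple[float, float]] = None  # fractions; None = complete
    quality_noise_sd: float = 0.3  # percent points on reported completeness
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.within_ani <= 100:
            raise MagderepError("within_ani must be in (0, 100]")
        if not self.between_ani < self.within_ani:
            raise MagderepError("between_ani must be below within_ani")
        if self.genome_length < self.n_contigs * 1000:
            raise MagderepError("genome_length must be >= n_contigs * 1000")
        if self.n_species < 1 or self.mags_per_species < 1:
            raise MagderepError("need at least one species and one MAG per species")


@dataclass(frozen=True)
class MutationMask:
    """Exact record of the edits applied to an ancestor.

    Substitutions are (position, new_base) on ancestor coordinates; indels
    are (position, 'ins', inserted_sequence) or (position, 'del', length),
    also on ancestor coordinates, applied after all substitutions in
    descending position order.
    """

    substitutions: tuple[tuple[int, str], ...]
    indels: tuple[tuple[int, str, object], ...]

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)


@dataclass
class SynthTruth:
    """Ground truth for one generated MAG set."""

    species_of: dict[str, str]
    mask_of: dict[str, MutationMask]  # relative to the species ancestor
    aux_blocks_of: dict[str, frozenset[str]]
    completeness_of: dict[str, float]  # true fraction retained, in (0, 1]
    species_ancestors: dict[str, str] = field(default_factory=dict)

    @property
    def species_labels(self) -> list[str]:
        return sorted(set(self.species_of.values()))


def branch_substitution_rate(pairwise_ani: float) -> float:
    """Per-branch rate q so two independent branches realise the target
    pairwise ANI: solves (1-q)^2 + q^2/3 = ANI/100."""
    a = pairwise_ani / 100.0
    disc = 1.0 - (4.0 / 3.0) * (1.0 - a)
    if disc < 0:
        raise MagderepError(f"pairwise ANI {pairwise_ani} too low to calibrate")
    return 0.75 * (1.0 - math.sqrt(disc))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_ancestor(length: int, seed) -> str:
    """i.i.d. uniform A/C/G/T string, deterministic per seed."""
    if length < 1000:
        raise MagderepError("ancestor length must be >= 1000")
    rng = _as_rng(seed)
    codes = rng.integers(0, 4, size=length)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")


def evolve_sequence(
    ancestor: str,
    target_ani: float,
    indel_rate: float = 0.0,
    seed=0,
    mean_indel_len: float = 3.0,
) -> tuple[str, MutationMask]:
    """Diverge a sequence from its ancestor to ``target_ani`` percent.

    Substitutions land i.i.d. at rate 1 - target_ani/100 and always change
    the base; indels land at ``indel_rate`` per base with geometric lengths
    (mean ``mean_indel_len``). The returned mask replays exactly.
    """
    if not 0 < target_ani <= 100:
        raise MagderepError("target_ani must be in (0, 100]")
    rng = _as_rng(seed)
    n = len(ancestor)
    p = 1.0 - target_ani / 100.0
    codes = np.frombuffer(ancestor.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    codes = lut[codes].astype(np.int64)

    sub_pos = np.nonzero(rng.random(n) < p)[0]
    shifts = rng.integers(1, 4, size=sub_pos.size)
    new_codes = (codes[sub_pos] + shifts) % 4
    substitutions = tuple(
        (int(pos), _BASES[int(c)]) for pos, c in zip(sub_pos, new_codes)
    )

    indels: list[tuple[int, str, object]] = []
    if indel_rate > 0:
        ind_pos = np.nonzero(rng.random(n) < indel_rate)[0]
        for pos in ind_pos:
            length = int(rng.geometric(1.0 / mean_indel_len))
            if rng.random() < 0.5:
                ins = "".join(_BASES[c] for c in rng.integers(0, 4, size=length))
                indels.append((int(pos), "ins", ins))
            else:
                indels.append((int(pos), "del", min(length, n - int(pos))))
    mask = MutationMask(substitutions, tuple(indels))
    return apply_mask(ancestor, mask), mask


def apply_mask(ancestor: str, mask: MutationMask) -> str:
    """Replay a mutation mask on its ancestor."""
    seq = list(ancestor)
    for pos, base in mask.substitutions:
        seq[pos] = base
    for pos, kind, payload in sorted(mask.indels, key=lambda t: -t[0]):
        if kind == "ins":
            seq[pos:pos] = list(payload)
        else:
            del seq[pos : pos + int(payload)]
    return "".join(seq)


def _fragment_into_contigs(
    seq: str, n_contigs: int, rng: np.random.Generator, min_contig: int = 1000
) -> list[str]:
    """Cut a linear sequence into n_contigs pieces at random breakpoints,
    each at least min_contig long."""
    n = len(seq)
    if n < n_contigs * min_contig:
        raise MagderepError("sequence too short for requested contig count")
    slack = n - n_contigs * min_contig
    cuts = np.sort(rng.integers(0, slack + 1, size=n_contigs - 1))
    lengths = np.diff(np.concatenate(([0], cuts, [slack]))) + min_contig
    out: list[str] = []
    start = 0
    for length in lengths:
        out.append(seq[start : start + int(length)])
        start += int(length)
    return out


def generate_mag_set(
    config: SynthConfig,
) -> tuple[list[GenomeRecord], dict[str, GenomeQuality], GeneClusterTable, SynthTruth]:
    """Generate a planted MAG set with quality table and gene-cluster truth.

    Gene-cluster universe: per species one core cluster (all members) plus a
    pool of 2 * aux_blocks_per_genome auxiliary blocks, each guaranteed to
    land in at least one MAG, each MAG carrying aux_blocks_per_genome of
    them (a few more where needed to cover the pool).
    """
    rng = np.random.default_rng(config.seed)
    q_within = branch_substitution_rate(config.within_ani)
    branch_within_ani = 100.0 * (1.0 - q_within)

    # species ancestors
    species = [f"sp{si:02d}" for si in range(config.n_species)]
    ancestors: dict[str, str] = {}
    if config.between_ani >= 90.0 and config.n_species > 1:
        root = generate_ancestor(config.genome_length, rng)
        q_between = branch_substitution_rate(config.between_ani)
        for sp in species:
            anc, _ = evolve_sequence(root, 100.0 * (1.0 - q_between), 0.0, rng)
            ancestors[sp] = anc
    else:
        for sp in species:
            ancestors[sp] = generate_ancestor(config.genome_length, rng)

    pool_size = 2 * config.aux_blocks_per_genome
    genomes: list[GenomeRecord] = []
    qualities: dict[str, GenomeQuality] = {}
    cluster_rows: list[tuple[str, str]] = []
    species_of: dict[str, str] = {}
    mask_of: dict[str, MutationMask] = {}
    aux_blocks_of: dict[str, frozenset[str]] = {}
    completeness_of: dict[str, float] = {}

    for sp in species:
        aux_pool = {
            f"{sp}_aux{bi:02d}": generate_ancestor(
                max(config.aux_block_len, 1000), rng
            )[: config.aux_block_len]
            for bi in range(pool_size)
        }
        mag_ids = [f"{sp}_mag{mi:02d}" for mi in range(config.mags_per_species)]
        # choose aux subsets, then patch so every pool block is carried somewhere
        chosen: dict[str, set[str]] = {
            m: (
                {
                    str(b)
                    for b in rng.choice(
                        sorted(aux_pool),
                        size=config.aux_blocks_per_genome,
                        replace=False,
                    )
                }
                if aux_pool
                else set()
            )
            for m in mag_ids
        }
        covered = set().union(*chosen.values()) if chosen else set()
        for block in sorted(set(aux_pool) - covered):
            chosen[mag_ids[int(rng.integers(0, len(mag_ids)))]].add(block)

        for mag in mag_ids:
            core, mask = evolve_sequence(
                ancestors[sp],
                branch_within_ani,
                config.indel_rate,
                rng,
                config.mean_indel_len,
            )
            seq = core
            for block in sorted(chosen[mag]):
                pos = int(rng.integers(0, len(seq) + 1))
                seq = seq[:pos] + aux_pool[block] + seq[pos:]
            contigs = _fragment_into_contigs(seq, config.n_contigs, rng)
            record = GenomeRecord(
                mag, tuple((f"{mag}_c{ci:03d}", c) for ci, c in enumerate(contigs))
            )
            true_fraction = 1.0
            if config.completeness_range is not None:
                lo, hi = config.completeness_range
                target = float(rng.uniform(lo, hi))
                full_len = record.total_length
                # drop a suffix of a shuffled contig ordering
                order = rng.permutation(config.n_contigs)
                keep: list[int] = []
                acc = 0
                for idx in order:
                    clen = len(contigs[int(idx)])
                    if keep and acc + clen > target * full_len:
                        continue
                    keep.append(int(idx))
                    acc += clen
                keep_set = sorted(keep)
                record = GenomeRecord(
                    mag,
                    tuple(
                        (f"{mag}_c{ci:03d}", contigs[ci]) for ci in keep_set
                    ),
                )
                true_fraction = acc / full_len

            genomes.append(record)
            species_of[mag] = sp
            mask_of[mag] = mask
            aux_blocks_of[mag] = frozenset(chosen[mag])
            completeness_of[mag] = true_fraction
            noisy = 100.0 * true_fraction + float(
                rng.normal(0.0, config.quality_noise_sd)
            )
            qualities[mag] = GenomeQuality(
                mag, min(100.0, max(0.0, noisy)), 0.0
            )
            cluster_rows.append((mag, f"{sp}_core"))
            cluster_rows.extend((mag, block) for block in sorted(chosen[mag]))

    table = GeneClusterTable.from_rows(cluster_rows)
    truth = SynthTruth(
        species_of, mask_of, aux_blocks_of, completeness_of, dict(ancestors)
    )
    return genomes, qualities, table, truth


def write_mag_set(
    genomes: list[GenomeRecord],
    qualities: dict[str, GenomeQuality],
    table: GeneClusterTable,
    truth: SynthTruth,
    outdir: str,
) -> None:
    """Write FASTA files, quality.tsv, gene_clusters.tsv and truth.json."""
    os.makedirs(outdir, exist_ok=True)
    for g in genomes:
        write_fasta(g, os.path.join(outdir, f"{g.genome_id}.fasta"))
    write_quality_table(qualities, os.path.join(outdir, "quality.tsv"))
    write_gene_clusters(table, os.path.join(outdir, "gene_clusters.tsv"))
    payload = {
        "species_of": truth.species_of,
        "aux_blocks_of": {g: sorted(s) for g, s in truth.aux_blocks_of.items()},
        "completeness_of": truth.completeness_of,
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
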