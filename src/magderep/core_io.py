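"""Shared data model and file I/O for MAG dereplication.

Genomes are multi-FASTA files, one file per MAG; metadata travels in
tab-separated tables with a single header line ('#'-prefixed lines are
comments). All coordinates in the package are 0-based half-open.
"""

from __future__ import annotations

import glob as _glob
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_CHARS = frozenset("ACGTN")

# translation applied on ingest: lower-case to upper, RNA U to T
_NORMALIZE = str.maketrans("acgtnuU", "ACGTNTT")


class MagderepError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class GenomeRecord:
    """One MAG: an ordered set of contigs.

    ``genome_id`` is the FASTA file stem; contig ids are taken from headers
    up to the first whitespace and must be unique within the genome.
    """

    genome_id: str
    contigs: tuple[tuple[str, str], ...]  # (contig_id, sequence)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, seq in self.contigs:
            if cid in seen:
                raise MagderepError(
                    f"genome {self.genome_id!r}: duplicate contig id {cid!r}"
                )
            seen.add(cid)
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise MagderepError(
                    f"genome {self.genome_id!r}, contig {cid!r}: "
                    f"invalid sequence characters {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.contigs)

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    @staticmethod
    def from_raw(genome_id: str, contigs: Iterable[tuple[str, str]]) -> "GenomeRecord":
        """Build a record, normalising case and U->T on the way in."""
        normed = tuple((cid, seq.translate(_NORMALIZE)) for cid, seq in contigs)
        return GenomeRecord(genome_id, normed)


@dataclass(frozen=True)
class GenomeQuality:
    """Estimated completeness and contamination (percent) for one genome.

    The estimates are inputs (CheckM-style tools produce them); this package
    only consumes them for representative selection.
    """

    genome_id: str
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise MagderepError(
                f"genome {self.genome_id!r}: completeness {self.completeness} "
                "outside [0, 100]"
            )
        if self.contamination < 0.0:
            raise MagderepError(
                f"genome {self.genome_id!r}: negative contamination "
                f"{self.contamination}"
            )


@dataclass
class GeneClusterTable:
    """Genome -> gene-cluster membership (pangenome presence/absence).

    Duplicate (genome, cluster) rows collapse; the *universe* is the union of
    all cluster ids across all genomes.
    """

    memberships: dict[str, frozenset[str]] = field(default_factory=dict)

    @staticmethod
    def from_rows(rows: Iterable[tuple[str, str]]) -> "GeneClusterTable":
        acc: dict[str, set[str]] = {}
        for gid, cid in rows:
            acc.setdefault(gid, set()).add(cid)
        return GeneClusterTable({g: frozenset(s) for g, s in acc.items()})

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.memberships.values():
            out |= s
        return frozenset(out)

    def clusters_of(self, genome_id: str) -> frozenset[str]:
        return self.memberships[genome_id]

    @property
    def genome_ids(self) -> frozenset[str]:
        return frozenset(self.memberships)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_fasta(path: str, genome_id: str | None = None) -> GenomeRecord:
    """Read one multi-FASTA file into a GenomeRecord.

    The genome id defaults to the file name stripped of .fa/.fasta/.fna and
    a trailing .gz; gzip-compressed files are decompressed transparently.
    """
    if genome_id is None:
        genome_id = _file_stem(path)
    contigs: list[tuple[str, str]] = []
    try:
        if path.endswith(".gz"):
            import gzip

            with gzip.open(path, "rt") as fh:
                for rec in SeqIO.parse(fh, "fasta"):
                    contigs.append((rec.id, str(rec.seq)))
        else:
            for rec in SeqIO.parse(path, "fasta"):
                contigs.append((rec.id, str(rec.seq)))
    except (ValueError, OSError) as exc:
        raise MagderepError(f"cannot parse FASTA file {path!r}: {exc}") from exc
    if not contigs:
        raise MagderepError(f"FASTA file {path!r} contains no sequences")
    try:
        return GenomeRecord.from_raw(genome_id, contigs)
    except MagderepError as exc:
        raise MagderepError(f"in file {path!r}: {exc}") from exc


def _file_stem(path: str) -> str:
    name = os.path.basename(path)
    if name.lower().endswith(".gz"):
        name = name[:-3]
    for ext in (".fasta", ".fa", ".fna"):
        if name.lower().endswith(ext):
            return name[: -len(ext)]
    return os.path.splitext(name)[0]


def read_fasta_dir(path: str, pattern: str = "*.fa*") -> list[GenomeRecord]:
    """Read every FASTA file matching ``pattern`` under ``path``.

    Returns records sorted lexicographically by genome id, so ingest order
    never depends on filesystem enumeration order.
    """
    if not os.path.isdir(path):
        raise MagderepError(f"not a directory: {path!r}")
    files = sorted(_glob.glob(os.path.join(path, pattern)))
    if not files:
        raise MagderepError(f"no files matching {pattern!r} in {path!r}")
    records = [read_fasta(f) for f in files]
    seen: dict[str, str] = {}
    for rec, f in zip(records, files):
        if rec.genome_id in seen:
            raise MagderepError(
                f"duplicate genome id {rec.genome_id!r}: files "
                f"{seen[rec.genome_id]!r} and {f!r}"
            )
        seen[rec.genome_id] = f
    records.sort(key=lambda r: r.genome_id)
    return records


def write_fasta(genome: GenomeRecord, path: str, width: int = 80) -> None:
    recs = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def _read_tsv(path: str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MagderepError(f"{path!r}: missing column(s) {missing}")
    return df


def read_quality_table(path: str) -> dict[str, GenomeQuality]:
    """Read quality.tsv (genome_id, completeness, contamination)."""
    df = _read_tsv(path, ["genome_id", "completeness", "contamination"])
    out: dict[str, GenomeQuality] = {}
    for i, row in df.iterrows():
        try:
            q = GenomeQuality(
                str(row["genome_id"]),
                float(row["completeness"]),
                float(row["contamination"]),
            )
        except (ValueError, MagderepError) as exc:
            raise MagderepError(f"{path!r}, data row {i + 1}: {exc}") from exc
        if q.genome_id in out:
            raise MagderepError(
                f"{path!r}, data row {i + 1}: duplicate genome_id {q.genome_id!r}"
            )
        out[q.genome_id] = q
    return out


def write_quality_table(qualities: Mapping[str, GenomeQuality], path: str) -> None:
    df = pd.DataFrame(
        [
            (q.genome_id, q.completeness, q.contamination)
            for q in sorted(qualities.values(), key=lambda q: q.genome_id)
        ],
        columns=["genome_id", "completeness", "contamination"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_clusters(path: str) -> GeneClusterTable:
    """Read gene_clusters.tsv (genome_id, cluster_id)."""
    df = _read_tsv(path, ["genome_id", "cluster_id"])
    return GeneClusterTable.from_rows(
        (str(r["genome_id"]), str(r["cluster_id"])) for _, r in df.iterrows()
    )


def write_gene_clusters(table: GeneClusterTable, path: str) -> None:
    rows = [
        (g, c)
        for g in sorted(table.memberships)
        for c in sorted(table.memberships[g])
    ]
    pd.DataFrame(rows, columns=["genome_id", "cluster_id"]).to_csv(
        path, sep="\t", index=False
    )
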