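"""MinHash genome sketching and Mash-style distance estimation.

A sketch is the ``s`` smallest 64-bit hash values over a genome's canonical
k-mers (the lexicographic minimum of a k-mer and its reverse complement).
Jaccard similarity between two genomes is estimated from the merged bottom-s
sketch (the Mash convention), and converted to an evolutionary-distance-like
quantity via the Mash distance transform.

Hashing is splitmix64 applied to the 2-bit-packed canonical k-mer integer
XORed with a constant seed; for k <= 31 the packed integer is a bijection of
the k-mer string, so the sketch is deterministic across runs and machines
and never depends on the platform hash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import GenomeRecord, MagderepError

# base encoding: A=0 C=1 G=2 T=3, N=4 (k-mers containing N are skipped)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class SketchParams:
    """MinHash parameters: k-mer length, sketch size, hash seed.

    Defaults (k=21, s=1000) follow the conventions of MinHash genome
    sketching tools used for MAG pre-clustering.
    """

    k: int = 21
    s: int = 1000
    hash_seed: int = 42

    def __post_init__(self) -> None:
        if not (11 <= self.k <= 31 and self.k % 2 == 1):
            raise MagderepError(f"k must be odd and in [11, 31], got {self.k}")
        if self.s < 1:
            raise MagderepError(f"sketch size must be >= 1, got {self.s}")


@dataclass(frozen=True)
class Sketch:
    genome_id: str
    params: SketchParams
    hashes: np.ndarray  # sorted, strictly increasing uint64

    def __len__(self) -> int:
        return len(self.hashes)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _packed_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit-pack every k-window of a code array; windows containing N are
    dropped. Returns uint64 packed values (with duplicates, in order)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    codes64 = codes.astype(np.uint64)
    comp64 = (np.uint64(3) - codes64) & np.uint64(3)  # N maps to junk; masked below
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | codes64[j : j + n]
        # reverse complement read right-to-left: base at offset k-1-j
        rc = (rc << np.uint64(2)) | comp64[k - 1 - j : k - 1 - j + n]
    canon = np.minimum(fwd, rc)
    # mask windows containing N
    is_n = (codes == 4).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(is_n)))
    n_in_window = cum[k:] - cum[:-k]
    return canon[n_in_window == 0]


def canonical_kmer_set(genome: GenomeRecord, k: int) -> np.ndarray:
    """Sorted unique 2-bit-packed canonical k-mers of a genome."""
    parts = [
        _packed_kmers(_encode(seq), k) for _, seq in genome.contigs if len(seq) >= k
    ]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 finaliser (wrapping uint64 arithmetic)."""
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def hash_kmers(packed: np.ndarray, seed: int) -> np.ndarray:
    return _splitmix64(packed ^ np.uint64(seed))


def exact_jaccard(a: GenomeRecord, b: GenomeRecord, k: int = 21) -> float:
    """Exact Jaccard similarity of the two genomes' full canonical k-mer
    sets. Reference quantity for judging the MinHash estimator; not used by
    the sketching path."""
    sa = canonical_kmer_set(a, k)
    sb = canonical_kmer_set(b, k)
    if sa.size == 0 and sb.size == 0:
        return 0.0
    inter = np.intersect1d(sa, sb, assume_unique=True).size
    return inter / (sa.size + sb.size - inter)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sketch_genome(genome: GenomeRecord, params: SketchParams | None = None) -> Sketch:
    """Bottom-s MinHash sketch of a genome's canonical k-mers."""
    params = params or SketchParams()
    if all(len(seq) < params.k for _, seq in genome.contigs):
        raise MagderepError(
            f"genome {genome.genome_id!r} too short to sketch (no contig >= k={params.k})"
        )
    kmers = canonical_kmer_set(genome, params.k)
    hashes = np.unique(hash_kmers(kmers, params.hash_seed))
    return Sketch(genome.genome_id, params, hashes[: params.s])


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Merged bottom-s' Jaccard estimate between two sketches.

    s' = min(s, |union of retained hashes|); the estimate is the number of
    shared hashes among the s' smallest of the union, divided by s'.
    """
    if a.params != b.params:
        raise MagderepError(
            f"sketch parameter mismatch: {a.params} vs {b.params}"
        )
    union = np.union1d(a.hashes, b.hashes)
    sp = min(a.params.s, union.size)
    if sp == 0:
        return 0.0
    bottom = union[:sp]
    shared = np.intersect1d(
        np.intersect1d(bottom, a.hashes, assume_unique=True),
        b.hashes,
        assume_unique=True,
    ).size
    return shared / sp


def mash_distance(j: float, k: int) -> float:
    """Mash distance transform of a Jaccard similarity.

    d = -(1/k) * ln(2j / (1+j)), capped at 1; j = 0 maps to 1.
    """
    if not 0.0 <= j <= 1.0:
        raise MagderepError(f"Jaccard value {j} outside [0, 1]")
    if j == 0.0:
        return 1.0
    return min(1.0, -math.log(2.0 * j / (1.0 + j)) / k)


def pairwise_distance_matrix(sketches: list[Sketch]) -> DistanceMatrix:
    """Symmetric Mash distance matrix over sketches, in input order."""
    if len(sketches) < 2:
        raise MagderepError("need at least 2 sketches for a distance matrix")
    params = sketches[0].params
    for sk in sketches[1:]:
        if sk.params != params:
            raise MagderepError("all sketches must share parameters")
    n = len(sketches)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = mash_distance(jaccard_estimate(sketches[i], sketches[j]), params.k)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(tuple(sk.genome_id for sk in sketches), mat)


# ---------------------------------------------------------------------------
# TSV round-trips (sketches.tsv, distances.tsv)
# ---------------------------------------------------------------------------

def write_sketches(sketches: list[Sketch], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tk\ts\thashes\n")
        for sk in sketches:
            hexes = ",".join(format(int(h), "016x") for h in sk.hashes)
            fh.write(f"{sk.genome_id}\t{sk.params.k}\t{sk.params.s}\t{hexes}\n")


def read_sketches(path: str, hash_seed: int = 42) -> list[Sketch]:
    out: list[Sketch] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("genome_id"):
            raise MagderepError(f"{path!r}: malformed sketches file")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gid, k, s, hexes = line.rstrip("\n").split("\t")
            hashes = np.array(
                [int(h, 16) for h in hexes.split(",") if h], dtype=np.uint64
            )
            out.append(Sketch(gid, SketchParams(int(k), int(s), hash_seed), hashes))
    return out


def write_distances(sketches: list[Sketch], path: str) -> None:
    """Pairwise distances.tsv: query, subject, distance, shared hashes and
    the merged sketch size s' used for the estimate."""
    with open(path, "w") as fh:
        fh.write("query\tsubject\tdistance\tshared\tsketch_size\n")
        for i, a in enumerate(sketches):
            for b in sketches[i + 1 :]:
                union = np.union1d(a.hashes, b.hashes)
                sp = min(a.params.s, union.size)
                bottom = union[:sp]
                shared = np.intersect1d(
                    np.intersect1d(bottom, a.hashes, assume_unique=True),
                    b.hashes,
                    assume_unique=True,
                ).size
                j = shared / sp if sp else 0.0
                d = mash_distance(j, a.params.k)
                fh.write(f"{a.genome_id}\t{b.genome_id}\t{d:.8f}\t{shared}\t{sp}\n")
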