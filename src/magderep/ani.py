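"""Fragment-based average nucleotide identity with alignment coverage.

Emulates BLAST-based genome-wide ANI (ANIb): the query genome is chopped
into consecutive fragments (1020 bp by default), each fragment is aligned
against the subject genome, and hits are accepted when they reach at least
30% identity over at least 70% of the fragment. ANI is the unweighted mean
identity of accepted fragments; coverage is the fraction of the query's
length participating in accepted alignments. Both directions of a genome
pair are computed, since dereplication decisions require the thresholds to
hold in both.

Alignment replaces BLASTN with seed-and-extend: shared seed k-mers (15 bp,
both strands) nominate subject loci by diagonal voting; each candidate
window is aligned with a banded edit-distance alignment (edlib, infix mode,
edit cap = band_fraction * fragment_length) and the alignment is trimmed to
its maximal-scoring segment (match +1, mismatch/gap -1) so that fragments
only partially contained in the subject report local, BLAST-like hits.
Identity counts matches over all alignment columns; indel columns count as
mismatches. The edit cap means per-fragment divergence beyond ~band_fraction
is not detectable, which is ample headroom for decisions made near 99%
identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import edlib
import numpy as np

from .core_io import GenomeRecord, MagderepError
from .sketch import _CODE

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ANIConfig:
    """Fragmenting, seeding and hit-acceptance parameters.

    ``fragment_length`` and the identity/length acceptance rule follow the
    BLAST-based ANI convention; ``band_fraction`` bounds the edit distance
    (and hence the DP band) of a fragment alignment as a fraction of the
    fragment length.
    """

    fragment_length: int = 1020
    min_fragment: int = 100
    seed_k: int = 15
    band_fraction: float = 0.2
    min_hit_identity: float = 0.3
    min_hit_fraction: float = 0.7
    seed_stride: int = 50
    max_candidates: int = 4
    max_seed_hits: int = 50  # per seed k-mer; repetitive seeds truncated

    def __post_init__(self) -> None:
        if not 0 < self.min_hit_identity <= 1:
            raise MagderepError("min_hit_identity must be in (0, 1]")
        if not 0 < self.min_hit_fraction <= 1:
            raise MagderepError("min_hit_fraction must be in (0, 1]")
        if not self.seed_k < self.min_fragment <= self.fragment_length:
            raise MagderepError("need seed_k < min_fragment <= fragment_length")


@dataclass(frozen=True)
class Fragment:
    contig_id: str
    start: int  # 0-based half-open on the query contig
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FragmentHit:
    identity: float  # matches / alignment columns, in [0, 1]
    aligned_query_bp: int  # query bases inside the trimmed alignment
    contig_id: str  # subject contig
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class ANIResult:
    """Bidirectional ANI/coverage for one genome pair (percent scale).

    ``ani_qs`` is None when no query fragment was accepted against the
    subject (and then ``cov_q`` is 0); likewise for the reverse direction.
    """

    query_id: str
    subject_id: str
    ani_qs: Optional[float]
    cov_q: float
    ani_sq: Optional[float]
    cov_s: float
    n_fragments_q: int = 0
    n_fragments_s: int = 0
    accepted_q: int = 0
    accepted_s: int = 0


# ---------------------------------------------------------------------------
# Fragmenting
# ---------------------------------------------------------------------------

def fragment_genome(genome: GenomeRecord, config: ANIConfig | None = None) -> list[Fragment]:
    """Split each contig into consecutive fragment_length windows; a trailing
    window is kept only if it reaches min_fragment."""
    config = config or ANIConfig()
    L = config.fragment_length
    out: list[Fragment] = []
    for cid, seq in genome.contigs:
        for start in range(0, len(seq), L):
            end = min(start + L, len(seq))
            if end - start >= config.min_fragment:
                out.append(Fragment(cid, start, end, seq[start:end]))
    return out


# ---------------------------------------------------------------------------
# Subject seed index
# ---------------------------------------------------------------------------

def _forward_kmers_with_pos(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-packed forward-strand k-mers and their start positions
    (N-containing windows dropped)."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    packed = np.zeros(n, dtype=np.uint64)
    codes64 = codes.astype(np.uint64)
    for j in range(k):
        packed = (packed << np.uint64(2)) | codes64[j : j + n]
    is_n = (codes == 4).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(is_n)))
    ok = (cum[k:] - cum[:-k]) == 0
    return packed[ok], np.nonzero(ok)[0].astype(np.int64)


class SubjectIndex:
    """Sorted array of a subject genome's forward-strand seed k-mers, for
    O(log n) candidate-locus lookup."""

    def __init__(self, genome: GenomeRecord, seed_k: int):
        self.genome = genome
        self.seed_k = seed_k
        kmer_parts: list[np.ndarray] = []
        pos_parts: list[np.ndarray] = []
        ctg_parts: list[np.ndarray] = []
        for idx, (cid, seq) in enumerate(genome.contigs):
            km, pos = _forward_kmers_with_pos(seq, seed_k)
            kmer_parts.append(km)
            pos_parts.append(pos)
            ctg_parts.append(np.full(km.size, idx, dtype=np.int32))
        kmers = np.concatenate(kmer_parts) if kmer_parts else np.empty(0, np.uint64)
        order = np.argsort(kmers, kind="stable")
        self.kmers = kmers[order]
        self.positions = (np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64))[order]
        self.contig_idx = (np.concatenate(ctg_parts) if ctg_parts else np.empty(0, np.int32))[order]

    def lookup(self, query_kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ranges [lo, hi) into the sorted arrays for each query k-mer."""
        lo = np.searchsorted(self.kmers, query_kmers, side="left")
        hi = np.searchsorted(self.kmers, query_kmers, side="right")
        return lo, hi


# ---------------------------------------------------------------------------
# Fragment alignment
# ---------------------------------------------------------------------------

def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


_MISMATCH_PENALTY = 2  # BLAST-like: segments below ~2/3 identity score negative,
# so spurious alignment through unrelated sequence (random DNA pairs reach
# ~55% matches under unit-cost optimal alignment) is trimmed away


def _best_segment(runs: list[tuple[int, str]]) -> tuple[int, int, int]:
    """Maximal-scoring contiguous alignment segment (match +1,
    mismatch/gap -2), computed at run level (an optimal segment starts and
    ends on a match run). Returns (matches, columns, query_bases) of the
    best segment."""
    best = (0, 0, 0)
    best_score = 0
    cur_score = 0
    cur = [0, 0, 0]  # matches, cols, qbases
    for length, op in runs:
        score = length if op == "=" else -_MISMATCH_PENALTY * length
        if cur_score + score < score:  # restart at this run
            cur_score = 0
            cur = [0, 0, 0]
        cur_score += score
        cur[1] += length
        if op == "=":
            cur[0] += length
        if op in "=XI":
            cur[2] += length
        if cur_score > best_score:
            best_score = cur_score
            best = tuple(cur)
    return best


def _candidate_windows(
    frag_len: int,
    seed_pos: np.ndarray,
    index: SubjectIndex,
    lo: np.ndarray,
    hi: np.ndarray,
    config: ANIConfig,
    band: int,
) -> list[tuple[int, int, int]]:
    """Cluster seed hits by (contig, diagonal band) and return up to
    max_candidates windows as (contig_idx, win_start, win_end), ordered by
    decreasing seed support."""
    ctgs: list[np.ndarray] = []
    diags: list[np.ndarray] = []
    for qi in range(seed_pos.size):
        a, b = int(lo[qi]), int(hi[qi])
        if a == b:
            continue
        if b - a > config.max_seed_hits:
            b = a + config.max_seed_hits
        ctgs.append(index.contig_idx[a:b])
        diags.append(index.positions[a:b] - int(seed_pos[qi]))
    if not ctgs:
        return []
    ctg = np.concatenate(ctgs)
    diag = np.concatenate(diags)
    bucket = diag // max(band, 1)
    key = ctg.astype(np.int64) * (1 << 40) + (bucket + (1 << 39))
    uniq, counts = np.unique(key, return_counts=True)
    top = uniq[np.argsort(-counts, kind="stable")][: config.max_candidates]
    windows: list[tuple[int, int, int]] = []
    for k in top:
        sel = key == k
        c = int(ctg[sel][0])
        dmin, dmax = int(diag[sel].min()), int(diag[sel].max())
        clen = len(index.genome.contigs[c][1])
        ws = max(0, dmin - band)
        we = min(clen, dmax + frag_len + band)
        if we > ws:
            windows.append((c, ws, we))
    return windows


def _sparse_seeds(
    seq: str, config: ANIConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Seed k-mers of a fragment at seed_stride spacing (plus the final
    position), with their offsets."""
    km, pos = _forward_kmers_with_pos(seq, config.seed_k)
    if km.size == 0:
        return km, pos
    take = np.arange(0, pos.size, config.seed_stride)
    if take.size == 0 or take[-1] != pos.size - 1:
        take = np.append(take, pos.size - 1)
    return km[take], pos[take]


def _align_oriented(
    fragment_len: int,
    oriented: str,
    km: np.ndarray,
    pos: np.ndarray,
    index: SubjectIndex,
    config: ANIConfig,
    band: int,
    strand: str,
    best: Optional[FragmentHit],
) -> Optional[FragmentHit]:
    if km.size > 0:
        lo, hi = index.lookup(km)
        for c, ws, we in _candidate_windows(len(oriented), pos, index, lo, hi, config, band):
            window = index.genome.contigs[c][1][ws:we]
            res = edlib.align(oriented, window, mode="HW", task="path", k=band)
            if res["editDistance"] < 0:
                continue
            matches, cols, qbases = _best_segment(_parse_cigar(res["cigar"]))
            if cols == 0:
                continue
            identity = matches / cols
            if identity < config.min_hit_identity:
                continue
            if qbases / fragment_len < config.min_hit_fraction:
                continue
            hit = FragmentHit(identity, qbases, index.genome.contigs[c][0], strand)
            if best is None or (hit.identity, hit.aligned_query_bp) > (
                best.identity,
                best.aligned_query_bp,
            ):
                best = hit
    return best


def align_fragment(
    fragment: str,
    subject: GenomeRecord | SubjectIndex,
    config: ANIConfig | None = None,
) -> Optional[FragmentHit]:
    """Best accepted hit of a fragment against a subject genome, or None.

    Both strands are searched; identity is computed on the aligned
    orientation after trimming to the maximal-scoring local segment.
    """
    config = config or ANIConfig()
    if len(fragment) < config.min_fragment:
        raise MagderepError(
            f"fragment of {len(fragment)} bp is below min_fragment={config.min_fragment}"
        )
    index = subject if isinstance(subject, SubjectIndex) else SubjectIndex(subject, config.seed_k)
    band = max(1, int(round(config.band_fraction * config.fragment_length)))
    best: Optional[FragmentHit] = None
    for strand in ("+", "-"):
        oriented = fragment if strand == "+" else reverse_complement(fragment)
        km, pos = _sparse_seeds(oriented, config)
        best = _align_oriented(
            len(fragment), oriented, km, pos, index, config, band, strand, best
        )
    return best


# ---------------------------------------------------------------------------
# Genome-level ANI
# ---------------------------------------------------------------------------

class QueryProfile:
    """Fragments of a query genome with precomputed sparse seed k-mers on
    both strands, reusable across subjects."""

    def __init__(self, genome: GenomeRecord, config: ANIConfig):
        self.genome = genome
        self.fragments = fragment_genome(genome, config)
        self.prepped: list[list[tuple[str, str, np.ndarray, np.ndarray]]] = []
        for frag in self.fragments:
            per_strand = []
            for strand in ("+", "-"):
                oriented = (
                    frag.sequence if strand == "+" else reverse_complement(frag.sequence)
                )
                km, pos = _sparse_seeds(oriented, config)
                per_strand.append((strand, oriented, km, pos))
            self.prepped.append(per_strand)


def one_way_ani(
    query: GenomeRecord,
    subject: GenomeRecord,
    config: ANIConfig | None = None,
    query_profile: QueryProfile | None = None,
    subject_index: SubjectIndex | None = None,
) -> tuple[Optional[float], float, int, int]:
    """One-direction ANI and coverage (percent).

    Returns (ani, coverage, n_fragments, n_accepted); ani is None when no
    fragment was accepted. ANI is the unweighted mean identity of accepted
    fragments; coverage sums accepted aligned query bases over the query's
    total length. ``query_profile``/``subject_index`` allow reusing the
    per-genome preprocessing across many pairs.
    """
    config = config or ANIConfig()
    profile = query_profile or QueryProfile(query, config)
    if not profile.fragments:
        raise MagderepError(
            f"genome {query.genome_id!r} yields no fragments "
            f"(all contigs < min_fragment={config.min_fragment})"
        )
    index = subject_index or SubjectIndex(subject, config.seed_k)
    band = max(1, int(round(config.band_fraction * config.fragment_length)))
    identities: list[float] = []
    aligned_bp = 0
    for frag, per_strand in zip(profile.fragments, profile.prepped):
        best: Optional[FragmentHit] = None
        for strand, oriented, km, pos in per_strand:
            best = _align_oriented(
                len(frag), oriented, km, pos, index, config, band, strand, best
            )
        if best is not None:
            identities.append(best.identity)
            aligned_bp += best.aligned_query_bp
    cov = 100.0 * aligned_bp / query.total_length
    if not identities:
        return None, 0.0, len(profile.fragments), 0
    ani = 100.0 * float(np.mean(identities))
    return ani, cov, len(profile.fragments), len(identities)


def compare_pair(
    a: GenomeRecord, b: GenomeRecord, config: ANIConfig | None = None
) -> ANIResult:
    """Bidirectional ANI for one genome pair (query = a, subject = b)."""
    ani_qs, cov_q, nf_q, acc_q = one_way_ani(a, b, config)
    ani_sq, cov_s, nf_s, acc_s = one_way_ani(b, a, config)
    return ANIResult(
        a.genome_id, b.genome_id, ani_qs, cov_q, ani_sq, cov_s, nf_q, nf_s, acc_q, acc_s
    )


def pairwise_ani(
    cluster: list[GenomeRecord], config: ANIConfig | None = None
) -> list[ANIResult]:
    """All unordered pairs within a cluster, both directions, in
    lexicographic (query, subject) order.

    Per-genome fragment profiles and seed indexes are built once and shared
    across the pairs.
    """
    if len(cluster) < 2:
        raise MagderepError("pairwise ANI needs a cluster of at least 2 genomes")
    config = config or ANIConfig()
    by_id = {g.genome_id: g for g in cluster}
    if len(by_id) != len(cluster):
        raise MagderepError("duplicate genome ids in cluster")
    ids = sorted(by_id)
    profiles = {g: QueryProfile(by_id[g], config) for g in ids}
    indexes = {g: SubjectIndex(by_id[g], config.seed_k) for g in ids}
    out: list[ANIResult] = []
    for i, qa in enumerate(ids):
        for sb in ids[i + 1 :]:
            ani_qs, cov_q, nf_q, acc_q = one_way_ani(
                by_id[qa], by_id[sb], config, profiles[qa], indexes[sb]
            )
            ani_sq, cov_s, nf_s, acc_s = one_way_ani(
                by_id[sb], by_id[qa], config, profiles[sb], indexes[qa]
            )
            out.append(
                ANIResult(
                    qa, sb, ani_qs, cov_q, ani_sq, cov_s, nf_q, nf_s, acc_q, acc_s
                )
            )
    return out


# ---------------------------------------------------------------------------
# ani_pairs.tsv round-trip
# ---------------------------------------------------------------------------

_ANI_COLUMNS = (
    "query\tsubject\tani_qs\tcov_q\tani_sq\tcov_s\t"
    "n_fragments_q\tn_fragments_s\taccepted_q\taccepted_s"
)


def _fmt(v: Optional[float]) -> str:
    # repr round-trips floats bit-exactly through the TSV
    return "NA" if v is None else repr(v)


def write_ani_pairs(results: Iterable[ANIResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_ANI_COLUMNS + "\n")
        for r in results:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{_fmt(r.ani_qs)}\t{r.cov_q!r}\t"
                f"{_fmt(r.ani_sq)}\t{r.cov_s!r}\t{r.n_fragments_q}\t"
                f"{r.n_fragments_s}\t{r.accepted_q}\t{r.accepted_s}\n"
            )


def read_ani_pairs(path: str) -> list[ANIResult]:
    out: list[ANIResult] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _ANI_COLUMNS:
            raise MagderepError(f"{path!r}: unexpected ani_pairs header")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                ANIResult(
                    f[0],
                    f[1],
                    None if f[2] == "NA" else float(f[2]),
                    float(f[3]),
                    None if f[4] == "NA" else float(f[4]),
                    float(f[5]),
                    int(f[6]),
                    int(f[7]),
                    int(f[8]),
                    int(f[9]),
                )
            )
    return out
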