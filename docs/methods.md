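# Methods

## Problem setting

Independent assembly of time- or space-series metagenomes yields multiple
metagenome-assembled genomes (MAGs) of the same bacterial population.
Dereplication removes genomes that are redundant with a retained
representative, usually judged by average nucleotide identity (ANI) over
aligned regions. `magderep` implements one specific, reproducible reading
of the common two-stage workflow — fast MinHash pre-grouping followed by
exact fragment-based ANI within groups — together with the measurement
procedures needed to understand its failure modes (incomplete genomes,
auxiliary-gene loss, read-coverage dilution).

## Sketching and pre-clustering

A genome's sketch is the *s* smallest values of a fixed 64-bit hash over
its canonical k-mers (lexicographic minimum of k-mer and reverse
complement; k-mers containing `N` are skipped). Defaults k = 21, s = 1000
follow MinHash genome-sketching convention. The hash is splitmix64 applied
to the 2-bit-packed k-mer XORed with a constant seed (42); for k ≤ 31 the
packed integer is a bijection of the k-mer string, so sketches are
identical across runs, machines and Python versions — the platform `hash`
is never used. Jaccard similarity is estimated on the *merged* bottom-s′
sketch (s′ = min(s, |union|)): the fraction of the s′ smallest union
hashes present in both sketches, the unbiased bottom-sketch estimator. The
Mash distance transform d = −(1/k)·ln(2j/(1+j)) maps j = 1 to 0 and is
capped at 1 (j = 0 maps to 1).

Pre-clusters are flat clusters of the average-linkage dendrogram of the
distance matrix, cut by SciPy's `fcluster` with the inconsistency
criterion at threshold 2 and depth 2 — the defaults of that routine, and
the configuration used by the published Mash-then-ANI workflows this
package follows. Genomes are presented to the agglomerator in
lexicographic id order so ties resolve deterministically.

Two properties of this criterion matter at small n. The inconsistency
coefficient of a merge is a z-score over at most 7 sub-merge heights
(depth 2), and a z-score over m values cannot exceed (m−1)/√m; balanced
trees over fewer than ~10 leaves therefore never reach 2, and small
genome sets land in a single pre-cluster regardless of structure. That is
harmless: pre-clustering only limits which pairs get exact ANI, and pairs
of unrelated genomes fail the ANI rule anyway. The property that matters —
conspecific genomes are never split across pre-clusters, which would
silently prevent their comparison — holds and is tested. Users who want
the pre-cluster partition itself to track species on small sets should use
`criterion="distance"` with a threshold around 0.05–0.1 (Mash distance
scale); tests verify exact planted-structure recovery in that mode.

## Fragment ANI

ANI follows the BLAST-based (ANIb-style) convention. The query is cut into
consecutive 1020-bp windows per contig (trailing windows kept if ≥ 100
bp). For each fragment:

1. **Seeding.** 15-bp seed k-mers at 50-bp spacing (both strands) are
   looked up in a sorted index of the subject's forward-strand k-mers;
   hits vote for (contig, diagonal-band) candidate loci, and up to 4
   candidates are examined, highest support first.
2. **Banded alignment.** The fragment is aligned to the candidate window
   with edlib in infix mode, with the edit distance capped at
   band_fraction·L = 204; the cap bounds both the DP band and the
   detectable per-fragment divergence (~20%), ample for decisions made
   near 99% identity.
3. **Local trim.** The alignment is trimmed to its maximal-scoring
   contiguous segment under match +1, mismatch/gap −2. The penalty is
   deliberately BLAST-like: optimal unit-cost alignment of unrelated DNA
   realises ~55% matches, which a −1 penalty would keep (net positive) but
   −2 trims (segments below 2/3 identity score negative). This makes
   fragments that only partially overlap the subject — aux-block
   junctions, contig boundaries — report local hits instead of diluted
   whole-fragment identities.
4. **Acceptance.** A hit needs identity ≥ 0.3 (matches over all alignment
   columns; indel columns count as mismatches) over ≥ 0.7 of the fragment.

One-way ANI is the *unweighted* mean identity of accepted fragments
(stated explicitly because trailing fragments are shorter); one-way
coverage is the sum of aligned query bases over total query length × 100.
Coordinates are 0-based half-open throughout. Self-comparison yields ANI
exactly 100 and coverage equal to the fragmentable fraction of the genome.

On substitution-only synthetic pairs the estimator recovers the planted
divergence within ±0.1 ANI points at 0.5–3.5% divergence (the test bound
is ±0.3). Realistic generator settings cost a little more: indels at the
default rates subtract ~0.3 points (indel columns count against identity),
and fragments spanning subject contig boundaries or genome-specific
auxiliary blocks are rejected by the length rule, leaving coverage of
complete conspecific genomes around 88–92%, comfortably above the 75%
threshold.

## Redundancy rule and representatives

A pair is redundant iff ANI ≥ θ and coverage ≥ γ **in both directions**
(defaults θ = 99, γ = 75); a pair with no accepted fragments is never
redundant. Redundant pairs are edges of a graph per pre-cluster; secondary
clusters are its connected components. Components are the weakest
defensible reading of "share ANI above the threshold" and make chaining
behaviour explicit; a stricter `grouping="complete"` mode builds maximal
all-pairs-pass groups greedily from the highest-quality seed. Each
secondary cluster retains the genome maximising completeness −
w·contamination (w = 5, the common dereplication convention for collapsing
the two-objective "most complete, least contaminated" rule into one
score; w = 0 gives pure-completeness selection). Ties break toward the
longer genome, then the lexicographically smaller id. Raising θ or γ can
only remove edges, so the retained count is monotone in both thresholds,
and re-running the pipeline on the retained set removes nothing; both
properties are tested.

## Evaluation procedures

**Completeness grid.** Every genome is subsampled by shuffling its contigs
with a seeded generator and keeping the longest prefix whose cumulative
length stays within fraction·total (never empty), preserving original
contig order — an unbiased-in-expectation sampler for "random subsampling
of contigs" that handles uneven contig lengths. The pipeline then runs at
θ = 99 for each coverage threshold in the grid. Because γ enters only the
redundancy rule, sketching/pre-clustering/ANI are computed once per
(replicate, fraction) and shared across the γ column; results are
identical to independent full runs. The default grid is fractions
0.1–1.0 × γ ∈ {10, 25, 50, 75} with 5 replicates (the number of replicates
behind the published grids is not stated; means are reported when
replicates > 1). The driving mechanism is the subset-coverage law: if a
genome retains fraction f of the shared content, mutual alignment coverage
estimates ~f, so f < γ/100 blocks dereplication regardless of ANI.

**Gene-cluster retention.** Given a genome → gene-cluster membership table
(pangenome presence/absence), the retained universe is the union of
cluster sets over kept genomes; retained + lost = universe size by
construction (fuzz-tested).

**Coverage dilution.** Error-free forward-strand reads (default 4000 ×
150 bp) are drawn uniformly from a source genome and assigned to the
database genome(s) containing their best match — exact substring first,
the fragment aligner as fallback — with ties broken uniformly at random
(one random placement, as read mappers report by default; an all-hits mode
is a flag). Mean coverage is reads × read length / genome length. With r
identical copies in the database each copy receives ~1/r of the reads, the
artifact that makes redundant populations look rare; after dereplication
the single representative receives all of them.

## Synthetic MAG generator

The generator plants known structure: per species one ancestor (siblings
diverged from a common root when between-species ANI ≥ 90%, so
species-boundary regimes ~95–96.5% are constructible; independent random
sequences below that), per MAG a diverged copy of the species ancestor
plus genome-specific auxiliary blocks, fragmented into contigs at random
breakpoints (≥1 kb each), optionally subsampled to a drawn completeness.
Auxiliary blocks come from a per-species pool of 2× the per-genome count;
each MAG carries a random subset and every pool block is guaranteed at
least one carrier, and blocks are registered as planted gene clusters
alongside one per-species core cluster. The quality table reports true
completeness with small Gaussian noise (sd 0.3 points) and zero
contamination.

ANI targets are **pairwise**: two conspecific MAGs should measure
`within_ani` against *each other*, not against their unobserved ancestor.
Each branch therefore receives substitution rate q solving
(1−q)² + q²/3 = ANI/100 (per-site match probability of two independent
branches when a substituted base is drawn uniformly from the three
alternatives). The literal alternative — per-branch rate 1 − ANI/100 —
would put conspecific pairs at roughly twice the intended divergence and
make a 99.5% "within-ANI" set straddle the 99% decision threshold.
Substitutions always change the base; indels (default 5×10⁻⁴ per base per
branch, geometric lengths with mean 3) are recorded, with substitutions,
in a mask that replays exactly. Defaults (200-kb genomes, 20 contigs,
within 99.5% / between 80%, 5 × 2-kb aux blocks) place planted structure
safely on both sides of the 99% boundary.

What the generator does **not** emulate: rearrangements and inversions,
repeat families, GC skew and composition bias, sequencing error,
chimeric/composite bins, and contamination > 0. Passing tests therefore
demonstrate the correctness of the decision logic and the estimators under
idealised conspecific structure, not performance on real assemblies —
real MAGs add alignment noise and binning artefacts that shift ANI and
coverage near the thresholds.

## Problem sizes and numerical choices

The test suite and the acceptance script use 200-kb genomes for
estimator-accuracy and planted-recovery runs (bacterial-scale dynamics at
desk-scale cost; ANI error scales with 1/√(aligned length), so 200 kb
already gives ~0.02-point standard error at 1% divergence), 100-kb pairs
for the MinHash fidelity trials, and 30–60-kb sets for pipeline-logic
checks where sequence length is irrelevant. Determinism is exact, not
approximate: fixed hash seed, lexicographic tie-breaks everywhere
(agglomeration order, candidate windows, representative selection), and
floats round-tripped through tables via shortest-repr formatting, so two
runs with the same seed produce byte-identical outputs.

Degenerate inputs have defined behaviour: a single genome passes through
as its own cluster and representative; genomes whose contigs are all
shorter than the minimum fragment are an error for ANI; a fraction-1.0
subsample is the identity; an empty quality-table body is an empty set. A
pair whose ANI is undefined (no accepted fragments) is non-redundant by
definition.

## Known limitations

- The pre-cluster inconsistency criterion cannot split sets of fewer than
  ~10 genomes (see above); use the distance criterion when the partition
  itself is the object of interest on small sets.
- The fragment aligner's edit cap hides homology below ~80% per-fragment
  identity; between-species ANI values reported near that floor are
  biased toward the accepted (higher-identity) fragments. Dereplication
  decisions at 99% are unaffected.
- Quality estimates are inputs; the package does not estimate completeness
  or contamination, and the completeness-grid experiment interprets the
  subsampling fraction, not a marker-gene estimate, as truth.
- The dilution simulator models error-free reads and exact redundancy; it
  quantifies the database-redundancy artifact, not mapper-specific
  behaviour.
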