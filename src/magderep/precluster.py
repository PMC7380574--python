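"""Mash pre-clustering: hierarchical clustering of the sketch distance
matrix with flat-cluster extraction.

The workflow mirrors the common custom-script approach for MAG sets:
average-linkage agglomeration of Mash distances, cut with SciPy's
``fcluster`` using the inconsistency criterion at a threshold of 2 (the
routine's defaults). A raw-distance cut is offered as an alternative; note a
distance threshold of 2 would be vacuous since Mash distances are <= 1, which
is why the inconsistency criterion is the meaningful default here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, inconsistent, linkage
from scipy.spatial.distance import squareform

from .core_io import GenomeRecord, MagderepError
from .sketch import DistanceMatrix, SketchParams, pairwise_distance_matrix, sketch_genome

_LINKAGES = ("average", "single", "complete")
_CRITERIA = ("inconsistent", "distance")


@dataclass(frozen=True)
class PreclusterConfig:
    linkage: str = "average"
    criterion: str = "inconsistent"
    threshold: float = 2.0
    depth: int = 2

    def __post_init__(self) -> None:
        if self.linkage not in _LINKAGES:
            raise MagderepError(f"linkage must be one of {_LINKAGES}")
        if self.criterion not in _CRITERIA:
            raise MagderepError(f"criterion must be one of {_CRITERIA}")
        if self.threshold <= 0:
            raise MagderepError("threshold must be > 0")
        if self.depth < 1:
            raise MagderepError("depth must be >= 1")


def build_linkage(dm: DistanceMatrix, method: str = "average") -> np.ndarray:
    """Agglomerative merge tree (SciPy linkage matrix, n-1 rows of
    [left, right, height, size]) over the distance matrix.

    Genomes are presented to the agglomerator in lexicographic id order so
    ties resolve identically regardless of input order.
    """
    if method not in _LINKAGES:
        raise MagderepError(f"linkage must be one of {_LINKAGES}")
    vals = dm.values
    if vals.shape[0] != vals.shape[1] or not np.allclose(vals, vals.T):
        raise MagderepError("distance matrix must be symmetric")
    if np.any(vals < 0) or np.any(np.diag(vals) != 0):
        raise MagderepError("distance matrix must be non-negative with zero diagonal")
    order = np.argsort(np.array(dm.ids))
    condensed = squareform(vals[np.ix_(order, order)], checks=False)
    return linkage(condensed, method=method)


def inconsistency_coefficient(merge_tree: np.ndarray, depth: int = 2) -> np.ndarray:
    """Per-merge inconsistency coefficient: (height - mean) / sd over the
    heights of merges within ``depth`` levels below (inclusive); 0 when the
    sd is 0."""
    return inconsistent(merge_tree, d=depth)[:, 3]


def flat_clusters(
    merge_tree: np.ndarray,
    ids_sorted: tuple[str, ...],
    config: PreclusterConfig,
) -> dict[str, int]:
    """Cut the tree so no within-cluster merge exceeds the threshold under
    the chosen criterion. Labels are 1-based, numbered by first appearance
    in ``ids_sorted`` order."""
    raw = fcluster(
        merge_tree,
        t=config.threshold,
        criterion=config.criterion,
        depth=config.depth,
    )
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for gid, lab in zip(ids_sorted, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[gid] = relabel[lab]
    return out


def precluster(
    genomes: list[GenomeRecord],
    sketch_params: SketchParams | None = None,
    config: PreclusterConfig | None = None,
) -> list[list[str]]:
    """Full pre-clustering stage: sketch -> distances -> linkage -> flat cut.

    Returns a partition of genome ids (list of clusters, each a sorted list
    of ids), ordered by cluster label. A single genome passes through as one
    singleton cluster.
    """
    if not genomes:
        raise MagderepError("no genomes to precluster")
    config = config or PreclusterConfig()
    if len(genomes) == 1:
        return [[genomes[0].genome_id]]
    sketches = [sketch_genome(g, sketch_params) for g in genomes]
    dm = pairwise_distance_matrix(sketches)
    tree = build_linkage(dm, config.linkage)
    ids_sorted = tuple(sorted(dm.ids))
    labels = flat_clusters(tree, ids_sorted, config)
    clusters: dict[int, list[str]] = {}
    for gid, lab in labels.items():
        clusters.setdefault(lab, []).append(gid)
    return [sorted(clusters[lab]) for lab in sorted(clusters)]


def write_preclusters(clusters: list[list[str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tprecluster\n")
        for lab, members in enumerate(clusters, start=1):
            for gid in members:
                fh.write(f"{gid}\t{lab}\n")


def read_preclusters(path: str) -> list[list[str]]:
    acc: dict[int, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("genome_id"):
            raise MagderepError(f"{path!r}: malformed preclusters file")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gid, lab = line.rstrip("\n").split("\t")
            acc.setdefault(int(lab), []).append(gid)
    return [sorted(acc[lab]) for lab in sorted(acc)]
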