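"""Edge-labeled triangle motif census.

Every pair of regions in an R2SN carries an edge, classified into four
classes by dichotomizing its weight (strength) and its inter-centroid
Euclidean distance (length) at cohort medians.  A triangle's motif type
is the multiset of its three edge classes; with 4 classes there are
exactly C(4+3-1, 3) = 20 types.  The census counts, for each region, the
triangles of each type it participates in, yielding a 20 x N matrix per
subject.
"""

from __future__ import annotations

from enum import IntEnum
from itertools import combinations, combinations_with_replacement, product

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .types import AtlasGeometry, MotifCountMatrix, R2SN, ThresholdPair

__all__ = [
    "EdgeClass",
    "MotifTypeCatalog",
    "compute_edge_lengths",
    "compute_thresholds",
    "label_edges",
    "build_catalog",
    "count_motifs",
    "count_motifs_bruteforce",
]


class EdgeClass(IntEnum):
    """Strength x length edge classes, in catalog (lexicographic) order."""

    STRONG_LONG = 0
    STRONG_SHORT = 1
    WEAK_LONG = 2
    WEAK_SHORT = 3

    @property
    def short_label(self) -> str:
        return {"STRONG_LONG": "SL", "STRONG_SHORT": "SS",
                "WEAK_LONG": "WL", "WEAK_SHORT": "WS"}[self.name]


class MotifTypeCatalog:
    """The 20 canonical triangle types: sorted triples of edge classes.

    Canonical form of an edge-label triple is the sorted tuple under the
    ``EdgeClass`` integer order; catalog entries are ordered
    lexicographically, indexed 0..19 internally (1..20 in output tables).
    """

    def __init__(self) -> None:
        triples = sorted(combinations_with_replacement(range(4), 3))
        self.triples: list[tuple[int, int, int]] = [tuple(t) for t in triples]
        self._index: dict[tuple[int, int, int], int] = {
            t: i for i, t in enumerate(self.triples)
        }

    def __len__(self) -> int:
        return len(self.triples)

    def index_of(self, classes) -> int:
        """Catalog index (0-based) of an edge-class triple in any order."""
        key = tuple(sorted(int(c) for c in classes))
        try:
            return self._index[key]
        except KeyError:
            raise ValueError(f"not a valid edge-class triple: {classes!r}") from None

    def label(self, idx: int) -> str:
        return "|".join(EdgeClass(c).short_label for c in self.triples[idx])

    @property
    def labels(self) -> list[str]:
        return [self.label(i) for i in range(len(self))]

    @property
    def all_weak_short_index(self) -> int:
        """Index of the homogeneous weak-short triangle (the PMV sign anchor)."""
        return self._index[(3, 3, 3)]


def build_catalog() -> MotifTypeCatalog:
    """Enumerate all 4**3 = 64 ordered edge-label triples, canonicalize by
    sorting, and deduplicate into the 20-type catalog."""
    catalog = MotifTypeCatalog()
    seen = {tuple(sorted(t)) for t in product(range(4), repeat=3)}
    assert seen == set(catalog.triples)  # construction self-check, O(64)
    return catalog


def compute_edge_lengths(atlas: AtlasGeometry) -> np.ndarray:
    """Symmetric matrix of Euclidean inter-centroid distances (mm)."""
    return squareform(pdist(atlas.centroids, metric="euclidean"))


def compute_thresholds(cohort_r2sns: list[R2SN], distances: np.ndarray) -> ThresholdPair:
    """Cohort medians used to binarize edges.

    Strength: median of the pooled upper-triangle weights of every
    subject's R2SN.  Length: median of the C(N, 2) pair distances, which
    is subject-invariant because geometry comes from the atlas.
    """
    if len(cohort_r2sns) == 0:
        raise ValueError("cannot compute thresholds from an empty cohort")
    n = cohort_r2sns[0].n_regions
    iu = np.triu_indices(n, k=1)
    pooled = np.concatenate([net.weights[iu] for net in cohort_r2sns])
    return ThresholdPair(
        strength_median=float(np.median(pooled)),
        length_median=float(np.median(distances[iu])),
        provenance=f"pooled over {len(cohort_r2sns)} subjects, {n} regions",
    )


def label_edges(net: R2SN, distances: np.ndarray, thr: ThresholdPair) -> np.ndarray:
    """Classify every edge into one of the four strength x length classes.

    Strength strictly above the strength median is STRONG, otherwise WEAK
    (ties fall on the WEAK side); distance strictly above the length
    median is LONG, otherwise SHORT.  Returns an (N, N) int array of
    ``EdgeClass`` values with -1 on the diagonal.
    """
    if distances.shape != net.weights.shape:
        raise ValueError(
            f"distance matrix shape {distances.shape} does not match "
            f"network shape {net.weights.shape}"
        )
    strong = net.weights > thr.strength_median
    long_ = distances > thr.length_median
    # class code = 2*(not strong) + (not long): SL=0, SS=1, WL=2, WS=3
    labels = 2 * (~strong).astype(np.int8) + (~long_).astype(np.int8)
    np.fill_diagonal(labels, -1)
    return labels


def _indicator_stack(labels: np.ndarray) -> np.ndarray:
    """(4, N, N) float indicators per edge class, zero diagonal."""
    n = labels.shape[0]
    ind = np.zeros((4, n, n))
    off = ~np.eye(n, dtype=bool)
    for c in range(4):
        ind[c] = (labels == c) & off
    return ind


def count_motifs(labels: np.ndarray, catalog: MotifTypeCatalog | None = None,
                 subject_id: str = "", region_ids=None) -> MotifCountMatrix:
    """Per-region census of the 20 triangle types.

    For every unordered region triple the triangle's type (the multiset
    of its 3 edge classes) is credited once to each of the three member
    regions.  Computed by matrix products over the four class-indicator
    matrices: for incident classes (a, b) at region j and opposite class
    c, the ordered path count is diag(A_a @ A_c @ A_b); unordered
    triangles follow by symmetry (halving when a == b).
    """
    if catalog is None:
        catalog = build_catalog()
    n = labels.shape[0]
    if labels.shape != (n, n) or n < 3:
        raise ValueError("labels must be a square matrix over >= 3 regions")
    if region_ids is None:
        region_ids = np.arange(1, n + 1)

    ind = _indicator_stack(labels)
    counts = np.zeros((len(catalog), n), dtype=np.int64)
    # diag(A_a @ A_c @ A_b) = rowsum((A_a @ A_c) * A_b) for symmetric A_b
    prod = {(a, c): ind[a] @ ind[c] for a in range(4) for c in range(4)}
    # incident pair {a, b} (a <= b) at the counted region, opposite edge c
    for a in range(4):
        for b in range(a, 4):
            for c in range(4):
                diag = (prod[a, c] * ind[b]).sum(axis=1)
                tri = diag / 2 if a == b else diag
                t = catalog.index_of((a, b, c))
                counts[t] += np.rint(tri).astype(np.int64)
    mcm = MotifCountMatrix(counts=counts, region_ids=region_ids, subject_id=subject_id)
    _check_conservation(mcm)
    return mcm


def count_motifs_bruteforce(labels: np.ndarray,
                            catalog: MotifTypeCatalog | None = None) -> np.ndarray:
    """Naive triple-loop census (the independent oracle; O(N^3) python)."""
    if catalog is None:
        catalog = build_catalog()
    n = labels.shape[0]
    counts = np.zeros((len(catalog), n), dtype=np.int64)
    for i, j, k in combinations(range(n), 3):
        t = catalog.index_of((labels[i, j], labels[i, k], labels[j, k]))
        counts[t, i] += 1
        counts[t, j] += 1
        counts[t, k] += 1
    return counts


def _check_conservation(mcm: MotifCountMatrix) -> None:
    n = mcm.n_regions
    expected = (n - 1) * (n - 2) // 2  # C(N-1, 2) triangles touch each region
    col_sums = mcm.counts.sum(axis=0)
    if not np.all(col_sums == expected):
        raise AssertionError(
            f"motif census conservation violated: column sums {np.unique(col_sums)} "
            f"!= C(N-1,2) = {expected} (internal error)"
        )
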