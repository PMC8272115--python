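"""Aggregate characterization: clustering, size statistics, order parameter
and gyration-tensor shape descriptors.

Aggregates are defined by a separation-distance criterion: any two beads of
the analyzed subset within 1.5 R_c of each other (minimum image) belong to
the same aggregate, i.e. aggregates are the connected components of the
proximity graph at that cutoff.  Size statistics follow the standard
number / weight averages

    Xn = sum_i X_i N_i / sum_i N_i,
    Xw = sum_i X_i^2 N_i / sum_i X_i N_i,     P = Xw / Xn >= 1,

where N_i is the number of aggregates of X_i beads.  Segregation of two
components is measured by slicing the box into N slabs of equal thickness
and averaging |phi_A - phi_B| over slices (0 = mixed, 1 = fully
segregated).  Shape is measured by the asphericity

    delta = [(l1-l2)^2 + (l1-l3)^2 + (l3-l2)^2] / [2 (l1+l2+l3)^2],

with l_k the principal moments (eigenvalues) of the gyration tensor of the
cluster; delta = 0 for a sphere, 1/4 for a flat disk, 1 for a line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

DEFAULT_CLUSTER_CUTOFF = 1.5


class UnwrapAmbiguityError(ValueError):
    """A cluster is connected to its own periodic image (percolates), so a
    single-image unwrapping does not exist."""


class UndefinedStatisticsError(ValueError):
    """Statistics requested for an empty aggregate set."""


@dataclass
class AggregateSet:
    """Partition of a bead subset into distance-criterion clusters.

    ``clusters`` holds arrays of *global* bead indices, sorted by decreasing
    size; ``subset`` is the analyzed bead subset.
    """

    clusters: list[np.ndarray] = field(default_factory=list)
    subset: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    cutoff: float = DEFAULT_CLUSTER_CUTOFF

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], dtype=np.int64)

    def largest(self) -> np.ndarray:
        if not self.clusters:
            raise UndefinedStatisticsError("no clusters in aggregate set")
        return self.clusters[0]


@dataclass(frozen=True)
class SizeStatistics:
    """Number-average and weight-average aggregate size and polydispersity."""

    Xn: float
    Xw: float
    P: float
    n_clusters: int


@dataclass(frozen=True)
class OrderParameterResult:
    """Per-slice volume fractions of two components and their mean
    absolute difference phi."""

    n_slices: int
    phi_a: np.ndarray
    phi_b: np.ndarray
    phi: float


@dataclass(frozen=True)
class ShapeDescriptor:
    """Principal gyration-tensor moments (descending) and asphericity."""

    lam1_sq: float
    lam2_sq: float
    lam3_sq: float
    delta: float

    @property
    def rg_sq(self) -> float:
        return self.lam1_sq + self.lam2_sq + self.lam3_sq


def _wrap(positions: np.ndarray, box_edge: float) -> np.ndarray:
    out = positions - box_edge * np.floor(positions / box_edge)
    # guard against coordinates landing exactly on the upper face
    out[out >= box_edge] = 0.0
    return out


def periodic_pairs(positions: np.ndarray, box_edge: float,
                   cutoff: float) -> np.ndarray:
    """All index pairs closer than ``cutoff`` under periodic boundaries."""
    tree = cKDTree(_wrap(positions, box_edge), boxsize=box_edge)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs


def find_aggregates(positions: np.ndarray, box_edge: float,
                    subset: np.ndarray | None = None,
                    cutoff: float = DEFAULT_CLUSTER_CUTOFF) -> AggregateSet:
    """Single-linkage clusters of ``subset`` beads at the distance cutoff.

    ``positions`` is the full (N, 3) coordinate array; ``subset`` selects
    the beads to cluster (default: all).  Returns clusters of global bead
    indices sorted largest first (ties broken by smallest member index, so
    the partition is independent of input ordering).
    """
    if subset is None:
        subset = np.arange(len(positions), dtype=np.int64)
    else:
        subset = np.asarray(subset, dtype=np.int64)
    if len(subset) == 0:
        return AggregateSet(clusters=[], subset=subset, cutoff=cutoff)
    pts = positions[subset]
    pairs = periodic_pairs(pts, box_edge, cutoff)
    n = len(subset)
    graph = sparse.coo_matrix(
        (np.ones(len(pairs), dtype=np.int8), (pairs[:, 0], pairs[:, 1])),
        shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters = [subset[labels == k] for k in range(n_comp)]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return AggregateSet(clusters=clusters, subset=subset, cutoff=cutoff)


def size_statistics(agg: AggregateSet | np.ndarray) -> SizeStatistics:
    """Number / weight average sizes and polydispersity index.

    Accepts an :class:`AggregateSet` or a plain array of cluster sizes.
    """
    sizes = agg.sizes if isinstance(agg, AggregateSet) else np.asarray(agg)
    if len(sizes) == 0:
        raise UndefinedStatisticsError("size statistics of an empty set")
    sizes = sizes.astype(float)
    xn = sizes.sum() / len(sizes)
    xw = (sizes**2).sum() / sizes.sum()
    return SizeStatistics(Xn=float(xn), Xw=float(xw), P=float(xw / xn),
                          n_clusters=len(sizes))


def order_parameter(positions: np.ndarray, box_edge: float,
                    a_indices: np.ndarray, b_indices: np.ndarray,
                    n_slices: int | None = None,
                    axis: int = 2) -> OrderParameterResult:
    """Segregation order parameter of components A and B.

    The box is cut into ``n_slices`` slabs of equal thickness perpendicular
    to ``axis`` (default: one slice per R_c).  In each slice the fractions
    phi_A, phi_B are bead-count fractions of each component among *all*
    beads in the slice (beads have equal volume in DPD); an empty slice
    contributes |0 - 0| = 0.  phi is the mean of |phi_A - phi_B|.
    """
    if n_slices is None:
        n_slices = max(int(round(box_edge)), 1)
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    coord = _wrap(positions, box_edge)[:, axis]
    idx = np.minimum((coord / box_edge * n_slices).astype(np.int64),
                     n_slices - 1)
    total = np.bincount(idx, minlength=n_slices).astype(float)
    in_a = np.bincount(idx[np.asarray(a_indices, dtype=np.int64)],
                       minlength=n_slices).astype(float)
    in_b = np.bincount(idx[np.asarray(b_indices, dtype=np.int64)],
                       minlength=n_slices).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_a = np.where(total > 0, in_a / total, 0.0)
        phi_b = np.where(total > 0, in_b / total, 0.0)
    phi = float(np.abs(phi_a - phi_b).mean())
    return OrderParameterResult(n_slices=n_slices, phi_a=phi_a, phi_b=phi_b,
                                phi=phi)


def unwrap_cluster(positions: np.ndarray, box_edge: float,
                   cutoff: float = DEFAULT_CLUSTER_CUTOFF) -> np.ndarray:
    """Unwrap a connected cluster into contiguous real-space coordinates.

    Breadth-first traversal of the proximity graph from an arbitrary
    member, placing each newly reached bead at its minimum image relative
    to its discovered parent.  If the cluster turns out to be connected to
    one of its own periodic images (two paths disagree about a bead's image
    by a box vector), the unwrapping is ill-defined and
    :class:`UnwrapAmbiguityError` is raised.
    """
    pts = np.asarray(positions, dtype=float)
    n = len(pts)
    if n == 0:
        return pts.copy()
    pairs = periodic_pairs(pts, box_edge, cutoff)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        adj[i].append(j)
        adj[j].append(i)
    out = pts.copy()
    seen = np.zeros(n, dtype=bool)
    half = 0.5 * box_edge
    stack = [0]
    seen[0] = True
    order = []
    while stack:
        i = stack.pop()
        order.append(i)
        for j in adj[i]:
            d = pts[j] - out[i]
            d -= box_edge * np.round(d / box_edge)
            cand = out[i] + d
            if seen[j]:
                if np.any(np.abs(cand - out[j]) > half):
                    raise UnwrapAmbiguityError(
                        "cluster connects to its own periodic image; "
                        "unwrapped coordinates are ambiguous")
            else:
                out[j] = cand
                seen[j] = True
                stack.append(j)
    if not seen.all():
        raise ValueError("positions do not form a single connected cluster "
                         f"at cutoff {cutoff}")
    return out


def gyration_shape(positions: np.ndarray, box_edge: float | None = None,
                   cutoff: float = DEFAULT_CLUSTER_CUTOFF,
                   unwrapped: bool = False) -> ShapeDescriptor:
    """Gyration-tensor principal moments and asphericity of one cluster.

    If ``unwrapped`` is False the cluster is first made contiguous with
    :func:`unwrap_cluster` (``box_edge`` required); pass ``unwrapped=True``
    for coordinates already in continuous space.
    """
    pts = np.asarray(positions, dtype=float)
    if len(pts) == 0:
        raise ValueError("cannot compute shape of an empty cluster")
    if not unwrapped:
        if box_edge is None:
            raise ValueError("box_edge required to unwrap the cluster")
        pts = unwrap_cluster(pts, box_edge, cutoff)
    centered = pts - pts.mean(axis=0)
    gyr = centered.T @ centered / len(pts)
    lams = np.linalg.eigvalsh(gyr)[::-1]  # descending
    l1, l2, l3 = (float(x) for x in lams)
    denom = 2.0 * (l1 + l2 + l3) ** 2
    if denom == 0.0:  # all beads coincide
        delta = 0.0
    else:
        delta = ((l1 - l2) ** 2 + (l1 - l3) ** 2 + (l3 - l2) ** 2) / denom
    return ShapeDescriptor(lam1_sq=l1, lam2_sq=l2, lam3_sq=l3,
                           delta=float(delta))


def detect_cores(positions: np.ndarray, box_edge: float, agg: AggregateSet,
                 core_indices: np.ndarray,
                 cutoff: float = DEFAULT_CLUSTER_CUTOFF) -> list[list[np.ndarray]]:
    """Solvophobic cores inside each aggregate.

    Re-clusters, within each aggregate of ``agg``, the beads listed in
    ``core_indices`` (e.g. the solvophobic-homopolymer beads) at the same
    distance criterion.  Returns, per aggregate, the list of core member
    arrays (global indices, largest first); aggregates without core-species
    beads get an empty list.
    """
    core_set = np.zeros(len(positions), dtype=bool)
    core_set[np.asarray(core_indices, dtype=np.int64)] = True
    out: list[list[np.ndarray]] = []
    for members in agg.clusters:
        sub = members[core_set[members]]
        if len(sub) == 0:
            out.append([])
            continue
        cores = find_aggregates(positions, box_edge, subset=sub,
                                cutoff=cutoff)
        out.append(list(cores.clusters))
    return out
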