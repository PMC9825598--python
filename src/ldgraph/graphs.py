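"""From lesion masks to graphs.

Two graph constructions are used downstream:

* a *complete-pair* graph over retained voxels, in which each patient
  contributes a binary edge vector (edge = both endpoint voxels lesioned) —
  the working structure for edge-wise network-based statistics;
* a *spatial-adjacency* graph whose edges join neighbouring voxels and carry
  two weight layers accumulated across the cohort — a lesion co-occurrence
  count and an adjusted deficit weight — the input to the layered stochastic
  block model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import LesionMask, PatientRecord
from .grid import GeometryError, GridSpec, make_grid


class GraphConstructionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeTable:
    """Dense node ids 0..N-1 in bijection with retained voxels."""

    voxel_indices: np.ndarray  # (N, 3) int
    grid: GridSpec

    def __post_init__(self):
        vi = np.asarray(self.voxel_indices, dtype=np.int64)
        if vi.ndim != 2 or vi.shape[1] != 3:
            raise GraphConstructionError("voxel_indices must be (N, 3)")
        object.__setattr__(self, "voxel_indices", vi)

    def __len__(self) -> int:
        return len(self.voxel_indices)

    def flat_index(self) -> np.ndarray:
        """Raveled voxel index per node (for fast mask lookups)."""
        return np.ravel_multi_index(tuple(self.voxel_indices.T), self.grid.shape)


@dataclass(frozen=True)
class EdgeSet:
    """Undirected edges as canonical (i < j) node-id pairs, no self-loops."""

    pairs: np.ndarray  # (E, 2) int, i < j
    topology: str  # complete_pairs | spatial_adjacency

    def __post_init__(self):
        p = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if len(p) and not (p[:, 0] < p[:, 1]).all():
            raise GraphConstructionError("edges must be canonically ordered i < j")
        object.__setattr__(self, "pairs", p)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class LesionGraph:
    """Group-level weighted graph over retained voxels.

    ``cooccurrence[e]`` counts the patients in whom both endpoints of edge e
    were lesioned (the Poisson layer); ``deficit_weight[e]`` is the mean
    adjusted deficit weight of those patients, min-max rescaled to [0, 1]
    across edges (the Gaussian layer). Edges nobody lesioned are absent.
    """

    nodes: NodeTable
    edges: EdgeSet
    cooccurrence: np.ndarray  # (E,) int
    deficit_weight: np.ndarray  # (E,) float in [0, 1]
    cooccurrence_scaled: np.ndarray = None  # min-max rescaled copy, reporting only
    aetiology_weight: Optional[np.ndarray] = None  # (E,) int category, optional

    def __post_init__(self):
        c = np.asarray(self.cooccurrence, dtype=np.int64)
        w = np.asarray(self.deficit_weight, dtype=float)
        if len(c) != len(self.edges) or len(w) != len(self.edges):
            raise GraphConstructionError("per-edge arrays must match edge count")
        if (c < 0).any():
            raise GraphConstructionError("co-occurrence counts must be >= 0")
        if len(w) and (w.min() < -1e-9 or w.max() > 1 + 1e-9):
            raise GraphConstructionError("deficit weights must lie in [0, 1]")
        object.__setattr__(self, "cooccurrence", c)
        object.__setattr__(self, "deficit_weight", np.clip(w, 0.0, 1.0))
        if self.cooccurrence_scaled is None:
            object.__setattr__(self, "cooccurrence_scaled", _minmax(c.astype(float)))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=np.int64)
        np.add.at(deg, self.edges.pairs[:, 0], 1)
        np.add.at(deg, self.edges.pairs[:, 1], 1)
        return deg


def _minmax(x: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to 0.5 everywhere."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        return x.copy()
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-300:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def resample_mask(mask: LesionMask, target_voxel_mm: Sequence[float]) -> LesionMask:
    """Downsample a binary mask to a coarser grid by block majority.

    The target voxel size must be an integer multiple of the source size on
    every axis. A coarse voxel is lesioned iff the mean of the fine voxels it
    contains is >= 0.5 (ties lesioned).
    """
    src = np.asarray(mask.grid.voxel_size, dtype=float)
    tgt = np.asarray(target_voxel_mm, dtype=float)
    ratio = tgt / src
    if not np.allclose(ratio, np.round(ratio)) or (ratio < 1).any():
        raise GeometryError(f"target voxel {tuple(tgt)} is not an integer multiple "
                            f"of source voxel {tuple(src)}")
    r = np.round(ratio).astype(int)
    shape = np.asarray(mask.grid.shape)
    if (shape % r).any():
        raise GeometryError(f"grid shape {tuple(shape)} not divisible by ratio {tuple(r)}")
    coarse_shape = shape // r
    blocks = mask.data.reshape(coarse_shape[0], r[0], coarse_shape[1], r[1],
                               coarse_shape[2], r[2])
    mean = blocks.mean(axis=(1, 3, 5))
    data = (mean >= 0.5).astype(np.uint8)
    grid = make_grid(tuple(coarse_shape), tuple(tgt), mask.grid.origin)
    return LesionMask(mask.patient_id, data, grid)


def enumerate_nodes(masks: Sequence[LesionMask], grid: GridSpec,
                    mode: str = "lesioned_anywhere") -> NodeTable:
    """Retain voxels as graph nodes, ordered lexicographically by index."""
    if mode == "brain":
        keep = grid.brain_mask()
    elif mode == "lesioned_anywhere":
        keep = np.zeros(grid.shape, dtype=bool)
        for m in masks:
            if m.grid != grid:
                raise GeometryError("all masks must share the node grid")
            keep |= m.data.astype(bool)
    else:
        raise GraphConstructionError(f"unknown node mode {mode!r}")
    idx = np.argwhere(keep)
    if len(idx) == 0:
        raise GraphConstructionError("no voxels retained as nodes")
    return NodeTable(idx, grid)


def complete_pair_edges(nodes: NodeTable) -> EdgeSet:
    """All N(N-1)/2 unordered node pairs."""
    n = len(nodes)
    if n < 2:
        raise GraphConstructionError("need at least 2 nodes for pair edges")
    i, j = np.triu_indices(n, k=1)
    return EdgeSet(np.column_stack([i, j]), topology="complete_pairs")


_CONNECTIVITY_OFFSETS = {
    6: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    18: [(1, 0, 0), (0, 1, 0), (0, 0, 1),
         (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)],
    26: [(1, 0, 0), (0, 1, 0), (0, 0, 1),
         (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
         (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)],
}


def spatial_adjacency_edges(nodes: NodeTable, connectivity: int = 26) -> EdgeSet:
    """Edges between voxel nodes adjacent under a 6/18/26 neighbourhood."""
    if connectivity not in _CONNECTIVITY_OFFSETS:
        raise GraphConstructionError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    grid = nodes.grid
    node_of = np.full(grid.shape, -1, dtype=np.int64)
    node_of[tuple(nodes.voxel_indices.T)] = np.arange(len(nodes))
    vi = nodes.voxel_indices
    pairs = []
    shape = np.asarray(grid.shape)
    for off in _CONNECTIVITY_OFFSETS[connectivity]:
        nb = vi + np.asarray(off)
        ok = ((nb >= 0) & (nb < shape)).all(axis=1)
        src = np.arange(len(nodes))[ok]
        tgt = node_of[tuple(nb[ok].T)]
        valid = tgt >= 0
        a, b = src[valid], tgt[valid]
        pairs.append(np.column_stack([np.minimum(a, b), np.maximum(a, b)]))
    allp = np.vstack(pairs) if pairs else np.empty((0, 2), dtype=np.int64)
    allp = np.unique(allp, axis=0) if len(allp) else allp
    return EdgeSet(allp, topology="spatial_adjacency")


def build_patient_edge_vector(mask: LesionMask, nodes: NodeTable,
                              edges: EdgeSet) -> np.ndarray:
    """Binary edge vector: 1 iff both endpoint voxels are lesioned in this patient."""
    if mask.grid != nodes.grid:
        raise GeometryError("mask and node table are on different grids")
    dmg = mask.data.ravel()[nodes.flat_index()].astype(bool)
    return (dmg[edges.pairs[:, 0]] & dmg[edges.pairs[:, 1]]).astype(np.uint8)


def patient_weight(record: PatientRecord, mode: str = "nart_over_score",
                   score_floor: float = 0.5) -> float:
    """Per-patient adjusted deficit weight.

    Default reading: premorbid index over (floored) deficit score, so a larger
    weight means worse performance relative to premorbid level. The
    alternative grouping — reciprocal of score, divided by NART — is also
    available.
    """
    s = max(record.score, score_floor)
    if mode == "nart_over_score":
        return record.nart / s
    if mode == "inv_score_over_nart":
        return 1.0 / (s * record.nart)
    raise GraphConstructionError(f"unknown weight mode {mode!r}")


def assemble_group_graph(masks: Sequence[LesionMask], records: Sequence[PatientRecord],
                         nodes: NodeTable, edges: EdgeSet,
                         weight_mode: str = "nart_over_score",
                         with_aetiology: bool = False) -> LesionGraph:
    """Accumulate the two edge-weight layers across the cohort.

    c_e counts patients lesioning both endpoints; the deficit layer is the
    mean of contributing patients' adjusted weights, min-max rescaled to
    [0, 1] across the surviving (c_e > 0) edges.
    """
    if len(masks) != len(records):
        raise GraphConstructionError("one record per mask required")
    ne = len(edges)
    counts = np.zeros(ne, dtype=np.int64)
    wsum = np.zeros(ne, dtype=float)
    aet_counts = np.zeros((ne, 2), dtype=np.int64) if with_aetiology else None
    for mask, rec in zip(masks, records):
        vec = build_patient_edge_vector(mask, nodes, edges).astype(bool)
        counts[vec] += 1
        wsum[vec] += patient_weight(rec, weight_mode)
        if with_aetiology:
            aet_counts[vec, 0 if rec.aetiology == "stroke" else 1] += 1
    keep = counts > 0
    kept_pairs = edges.pairs[keep]
    mean_u = wsum[keep] / counts[keep]
    graph = LesionGraph(
        nodes=nodes,
        edges=EdgeSet(kept_pairs, topology=edges.topology),
        cooccurrence=counts[keep],
        deficit_weight=_minmax(mean_u),
        aetiology_weight=(np.argmax(aet_counts[keep], axis=1)
                          if with_aetiology else None),
    )
    return graph


def filter_graph(g: LesionGraph, node_quantile: float = 0.5,
                 min_count: int = 3) -> LesionGraph:
    """Restrict to well-sampled structure.

    Keeps nodes whose degree is >= the ``node_quantile`` quantile of the
    degree distribution (ties kept), then drops edges with co-occurrence
    below ``min_count``, then drops isolated nodes. Node ids are renumbered
    densely; weights are carried over unchanged.
    """
    if g.n_edges == 0:
        raise GraphConstructionError("cannot filter an empty graph")
    deg = g.degrees()
    thresh = np.quantile(deg, node_quantile)
    keep_node = deg >= thresh
    pairs = g.edges.pairs
    keep_edge = (keep_node[pairs[:, 0]] & keep_node[pairs[:, 1]]
                 & (g.cooccurrence >= min_count))
    if not keep_edge.any():
        raise GraphConstructionError(
            f"filtering removed every edge (degree threshold {thresh}, "
            f"min count {min_count})")
    pairs = pairs[keep_edge]
    used = np.unique(pairs)
    remap = np.full(g.n_nodes, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    new_pairs = remap[pairs]
    return LesionGraph(
        nodes=NodeTable(g.nodes.voxel_indices[used], g.nodes.grid),
        edges=EdgeSet(new_pairs, topology=g.edges.topology),
        cooccurrence=g.cooccurrence[keep_edge],
        deficit_weight=g.deficit_weight[keep_edge],
        aetiology_weight=(g.aetiology_weight[keep_edge]
                          if g.aetiology_weight is not None else None),
    )


def md_involvement(mask: LesionMask, template_mask: np.ndarray) -> float:
    """Percentage of the lesion falling inside a template region:
    100 * |lesion ∩ template| / |lesion|."""
    tmpl = np.asarray(template_mask).astype(bool)
    if tmpl.shape != mask.grid.shape:
        raise GeometryError("template is on a different grid")
    vol = mask.volume
    if vol == 0:
        raise ValueError("lesion mask is empty")
    return 100.0 * float((mask.data.astype(bool) & tmpl).sum()) / vol
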