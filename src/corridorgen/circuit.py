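"""Circuit-theory effective resistance and current maps on resistance rasters.

The raster becomes an electrical network: every valid cell is a node, every
neighbour pair (8-neighbourhood by default) an edge whose conductance is the
reciprocal of the mean of the two cell resistances, scaled by sqrt(2) for
diagonal steps.  Population polygons are short-circuited into supernodes;
effective resistance between two regions is the potential difference when a
unit current is injected at one and drained at the other, obtained from one
sparse factorization of the grounded graph Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from corridorgen.landscape import RasterGrid, ResistanceLayer


@dataclass
class NodeGraph:
    """Conductance graph over the valid cells of a resistance raster."""

    n_nodes: int
    edges: np.ndarray          # (m, 2) node indices
    conductance: np.ndarray    # (m,)
    cell_node: np.ndarray      # (nr, nc) node index or -1
    merged: dict[str, int]     # region label -> supernode index

    def laplacian(self) -> sparse.csc_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        g = self.conductance
        n = self.n_nodes
        W = sparse.coo_matrix((np.r_[g, g], (np.r_[i, j], np.r_[j, i])),
                              shape=(n, n)).tocsr()
        d = np.asarray(W.sum(axis=1)).ravel()
        return (sparse.diags(d) - W).tocsc()


def build_graph(layer: ResistanceLayer | RasterGrid, neighbourhood: int = 8,
                regions: dict[str, np.ndarray] | None = None) -> NodeGraph:
    """Build the conductance graph of a resistance raster.

    Edge conductance between cells i, j is 1 / (d · (r_i + r_j)/2) with
    d = 1 for cardinal and sqrt(2) for diagonal neighbours.  ``regions``
    maps labels to boolean cell masks; each region's cells are merged into
    one supernode (infinite internal conductance).
    """
    raster = layer.raster if isinstance(layer, ResistanceLayer) else layer
    r = raster.data
    valid = raster.valid_mask()
    nr, nc = r.shape
    if valid.sum() < 2:
        raise ValueError("graph needs at least two valid cells")
    regions = regions or {}
    for name, mask in regions.items():
        if not (mask & valid).any():
            raise ValueError(f"region '{name}' has no valid cells")

    # node numbering: first supernodes in label order, then free cells
    cell_node = np.full((nr, nc), -1, dtype=np.int64)
    merged: dict[str, int] = {}
    covered = np.zeros((nr, nc), dtype=bool)
    for k, (name, mask) in enumerate(regions.items()):
        m = mask & valid
        if (m & covered).any():
            raise ValueError("regions overlap")
        cell_node[m] = k
        covered |= m
        merged[name] = k
    free = valid & ~covered
    cell_node[free] = len(regions) + np.arange(free.sum())
    n_nodes = len(regions) + int(free.sum())

    steps = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighbourhood == 8:
        steps += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]
    elif neighbourhood != 4:
        raise ValueError("neighbourhood must be 4 or 8")

    ii, jj, gg = [], [], []
    for dr, dc, dist in steps:
        r0 = slice(max(0, -dr), nr - max(0, dr))
        r1 = slice(max(0, dr), nr - max(0, -dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        ok = valid[r0, c0] & valid[r1, c1]
        a = cell_node[r0, c0][ok]
        b = cell_node[r1, c1][ok]
        res = (r[r0, c0][ok] + r[r1, c1][ok]) / 2.0
        g = 1.0 / (dist * res)
        keep = a != b  # intra-region edges collapse into the supernode
        ii.append(a[keep])
        jj.append(b[keep])
        gg.append(g[keep])
    edges = np.stack([np.concatenate(ii), np.concatenate(jj)], axis=1)
    cond = np.concatenate(gg)
    return NodeGraph(n_nodes=n_nodes, edges=edges, conductance=cond,
                     cell_node=cell_node, merged=merged)


@dataclass
class ResistanceResult:
    """Pairwise effective resistances with an optional cumulative current map."""

    labels: list[str]
    resistance: np.ndarray                 # (k, k), inf where disconnected
    strength_normalized: np.ndarray | None = None
    current_map: RasterGrid | None = None


class _Solver:
    """Grounded-Laplacian solver shared across region pairs."""

    def __init__(self, graph: NodeGraph):
        self.graph = graph
        L = graph.laplacian()
        comp = csgraph.connected_components(
            sparse.coo_matrix((graph.conductance,
                               (graph.edges[:, 0], graph.edges[:, 1])),
                              shape=(graph.n_nodes, graph.n_nodes)),
            directed=False)[1]
        self.comp = comp
        # ground one node per component; solve the remaining system once
        ground = np.zeros(graph.n_nodes, dtype=bool)
        for c in np.unique(comp):
            ground[np.flatnonzero(comp == c)[-1]] = True
        self.keep = np.flatnonzero(~ground)
        self.pos = -np.ones(graph.n_nodes, dtype=np.int64)
        self.pos[self.keep] = np.arange(len(self.keep))
        self.lu = splu(L[np.ix_(self.keep, self.keep)].tocsc())

    def potentials(self, a: int, b: int) -> np.ndarray | None:
        """Node potentials for unit current a -> b; None if disconnected."""
        if self.comp[a] != self.comp[b]:
            return None
        rhs = np.zeros(len(self.keep))
        if self.pos[a] >= 0:
            rhs[self.pos[a]] = 1.0
        if self.pos[b] >= 0:
            rhs[self.pos[b]] -= 1.0
        x = self.lu.solve(rhs)
        phi = np.zeros(self.graph.n_nodes)
        phi[self.keep] = x
        return phi


def effective_resistance(graph: NodeGraph, regionA: str, regionB: str,
                         solver: _Solver | None = None) -> float:
    """Effective resistance between two merged regions (inf if disconnected)."""
    a = graph.merged[regionA]
    b = graph.merged[regionB]
    solver = solver or _Solver(graph)
    phi = solver.potentials(a, b)
    if phi is None:
        return float("inf")
    return float(phi[a] - phi[b])


def pairwise_resistance(graph: NodeGraph,
                        strengths: dict[str, float] | None = None,
                        raster: RasterGrid | None = None,
                        current_map: bool = False) -> ResistanceResult:
    """All-pairs effective resistance between merged regions.

    ``strengths`` (source strengths, e.g. censused population counts) do not
    change effective resistances — the network equations are linear in the
    injected current — so they enter two documented ways: per-pair weights
    s_i·s_j / mean(s_i·s_j) on the cumulative current map, and a
    strength-normalized variant R'_ij = R_ij/(s_i·s_j).
    """
    labels = list(graph.merged)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two regions")
    solver = _Solver(graph)
    R = np.zeros((k, k))
    s = np.array([1.0 if strengths is None else float(strengths[l])
                  for l in labels])
    if (s <= 0).any():
        raise ValueError("source strengths must be positive")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    wprod = np.array([s[i] * s[j] for i, j in pairs])
    wnorm = wprod / wprod.mean()
    cmap = None
    if current_map:
        if raster is None:
            raise ValueError("current_map requires the source raster")
        cmap = np.zeros(raster.shape)
    for (i, j), w in zip(pairs, wnorm):
        a, b = graph.merged[labels[i]], graph.merged[labels[j]]
        phi = solver.potentials(a, b)
        if phi is None:
            R[i, j] = R[j, i] = np.inf
            continue
        R[i, j] = R[j, i] = phi[a] - phi[b]
        if cmap is not None:
            node_cur = _node_currents(graph, phi)
            node_cur[a] = node_cur[b] = 1.0  # focal nodes carry the full ampere
            cmap += w * node_cur[graph.cell_node.clip(min=0)] * (graph.cell_node >= 0)
    norm = None
    if strengths is not None:
        norm = R / np.outer(s, s)
        np.fill_diagonal(norm, 0.0)
    grid = None
    if cmap is not None:
        grid = RasterGrid(data=np.where(graph.cell_node >= 0, cmap,
                                        raster.nodata),
                          cell_size_km=raster.cell_size_km,
                          origin=raster.origin, nodata=raster.nodata)
    return ResistanceResult(labels=labels, resistance=R,
                            strength_normalized=norm, current_map=grid)


def _node_currents(graph: NodeGraph, phi: np.ndarray) -> np.ndarray:
    """Per-node current = half the sum of absolute currents on incident edges."""
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    edge_cur = np.abs(graph.conductance * (phi[i] - phi[j]))
    out = np.zeros(graph.n_nodes)
    np.add.at(out, i, edge_cur)
    np.add.at(out, j, edge_cur)
    return out / 2.0
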