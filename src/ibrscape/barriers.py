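"""Genetic-discontinuity detection: Gabriel graphs and Monmonier's
maximum-difference barrier tracing.

A Gabriel graph connects two samples when the disc having their segment as
diameter contains no third sample.  Monmonier's algorithm walks across the
Delaunay triangulation starting at the connection-network edge with the
largest genetic distance, repeatedly crossing the adjacent edge with the
locally maximal distance, tracing a candidate barrier until it reaches the
convex-hull boundary, closes a loop, or runs out of eligible edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["SpatialGraph", "Barrier", "gabriel_graph", "monmonier_barrier"]


@dataclass
class SpatialGraph:
    """Node coordinates, undirected edges and per-edge genetic distances."""

    coords: np.ndarray
    edges: list                      # list of (i, j) with i < j
    edge_values: dict = field(default_factory=dict)

    def set_values(self, dist_matrix: np.ndarray) -> "SpatialGraph":
        """Attach per-edge values from a full pairwise distance matrix."""
        self.edge_values = {e: float(dist_matrix[e[0], e[1]]) for e in self.edges}
        return self

    def neighbors(self, i: int) -> list:
        return [b if a == i else a for a, b in self.edges if i in (a, b)]


def gabriel_graph(coords: np.ndarray) -> SpatialGraph:
    """Gabriel graph: edge (i, j) iff d2(i,j) < d2(i,k) + d2(j,k) for all k.

    Duplicate coordinates are an error (the diametral-disc test is
    undefined at zero distance).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 points")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    dup = np.argwhere((d2 < 1e-24) & ~np.eye(n, dtype=bool))
    if len(dup):
        pairs = sorted({tuple(sorted(p)) for p in dup})
        raise ValueError(f"duplicate coordinates at index pairs {pairs}")
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            # strict inequality must hold for every third point
            other = d2[i] + d2[j]
            other[i] = other[j] = np.inf
            if d2[i, j] < other.min():
                edges.append((i, j))
    return SpatialGraph(coords=coords, edges=edges)


@dataclass
class Barrier:
    """An ordered walk of crossed edges with their distance values."""

    crossed_edges: list
    values: list
    termination: str                 # boundary | loop | threshold
    low_contrast: bool = False

    @property
    def n_crossed(self) -> int:
        return len(self.crossed_edges)


def _face_maps(tri: Delaunay):
    """edge -> adjacent simplex indices, and simplex -> its 3 edges."""
    edge_faces: dict = {}
    face_edges = []
    for s, simplex in enumerate(tri.simplices):
        es = []
        for a in range(3):
            e = tuple(sorted((int(simplex[a]), int(simplex[(a + 1) % 3]))))
            es.append(e)
            edge_faces.setdefault(e, []).append(s)
        face_edges.append(es)
    return edge_faces, face_edges


def monmonier_barrier(graph: SpatialGraph, dist_matrix: np.ndarray | None = None,
                      n_barriers: int = 1, threshold: float | None = None
                      ) -> list[Barrier]:
    """Trace genetic barriers across the triangulation of a spatial graph.

    Starting at the graph edge with the maximal genetic distance, the
    barrier extends in both directions; at each step it crosses the
    adjacent (same-triangle) graph edge with the locally maximal distance,
    provided it exceeds ``threshold`` when one is given.  Additional
    barriers (``n_barriers`` > 1) mask previously crossed edges and
    restart.
    """
    tri = Delaunay(graph.coords)
    edge_faces, face_edges = _face_maps(tri)
    graph_edges = set(graph.edges)
    if dist_matrix is not None:
        # the walk may cross any triangulation edge; the network defines
        # where barriers start and which crossings are reported
        values = {e: float(dist_matrix[e[0], e[1]]) for e in edge_faces}
        values.update({e: float(dist_matrix[e[0], e[1]]) for e in graph.edges})
    else:
        values = dict(graph.edge_values)
    if set(graph.edges) - set(values):
        raise ValueError("every graph edge needs a distance value")
    vals = np.array([values[e] for e in graph.edges])
    uniform = np.ptp(vals) < 1e-12
    if uniform:
        if threshold is not None:
            return [Barrier(crossed_edges=[], values=[],
                            termination="threshold")]
        start = graph.edges[0]
        return [Barrier(crossed_edges=[start], values=[values[start]],
                        termination="threshold", low_contrast=True)]
    if threshold is None:
        # stop once local differences drop to the background level: the mean
        # of network-edge values sits between the background and barrier
        # modes when a genuine discontinuity exists
        threshold = float(vals.mean())

    barriers = []
    masked: set = set()
    for _b in range(n_barriers):
        candidates = {e: v for e, v in values.items()
                      if e not in masked and e in edge_faces
                      and e in graph_edges
                      and (threshold is None or v > threshold)}
        if not candidates:
            barriers.append(Barrier(crossed_edges=[], values=[],
                                    termination="threshold"))
            break
        start = max(candidates, key=candidates.get)
        crossed = [start]
        visited_faces: set = set()

        def extend(direction_face):
            term = "boundary"
            face = direction_face
            out_edges, out_vals = [], []
            while face is not None:
                if face in visited_faces:
                    term = "loop"
                    break
                visited_faces.add(face)
                eligible = [e for e in face_edges[face]
                            if e in values and e not in crossed
                            and e not in masked
                            and (threshold is None or values[e] > threshold)]
                if not eligible:
                    term = "threshold" if threshold is not None else "boundary"
                    break
                nxt = max(eligible, key=lambda e: values[e])
                crossed.append(nxt)
                out_edges.append(nxt)
                out_vals.append(values[nxt])
                adj = [f for f in edge_faces[nxt] if f != face]
                face = adj[0] if adj else None
            return out_edges, out_vals, term

        faces0 = edge_faces[start]
        fwd_edges, fwd_vals, term_f = extend(faces0[0])
        if len(faces0) > 1:
            bwd_edges, bwd_vals, term_b = extend(faces0[1])
        else:
            bwd_edges, bwd_vals, term_b = [], [], "boundary"
        ordered = bwd_edges[::-1] + [start] + fwd_edges
        ordered_vals = bwd_vals[::-1] + [values[start]] + fwd_vals
        termination = term_f if term_f == "loop" or term_b == "boundary" else term_b
        barriers.append(Barrier(crossed_edges=ordered, values=ordered_vals,
                                termination=termination,
                                low_contrast=bool(uniform)))
        masked.update(ordered)
    return barriers
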