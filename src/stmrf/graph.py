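"""Areal adjacency graphs and the intrinsic CAR (ICAR) spatial structure.

An areal map is represented as an undirected graph: one node per district,
one edge per shared border.  Maps spanning several countries with no common
border give *disconnected* graphs; every operation here is component-aware,
because the ICAR prior is improper separately on each connected component
(one sum-to-zero constraint per component is needed downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "AdjacencyGraph",
    "PrecisionStructure",
    "build_adjacency",
    "connected_components",
    "icar_structure",
    "read_edge_list",
    "polygon_contiguity",
    "adjacency_summary",
]

#: eigenvalues below this (relative to the largest) count as zero
_RANK_TOL = 1e-8


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected areal neighbourhood structure.

    Attributes
    ----------
    n_areas : int
        Number of districts S.
    edges : frozenset of tuple(int, int)
        Unordered neighbour pairs as (i, j) index pairs with i < j.
    component_labels : ndarray of int, shape (S,)
        Connected-component label of each area, contiguous in [0, C).
    area_ids : tuple of str
        Stable string identifiers, in index order.
    """

    n_areas: int
    edges: frozenset
    component_labels: np.ndarray
    area_ids: tuple

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n_areas else 0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbours(self, i: int) -> list:
        out = []
        for a, b in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def adjacency_matrix(self) -> np.ndarray:
        A = np.zeros((self.n_areas, self.n_areas))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        return A


@dataclass(frozen=True)
class PrecisionStructure:
    """A symmetric PSD structure matrix with its rank and null space.

    The precision of the associated Gaussian Markov random field is
    ``matrix / variance``; intrinsic structures (ICAR, RW1, structured
    interactions) are rank deficient and ``null_basis`` spans the improper
    directions that must be pinned by sum-to-zero constraints.
    """

    matrix: np.ndarray
    rank: int
    null_basis: np.ndarray  # (n, n - rank), orthonormal columns
    label: str
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def null_dim(self) -> int:
        return self.n - self.rank


def _null_basis_from_eigh(matrix: np.ndarray) -> tuple[int, np.ndarray]:
    """Rank and orthonormal null basis via dense symmetric eigendecomposition."""
    w, V = np.linalg.eigh(matrix)
    scale = max(abs(w[-1]), 1.0)
    null = w < _RANK_TOL * scale
    return int((~null).sum()), V[:, null]


def build_adjacency(edge_list, area_ids) -> AdjacencyGraph:
    """Build an :class:`AdjacencyGraph` from id pairs.

    Parameters
    ----------
    edge_list : iterable of (id, id)
        Neighbour pairs; order within a pair is irrelevant.
    area_ids : ordered iterable of str
        All area identifiers; areas without edges become singleton
        components (islands).

    Raises
    ------
    ValueError
        On duplicate ids, unknown endpoints, or self-edges.
    """
    area_ids = tuple(str(a) for a in area_ids)
    if len(set(area_ids)) != len(area_ids):
        raise ValueError("duplicate area ids")
    index = {a: k for k, a in enumerate(area_ids)}

    edges = set()
    for a, b in edge_list:
        a, b = str(a), str(b)
        if a not in index:
            raise ValueError(f"unknown area id in edge list: {a!r}")
        if b not in index:
            raise ValueError(f"unknown area id in edge list: {b!r}")
        if a == b:
            raise ValueError(f"self-edge on area {a!r}")
        i, j = index[a], index[b]
        edges.add((min(i, j), max(i, j)))

    g = nx.Graph()
    g.add_nodes_from(range(len(area_ids)))
    g.add_edges_from(edges)
    labels = np.full(len(area_ids), -1, dtype=int)
    for c, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        labels[sorted(comp)] = c

    return AdjacencyGraph(
        n_areas=len(area_ids),
        edges=frozenset(edges),
        component_labels=labels,
        area_ids=area_ids,
    )


def connected_components(graph: AdjacencyGraph) -> np.ndarray:
    """Connected-component labels, contiguous integers in [0, C)."""
    return graph.component_labels.copy()


def icar_structure(graph: AdjacencyGraph) -> PrecisionStructure:
    """ICAR structure matrix W = D - A on a (possibly disconnected) graph.

    D is the diagonal matrix of neighbour counts and A the 0/1 adjacency.
    Under precision W/delta^2 each area's effect is conditionally normal
    around the plain average of its neighbours with conditional variance
    delta^2 / n_i.  Rank is S - C; the null space is spanned by the
    per-component indicator vectors (normalised).  Isolated areas
    contribute an all-zero row and are flagged in ``meta['isolated']``;
    their singleton sum-to-zero constraint pins their effect to zero.
    """
    S = graph.n_areas
    A = graph.adjacency_matrix()
    deg = A.sum(axis=1)
    W = np.diag(deg) - A

    labels = graph.component_labels
    C = graph.n_components
    null = np.zeros((S, C))
    for c in range(C):
        mask = labels == c
        null[mask, c] = 1.0 / np.sqrt(mask.sum())

    return PrecisionStructure(
        matrix=W,
        rank=S - C,
        null_basis=null,
        label="icar",
        meta={"isolated": [int(i) for i in np.where(deg == 0)[0]],
              "component_labels": labels.copy()},
    )


def read_edge_list(path, delimiter=None) -> list:
    """Read a two-column plain-text edge list (comma- or tab-separated)."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is None:
                sep = "," if "," in line else "\t"
            else:
                sep = delimiter
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {line!r}")
            pairs.append((parts[0], parts[1]))
    return pairs


def polygon_contiguity(path, id_property: str, rule: str = "queen") -> AdjacencyGraph:
    """Contiguity graph from a GeoJSON FeatureCollection of polygons.

    ``rule="queen"`` (default) links polygons that touch at all (shared
    border or corner); ``rule="rook"`` requires a shared border of
    positive length.  ``id_property`` names the feature property holding
    the stable area identifier.
    """
    import json as _json

    from shapely.geometry import shape

    if rule not in ("queen", "rook"):
        raise ValueError("rule must be 'queen' or 'rook'")
    with open(path) as fh:
        gj = _json.load(fh)
    feats = gj.get("features", [])
    ids, geoms = [], []
    for f in feats:
        props = f.get("properties", {})
        if id_property not in props:
            raise ValueError(f"feature missing id property {id_property!r}")
        ids.append(str(props[id_property]))
        geoms.append(shape(f["geometry"]))

    edges = []
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            if not geoms[i].touches(geoms[j]) and not geoms[i].intersects(geoms[j]):
                continue
            if rule == "rook":
                inter = geoms[i].boundary.intersection(geoms[j].boundary)
                if inter.length <= 0:
                    continue
            edges.append((ids[i], ids[j]))
    return build_adjacency(edges, ids)


def adjacency_summary(graph: AdjacencyGraph) -> dict:
    """JSON-ready summary: areas, edges, component sizes."""
    sizes = np.bincount(graph.component_labels, minlength=graph.n_components)
    return {
        "n_areas": graph.n_areas,
        "n_edges": graph.n_edges,
        "n_components": graph.n_components,
        "component_sizes": [int(s) for s in sizes],
    }
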