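"""Three-layer multiplex substrate: layer graphs, generators, I/O, spectra.

The model lives on three undirected, unweighted networks over one shared
node set: an online information layer (adjacency ``A``), a resource-sharing
contact layer (``B``) and an epidemic contact layer (``C``).  Node ``i`` is
the same individual in every layer.  Layers are plain 0/1 symmetric
adjacency structures with zero diagonal; all heavy lifting downstream is
done on :mod:`scipy.sparse` CSR matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

__all__ = [
    "LayerGraph",
    "MultiplexNetwork",
    "generate_er",
    "generate_ba",
    "generate_multiplex",
    "leading_eigenvalue",
    "read_edge_list",
    "write_edge_list",
    "fixture_multiplex",
    "FIXTURE_NAMES",
]

# below this size a dense full-spectrum solve is cheaper and more robust
# than sparse Lanczos iteration
_DENSE_EIG_CUTOFF = 64


class EdgeListFormatError(ValueError):
    """Raised for malformed edge-list files; message names the offending line."""


@dataclass(frozen=True)
class LayerGraph:
    """One undirected, unweighted network layer.

    Parameters
    ----------
    n_nodes : int
        Number of nodes; node labels are ``0 .. n_nodes-1``.
    adjacency : scipy.sparse.csr_array
        Symmetric 0/1 adjacency with zero diagonal, dtype float64.
    """

    n_nodes: int
    adjacency: sp.csr_array = field(repr=False)

    def __post_init__(self) -> None:
        a = self.adjacency
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if a.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape does not match n_nodes")
        if a.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal (self-loops)")
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency is not symmetric")
        data = a.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValueError("adjacency entries must be 0 or 1")

    # -- convenience ----------------------------------------------------
    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def edges(self) -> list[tuple[int, int]]:
        """Unordered edge list as sorted (i, j) pairs with i < j."""
        coo = self.adjacency.tocoo()
        return sorted({(int(min(i, j)), int(max(i, j))) for i, j in zip(coo.row, coo.col)})

    @classmethod
    def from_edges(cls, n_nodes: int, edges: Iterable[tuple[int, int]]) -> "LayerGraph":
        rows, cols = [], []
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop ({i}, {j}) not allowed")
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise ValueError(f"edge ({i}, {j}) out of range for n={n_nodes}")
            rows += [i, j]
            cols += [j, i]
        a = sp.csr_array(
            (np.ones(len(rows)), (rows, cols)), shape=(n_nodes, n_nodes)
        )
        a.data[:] = 1.0  # collapse duplicate edges
        return cls(n_nodes, a)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "LayerGraph":
        a = nx.to_scipy_sparse_array(g, nodelist=sorted(g.nodes()), dtype=np.float64, format="csr")
        return cls(g.number_of_nodes(), sp.csr_array(a))


@dataclass(frozen=True)
class MultiplexNetwork:
    """Information (A), resource (B) and epidemic (C) layers over one node set."""

    info_layer: LayerGraph
    resource_layer: LayerGraph
    epidemic_layer: LayerGraph

    def __post_init__(self) -> None:
        ns = {self.info_layer.n_nodes, self.resource_layer.n_nodes, self.epidemic_layer.n_nodes}
        if len(ns) != 1:
            raise ValueError("all three layers must share one node set")

    @property
    def n_nodes(self) -> int:
        return self.info_layer.n_nodes

    @property
    def layers(self) -> tuple[LayerGraph, LayerGraph, LayerGraph]:
        return (self.info_layer, self.resource_layer, self.epidemic_layer)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_er(n: int, mean_degree: float, seed: int, *, require_connected: bool = False) -> LayerGraph:
    """Erdős–Rényi G(n, p) layer with p = mean_degree / (n - 1).

    With ``require_connected`` the giant component is extracted and relabelled
    0..m-1 (the returned graph is then smaller than ``n``); by default the
    possibly-disconnected graph is used as-is, which both engines handle.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not 0 < mean_degree < n:
        raise ValueError("mean_degree must lie in (0, n)")
    p = mean_degree / (n - 1)
    g = nx.fast_gnp_random_graph(n, p, seed=seed)
    if require_connected:
        giant = max(nx.connected_components(g), key=len)
        g = nx.convert_node_labels_to_integers(g.subgraph(giant))
    return LayerGraph.from_networkx(g)


def generate_ba(n: int, m_attach: int, seed: int) -> LayerGraph:
    """Barabási–Albert preferential-attachment layer; ⟨k⟩ ≈ 2·m_attach."""
    if not 1 <= m_attach < n:
        raise ValueError("m_attach must satisfy 1 <= m_attach < n")
    g = nx.barabasi_albert_graph(n, m_attach, seed=seed)
    return LayerGraph.from_networkx(g)


def generate_multiplex(
    n: int,
    mean_degree: float = 6.0,
    topologies: Sequence[str] = ("ba", "er", "er"),
    seed: int = 0,
    *,
    share_physical: bool = False,
) -> MultiplexNetwork:
    """Generate the three layers with independent seeds derived from ``seed``.

    ``topologies`` gives (info, resource, epidemic) layer types, each "er" or
    "ba".  BA layers use m = round(mean_degree / 2).  With ``share_physical``
    one graph is drawn and used for both the resource and epidemic layers.
    """
    m = max(1, int(round(mean_degree / 2.0)))

    def one(kind: str, s: int) -> LayerGraph:
        if kind == "er":
            return generate_er(n, mean_degree, seed=s)
        if kind == "ba":
            return generate_ba(n, m, seed=s)
        raise ValueError(f"unknown topology {kind!r}")

    info = one(topologies[0], seed * 3 + 1)
    res = one(topologies[1], seed * 3 + 2)
    if share_physical:
        if topologies[1] != topologies[2]:
            raise ValueError("share_physical requires identical layer-2/3 topologies")
        epi = res
    else:
        epi = one(topologies[2], seed * 3 + 3)
    return MultiplexNetwork(info, res, epi)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def leading_eigenvalue(g: LayerGraph) -> float:
    """Largest eigenvalue of the adjacency matrix (Perron root).

    Uses a dense symmetric eigensolve for small graphs and sparse Lanczos
    (ARPACK) otherwise; either way accurate to ~1e-12 relative.
    """
    if g.n_nodes < 1 or g.adjacency.nnz == 0:
        raise ValueError("leading eigenvalue undefined for an edgeless graph")
    if g.n_nodes < _DENSE_EIG_CUTOFF:
        return float(np.linalg.eigvalsh(g.adjacency.toarray())[-1])
    val = eigsh(g.adjacency, k=1, which="LA", return_eigenvectors=False)
    return float(val[0])


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, n_nodes: int | None = None) -> LayerGraph:
    """Read a whitespace-separated 0-based edge list; '#' starts a comment.

    If ``n_nodes`` is omitted it is inferred as max index + 1.
    """
    edges: list[tuple[int, int]] = []
    max_idx = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListFormatError(f"line {lineno}: expected two indices, got {line!r}")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise EdgeListFormatError(f"line {lineno}: non-integer index in {line!r}") from None
            if i < 0 or j < 0:
                raise EdgeListFormatError(f"line {lineno}: negative node index in {line!r}")
            if i == j:
                raise EdgeListFormatError(f"line {lineno}: self-loop {i}--{j}")
            if n_nodes is not None and (i >= n_nodes or j >= n_nodes):
                raise EdgeListFormatError(f"line {lineno}: index out of range for n={n_nodes}")
            edges.append((i, j))
            max_idx = max(max_idx, i, j)
    n = n_nodes if n_nodes is not None else max_idx + 1
    if n < 1:
        raise EdgeListFormatError("edge list is empty and n_nodes was not given")
    return LayerGraph.from_edges(n, edges)


def write_edge_list(g: LayerGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={g.n_nodes}\n")
        for i, j in g.edges():
            fh.write(f"{i} {j}\n")


def write_matrix_market(g: LayerGraph, path: str | Path) -> None:
    """Export the adjacency as a Matrix Market file for interoperability."""
    from scipy.io import mmwrite

    mmwrite(str(path), sp.coo_array(g.adjacency))


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("triangle3", "star5", "path4", "er300", "ba300")


def _replicate(g: LayerGraph) -> MultiplexNetwork:
    return MultiplexNetwork(g, g, g)


def fixture_multiplex(name: str) -> MultiplexNetwork:
    """Seed-pinned small multiplexes for tests and examples.

    Catalogue: ``triangle3`` (all layers a 3-node triangle), ``star5``
    (all layers the 5-node star with hub 0), ``path4`` (all layers the
    4-node path), ``er300`` (three independent ER draws, n=300, ⟨k⟩=6),
    ``ba300`` (BA info layer, ER resource/epidemic layers, n=300).
    """
    if name == "triangle3":
        return _replicate(LayerGraph.from_edges(3, [(0, 1), (1, 2), (0, 2)]))
    if name == "star5":
        return _replicate(LayerGraph.from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)]))
    if name == "path4":
        return _replicate(LayerGraph.from_edges(4, [(0, 1), (1, 2), (2, 3)]))
    if name == "er300":
        return MultiplexNetwork(
            generate_er(300, 6.0, seed=11),
            generate_er(300, 6.0, seed=12),
            generate_er(300, 6.0, seed=13),
        )
    if name == "ba300":
        return MultiplexNetwork(
            generate_ba(300, 3, seed=21),
            generate_er(300, 6.0, seed=22),
            generate_er(300, 6.0, seed=23),
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
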