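"""Adjacency structure for areal (lattice / census-tract style) data.

The conditional autoregressive (CAR) prior used throughout this package is
defined on a symmetric binary neighbor graph: ``w_ig = 1`` if areas *i* and
*g* share a border, 0 otherwise, with zero diagonal.  The per-area degree
``w_i+`` (row sum of W) sets the CAR conditional variance ``tau2 / w_i+``,
so every area must have at least one neighbor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.io import mmread

__all__ = ["AdjacencyGraph", "build_lattice_adjacency", "load_adjacency", "morans_i"]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric binary neighbor structure over ``n_areas`` areas.

    Areas are indexed 0..n_areas-1 internally; file formats are 1-based.

    Attributes
    ----------
    n_areas : int
        Number of areas.
    weight_matrix : scipy.sparse.csr_array
        Binary symmetric adjacency W with zero diagonal.
    degrees : numpy.ndarray
        Row sums ``w_i+`` of W; all entries >= 1.
    """

    n_areas: int
    weight_matrix: sp.csr_array
    degrees: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        W = self.weight_matrix
        if W.shape != (self.n_areas, self.n_areas):
            raise ValueError("weight matrix shape does not match n_areas")
        if self.n_areas < 2:
            raise ValueError("need at least 2 areas (CAR undefined on one isolated area)")
        if (W != W.T).nnz:
            raise ValueError("adjacency matrix must be symmetric")
        if W.diagonal().any():
            raise ValueError("adjacency matrix must have zero diagonal")
        data = W.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValueError("adjacency weights must be binary")
        degrees = np.asarray(W.sum(axis=1)).ravel().astype(np.int64)
        if (degrees == 0).any():
            bad = int(np.flatnonzero(degrees == 0)[0]) + 1
            raise ValueError(f"area {bad} is isolated (no neighbors); CAR variance undefined")
        g = nx.from_scipy_sparse_array(W)
        if not nx.is_connected(g):
            raise ValueError("adjacency graph must be connected")
        object.__setattr__(self, "degrees", degrees)

    @property
    def n_edges(self) -> int:
        return int(self.weight_matrix.nnz // 2)

    def edges(self) -> list[tuple[int, int]]:
        """Unordered edge pairs as 0-based ``(i, g)`` with ``i < g``."""
        coo = sp.coo_array(sp.triu(self.weight_matrix))
        return sorted(zip(coo.row.tolist(), coo.col.tolist()))

    def neighbor_sum(self, values: np.ndarray) -> np.ndarray:
        """``(W @ values)``: per-area sum of a vector over neighbors."""
        return self.weight_matrix @ np.asarray(values, dtype=float)

    def coloring(self) -> list[np.ndarray]:
        """Partition areas into classes with no within-class edges.

        Used to update CAR effects in valid simultaneous Metropolis blocks:
        areas in one class are conditionally independent given the rest.
        """
        g = nx.from_scipy_sparse_array(self.weight_matrix)
        colors = nx.greedy_color(g, strategy="largest_first")
        n_colors = max(colors.values()) + 1
        out = [[] for _ in range(n_colors)]
        for node, c in colors.items():
            out[c].append(node)
        return [np.array(sorted(c), dtype=np.int64) for c in out]

    def to_edge_list(self, path: str | Path) -> None:
        """Write a whitespace-delimited 1-based edge list."""
        with open(path, "w") as fh:
            for i, g in self.edges():
                fh.write(f"{i + 1} {g + 1}\n")


def build_lattice_adjacency(n_rows: int, n_cols: int) -> AdjacencyGraph:
    """Rook-neighbor rectangular lattice: cells adjacent iff they share a side.

    Corner cells have degree 2, edge cells 3 and interior cells 4 (for
    lattices with both dimensions >= 2); the graph is connected.

    Parameters
    ----------
    n_rows, n_cols : int
        Lattice dimensions; ``n_rows * n_cols >= 2`` required.
    """
    if n_rows < 1 or n_cols < 1 or n_rows * n_cols < 2:
        raise ValueError("lattice must contain at least 2 areas")
    g = nx.grid_2d_graph(n_rows, n_cols)
    order = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    W = sp.csr_array(nx.to_scipy_sparse_array(g, nodelist=order, dtype=np.int8))
    return AdjacencyGraph(n_rows * n_cols, W)


def load_adjacency(
    path: str | Path, format: str = "edge-list", n_areas: int | None = None
) -> AdjacencyGraph:
    """Read adjacency from a 1-based edge list or Matrix Market file.

    Input is symmetrized (a warning is emitted if it was not symmetric) and
    self-loops are dropped with a warning.  An isolated area — including any
    trailing area implied by ``n_areas`` but absent from the file — is a
    hard error.

    Parameters
    ----------
    path : str or Path
        File to read.
    format : {"edge-list", "matrix-market"}
        ``edge-list``: whitespace-delimited 1-based pairs, one per line.
        ``matrix-market``: coordinate-format sparse matrix.
    n_areas : int, optional
        Total number of areas; inferred as the largest index seen if omitted.
    """
    path = Path(path)
    if format == "edge-list":
        pairs: list[tuple[int, int]] = []
        for line_no, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected two indices, got {line!r}")
            i, g = int(parts[0]), int(parts[1])
            if i < 1 or g < 1:
                raise ValueError(f"{path}:{line_no}: indices are 1-based and must be >= 1")
            pairs.append((i - 1, g - 1))
        n = n_areas if n_areas is not None else (max(max(p) for p in pairs) + 1 if pairs else 0)
        W = sp.lil_array((n, n), dtype=np.int8)
        for i, g in pairs:
            if i >= n or g >= n:
                raise ValueError(f"edge ({i + 1}, {g + 1}) exceeds n_areas={n}")
            if i == g:
                warnings.warn(f"dropping self-loop on area {i + 1}", stacklevel=2)
                continue
            W[i, g] = 1
            W[g, i] = 1
        W = sp.csr_array(W)
    elif format == "matrix-market":
        M = sp.coo_array(sp.csr_matrix(mmread(path)))
        n = n_areas if n_areas is not None else M.shape[0]
        if M.shape[0] != M.shape[1]:
            raise ValueError("matrix-market adjacency must be square")
        keep = M.row != M.col
        if (~keep).any() and M.data[~keep].any():
            warnings.warn("dropping nonzero diagonal entries (self-loops)", stacklevel=2)
        W = sp.csr_array(
            ((M.data[keep] != 0).astype(np.int8), (M.row[keep], M.col[keep])), shape=(n, n)
        )
        if (W != W.T).nnz:
            warnings.warn("asymmetric adjacency input; symmetrizing", stacklevel=2)
        W = sp.csr_array(((W + W.T) > 0).astype(np.int8))
    else:
        raise ValueError(f"unknown adjacency format {format!r}")

    degrees = np.asarray(W.sum(axis=1)).ravel()
    if (degrees == 0).any():
        bad = int(np.flatnonzero(degrees == 0)[0]) + 1
        raise ValueError(f"area {bad} is isolated (no neighbors)")
    return AdjacencyGraph(n, W)


def morans_i(graph: AdjacencyGraph, values: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of ``values`` on ``graph``.

    I = (n / S0) * (z' W z) / (z' z) with z the centered values and
    S0 the sum of all weights.  Used to verify that the "concentrated"
    population regime is more spatially autocorrelated than "diffuse".
    """
    z = np.asarray(values, dtype=float) - float(np.mean(values))
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I undefined for constant values")
    s0 = float(graph.weight_matrix.sum())
    return graph.n_areas / s0 * float(z @ (graph.weight_matrix @ z)) / denom
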