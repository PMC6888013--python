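"""Region adjacency graphs and intrinsic CAR (ICAR) precision matrices.

The spatial building block of every model in this package is an intrinsic
Gaussian Markov random field over a region graph: the precision matrix is
the graph Laplacian Q = D - A, identified through a sum-to-zero constraint.
Following Simpson et al.'s BYM2 construction, the structured effect is
*scaled* so that the geometric mean of the marginal variances of its
generalized inverse equals one; this makes hyperpriors transferable across
graphs.

Graphs can be built as rook-adjacency lattices (the stand-in for real
administrative maps in the simulation study), or read from plain edge lists
and INLA-style graph text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "RegionGraph",
    "ScaledPrecision",
    "build_lattice_graph",
    "read_graph",
    "write_graph",
    "icar_precision",
    "scale_icar",
    "sample_structured",
]

#: relative eigenvalue threshold below which a Laplacian eigenvalue is
#: treated as a structural zero (one per connected component)
_NULL_TOL = 1e-10


@dataclass(frozen=True)
class RegionGraph:
    """Undirected adjacency over ``n_regions`` regions.

    Edges are stored as a frozenset of sorted 0-based index pairs; no
    self-loops, symmetric by construction.
    """

    n_regions: int
    edges: frozenset
    region_labels: tuple | None = None

    def __post_init__(self):
        if self.n_regions < 1:
            raise ValueError(f"n_regions must be positive, got {self.n_regions}")
        for e in self.edges:
            i, j = e
            if i == j:
                raise ValueError(f"self-loop at region {i}")
            if not (0 <= i < j < self.n_regions):
                raise ValueError(
                    f"edge {e} out of range for {self.n_regions} regions"
                )
        if self.region_labels is not None and len(self.region_labels) != self.n_regions:
            raise ValueError("region_labels length mismatch")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix."""
        if not self.edges:
            return sp.csr_matrix((self.n_regions, self.n_regions))
        rows, cols = zip(*self.edges)
        i = np.array(rows + cols)
        j = np.array(cols + rows)
        a = sp.coo_matrix(
            (np.ones(i.size), (i, j)), shape=(self.n_regions, self.n_regions)
        )
        return a.tocsr()

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def component_labels(self) -> np.ndarray:
        """Connected-component label per region."""
        _, labels = connected_components(self.adjacency(), directed=False)
        return labels

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)


def build_lattice_graph(nrows: int, ncols: int) -> RegionGraph:
    """Rook-adjacency lattice with ``nrows * ncols`` regions.

    Cell (r, c) maps to index ``r * ncols + c``; each interior cell has four
    neighbors. A 19x19 lattice (361 regions) is the default stand-in for a
    real administrative map in the simulation study.
    """
    if nrows < 1 or ncols < 1:
        raise ValueError(f"lattice dimensions must be positive, got {nrows}x{ncols}")
    if nrows * ncols < 2:
        raise ValueError("lattice must have at least 2 regions")
    edges = set()
    for r in range(nrows):
        for c in range(ncols):
            k = r * ncols + c
            if c + 1 < ncols:
                edges.add((k, k + 1))
            if r + 1 < nrows:
                edges.add((k, k + ncols))
    return RegionGraph(nrows * ncols, frozenset(edges))


def read_graph(path, format: str = "edge_list") -> RegionGraph:
    """Read a region graph from disk.

    ``edge_list``: two whitespace-separated 1-based region indices per line.
    ``inla_graph``: first line the number of regions n, then one line per
    region ``i k j1 ... jk`` with 1-based indices; neighbor listings must be
    symmetric.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if format == "edge_list":
        edges = set()
        nmax = 0
        for ln in lines:
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {ln!r}")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            if i < 0 or j < 0:
                raise ValueError(f"edge indices must be >= 1: {ln!r}")
            if i == j:
                raise ValueError(f"self-loop in edge list: {ln!r}")
            edges.add((min(i, j), max(i, j)))
            nmax = max(nmax, i + 1, j + 1)
        return RegionGraph(nmax, frozenset(edges))
    elif format == "inla_graph":
        n = int(lines[0])
        nbrs: dict[int, set[int]] = {}
        for ln in lines[1:]:
            parts = [int(x) for x in ln.split()]
            i, k, js = parts[0] - 1, parts[1], [j - 1 for j in parts[2:]]
            if len(js) != k:
                raise ValueError(f"region {i + 1}: declared {k} neighbors, listed {len(js)}")
            if not 0 <= i < n:
                raise ValueError(f"region index {i + 1} out of range 1..{n}")
            for j in js:
                if not 0 <= j < n:
                    raise ValueError(f"neighbor index {j + 1} out of range 1..{n}")
            nbrs[i] = set(js)
        for i, js in nbrs.items():
            for j in js:
                if i not in nbrs.get(j, set()):
                    raise ValueError(
                        f"asymmetric neighbor listing: {i + 1} lists {j + 1} "
                        f"but not conversely"
                    )
        edges = frozenset(
            (min(i, j), max(i, j)) for i, js in nbrs.items() for j in js
        )
        return RegionGraph(n, edges)
    raise ValueError(f"unknown graph format: {format!r}")


def write_graph(graph: RegionGraph, path, format: str = "edge_list") -> None:
    """Write a graph in either supported dialect (1-based indices on disk)."""
    with open(path, "w") as fh:
        if format == "edge_list":
            for i, j in sorted(graph.edges):
                fh.write(f"{i + 1} {j + 1}\n")
        elif format == "inla_graph":
            nbrs: dict[int, list[int]] = {i: [] for i in range(graph.n_regions)}
            for i, j in graph.edges:
                nbrs[i].append(j)
                nbrs[j].append(i)
            fh.write(f"{graph.n_regions}\n")
            for i in range(graph.n_regions):
                js = " ".join(str(j + 1) for j in sorted(nbrs[i]))
                fh.write(f"{i + 1} {len(nbrs[i])}{' ' + js if js else ''}\n")
        else:
            raise ValueError(f"unknown graph format: {format!r}")


@dataclass
class ScaledPrecision:
    """ICAR precision Q = D - A, its scaled version Q* and scaling metadata.

    ``scale_c`` holds the per-connected-component scaling constants
    c_k = exp(mean(log diag(V_k))) where V_k are the marginal variances of
    the generalized inverse of Q restricted to component k under the
    sum-to-zero constraint; Q* multiplies each component block by its c_k so
    that the geometric mean of marginal variances of (Q*)^- is one per
    component.  ``gen_inverse_diag`` is the diagonal of the generalized
    inverse of Q* (absent until :func:`scale_icar` runs).
    """

    Q: sp.csr_matrix
    graph: RegionGraph
    Q_star: sp.csr_matrix | None = None
    scale_c: np.ndarray | None = None
    gen_inverse_diag: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def is_scaled(self) -> bool:
        return self.Q_star is not None

    def eig_pinv(self, scaled: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvectors V and pseudo-inverse eigenvalues s of Q* (or Q).

        Returns (V, s) with Q^+ = V diag(s) V^T; the null directions (one
        constant direction per connected component) get s = 0, which encodes
        the sum-to-zero constraint.
        """
        key = ("eig", scaled)
        if key not in self._cache:
            M = self.Q_star if scaled else self.Q
            if M is None:
                raise ValueError("precision not scaled yet; call scale_icar first")
            w, V = np.linalg.eigh(M.toarray())
            tol = _NULL_TOL * max(1.0, float(w[-1]))
            s = np.where(w > tol, 1.0 / np.where(w > tol, w, 1.0), 0.0)
            self._cache[key] = (V, s)
        return self._cache[key]


def icar_precision(graph: RegionGraph) -> ScaledPrecision:
    """Unscaled ICAR precision Q = D - A for a region graph.

    Row sums are exactly zero; the rank deficiency equals the number of
    connected components.
    """
    if graph.n_regions < 2:
        raise ValueError("ICAR precision needs at least 2 regions")
    A = graph.adjacency()
    D = sp.diags(np.asarray(A.sum(axis=1)).ravel())
    Q = (D - A).tocsr()
    return ScaledPrecision(Q=Q, graph=graph)


def _component_pinv_diag(Q_dense: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Marginal variances of the sum-to-zero constrained GMRF on one component."""
    block = Q_dense[np.ix_(idx, idx)]
    w, V = np.linalg.eigh(block)
    tol = _NULL_TOL * max(1.0, float(w[-1]))
    keep = w > tol
    return ((V[:, keep] ** 2) / w[keep]).sum(axis=1)


def scale_icar(precision: ScaledPrecision | sp.spmatrix) -> ScaledPrecision:
    """Scale an ICAR precision per Simpson/Riebler: Q* = c * Q per component.

    Each connected component k is scaled by c_k, the geometric mean of the
    marginal variances of the generalized inverse of its Laplacian block
    under the sum-to-zero constraint; afterwards the geometric mean of
    marginal variances of (Q*)^- is 1 within each component. Isolated
    (zero-degree) regions are rejected: a region with no neighbors has no
    structured effect to scale.
    """
    if isinstance(precision, ScaledPrecision):
        graph = precision.graph
        Q = precision.Q
    else:
        raise TypeError("scale_icar expects the ScaledPrecision from icar_precision")
    deg = graph.degrees()
    if np.any(deg == 0):
        bad = np.flatnonzero(deg == 0)
        raise ValueError(
            f"isolated regions (no neighbors) cannot be scaled: {bad.tolist()}"
        )
    labels = graph.component_labels()
    Qd = Q.toarray()
    n_comp = labels.max() + 1
    scale_c = np.empty(n_comp)
    gi_diag = np.empty(Q.shape[0])
    row_scale = np.empty(Q.shape[0])
    for k in range(n_comp):
        idx = np.flatnonzero(labels == k)
        v = _component_pinv_diag(Qd, idx)
        c = float(np.exp(np.mean(np.log(v))))
        scale_c[k] = c
        row_scale[idx] = c
        gi_diag[idx] = v / c
    Q_star = sp.diags(row_scale) @ Q
    Q_star = ((Q_star + Q_star.T) / 2.0).tocsr()  # exact symmetry
    return ScaledPrecision(
        Q=Q, graph=graph, Q_star=Q_star, scale_c=scale_c, gen_inverse_diag=gi_diag
    )


def sample_structured(
    precision: ScaledPrecision, tau: float, rng_seed
) -> np.ndarray:
    """Draw one structured effect u* from the intrinsic GMRF tau * Q*.

    The draw is conditioned on a sum-to-zero constraint per connected
    component (implemented spectrally: null directions of Q* carry no
    mass), so the returned vector sums to zero within each component.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    V, s = precision.eig_pinv(scaled=True)
    eps = rng.standard_normal(precision.n)
    return V @ (np.sqrt(s / tau) * eps)
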