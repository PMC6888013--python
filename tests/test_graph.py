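"""Region graphs, ICAR precisions, scaling and constrained sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatzip import (
    RegionGraph,
    build_lattice_graph,
    icar_precision,
    read_graph,
    sample_structured,
    scale_icar,
    write_graph,
)
from tests.conftest import dense_pinv_diag


@pytest.mark.parametrize(
    "nrows,ncols,n_nodes,n_edges",
    [(1, 2, 2, 1), (2, 2, 4, 4), (19, 19, 361, 684), (3, 5, 15, 22)],
)
def test_lattice_counts(nrows, ncols, n_nodes, n_edges):
    # rook rule: edges = r(c-1) + c(r-1)
    g = build_lattice_graph(nrows, ncols)
    assert g.n_regions == n_nodes
    assert g.n_edges == n_edges


def test_lattice_interior_degree_and_connectivity():
    g = build_lattice_graph(5, 7)
    deg = g.degrees()
    interior = [r * 7 + c for r in range(1, 4) for c in range(1, 6)]
    assert all(deg[i] == 4 for i in interior)
    assert len(np.unique(g.component_labels())) == 1


@pytest.mark.parametrize("nrows,ncols", [(0, 3), (-1, 2), (1, 1)])
def test_lattice_rejects_bad_dimensions(nrows, ncols):
    with pytest.raises(ValueError):
        build_lattice_graph(nrows, ncols)


def test_icar_precision_matches_hand_examples():
    Q = icar_precision(build_lattice_graph(1, 2)).Q.toarray()
    assert np.array_equal(Q, [[1, -1], [-1, 1]])
    Q3 = icar_precision(build_lattice_graph(1, 3)).Q.toarray()
    assert np.array_equal(Q3, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])
    Q22 = icar_precision(build_lattice_graph(2, 2)).Q.toarray()
    assert np.array_equal(np.diag(Q22), [2, 2, 2, 2])


@given(st.integers(1, 6), st.integers(2, 6))
@settings(deadline=None, derandomize=True, max_examples=20)
def test_icar_rowsums_zero(nrows, ncols):
    Q = icar_precision(build_lattice_graph(nrows, ncols)).Q
    assert np.allclose(Q.toarray().sum(axis=1), 0.0, atol=0.0)


def test_scale_icar_two_node_path():
    # pinv of [[1,-1],[-1,1]] is [[.25,-.25],[-.25,.25]] -> c = 0.25
    sp = scale_icar(icar_precision(build_lattice_graph(1, 2)))
    assert np.allclose(sp.scale_c, [0.25])
    assert np.allclose(sp.Q_star.toarray(), 0.25 * np.array([[1, -1], [-1, 1]]))


@pytest.mark.parametrize("dims", [(1, 3), (2, 2), (3, 3), (4, 5)])
def test_scaled_geometric_mean_is_one(dims):
    sp = scale_icar(icar_precision(build_lattice_graph(*dims)))
    v = dense_pinv_diag(sp.Q_star.toarray())
    assert abs(np.exp(np.mean(np.log(v))) - 1.0) < 1e-8
    assert np.allclose(sp.gen_inverse_diag, v, atol=1e-8)


def test_scaling_idempotent():
    sp = scale_icar(icar_precision(build_lattice_graph(3, 4)))
    graph = sp.graph
    from spatzip.graph import ScaledPrecision

    again = scale_icar(ScaledPrecision(Q=sp.Q_star, graph=graph))
    assert np.allclose(again.scale_c, 1.0, atol=1e-8)


def test_scale_matches_dense_oracle_per_component():
    # two disconnected lattices scaled independently
    g1 = build_lattice_graph(2, 3)
    edges = set(g1.edges) | {(i + 6, j + 6) for i, j in build_lattice_graph(2, 2).edges}
    g = RegionGraph(10, frozenset(edges))
    sp = scale_icar(icar_precision(g))
    Qd = sp.Q.toarray()
    for idx in (np.arange(6), np.arange(6, 10)):
        v = dense_pinv_diag(Qd[np.ix_(idx, idx)])
        c = np.exp(np.mean(np.log(v)))
        assert abs(np.exp(np.mean(np.log(dense_pinv_diag(sp.Q_star.toarray()[np.ix_(idx, idx)])))) - 1.0) < 1e-8
        assert np.allclose(sp.gen_inverse_diag[idx], v / c, atol=1e-8)


def test_isolated_node_rejected():
    g = RegionGraph(3, frozenset({(0, 1)}))
    with pytest.raises(ValueError, match="isolated"):
        scale_icar(icar_precision(g))


def test_graph_validation_errors():
    with pytest.raises(ValueError, match="self-loop"):
        RegionGraph(3, frozenset({(1, 1)}))
    with pytest.raises(ValueError, match="out of range"):
        RegionGraph(2, frozenset({(0, 5)}))


def test_edge_list_round_trip(tmp_path):
    g = build_lattice_graph(19, 19)
    p = tmp_path / "lattice.txt"
    write_graph(g, p, format="edge_list")
    g2 = read_graph(p, format="edge_list")
    assert g2.edges == g.edges and g2.n_regions == g.n_regions


def test_inla_graph_dialect(tmp_path):
    p = tmp_path / "tiny.graph"
    p.write_text("2\n1 1 2\n2 1 1\n")
    g = read_graph(p, format="inla_graph")
    assert g.n_regions == 2 and g.edges == frozenset({(0, 1)})


def test_inla_graph_round_trip(tmp_path):
    g = build_lattice_graph(19, 19)
    p = tmp_path / "lattice.graph"
    write_graph(g, p, format="inla_graph")
    assert read_graph(p, format="inla_graph").edges == g.edges


def test_edge_list_parse():
    import os
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".txt", delete=False) as fh:
        fh.write("1 2\n2 3\n")
        name = fh.name
    try:
        g = read_graph(name, format="edge_list")
        assert g.n_regions == 3 and g.edges == frozenset({(0, 1), (1, 2)})
    finally:
        os.unlink(name)


def test_asymmetric_inla_graph_rejected(tmp_path):
    p = tmp_path / "bad.graph"
    p.write_text("3\n1 1 2\n2 0\n3 0\n")
    with pytest.raises(ValueError, match="asymmetric"):
        read_graph(p, format="inla_graph")


def test_inla_graph_index_out_of_range(tmp_path):
    p = tmp_path / "bad2.graph"
    p.write_text("2\n1 1 5\n2 0\n")
    with pytest.raises(ValueError, match="out of range"):
        read_graph(p, format="inla_graph")


def test_sample_structured_constraint_and_determinism(path3_precision):
    u1 = sample_structured(path3_precision, tau=2.0, rng_seed=7)
    u2 = sample_structured(path3_precision, tau=2.0, rng_seed=7)
    assert abs(u1.sum()) < 1e-10
    assert np.array_equal(u1, u2)
    with pytest.raises(ValueError):
        sample_structured(path3_precision, tau=0.0, rng_seed=1)


def test_sample_structured_covariance_oracle(path3_precision):
    # empirical covariance over many draws vs (1/tau) * pinv(Q*)
    tau = 1.7
    rng = np.random.default_rng(11)
    draws = np.array([sample_structured(path3_precision, tau, rng) for _ in range(20000)])
    emp = draws.T @ draws / len(draws)
    oracle = np.linalg.pinv(path3_precision.Q_star.toarray()) / tau
    assert np.max(np.abs(emp - oracle)) < 0.05
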