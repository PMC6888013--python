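import numpy as np
import pytest

from spatzip import build_lattice_graph, icar_precision, scale_icar


@pytest.fixture(scope="session")
def path3_precision():
    """Scaled ICAR precision of the 3-node path graph (1x3 lattice)."""
    return scale_icar(icar_precision(build_lattice_graph(1, 3)))


@pytest.fixture(scope="session")
def lattice22_precision():
    return scale_icar(icar_precision(build_lattice_graph(2, 2)))


@pytest.fixture(scope="session")
def lattice33_precision():
    return scale_icar(icar_precision(build_lattice_graph(3, 3)))


@pytest.fixture(scope="session")
def study_precision():
    """The 19x19 rook lattice used as the study's stand-in graph."""
    return scale_icar(icar_precision(build_lattice_graph(19, 19)))


def dense_pinv_diag(Q_dense):
    """Dense eigendecomposition oracle for constrained marginal variances."""
    w, V = np.linalg.eigh(Q_dense)
    keep = w > 1e-10 * max(1.0, w[-1])
    return ((V[:, keep] ** 2) / w[keep]).sum(axis=1)
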