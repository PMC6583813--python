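import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import spdurbin as sd
from spdurbin.weights import WeightsFormatError


def ring_weights(n):
    rows = np.arange(n)
    m = sp.coo_matrix(
        (np.ones(2 * n), (np.tile(rows, 2),
                          np.concatenate([(rows + 1) % n, (rows - 1) % n]))),
        shape=(n, n),
    )
    return sd.SpatialWeights(m)


@pytest.mark.parametrize(
    "contiguity, center_deg, corner_deg",
    [("rook", 4, 2), ("queen", 8, 3)],
)
def test_lattice_neighbor_counts(contiguity, center_deg, corner_deg):
    w = sd.lattice_weights(3, 3, contiguity)
    deg = w.cardinalities
    assert deg[4] == center_deg          # center cell
    assert all(deg[i] == corner_deg for i in (0, 2, 6, 8))
    assert (w.sparse != w.sparse.T).nnz == 0


def test_smallest_lattice():
    w = sd.lattice_weights(1, 2, "rook")
    assert list(w.cardinalities) == [1, 1]


@pytest.mark.parametrize("bad", [(0, 3), (3, 0), (-1, 5), (1, 1)])
def test_lattice_bad_dimensions(bad):
    with pytest.raises(ValueError):
        sd.lattice_weights(*bad)


def test_gal_round_trip(tmp_path):
    w = sd.lattice_weights(3, 3, "rook")
    path = tmp_path / "w.gal"
    sd.write_gal(w, path)
    w2 = sd.read_gal(path)
    assert w2.neighbor_lists == w.neighbor_lists
    assert w2.ids == w.ids


def test_gal_unknown_id_is_format_error(tmp_path):
    path = tmp_path / "bad.gal"
    path.write_text("2\na 1\nb\nb 1\nzzz\n")
    with pytest.raises(WeightsFormatError):
        sd.read_gal(path)


def test_gal_island_is_legal(tmp_path):
    path = tmp_path / "island.gal"
    path.write_text("3\na 1\nb\nb 1\na\nc 0\n")
    w = sd.read_gal(path)
    assert list(w.islands) == [2]
    assert w.neighbor_lists["c"] == []


def test_row_standardize_ring_splits_equally():
    w = ring_weights(6).row_standardize()
    assert np.allclose(w.sparse.data, 0.5)
    rs = np.asarray(w.sparse.sum(axis=1)).ravel()
    assert np.allclose(rs, 1.0, atol=1e-12)


def test_row_standardize_island_row_stays_zero():
    m = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0.0]]))
    with pytest.warns(UserWarning, match="island"):
        w = sd.SpatialWeights(m).row_standardize()
    assert w.sparse[2].nnz == 0
    assert list(w.islands) == [2]


def test_row_standardize_queen_center():
    w = sd.lattice_weights(3, 3, "queen").row_standardize()
    center = w.sparse[4].toarray().ravel()
    assert np.allclose(center[center > 0], 0.125)


def test_power_zero_is_identity(queen5):
    p0 = queen5.power(0)
    assert (p0 != sp.identity(25)).nnz == 0


def test_power_two_step_walks():
    # path graph a-b-c
    m = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]]))
    w = sd.SpatialWeights(m)
    w2 = w.power(2).toarray()
    assert w2[0, 2] != 0            # a reaches c in two steps
    assert all(w2[i, i] != 0 for i in range(3))


def test_power_validation(queen5):
    with pytest.raises(ValueError):
        queen5.power(-1)
    with pytest.raises(ValueError):
        queen5.power(11)  # above default maximum
    assert queen5.power(11, max_order=12).shape == (25, 25)


def test_row_standardized_powers_are_stochastic(queen5):
    for k in (1, 2, 3):
        rs = np.asarray(queen5.power(k, max_order=5).sum(axis=1)).ravel()
        assert np.allclose(rs, 1.0, atol=1e-12)


def test_power_additivity_dense_oracle(queen5):
    d = queen5.sparse.toarray()
    lhs = (queen5.power(2, 6) @ queen5.power(3, 6)).toarray()
    rhs = np.linalg.matrix_power(d, 5)
    assert np.allclose(lhs, rhs, atol=1e-12)


def test_spectral_radius_of_row_standardized(queen5):
    ev = queen5.eigenvalues()
    assert abs(ev[-1] - 1.0) < 1e-10
    assert np.abs(ev).max() <= 1 + 1e-10
    lo, hi = queen5.rho_interval()
    assert hi == pytest.approx(1.0, abs=1e-10)
    assert lo < 0


def test_asymmetric_adjacency_symmetrized_by_union():
    m = sp.csr_matrix(np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0.0]]))
    with pytest.warns(UserWarning, match="symmetrized"):
        w = sd.SpatialWeights(m)
    assert (w.sparse != w.sparse.T).nnz == 0
    assert w.sparse.nnz == 4


def test_invalid_matrices_rejected():
    with pytest.raises(ValueError, match="negative"):
        sd.SpatialWeights(sp.csr_matrix(np.array([[0, -1], [-1, 0.0]])))
    with pytest.raises(ValueError, match="diagonal"):
        sd.SpatialWeights(sp.csr_matrix(np.array([[1, 1], [1, 0.0]])))


def test_edgelist_round(tmp_path):
    path = tmp_path / "edges.csv"
    path.write_text("id_from,id_to,weight\na,b,1\nb,a,1\nb,c,2\nc,b,2\n")
    w = sd.read_edgelist(path)
    assert w.ids == ["a", "b", "c"]
    assert w.sparse[1, 2] == 2.0


def test_gal_write_read_preserves_islands(tmp_path):
    m = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0.0]]))
    w = sd.SpatialWeights(m, ids=["x", "y", "z"])
    path = tmp_path / "isl.gal"
    sd.write_gal(w, path)
    w2 = sd.read_gal(path)
    assert w2.neighbor_lists == w.neighbor_lists


def test_log_det_zero_at_rho_zero(queen5):
    assert queen5.log_det(0.0, method="eig") == pytest.approx(0.0, abs=1e-12)
    assert queen5.log_det(0.0, method="lu") == pytest.approx(0.0, abs=1e-12)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(rows=st.integers(2, 6), cols=st.integers(2, 6),
       contiguity=st.sampled_from(["rook", "queen"]))
def test_lattice_invariants(rows, cols, contiguity):
    w = sd.lattice_weights(rows, cols, contiguity)
    assert (w.sparse != w.sparse.T).nnz == 0       # symmetric
    assert w.sparse.diagonal().sum() == 0          # no self-neighbors
    assert w.islands.size == 0                     # lattices have no islands
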