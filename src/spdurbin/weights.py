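"""Spatial weights matrices for areal data.

A :class:`SpatialWeights` object wraps a sparse n x n non-negative matrix W
encoding the neighbor structure of a set of areas (counties, tracts, grid
cells).  It enforces the conventions spatial regression relies on: zero
diagonal (no area is its own neighbor), symmetric underlying adjacency, and
optional row standardization so each non-island row sums to one.  Row
standardization makes the spatial autoregressive parameter rho interpretable
on the interval (1/lambda_min, 1) and turns Wx into "the average of x over
the neighbors of each area".

Construction helpers cover the cases a simulation or applied study needs:
regular lattices with rook or queen contiguity, GAL contiguity files (the
GeoDa exchange dialect), and edge-list CSVs.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

#: Largest n for which dense eigen-decomposition / dense oracle paths are allowed.
DENSE_THRESHOLD = 4000

#: Default cap on the exponent accepted by :func:`weights_power`.
MAX_POWER = 10


class WeightsFormatError(ValueError):
    """A weights file (GAL or edge list) is internally inconsistent."""


class SpatialWeights:
    """Sparse spatial weights matrix with neighbor-list semantics.

    Parameters
    ----------
    matrix : sparse or dense array, shape (n, n)
        Non-negative weights with zero diagonal.  If the sparsity pattern is
        asymmetric and ``standardized`` is False, the adjacency is
        symmetrized by union (elementwise maximum) with a warning;
        contiguity is symmetric by definition.
    ids : sequence of hashable, optional
        Area identifiers in matrix order; defaults to ``"0" .. "n-1"``.
        Stored as strings.
    standardized : bool
        True when rows have been standardized to sum to one (islands keep
        all-zero rows).  Use :meth:`row_standardize` rather than passing a
        pre-standardized matrix where possible, so the binary adjacency is
        retained for the symmetric eigenvalue path.
    """

    def __init__(self, matrix, ids=None, standardized: bool = False):
        m = sp.csr_matrix(matrix, dtype=float, copy=True)
        if m.shape[0] != m.shape[1]:
            raise ValueError(f"weights matrix must be square, got {m.shape}")
        if m.nnz and (m.data < 0).any():
            raise ValueError("negative spatial weights are not allowed")
        if np.abs(m.diagonal()).max(initial=0.0) > 0:
            raise ValueError("weights matrix must have a zero diagonal (no self-neighbors)")
        pattern = (m != 0)
        if (pattern != pattern.T).nnz:
            if standardized:
                raise WeightsFormatError(
                    "row-standardized weights must come from a symmetric adjacency"
                )
            warnings.warn(
                "asymmetric adjacency symmetrized by union", UserWarning, stacklevel=2
            )
            m = m.maximum(m.T.tocsr())
        m.eliminate_zeros()
        m.sort_indices()
        self.sparse: sp.csr_matrix = m
        self.n: int = m.shape[0]
        if ids is None:
            ids = range(self.n)
        self.ids: list[str] = [str(i) for i in ids]
        if len(self.ids) != self.n:
            raise ValueError("length of ids does not match matrix dimension")
        if len(set(self.ids)) != self.n:
            raise ValueError("area ids must be unique")
        self.standardized: bool = bool(standardized)
        # binary adjacency underlying a standardized matrix (for eigenvalues)
        self._base: sp.csr_matrix | None = None
        self._eigvals: np.ndarray | None = None

    # ------------------------------------------------------------------ #
    # basic structure
    # ------------------------------------------------------------------ #

    @property
    def cardinalities(self) -> np.ndarray:
        """Number of neighbors of each area."""
        return np.diff(self.sparse.indptr)

    @property
    def islands(self) -> np.ndarray:
        """Indices of areas with no neighbors (all-zero rows)."""
        return np.flatnonzero(self.cardinalities == 0)

    @property
    def s0(self) -> float:
        """Sum of all weights (islands contribute nothing)."""
        return float(self.sparse.sum())

    @property
    def neighbor_lists(self) -> dict[str, list[str]]:
        """Mapping id -> list of neighbor ids, in matrix order."""
        out = {}
        indptr, indices = self.sparse.indptr, self.sparse.indices
        for i, aid in enumerate(self.ids):
            out[aid] = [self.ids[j] for j in indices[indptr[i]:indptr[i + 1]]]
        return out

    def neighbors(self, i: int) -> np.ndarray:
        """Neighbor indices of area ``i``."""
        return self.sparse.indices[self.sparse.indptr[i]:self.sparse.indptr[i + 1]]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "row-standardized" if self.standardized else "binary/raw"
        return f"<SpatialWeights n={self.n} nnz={self.sparse.nnz} {kind}>"

    # ------------------------------------------------------------------ #
    # transforms
    # ------------------------------------------------------------------ #

    def row_standardize(self) -> "SpatialWeights":
        """Return a copy with each non-island row scaled to sum to one.

        Island rows stay all-zero; their presence is reported with a warning
        so downstream interpretation (lag terms identically zero) is not
        silent.
        """
        rs = np.asarray(self.sparse.sum(axis=1)).ravel()
        isl = np.flatnonzero(rs == 0)
        if isl.size:
            warnings.warn(
                f"{isl.size} island(s) retained with all-zero rows: "
                f"{[self.ids[i] for i in isl[:10]]}",
                UserWarning,
                stacklevel=2,
            )
        inv = np.zeros_like(rs)
        nz = rs > 0
        inv[nz] = 1.0 / rs[nz]
        m = sp.diags(inv) @ self.sparse
        out = SpatialWeights(m, ids=self.ids, standardized=True)
        out._base = self.sparse
        return out

    def power(self, k: int, max_order: int = MAX_POWER) -> sp.csr_matrix:
        """Exact sparse matrix power W^k; ``k=0`` returns the identity."""
        if not isinstance(k, (int, np.integer)) or k < 0:
            raise ValueError(f"power k must be a non-negative integer, got {k!r}")
        if k > max_order:
            raise ValueError(f"power k={k} exceeds configured maximum {max_order}")
        if k == 0:
            return sp.identity(self.n, format="csr")
        out = self.sparse.copy()
        for _ in range(k - 1):
            out = out @ self.sparse
        return out.tocsr()

    # ------------------------------------------------------------------ #
    # spectra and determinants
    # ------------------------------------------------------------------ #

    def eigenvalues(self) -> np.ndarray:
        """All eigenvalues of W, sorted ascending (real).

        For a row-standardized matrix built by :meth:`row_standardize` from a
        symmetric adjacency A, eigenvalues are computed on the similar
        symmetric matrix D^{-1/2} A D^{-1/2}, guaranteeing a real spectrum.
        Island rows contribute zero eigenvalues.
        """
        if self._eigvals is not None:
            return self._eigvals
        if self.n > DENSE_THRESHOLD:
            raise ValueError(
                f"dense eigen-decomposition refused for n={self.n} > {DENSE_THRESHOLD}"
            )
        if self.standardized and self._base is not None:
            a = self._base
            d = np.asarray(a.sum(axis=1)).ravel()
            dm = np.zeros_like(d)
            nz = d > 0
            dm[nz] = d[nz] ** -0.5
            sym = (sp.diags(dm) @ a @ sp.diags(dm)).toarray()
            ev = np.linalg.eigvalsh(sym)
        else:
            dense = self.sparse.toarray()
            if np.allclose(dense, dense.T, atol=1e-12):
                ev = np.linalg.eigvalsh(dense)
            else:
                evc = np.linalg.eigvals(dense)
                if np.abs(evc.imag).max(initial=0.0) > 1e-8:
                    warnings.warn(
                        "complex eigenvalues of asymmetric W; using real parts",
                        UserWarning,
                        stacklevel=2,
                    )
                ev = np.sort(evc.real)
        self._eigvals = np.sort(ev)
        return self._eigvals

    def rho_interval(self) -> tuple[float, float]:
        """Open admissible interval for the autoregressive parameter rho.

        ``(1/lambda_min, 1/lambda_max)``; for row-standardized W this is
        ``(1/lambda_min, 1)``.
        """
        ev = self.eigenvalues()
        lam_min, lam_max = float(ev[0]), float(ev[-1])
        lo = 1.0 / lam_min if lam_min < 0 else -np.inf
        hi = 1.0 / lam_max if lam_max > 0 else np.inf
        return lo, hi

    def log_det(self, rho: float, method: str = "auto") -> float:
        """log|I - rho W| via precomputed eigenvalues or sparse LU.

        ``method`` is one of ``"auto"`` (eigenvalues when available or
        n <= DENSE_THRESHOLD, else LU), ``"eig"``, ``"lu"``.
        """
        if method not in ("auto", "eig", "lu"):
            raise ValueError(f"unknown log-det method {method!r}")
        if method == "eig" or (
            method == "auto" and (self._eigvals is not None or self.n <= DENSE_THRESHOLD)
        ):
            ev = self.eigenvalues()
            vals = 1.0 - rho * ev
            if np.any(vals <= 0):
                raise ArithmeticError(
                    f"I - rho W singular or indefinite at rho={rho}"
                )
            return float(np.log(vals).sum())
        a = (sp.identity(self.n, format="csc") - rho * self.sparse).tocsc()
        lu = splu(a)
        du = lu.U.diagonal()
        if np.any(du == 0):
            raise ArithmeticError(f"I - rho W singular at rho={rho}")
        # inside the admissible interval the determinant is positive
        return float(np.log(np.abs(du)).sum())

    # ------------------------------------------------------------------ #
    # provenance
    # ------------------------------------------------------------------ #

    def checksum(self) -> str:
        """SHA-256 over ids and the (rounded) edge list; provenance for reports."""
        h = hashlib.sha256()
        h.update(("\n".join(self.ids)).encode())
        coo = self.sparse.tocoo()
        order = np.lexsort((coo.col, coo.row))
        for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            h.update(f"{i},{j},{v:.12g};".encode())
        return h.hexdigest()


# ---------------------------------------------------------------------- #
# constructors
# ---------------------------------------------------------------------- #

def lattice_weights(rows: int, cols: int, contiguity: str = "queen") -> SpatialWeights:
    """Binary contiguity weights for a regular rows x cols lattice.

    Rook contiguity joins cells sharing an edge (interior cells have 4
    neighbors); queen also joins diagonal cells (interior cells have 8).
    """
    if not (isinstance(rows, (int, np.integer)) and isinstance(cols, (int, np.integer))):
        raise ValueError("lattice dimensions must be integers")
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError(f"need a lattice with at least 2 cells, got {rows}x{cols}")
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"contiguity must be 'rook' or 'queen', got {contiguity!r}")

    idx = np.arange(rows * cols).reshape(rows, cols)
    pairs = [
        (idx[:, :-1], idx[:, 1:]),   # east
        (idx[:-1, :], idx[1:, :]),   # south
    ]
    if contiguity == "queen":
        pairs += [
            (idx[:-1, :-1], idx[1:, 1:]),   # south-east
            (idx[:-1, 1:], idx[1:, :-1]),   # south-west
        ]
    src = np.concatenate([a.ravel() for a, _ in pairs])
    dst = np.concatenate([b.ravel() for _, b in pairs])
    row = np.concatenate([src, dst])
    col = np.concatenate([dst, src])
    m = sp.coo_matrix(
        (np.ones(row.size), (row, col)), shape=(rows * cols, rows * cols)
    ).tocsr()
    return SpatialWeights(m)


# kept under the name the operation is usually referred to by
build_lattice_weights = lattice_weights


def weights_power(w: SpatialWeights, k: int, max_order: int = MAX_POWER) -> sp.csr_matrix:
    """Module-level alias for :meth:`SpatialWeights.power`."""
    return w.power(k, max_order=max_order)


def read_gal(path) -> SpatialWeights:
    """Read a GAL contiguity file (GeoDa dialect).

    The header is either a bare ``n`` or ``0 n fileName idVar``; the body
    alternates an ``id k`` line with a line of ``k`` neighbor ids.  Island
    areas are written as ``id 0`` with no neighbor line.  Neighbor ids that
    were never declared raise :class:`WeightsFormatError`; an asymmetric
    adjacency is symmetrized by union with a warning.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise WeightsFormatError(f"empty GAL file: {path}")
    head = lines[0].split()
    if len(head) == 1:
        n = int(head[0])
    elif len(head) >= 2 and head[0] == "0":
        n = int(head[1])
    else:
        raise WeightsFormatError(f"unrecognized GAL header: {lines[0]!r}")
    tokens = " ".join(lines[1:]).split()
    pos = 0

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise WeightsFormatError("truncated GAL body")
        tok = tokens[pos]
        pos += 1
        return tok

    ids: list[str] = []
    nbrs: list[list[str]] = []
    for _ in range(n):
        aid = take()
        try:
            k = int(take())
        except ValueError as exc:
            raise WeightsFormatError(f"bad cardinality for area {aid!r}") from exc
        ids.append(aid)
        nbrs.append([take() for _ in range(k)])
    if pos != len(tokens):
        raise WeightsFormatError("trailing tokens in GAL body")
    if len(set(ids)) != n:
        raise WeightsFormatError("duplicate area ids in GAL file")
    index = {aid: i for i, aid in enumerate(ids)}
    rows, cols = [], []
    for i, lst in enumerate(nbrs):
        for aid in lst:
            if aid not in index:
                raise WeightsFormatError(f"neighbor id {aid!r} never declared")
            rows.append(i)
            cols.append(index[aid])
    m = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    m.data[:] = 1.0  # collapse accidental duplicates to binary
    return SpatialWeights(m, ids=ids)


def write_gal(w: SpatialWeights, path) -> None:
    """Write the neighbor structure of ``w`` as a GAL file (bare-``n`` header)."""
    lines = [str(w.n)]
    for i, aid in enumerate(w.ids):
        nb = w.neighbors(i)
        lines.append(f"{aid} {nb.size}")
        if nb.size:
            lines.append(" ".join(w.ids[j] for j in nb))
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path) -> SpatialWeights:
    """Read weights from a CSV with columns ``id_from,id_to[,weight]``.

    Areas are ordered by first appearance.  Missing reciprocal edges are
    added by union symmetrization (with a warning).
    """
    df = pd.read_csv(path, dtype={0: str, 1: str})
    need = {"id_from", "id_to"}
    if not need.issubset(df.columns):
        raise WeightsFormatError(
            f"edge list must have columns id_from,id_to[,weight]; got {list(df.columns)}"
        )
    ids: list[str] = []
    index: dict[str, int] = {}
    for aid in pd.concat([df["id_from"], df["id_to"]]).astype(str):
        if aid not in index:
            index[aid] = len(ids)
            ids.append(aid)
    n = len(ids)
    vals = (
        df["weight"].to_numpy(float)
        if "weight" in df.columns
        else np.ones(len(df))
    )
    rows = df["id_from"].astype(str).map(index).to_numpy()
    cols = df["id_to"].astype(str).map(index).to_numpy()
    if np.any(rows == cols):
        raise WeightsFormatError("edge list contains self-loops")
    m = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return SpatialWeights(m, ids=ids)
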