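"""Magnetic Laplacian construction and Chebyshev filtering for directed graphs.

Edge direction is encoded as a complex phase: given the binary asymmetric
adjacency A, the symmetrized adjacency S(u,v) = (A(u,v) + A(v,u)) / 2
carries undirected connectivity, while the phase matrix
Theta(u,v) = 2*pi*q*(A(u,v) - A(v,u)) carries orientation. Their
combination H = S ⊙ exp(i·Theta) is Hermitian, and the degree-normalized
magnetic Laplacian

    L(q) = I − D^{−1/2} S D^{−1/2} ⊙ exp(i·Theta)

is Hermitian positive-semidefinite with spectrum in [0, 2]. q = 0 recovers
the classical symmetric normalized Laplacian; q = 0.25 maps a one-way edge
to a purely imaginary entry (maximal direction contrast). Reciprocal edge
pairs always carry zero phase.

Spectral filters are Chebyshev polynomials of the shifted operator
L̃ = L − I (spectrum in [−1, 1]), evaluated by the three-term recurrence —
no eigendecomposition is ever required.

All operators are scipy CSR matrices (complex128), so the same code path
serves dense test graphs and large sparse networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core_io import GeneGraph

__all__ = [
    "HermitianOperator",
    "symmetrize",
    "phase_matrix",
    "hermitian_adjacency",
    "magnetic_laplacian",
    "laplacian_from_edges",
    "shift_operator",
    "cheb_filter",
    "save_operator",
    "load_operator",
]


def _to_csr(A) -> sp.csr_matrix:
    if sp.issparse(A):
        return A.tocsr()
    return sp.csr_matrix(np.asarray(A))


def symmetrize(A) -> sp.csr_matrix:
    """S = (A + Aᵀ)/2 for a binary adjacency; entries in {0, 0.5, 1}."""
    A = _to_csr(A).astype(np.float64)
    S = (A + A.T) * 0.5
    S.sum_duplicates()
    return S.tocsr()


def phase_matrix(A, q: float) -> sp.csr_matrix:
    """Theta(q) = 2*pi*q*(A − Aᵀ); skew-symmetric, entries in {−2πq, 0, 2πq}."""
    if q < 0:
        raise ValueError("q must be >= 0")
    A = _to_csr(A).astype(np.float64)
    Theta = (A - A.T) * (2.0 * np.pi * q)
    Theta.sum_duplicates()
    Theta.eliminate_zeros()
    return Theta.tocsr()


def hermitian_adjacency(S, Theta) -> sp.csr_matrix:
    """H = S ⊙ exp(i·Theta); Hermitian by construction.

    The elementwise product is evaluated only on the support of S (Theta is
    zero wherever S is zero, so exp(i·Theta)=1 there contributes nothing).
    """
    S = _to_csr(S)
    Theta = _to_csr(Theta)
    if S.shape != Theta.shape:
        raise ValueError("shape mismatch between S and Theta")
    S = S.tocoo()
    if S.nnz == 0:
        return sp.csr_matrix(S.shape, dtype=np.complex128)
    theta_vals = np.asarray(Theta.tocsr()[S.row, S.col]).ravel()
    data = S.data * np.exp(1j * theta_vals)
    # snap components at machine-epsilon scale to exact zero so that e.g.
    # q=0.25 yields exactly ±i·S(u,v) for one-way edges (cos(π/2) is not
    # exactly 0 in floating point, and the complex ReLU keys on Re ≥ 0)
    re, im = data.real.copy(), data.imag.copy()
    tiny = np.abs(data) * 1e-12
    re[np.abs(re) < tiny] = 0.0
    im[np.abs(im) < tiny] = 0.0
    return sp.csr_matrix((re + 1j * im, (S.row, S.col)), shape=S.shape)


@dataclass(frozen=True)
class HermitianOperator:
    """The spectral bundle for one graph at one value of q.

    ``L`` is the normalized magnetic Laplacian and ``L_shifted`` = L − I the
    Chebyshev-rescaled operator (spectrum in [−1, 1]); degree-zero nodes get
    identity rows in L, i.e. zero rows in L_shifted.
    """

    n: int
    q: float
    S: sp.csr_matrix
    Theta: sp.csr_matrix
    H: sp.csr_matrix
    degrees: np.ndarray
    L: sp.csr_matrix
    L_shifted: sp.csr_matrix

    def dense(self) -> np.ndarray:
        return self.L.toarray()

    def hermitian_defect(self) -> float:
        """max |L − conj(L)ᵀ| — exact Hermitian symmetry check in O(nnz)."""
        diff = self.L - self.L.conj().T
        return float(np.abs(diff.data).max()) if diff.nnz else 0.0


def _laplacian_from_adjacency(A: sp.csr_matrix, q: float) -> HermitianOperator:
    n = A.shape[0]
    S = symmetrize(A)
    Theta = phase_matrix(A, q)
    H = hermitian_adjacency(S, Theta)
    degrees = np.asarray(S.sum(axis=1)).ravel()
    # guarded normalization: zero-degree nodes get D^{-1/2} entry 0,
    # leaving an identity row in L
    inv_sqrt = np.zeros(n)
    nz = degrees > 0
    inv_sqrt[nz] = degrees[nz] ** -0.5
    Dinv = sp.diags(inv_sqrt)
    norm_H = (Dinv @ H @ Dinv).tocsr()
    L = (sp.identity(n, format="csr", dtype=np.complex128) - norm_H).tocsr()
    L_shifted = (-norm_H).tocsr()
    return HermitianOperator(
        n=n, q=q, S=S, Theta=Theta, H=H, degrees=degrees, L=L, L_shifted=L_shifted
    )


def magnetic_laplacian(graph: GeneGraph, q: float) -> HermitianOperator:
    """Build the normalized magnetic Laplacian of a GeneGraph at phase q."""
    if graph.n_nodes == 0:
        raise ValueError("graph is empty")
    rows, cols = graph.edge_arrays()
    return laplacian_from_edges(rows, cols, graph.n_nodes, q)


def laplacian_from_edges(
    sources: np.ndarray, targets: np.ndarray, n: int, q: float
) -> HermitianOperator:
    """Operator from raw directed edge index arrays (used by edge dropout)."""
    data = np.ones(len(sources), dtype=np.float64)
    A = sp.csr_matrix((data, (sources, targets)), shape=(n, n))
    A.sum_duplicates()
    A.data[:] = 1.0  # binary adjacency regardless of duplicates
    return _laplacian_from_adjacency(A, q)


def shift_operator(L) -> sp.csr_matrix:
    """L̃ = L − I: Chebyshev rescaling 2L/λmax − I with λmax at the
    spectral bound 2; eigenvalues land in [−1, 1]."""
    L = _to_csr(L)
    return (L - sp.identity(L.shape[0], format="csr", dtype=L.dtype)).tocsr()


def cheb_filter(L_shifted, x, thetas) -> np.ndarray:
    """y = Σ_k θk · Tk(L̃) x via the three-term recurrence.

    ``x`` may be a complex N-vector or N×F matrix; ``thetas`` has length
    K+1. T0 = I, T1 = L̃, Tk = 2 L̃ T_{k−1} − T_{k−2}.
    """
    thetas = np.asarray(thetas)
    if thetas.ndim != 1 or len(thetas) < 1:
        raise ValueError("thetas must be a nonempty 1-D sequence (K >= 0)")
    L_shifted = _to_csr(L_shifted)
    x = np.asarray(x, dtype=np.complex128)
    t_prev = x
    y = thetas[0] * t_prev
    if len(thetas) == 1:
        return y
    t_curr = L_shifted @ x
    y = y + thetas[1] * t_curr
    for k in range(2, len(thetas)):
        t_next = 2.0 * (L_shifted @ t_curr) - t_prev
        y = y + thetas[k] * t_next
        t_prev, t_curr = t_curr, t_next
    return y


def save_operator(op: HermitianOperator, path, meta_path=None) -> None:
    """Serialize L as a triplet TSV (row, col, re, im); JSON sidecar holds
    (n, q) for cache validation."""
    import json

    coo = op.L.tocoo()
    with open(path, "w") as fh:
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c}\t{v.real:.17g}\t{v.imag:.17g}\n")
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            json.dump({"n": op.n, "q": op.q}, fh)


def load_operator(path, n: int) -> sp.csr_matrix:
    """Load a triplet TSV written by :func:`save_operator` back into CSR."""
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            r, c, re, im = line.split("\t")
            rows.append(int(r))
            cols.append(int(c))
            vals.append(complex(float(re), float(im)))
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
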