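"""Exact spectral graph convolution, used as a test oracle.

The graph Fourier transform diagonalizes the Laplacian, L = U diag(w) U^T,
and convolution of two vertex signals is defined in that basis as
``x * y = U(U^T x . U^T y)`` (elementwise product of spectra). Training never
uses this dense route; Chebyshev filters approximate polynomial kernels with
sparse matrix products only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..mesh_core import GraphLaplacian


@dataclass
class SpectralBasis:
    fourier_basis: np.ndarray  # (M, M), columns are eigenvectors
    eigenvalues: np.ndarray    # (M,)

    @property
    def n(self) -> int:
        return self.fourier_basis.shape[0]


def spectral_basis(laplacian: GraphLaplacian) -> SpectralBasis:
    w, u = np.linalg.eigh(laplacian.laplacian.toarray())
    return SpectralBasis(u, w)


def spectral_convolve_reference(
    x: np.ndarray, y: np.ndarray, basis: SpectralBasis, atol: float = 1e-8
) -> np.ndarray:
    """Dense evaluation of the graph convolution x * y in the Fourier basis."""
    u = basis.fourier_basis
    if not np.allclose(u.T @ u, np.eye(basis.n), atol=max(atol, 1e-6)):
        raise ValueError("Fourier basis is not orthogonal")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape[0] != basis.n or y.shape[0] != basis.n:
        raise ValueError("signal length does not match the basis")
    return u @ ((u.T @ x) * (u.T @ y))


def polynomial_filter_signal(basis: SpectralBasis, coeffs: np.ndarray) -> np.ndarray:
    """Vertex signal y such that convolving with y applies g(L) = sum c_k L^k.

    Spectrally, U^T y must equal g(eigenvalues); hence y = U g(w). Convolving
    any x with this y reproduces the polynomial-in-Laplacian filter, linking
    the Fourier-domain definition of convolution to Chebyshev-style filters.
    """
    g = np.polynomial.polynomial.polyval(basis.eigenvalues, np.asarray(coeffs, float))
    return basis.fourier_basis @ g
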