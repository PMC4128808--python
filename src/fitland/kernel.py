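"""Gaussian kernel and rectangular kernel-matrix construction.

The fitness landscape is an expansion in Gaussian bumps centered on a
small basis set of contact vectors.  Training only ever needs the
rectangular m x mbar kernel matrix between the full training pool and
the basis set, never the square m x m matrix — that is the point of the
reduced SVM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KernelParams:
    """Gaussian kernel K(x, y) = exp(-mu * ||x - y||^2)."""

    mu: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")


def gaussian_kernel(x: np.ndarray, y: np.ndarray, params: KernelParams) -> float:
    """exp(-mu * ||x - y||^2) for a single pair of vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d = x - y
    return float(np.exp(-params.mu * d.dot(d)))


def rect_kernel(
    A: np.ndarray,
    Abar: np.ndarray,
    params: KernelParams,
    block_size: int = 2048,
) -> np.ndarray:
    """Rectangular kernel matrix K(A, Abar'): entry (i, j) = K(A_i, Abar_j).

    Evaluated in row blocks of ``block_size`` so peak memory stays
    O(mbar * block_size) regardless of the pool size m.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    Abar = np.atleast_2d(np.asarray(Abar, dtype=float))
    if A.shape[1] != Abar.shape[1]:
        raise ValueError(
            f"dimension mismatch: pool {A.shape[1]} vs basis {Abar.shape[1]}"
        )
    if Abar.shape[0] == 0:
        raise ValueError("empty basis set")
    bb = np.einsum("ij,ij->i", Abar, Abar)
    out = np.empty((A.shape[0], Abar.shape[0]))
    for lo in range(0, A.shape[0], block_size):
        hi = min(lo + block_size, A.shape[0])
        block = A[lo:hi]
        sq = (
            np.einsum("ij,ij->i", block, block)[:, None]
            + bb[None, :]
            - 2.0 * block @ Abar.T
        )
        np.maximum(sq, 0.0, out=sq)  # guard tiny negative round-off
        out[lo:hi] = np.exp(-params.mu * sq)
    return out


def median_mu(
    A: np.ndarray, n_pairs: int = 1000, seed: int = 0
) -> float:
    """Median heuristic for the kernel width.

    mu = 1 / median(||x - y||^2) over ``n_pairs`` random pairs of
    distinct pool rows, so that a typical pair has kernel value 1/e.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    m = A.shape[0]
    if m < 2:
        raise ValueError("need at least 2 vectors for the median heuristic")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, m, size=n_pairs)
    j = rng.integers(0, m - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)  # distinct partner
    d = A[i] - A[j]
    med = float(np.median(np.einsum("ij,ij->i", d, d)))
    if med <= 0:
        raise ValueError("median pairwise squared distance is zero; "
                         "pool vectors are degenerate")
    return 1.0 / med
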