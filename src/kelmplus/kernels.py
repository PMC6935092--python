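"""Gram matrices and the empirical kernel map (EKM).

The EKM turns an implicit kernel into an explicit finite-dimensional
feature map. Eigendecompose the m x m training Gram matrix K = P L P^T,
keep the r eigenpairs with eigenvalues above a relative tolerance, and map
any sample x to

    Phi(x) = L^{-1/2} P^T (ker(x, x_1), ..., ker(x, x_m))^T  in R^r,

so that inner products in the empirical feature space reproduce kernel
values up to the discarded eigenvalue mass. Eigenvector signs are fixed
(largest-magnitude component non-negative) to make the map reproducible
across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.spatial.distance import pdist
from sklearn.metrics.pairwise import euclidean_distances

from .errors import DegenerateInputError, InvalidInputError


@dataclass(frozen=True)
class KernelSpec:
    """A kernel function: linear inner product or RBF exp(-gamma ||x-z||^2)."""

    kind: str = "rbf"
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise InvalidInputError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf" and self.gamma is not None and not self.gamma > 0:
            raise InvalidInputError(f"rbf gamma must be positive, got {self.gamma}")

    def with_gamma(self, gamma: float) -> "KernelSpec":
        return KernelSpec(self.kind, gamma)


def median_heuristic_gamma(X: np.ndarray) -> float:
    """gamma = 1 / (2 * median squared pairwise distance); 1.0 if degenerate."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        return 1.0
    d2 = pdist(X, "sqeuclidean")
    med = float(np.median(d2[d2 > 0])) if np.any(d2 > 0) else 0.0
    return 1.0 / (2.0 * med) if med > 0 else 1.0


def gram(X: np.ndarray, Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix with entries ker(X_i, Z_j)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise InvalidInputError(f"feature dimensions differ: {X.shape[1]} vs {Z.shape[1]}")
    if spec.kind == "linear":
        return X @ Z.T
    gamma = spec.gamma if spec.gamma is not None else median_heuristic_gamma(X)
    return np.exp(-gamma * euclidean_distances(X, Z, squared=True))


@dataclass
class EmpiricalKernelMap:
    """A fitted EKM: training samples plus the retained eigenstructure."""

    X_train: np.ndarray
    spec: KernelSpec
    eigenvalues: np.ndarray  # shape (r,), positive, non-increasing
    eigenvectors: np.ndarray  # shape (m, r), orthonormal columns
    tol: float

    @property
    def rank(self) -> int:
        return len(self.eigenvalues)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return transform_ekm(self, X)


def fit_ekm(X_train: np.ndarray, spec: KernelSpec, tol: float = 1e-10) -> EmpiricalKernelMap:
    """Eigendecompose the training Gram matrix and retain dominant eigenpairs.

    Eigenpairs with eigenvalue > tol * max-eigenvalue are kept, in
    decreasing order.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    if X_train.shape[0] < 1:
        raise InvalidInputError("need at least one training sample")
    if spec.kind == "rbf" and spec.gamma is None:
        spec = spec.with_gamma(median_heuristic_gamma(X_train))
    K = gram(X_train, X_train, spec)
    K = 0.5 * (K + K.T)
    evals, evecs = sla.eigh(K)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[0] <= 0 or not np.isfinite(evals[0]):
        raise DegenerateInputError("training Gram matrix has no positive eigenvalue")
    keep = evals > tol * evals[0]
    evals, evecs = evals[keep], evecs[:, keep]
    # sign convention: largest-magnitude component of each eigenvector >= 0
    flip = evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])] < 0
    evecs = evecs * np.where(flip, -1.0, 1.0)
    return EmpiricalKernelMap(X_train, spec, evals, evecs, tol)


def transform_ekm(ekm: EmpiricalKernelMap, X: np.ndarray) -> np.ndarray:
    """Map samples into the r-dimensional empirical feature space."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k = gram(X, ekm.X_train, ekm.spec)  # p x m
    return k @ ekm.eigenvectors / np.sqrt(ekm.eigenvalues)
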