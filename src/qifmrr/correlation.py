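"""Working-correlation basis matrices for quadratic inference functions.

The QIF trick expands the inverse working correlation matrix as a linear
combination of known basis matrices, R^{-1}(rho) ~ sum_l tau_l M_l, so the
estimating equations never need the nuisance coefficients tau_l: the GMM
objective absorbs them.  Three structures are provided:

* ``ar1``: M0 = I, M1 = ones on the two main off-diagonals, M2 = ones at
  the (1,1) and (K,K) corners.  The expansion is exact for AR(1).
* ``exchangeable``: M0 = I, M1 = ones off the diagonal.  Exact.
* ``unspecified``: M0 = I, M1 = the empirical residual second-moment matrix
  U_hat = (1/n) sum_i r_i r_i^T, a consistent estimate of var(Y).

The tau formulas are implemented only as a verification surface for the
bases (reconstruction of the numeric inverse); estimation never uses them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import numpy.typing as npt

__all__ = [
    "CorrelationBasis",
    "TauCoefficients",
    "ar1_basis",
    "exchangeable_basis",
    "unspecified_basis",
    "ar1_inverse_coeffs",
    "exchangeable_inverse_coeffs",
    "ar1_correlation",
]

StructureLabel = Literal["ar1", "exchangeable", "unspecified"]


@dataclass(frozen=True)
class CorrelationBasis:
    """An ordered list of m symmetric K x K basis matrices, M_0 first (= identity)."""

    label: str
    matrices: tuple

    def __post_init__(self):
        for M in self.matrices:
            M.setflags(write=False)

    @property
    def m(self) -> int:
        return len(self.matrices)

    @property
    def K(self) -> int:
        return self.matrices[0].shape[0]

    def stacked(self) -> npt.NDArray[np.float64]:
        return np.stack(self.matrices)


@dataclass(frozen=True)
class TauCoefficients:
    """Expansion coefficients tau_l with sum_l tau_l M_l = R^{-1}(rho)."""

    taus: tuple


def _check_K(K: int) -> None:
    if K < 2:
        raise ValueError(f"need K >= 2 visits, got K={K}")


def ar1_basis(K: int) -> CorrelationBasis:
    """Basis (I, off-diagonal band, corner matrix) whose span contains the AR(1) inverse."""
    _check_K(K)
    M0 = np.eye(K)
    M1 = np.diag(np.ones(K - 1), 1) + np.diag(np.ones(K - 1), -1)
    M2 = np.zeros((K, K))
    M2[0, 0] = M2[K - 1, K - 1] = 1.0
    return CorrelationBasis(label="ar1", matrices=(M0, M1, M2))


def exchangeable_basis(K: int) -> CorrelationBasis:
    """Basis (I, all-ones-minus-identity) whose span contains the exchangeable inverse."""
    _check_K(K)
    M0 = np.eye(K)
    M1 = np.ones((K, K)) - np.eye(K)
    return CorrelationBasis(label="exchangeable", matrices=(M0, M1))


def unspecified_basis(K: int, residuals: npt.NDArray[np.float64]) -> CorrelationBasis:
    """Data-driven basis (I, U_hat) with U_hat = (1/n) sum_i r_i r_i^T.

    ``residuals`` is the (n, K) matrix of response residuals Y_i - h_i,
    normally taken at a pilot (independence-structure) estimate and then held
    fixed.  U_hat is symmetric positive semidefinite by construction.
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim != 2 or r.shape[1] != K:
        raise ValueError(f"residuals must have shape (n, {K})")
    n = r.shape[0]
    if n < 2:
        raise ValueError("the empirical second-moment basis needs n >= 2 subjects")
    U = r.T @ r / n
    return CorrelationBasis(label="unspecified", matrices=(np.eye(K), U))


def ar1_inverse_coeffs(rho: float) -> TauCoefficients:
    """Exact tau for the AR(1) inverse: ((1+rho^2), -rho, -rho^2) / (1-rho^2)."""
    if not abs(rho) < 1:
        raise ValueError(f"AR(1) requires |rho| < 1, got rho={rho}")
    d = 1.0 - rho**2
    return TauCoefficients(taus=((1.0 + rho**2) / d, -rho / d, -(rho**2) / d))


def exchangeable_inverse_coeffs(rho: float, K: int) -> TauCoefficients:
    """Exact tau for the exchangeable inverse at dimension K.

    tau_0 = -((K-2)rho + 1)/D and tau_1 = rho/D with
    D = (K-1)rho^2 - (K-2)rho - 1.  Valid on the positive-definite range
    rho in (-1/(K-1), 1).
    """
    _check_K(K)
    if not (-1.0 / (K - 1) < rho < 1.0):
        raise ValueError(
            f"exchangeable correlation is positive definite only for "
            f"rho in (-1/{K - 1}, 1), got rho={rho}"
        )
    D = (K - 1) * rho**2 - (K - 2) * rho - 1.0
    return TauCoefficients(taus=(-((K - 2) * rho + 1.0) / D, rho / D))


def ar1_correlation(rho: float, K: int) -> npt.NDArray[np.float64]:
    """The AR(1) correlation matrix with entries rho^|j-k| (positive definite for |rho|<1)."""
    _check_K(K)
    if not abs(rho) < 1:
        raise ValueError(f"AR(1) requires |rho| < 1, got rho={rho}")
    idx = np.arange(K)
    return rho ** np.abs(idx[:, None] - idx[None, :]).astype(float)


def basis_for_structure(structure: StructureLabel, K: int,
                        residuals: npt.NDArray[np.float64] | None = None) -> CorrelationBasis:
    """Dispatch on the structure token used in configs and the CLI."""
    if structure == "ar1":
        return ar1_basis(K)
    if structure == "exchangeable":
        return exchangeable_basis(K)
    if structure == "unspecified":
        if residuals is None:
            raise ValueError("unspecified structure needs pilot residuals for U_hat")
        return unspecified_basis(K, residuals)
    raise ValueError(f"unknown correlation structure {structure!r}")
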