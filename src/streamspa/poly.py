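"""Shared polynomial bases for the deformation and defocus-field models.

Both the motion deformation model (trivariate in normalized x, y, t) and the
anisotropic defocus field (bivariate in normalized x, y) use complete
3rd-order monomial bases over coordinates normalized to [-1, 1]. The ground
truth generators use the exact same basis and coefficient ordering so that
recovery can be asserted coefficient-wise.

Coefficient order: monomial exponents sorted by total degree, then
lexicographically by (exponent_x, exponent_y[, exponent_t]).
"""

from __future__ import annotations

from itertools import product

import numpy as np


def monomial_exponents(n_vars: int, order: int = 3) -> list[tuple[int, ...]]:
    """Exponent tuples of the complete polynomial basis of given order."""
    exps = [e for e in product(range(order + 1), repeat=n_vars)
            if sum(e) <= order]
    exps.sort(key=lambda e: (sum(e), e))
    return exps


TRIVARIATE_EXPONENTS = monomial_exponents(3)   # 20 terms, (a, b, c) for x^a y^b t^c
BIVARIATE_EXPONENTS = monomial_exponents(2)    # 10 terms, (a, b) for x^a y^b


def design_matrix(coords: np.ndarray, exponents) -> np.ndarray:
    """Vandermonde-style design matrix, one column per monomial.

    coords: (n_points, n_vars) array of normalized coordinates.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    cols = [np.prod([coords[:, v] ** e for v, e in enumerate(exp)], axis=0)
            for exp in exponents]
    return np.stack(cols, axis=1)


def eval_poly(coeffs: np.ndarray, coords: np.ndarray, exponents) -> np.ndarray:
    """Evaluate the polynomial with given coefficients at coords."""
    return design_matrix(coords, exponents) @ np.asarray(coeffs, dtype=np.float64)


def normalize_coords(values, extent) -> np.ndarray:
    """Map raw coordinates in [0, extent] linearly onto [-1, 1]."""
    values = np.asarray(values, dtype=np.float64)
    if extent <= 0:
        return np.zeros_like(values)
    return 2.0 * values / extent - 1.0


def fit_least_squares(coords: np.ndarray, values: np.ndarray, exponents,
                      rcond: float = 1e-10):
    """Least-squares polynomial fit; raises on rank deficiency.

    Returns (coefficients, rms residual).
    """
    A = design_matrix(coords, exponents)
    if A.shape[0] < A.shape[1]:
        raise np.linalg.LinAlgError(
            f"underdetermined polynomial fit: {A.shape[0]} samples for "
            f"{A.shape[1]} coefficients"
        )
    coeffs, _, rank, _ = np.linalg.lstsq(A, values, rcond=rcond)
    if rank < A.shape[1]:
        deficient = [exponents[i] for i in range(rank, A.shape[1])]
        raise np.linalg.LinAlgError(
            f"rank-deficient polynomial fit (rank {rank} < {A.shape[1]}); "
            f"sample layout cannot determine all terms, e.g. {deficient[:3]}"
        )
    resid = values - A @ coeffs
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return coeffs, rms
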