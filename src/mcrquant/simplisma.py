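"""SIMPLISMA purest-variable selection for ALS initialization.

SIMPLISMA (SIMPLe-to-use Interactive Self-modeling Mixture Analysis) picks
the variables of a mixed-signal matrix that are most nearly "pure" — each
dominated by a single underlying component. The purity of variable j is

    p_j = sigma_j / (mu_j + alpha),        alpha = offset_pct/100 * max(mu)

where mu_j and sigma_j are the column mean and (population) standard
deviation. The offset alpha damps the purity of low-intensity, noise-driven
variables. After the first winner, each subsequent round multiplies the
purity by a determinant-based independence weight computed from the
correlation-around-origin (COO) matrix of length-scaled variables, so that
near-duplicates of already-selected variables are suppressed — the classical
formulation, which matters on a short 26-point wavelength grid where
neighbouring channels are almost collinear.

With ``direction="spectral"`` the variables are wavelengths (columns of the
samples x wavelengths matrix) and the returned profiles are the data columns
at the winners, i.e. concentration-like seeds for the ALS. With
``direction="concentration"`` the matrix is transposed: the purest samples
are picked and the returned profiles are their spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import SpectraMatrix

__all__ = ["SimplismaResult", "simplisma_select"]


@dataclass
class SimplismaResult:
    """Selected pure variables and the profiles they seed.

    ``selected_indices`` are wavelength indices for the spectral direction,
    sample indices for the concentration direction. ``initial_profiles``
    holds the corresponding matrix slices: columns (samples x n_components)
    in the spectral direction, rows (n_components x wavelengths) otherwise.
    """

    selected_indices: list[int]
    purity_values: list[float]
    initial_profiles: np.ndarray
    direction: str
    offset_pct: float


def _purity_and_coo(X: np.ndarray, offset_pct: float):
    n = X.shape[0]
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    alpha = offset_pct / 100.0 * mu.max()
    if mu.max() == 0 and alpha == 0:
        alpha = np.finfo(float).tiny
    purity = sigma / (mu + alpha)
    # length scaling for the correlation-around-origin matrix; the offset
    # enters the length so weak variables also get damped determinants
    lam = np.sqrt(mu**2 + (sigma + alpha) ** 2)
    lam[lam == 0] = np.finfo(float).tiny
    Z = X / (np.sqrt(n) * lam)
    coo = Z.T @ Z
    return purity, coo


def simplisma_select(
    D: SpectraMatrix | np.ndarray,
    n_components: int,
    offset_pct: float = 1.0,
    direction: str = "spectral",
) -> SimplismaResult:
    """Select the ``n_components`` purest variables of D.

    Raises if D is degenerate (all variables constant); warns when
    ``n_components`` exceeds the matrix rank, in which case selection still
    proceeds but later picks carry near-zero determinant weights.
    """
    X = D.absorbance if isinstance(D, SpectraMatrix) else np.asarray(D, dtype=float)
    if direction not in ("spectral", "concentration"):
        raise ValueError(f"direction must be 'spectral' or 'concentration', got {direction!r}")
    if direction == "concentration":
        X = X.T
    n_rows, n_vars = X.shape
    if not 1 <= n_components <= min(n_rows, n_vars):
        raise ValueError(
            f"n_components={n_components} outside 1..min{X.shape}"
        )
    if offset_pct < 0:
        raise ValueError("offset_pct must be >= 0")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate matrix: every variable is constant")
    if n_components > np.linalg.matrix_rank(X):
        warnings.warn(
            f"n_components={n_components} exceeds matrix rank "
            f"{np.linalg.matrix_rank(X)}; selection proceeds",
            stacklevel=2,
        )

    purity, coo = _purity_and_coo(X, offset_pct)
    selected: list[int] = []
    scores: list[float] = []
    for round_ in range(n_components):
        best_j, best_p = -1, -np.inf
        for j in range(n_vars):
            if j in selected:
                continue
            if round_ == 0:
                # the first selection maximizes the raw purity
                p = purity[j]
            else:
                idx = [j] + selected
                w = np.linalg.det(coo[np.ix_(idx, idx)])
                p = w * purity[j]
            if p > best_p:
                best_j, best_p = j, p
        selected.append(best_j)
        scores.append(float(best_p))

    if direction == "spectral":
        profiles = X[:, selected].copy()
    else:
        profiles = X[:, selected].T.copy()  # X is D.T here; rows of original D
    return SimplismaResult(selected, scores, profiles, direction, offset_pct)
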