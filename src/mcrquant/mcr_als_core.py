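"""Constrained alternating least squares for D = C S^T + E.

The engine decomposes a samples x wavelengths absorbance matrix into
concentration profiles C and pure-ish spectral profiles S under two
constraints:

* **nonnegativity** — each least-squares sub-problem is solved as a true
  nonnegative least-squares problem (active-set NNLS), not by clipping an
  unconstrained solution, which would break optimality and can cycle;
* **correlation** — for each quantified component, the resolved
  concentration values of the calibration samples are regressed against
  their known reference concentrations each iteration, and the whole column
  (calibration and unknown rows alike) is mapped through the fitted line.
  This puts the column in real concentration units every sweep and is what
  turns curve resolution into a calibration model that tolerates unmodelled
  interferents.

The intensity ambiguity of the bilinear model is fixed by normalizing each
spectral profile to unit Euclidean length at the end of every sweep; the
concentration scale is then owned entirely by the correlation constraint.

Convergence is tracked through the percentage lack of fit
LOF% = 100 * sqrt(sum(E^2) / sum(D^2)); iteration stops when the relative
change of LOF between sweeps falls below ``tol_pct`` percent (default 0.1)
or the iteration cap (default 50) is hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .datatypes import ConcentrationTable, SpectraMatrix
from .simplisma import SimplismaResult

__all__ = [
    "ALSConfig",
    "MCRResult",
    "lack_of_fit",
    "nonneg_ls_solve",
    "apply_correlation_constraint",
    "run_mcr_als",
]


@dataclass(frozen=True)
class ALSConfig:
    """ALS settings.

    ``correlation_components`` restricts the correlation constraint to a
    subset of components (by index); ``None`` means every component that can
    be matched to an analyte carries it.
    """

    n_components: int = 5
    tol_pct: float = 0.1
    max_iter: int = 50
    nonneg_C: bool = True
    nonneg_S: bool = True
    correlation_components: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.tol_pct <= 0:
            raise ValueError("tol_pct must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class MCRResult:
    """Converged decomposition plus bookkeeping.

    ``C_resolved`` columns matched to an analyte are in ug/mL (the
    correlation constraint re-anchors them each sweep); unmatched columns
    keep the arbitrary scale implied by unit-length spectral profiles.
    ``component_of_analyte`` maps analyte name -> component index (or None
    when there are fewer components than analytes); ``regressions`` maps
    analyte name -> (slope, intercept) of the final constraint regression.

    ``C_predicted`` holds, for each correlation-constrained component, the
    resolved values mapped through the final regression line *without*
    resetting calibration rows onto their references — i.e. what the model
    actually predicts for every sample, calibration rows included. This is
    the matrix that calibration figures of merit are computed from;
    ``C_resolved`` is the constrained matrix that the decomposition itself
    iterates on. Unconstrained components are NaN in ``C_predicted``.
    """

    C_resolved: np.ndarray
    S_resolved: np.ndarray
    E: np.ndarray
    lof_trace: list[float]
    n_iter: int
    converged: bool
    regressions: dict[str, tuple[float, float]]
    component_of_analyte: dict[str, int | None]
    C_predicted: np.ndarray = field(default=None)  # type: ignore[assignment]
    lof_initial: float = field(default=np.nan)

    @property
    def lof_final(self) -> float:
        return self.lof_trace[-1]


def lack_of_fit(D: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    """Percentage lack of fit, 100 * sqrt(sum(D - C S)^2 / sum D^2)).

    ``S`` is components x wavelengths (the S^T of the bilinear model).
    """
    D = np.asarray(D, dtype=float)
    ss_D = np.sum(D**2)
    if ss_D == 0:
        raise ValueError("all-zero data matrix: lack of fit undefined")
    E = D - np.asarray(C) @ np.asarray(S)
    return 100.0 * np.sqrt(np.sum(E**2) / ss_D)


def nonneg_ls_solve(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A X - B|| with X >= 0, column by column (active-set NNLS).

    Warns on rank-deficient A; each column is then still the NNLS solution
    scipy returns (a minimum-residual feasible point).
    """
    A = np.asarray(A, dtype=float)
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if B.shape[0] != A.shape[0]:
        raise ValueError(f"A has {A.shape[0]} rows but B has {B.shape[0]}")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("rank-deficient design matrix in NNLS", stacklevel=2)
    X = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        X[:, j], _ = nnls(A, B[:, j])
    return X


def apply_correlation_constraint(
    C_col: np.ndarray,
    known: np.ndarray,
    calib_mask: np.ndarray,
    nonneg: bool = True,
) -> tuple[np.ndarray, float, float]:
    """Re-express a resolved concentration column in reference units.

    An ordinary least-squares line is fitted between the resolved values and
    the known reference concentrations over the calibration rows
    (resolved = m * known + n). The whole column is then converted to
    concentration units through the inverted line, c = (resolved - n) / m,
    and the calibration rows are reset onto their reference values — the
    step that actually injects the reference pattern into the decomposition
    each sweep. Without that injection the constraint would merely rescale
    the column: every row would keep the *resolved* (possibly still mixed)
    pattern, the bilinear rotational ambiguity would survive intact, and the
    model could converge to an excellent spectral fit that predicts nothing.

    Returns the updated column plus the slope and intercept of the
    resolved-to-concentration mapping (b1 = 1/m, b0 = -n/m). Negative
    converted values are floored at zero when ``nonneg`` is set.
    """
    C_col = np.asarray(C_col, dtype=float)
    calib_mask = np.asarray(calib_mask, dtype=bool)
    x = C_col[calib_mask]
    y = np.asarray(known, dtype=float)[calib_mask]
    if len(x) < 2 or len(np.unique(y)) < 2:
        raise ValueError("need >= 2 calibration rows with distinct known values")
    if np.var(x) == 0:
        raise ValueError("degenerate correlation constraint: zero variance in resolved values")
    m = np.cov(y, x, bias=True)[0, 1] / np.var(y)
    if m == 0:
        raise ValueError("degenerate correlation constraint: resolved values uncorrelated with references")
    n_off = x.mean() - m * y.mean()
    b1 = 1.0 / m
    b0 = -n_off / m
    updated = b0 + b1 * C_col
    updated[calib_mask] = y
    if nonneg:
        updated = np.maximum(updated, 0.0)
    return updated, float(b1), float(b0)


def _solve_C(D: np.ndarray, S: np.ndarray, nonneg: bool) -> np.ndarray:
    # D (n x m), S (k x m); rows of C solve S^T c = d
    if nonneg:
        return nonneg_ls_solve(S.T, D.T).T
    return np.linalg.lstsq(S.T, D.T, rcond=None)[0].T


def _solve_S(D: np.ndarray, C: np.ndarray, nonneg: bool) -> np.ndarray:
    if nonneg:
        return nonneg_ls_solve(C, D)
    return np.linalg.lstsq(C, D, rcond=None)[0]


def _match_components(
    C: np.ndarray, known: ConcentrationTable, constrainable: list[int]
) -> dict[str, int | None]:
    """Match components to analytes by correlation over calibration rows.

    A one-to-one assignment (Hungarian algorithm on the negated correlation
    matrix) so that each analyte's reference column tracks a distinct
    resolved component. With fewer components than analytes, the analytes
    that fit worst remain unmatched.
    """
    mask = known.calibration_mask
    analytes = known.analyte_names
    corr = np.zeros((len(constrainable), len(analytes)))
    for ci, comp in enumerate(constrainable):
        x = C[mask, comp]
        for ai in range(len(analytes)):
            y = known.values[mask, ai]
            sx, sy = np.std(x), np.std(y)
            if sx == 0 or sy == 0:
                corr[ci, ai] = 0.0
            else:
                corr[ci, ai] = np.corrcoef(x, y)[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    mapping: dict[str, int | None] = {a: None for a in analytes}
    for r, c in zip(rows, cols):
        mapping[analytes[c]] = constrainable[r]
    return mapping


def run_mcr_als(
    D: SpectraMatrix | np.ndarray,
    known: ConcentrationTable,
    init: SimplismaResult | np.ndarray,
    cfg: ALSConfig = ALSConfig(),
) -> MCRResult:
    """Alternating least squares under nonnegativity + correlation constraints.

    ``init`` seeds the decomposition: a components x wavelengths array (or a
    spectral-profile SIMPLISMA result from the concentration direction) is
    used as initial S; a samples x components array (wavelength-direction
    SIMPLISMA profiles) is used as initial C, from which an initial S is
    solved before the first sweep.

    Each sweep: (a) solve C from D and S, (b) apply the correlation
    constraint per matched component, (c) solve S from D and C,
    (d) renormalize S rows entering the next sweep, (e) evaluate LOF and
    test |LOF_prev - LOF| / LOF_prev * 100 < tol_pct. The reported iteration
    count includes the sweep that triggers convergence.
    """
    X = D.absorbance if isinstance(D, SpectraMatrix) else np.asarray(D, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in data matrix")
    n, m = X.shape
    k = cfg.n_components
    if k > min(n, m):
        raise ValueError(f"n_components={k} exceeds min dimension {min(n, m)}")
    if known.n_samples != n:
        raise ValueError(
            f"concentration table has {known.n_samples} rows, data has {n}"
        )
    if not np.any(known.calibration_mask):
        raise ValueError("no calibration rows flagged in concentration table")

    profiles = init.initial_profiles if isinstance(init, SimplismaResult) else np.asarray(init, dtype=float)
    if profiles.ndim == 1:
        profiles = profiles[None, :]
    if profiles.shape == (k, m):
        S = profiles.astype(float).copy()
    elif profiles.shape == (n, k):
        # classical pure-variable seeding: derive the spectral estimates from
        # the concentration-like seed by plain least squares; the constrained
        # solves inside the loop take over from the first sweep
        S = np.linalg.lstsq(profiles.astype(float), X, rcond=None)[0]
    else:
        raise ValueError(
            f"init profiles shape {profiles.shape} matches neither "
            f"(n_components, n_wavelengths)=({k}, {m}) nor "
            f"(n_samples, n_components)=({n}, {k})"
        )
    S = _normalize_rows(S)

    constrainable = (
        sorted(cfg.correlation_components)
        if cfg.correlation_components is not None
        else list(range(k))
    )

    C0 = _solve_C(X, S, cfg.nonneg_C)
    lof_initial = lack_of_fit(X, C0, S)

    mapping: dict[str, int | None] = {}
    regressions: dict[str, tuple[float, float]] = {}
    lof_trace: list[float] = []
    lof_prev = lof_initial
    converged = False
    C = C0
    calib_mask = known.calibration_mask

    S_raw = S
    for _ in range(cfg.max_iter):
        C = _solve_C(X, S, cfg.nonneg_C)
        if not mapping:
            # component-analyte correspondence fixed at the first sweep
            mapping = _match_components(C, known, constrainable)
        for analyte, comp in mapping.items():
            if comp is None:
                continue
            col, b1, b0 = apply_correlation_constraint(
                C[:, comp], known.values[:, known.analyte_names.index(analyte)],
                calib_mask, nonneg=cfg.nonneg_C,
            )
            C[:, comp] = col
            regressions[analyte] = (b1, b0)
        S_raw = _solve_S(X, C, cfg.nonneg_S)
        lof = lack_of_fit(X, C, S_raw)
        lof_trace.append(lof)
        # absolute floor guards the relative test against round-off churn
        # once the residual is at machine zero
        if lof < 1e-10 or (
            lof_prev > 0 and abs(lof_prev - lof) / lof_prev * 100.0 < cfg.tol_pct
        ):
            converged = True
        lof_prev = lof
        if converged:
            break
        # unit-length spectral rows entering the next sweep fix the intensity
        # ambiguity; C is fully re-solved from D and S at (a), which is where
        # the scale gets folded back in
        S = _normalize_rows(S_raw)

    if not converged:
        warnings.warn(
            f"ALS hit the iteration cap ({cfg.max_iter}) without meeting the "
            f"{cfg.tol_pct}% convergence criterion",
            stacklevel=2,
        )
    # prediction read-out: resolve concentrations once more against the
    # converged spectra and map them through the final calibration lines
    # WITHOUT pinning calibration rows, so calibration predictions show
    # genuine model error
    C_pred = np.full((n, k), np.nan)
    C_read = _solve_C(X, S_raw, cfg.nonneg_C)
    for analyte, comp in mapping.items():
        if comp is None:
            continue
        _, b1, b0 = apply_correlation_constraint(
            C_read[:, comp], known.values[:, known.analyte_names.index(analyte)],
            calib_mask, nonneg=cfg.nonneg_C,
        )
        pred = b0 + b1 * C_read[:, comp]
        C_pred[:, comp] = np.maximum(pred, 0.0) if cfg.nonneg_C else pred
        regressions[analyte] = (b1, b0)

    E = X - C @ S_raw
    return MCRResult(
        C_resolved=C,
        S_resolved=S_raw,
        E=E,
        lof_trace=lof_trace,
        n_iter=len(lof_trace),
        converged=converged,
        regressions=regressions,
        component_of_analyte=mapping,
        C_predicted=C_pred,
        lof_initial=lof_initial,
    )


def _normalize_rows(S: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(S, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return S / norms
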