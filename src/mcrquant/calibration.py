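"""Calibration workflow: rank selection by LOO-CV and unknown prediction.

The calibration model is the constrained ALS decomposition of the
calibration spectra, seeded by SIMPLISMA. Predicting unknowns re-runs the
decomposition on the calibration matrix augmented with the unknown rows
(the correlation constraint converts the resolved values of every row,
calibration and unknown alike, to concentration units at convergence)
rather than projecting onto a frozen spectral matrix; the augmented run is
warm-started from the fitted model's resolved spectra.

The number of components is chosen by leave-one-out cross-validation: the
smallest count for which adding one more component no longer improves the
mean RMSECV by at least ``improvement_threshold`` (default 5% relative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    ROLE_UNKNOWN,
    ConcentrationTable,
    SpectraMatrix,
)
from .mcr_als_core import ALSConfig, MCRResult, run_mcr_als
from .simplisma import SimplismaResult, simplisma_select

__all__ = [
    "CVReport",
    "CalibrationModel",
    "fit_calibration",
    "analyte_predictions",
    "rmsecv_loo",
    "select_ncomp",
]


@dataclass
class CVReport:
    """Leave-one-out cross-validation summary across candidate ranks."""

    candidate_ncomp: list[int]
    rmsecv_per_analyte: np.ndarray  # candidates x analytes, ug/mL
    mean_rmsecv: np.ndarray
    chosen_ncomp: int
    rule_trace: list[dict] = field(default_factory=list)


def analyte_predictions(result: MCRResult, known: ConcentrationTable) -> np.ndarray:
    """Per-analyte concentration predictions for every row of a fit.

    Analytes matched to a component read that component's regression-mapped
    column (``C_predicted``, in ug/mL): the resolved values passed through
    the final correlation-constraint line, so calibration rows show genuine
    prediction error rather than the reference values they were constrained
    to. When the decomposition has fewer components than analytes, each
    unmatched analyte falls back to an ordinary regression of its known
    calibration values on the single best-correlated resolved component — a
    deliberately crude stand-in whose large cross-validation error is
    exactly how underfitting is detected.
    """
    n = result.C_resolved.shape[0]
    preds = np.full((n, len(known.analyte_names)), np.nan)
    mask = known.calibration_mask
    for ai, analyte in enumerate(known.analyte_names):
        comp = result.component_of_analyte.get(analyte)
        if comp is not None:
            preds[:, ai] = result.C_predicted[:, comp]
            continue
        y = known.values[mask, ai]
        best, best_r = None, -np.inf
        for c in range(result.C_resolved.shape[1]):
            x = result.C_resolved[mask, c]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = abs(np.corrcoef(x, y)[0, 1])
            if r > best_r:
                best, best_r = c, r
        if best is None:
            preds[:, ai] = np.mean(y)
            continue
        x = result.C_resolved[mask, best]
        b1 = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        b0 = y.mean() - b1 * x.mean()
        preds[:, ai] = np.maximum(b0 + b1 * result.C_resolved[:, best], 0.0)
    return preds


@dataclass
class CalibrationModel:
    """A fitted MCR-ALS calibration ready to predict unknown spectra."""

    D_cal: SpectraMatrix
    C_known: ConcentrationTable
    cfg: ALSConfig
    init: SimplismaResult
    result: MCRResult

    @property
    def calibration_predictions(self) -> np.ndarray:
        return analyte_predictions(self.result, self.C_known)

    def predict(self, D_unknown: SpectraMatrix) -> ConcentrationTable:
        """Predict analyte concentrations for unknown spectra (ug/mL).

        The unknown rows are appended to the calibration matrix as
        unconstrained-concentration rows and the ALS re-run with the frozen
        configuration, seeded with the fitted model's resolved spectral
        profiles (it is the developed calibration model that predicts, not a
        fresh decomposition); only the unknown rows are returned.
        """
        if D_unknown.n_samples == 0:
            return ConcentrationTable([], list(self.C_known.analyte_names),
                                      np.empty((0, len(self.C_known.analyte_names))), [])
        if D_unknown.grid != self.D_cal.grid:
            mine = self.D_cal.grid
            theirs = D_unknown.grid
            raise ValueError(
                f"wavelength grid mismatch: model fitted on "
                f"{mine.start_nm}-{mine.end_nm}/{mine.step_nm} nm, unknowns on "
                f"{theirs.start_nm}-{theirs.end_nm}/{theirs.step_nm} nm"
            )
        n_cal = self.D_cal.n_samples
        X_aug = np.vstack([self.D_cal.absorbance, D_unknown.absorbance])
        ids = list(self.D_cal.sample_ids) + [f"u:{s}" for s in D_unknown.sample_ids]
        D_aug = SpectraMatrix(ids, self.D_cal.grid, X_aug)
        values = np.vstack([
            self.C_known.values,
            np.full((D_unknown.n_samples, len(self.C_known.analyte_names)), np.nan),
        ])
        known_aug = ConcentrationTable(
            ids, list(self.C_known.analyte_names), values,
            list(self.C_known.roles) + [ROLE_UNKNOWN] * D_unknown.n_samples,
        )
        res = run_mcr_als(D_aug, known_aug, self.result.S_resolved, self.cfg)
        preds = analyte_predictions(res, known_aug)[n_cal:]
        return ConcentrationTable(
            list(D_unknown.sample_ids), list(self.C_known.analyte_names),
            preds, [ROLE_UNKNOWN] * D_unknown.n_samples,
        )


def fit_calibration(
    D_cal: SpectraMatrix,
    C_known: ConcentrationTable,
    cfg: ALSConfig = ALSConfig(),
    offset_pct: float = 1.0,
    direction: str = "spectral",
) -> CalibrationModel:
    """SIMPLISMA-seed and fit the constrained ALS on the calibration set."""
    init = simplisma_select(D_cal, cfg.n_components, offset_pct, direction)
    result = run_mcr_als(D_cal, C_known, init, cfg)
    return CalibrationModel(D_cal, C_known, cfg, init, result)


def rmsecv_loo(
    D_cal: SpectraMatrix,
    C_known: ConcentrationTable,
    ncomp: int,
    cfg: ALSConfig = ALSConfig(),
    offset_pct: float = 1.0,
    direction: str = "spectral",
    _trace: list | None = None,
) -> np.ndarray:
    """Per-analyte leave-one-out RMSECV (ug/mL).

    Each calibration sample is held out in turn: the model is refitted on
    the remaining rows and the held-out spectrum predicted as an unknown.
    Non-convergent folds are excluded with a warning and recorded in
    ``_trace`` when given.
    """
    n = D_cal.n_samples
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 calibration samples")
    cfg = ALSConfig(ncomp, cfg.tol_pct, cfg.max_iter, cfg.nonneg_C, cfg.nonneg_S,
                    cfg.correlation_components)
    sq_err = np.zeros(len(C_known.analyte_names))
    used = 0
    for i in range(n):
        keep = np.arange(n) != i
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_calibration(
                D_cal.subset(keep), C_known.subset(keep), cfg, offset_pct, direction
            )
            pred = model.predict(D_cal.subset(~keep))
        if not model.result.converged:
            warnings.warn(f"LOO fold {i}: fit did not converge; fold excluded",
                          stacklevel=2)
            if _trace is not None:
                _trace.append({"fold": i, "converged": False})
            continue
        sq_err += (C_known.values[i] - pred.values[0]) ** 2
        used += 1
    if used == 0:
        raise RuntimeError("no LOO fold converged")
    return np.sqrt(sq_err / used)


def select_ncomp(
    D_cal: SpectraMatrix,
    C_known: ConcentrationTable,
    max_ncomp: int,
    cfg: ALSConfig = ALSConfig(),
    improvement_threshold: float = 0.05,
    offset_pct: float = 1.0,
    direction: str = "spectral",
) -> CVReport:
    """Choose the number of components from LOO-CV error curves.

    The optimum is the smallest rank whose mean RMSECV is not significantly
    worse than the best achievable — operationalized as lying within
    ``improvement_threshold`` (relative, default 5%) of the minimum mean
    RMSECV over the candidates. Anchoring the comparison at the curve's
    minimum rather than at the next candidate makes the rule robust to
    non-monotone error values among badly underfitted ranks, where two
    successive hopeless models can look equally bad.
    """
    if max_ncomp < 2:
        raise ValueError("max_ncomp must be >= 2")
    candidates = list(range(1, max_ncomp + 1))
    per_analyte = np.empty((len(candidates), len(C_known.analyte_names)))
    for idx, k in enumerate(candidates):
        per_analyte[idx] = rmsecv_loo(D_cal, C_known, k, cfg, offset_pct, direction)
    means = per_analyte.mean(axis=1)

    floor = float(means.min())
    band = (1.0 + improvement_threshold) * floor
    trace: list[dict] = []
    chosen = None
    for idx, k in enumerate(candidates):
        within = means[idx] <= band
        trace.append({
            "ncomp": k,
            "rmsecv": float(means[idx]),
            "band": band,
            "within_band_of_minimum": bool(within),
        })
        if within and chosen is None:
            chosen = k
    if chosen == candidates[-1] and len(candidates) > 1 and \
            means[-1] < (1.0 - improvement_threshold) * means[-2]:
        warnings.warn(
            "mean RMSECV was still improving at the largest candidate rank; "
            "consider raising max_ncomp",
            stacklevel=2,
        )
    return CVReport(candidates, per_analyte, means, chosen, trace)
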