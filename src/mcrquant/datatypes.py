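"""Core in-memory containers shared across the package.

``SpectraMatrix`` holds the mixed-signal matrix D (samples x wavelengths,
absorbance units), ``ConcentrationTable`` the matching concentration matrix C
(samples x analytes, ug/mL) with per-row roles, and ``WavelengthGrid`` the
equally spaced wavelength axis both are defined on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraMatrix",
    "ConcentrationTable",
    "ROLE_CALIBRATION",
    "ROLE_VALIDATION",
    "ROLE_UNKNOWN",
]

ROLE_CALIBRATION = "calibration"
ROLE_VALIDATION = "validation"
ROLE_UNKNOWN = "unknown"
_ROLES = (ROLE_CALIBRATION, ROLE_VALIDATION, ROLE_UNKNOWN)


@dataclass(frozen=True)
class WavelengthGrid:
    """Equally spaced wavelength axis in nanometres.

    The default grid spans 220-240 nm at 0.8 nm spacing (26 points), the
    window where the five target drugs absorb strongly enough to quantify
    while remaining free of short-wavelength solvent noise.
    """

    start_nm: float = 220.0
    end_nm: float = 240.0
    step_nm: float = 0.8

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.end_nm <= self.start_nm:
            raise ValueError("end_nm must exceed start_nm")
        n_steps = (self.end_nm - self.start_nm) / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                f"grid span {self.start_nm}-{self.end_nm} nm is not an integer "
                f"multiple of step {self.step_nm} nm"
            )

    @property
    def points(self) -> np.ndarray:
        n = int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @classmethod
    def from_points(cls, points: np.ndarray) -> "WavelengthGrid":
        points = np.asarray(points, dtype=float)
        if points.ndim != 1 or len(points) < 2:
            raise ValueError("need at least two wavelength points")
        steps = np.diff(points)
        if np.any(steps <= 0):
            raise ValueError("non-monotone wavelengths")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ValueError("wavelengths are not equally spaced")
        return cls(float(points[0]), float(points[-1]), float(round(steps[0], 9)))


@dataclass
class SpectraMatrix:
    """Absorbance spectra: rows are samples, columns are grid wavelengths."""

    sample_ids: list[str]
    grid: WavelengthGrid
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, m = self.absorbance.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if m != len(self.grid):
            raise ValueError(
                f"{m} absorbance columns but grid has {len(self.grid)} points"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.absorbance, columns=[repr(float(w)) for w in self.grid.points]
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def subset(self, rows: np.ndarray) -> "SpectraMatrix":
        rows = np.asarray(rows)
        ids = [self.sample_ids[i] for i in np.arange(self.n_samples)[rows]] \
            if rows.dtype == bool else [self.sample_ids[i] for i in rows]
        return SpectraMatrix(ids, self.grid, self.absorbance[rows])


@dataclass
class ConcentrationTable:
    """Known or predicted analyte concentrations in ug/mL.

    Unknown cells carry NaN, never zero; ``roles`` flags each row as
    calibration, validation, or unknown.
    """

    sample_ids: list[str]
    analyte_names: list[str]
    values: np.ndarray
    roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, a = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.analyte_names) != a:
            raise ValueError(f"{len(self.analyte_names)} analyte names for {a} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        known = ~np.isnan(self.values)
        if np.any(self.values[known] < 0):
            raise ValueError("negative concentration")
        if not self.roles:
            self.roles = [
                ROLE_CALIBRATION if np.all(known[i]) else ROLE_UNKNOWN
                for i in range(n)
            ]
        if len(self.roles) != n:
            raise ValueError("one role per row required")
        for r in self.roles:
            if r not in _ROLES:
                raise ValueError(f"unknown role {r!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def calibration_mask(self) -> np.ndarray:
        return np.array([r == ROLE_CALIBRATION for r in self.roles])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.analyte_names)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def subset(self, rows: np.ndarray) -> "ConcentrationTable":
        rows = np.asarray(rows)
        idx = np.arange(self.n_samples)[rows] if rows.dtype == bool else rows
        return ConcentrationTable(
            [self.sample_ids[i] for i in idx],
            list(self.analyte_names),
            self.values[idx],
            [self.roles[i] for i in idx],
        )
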