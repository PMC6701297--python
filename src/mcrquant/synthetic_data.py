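"""Synthetic UV mixture spectra for the five-drug quantification problem.

Real instrument spectra for the paracetamol / aspirin / caffeine / naproxen /
ibuprofen system are not publicly deposited, so every downstream stage is
exercised on synthetic data built from three ingredients:

* five Gaussian-band pure spectra on the 220-240 nm grid, frozen so that the
  profiles are severely overlapped (all pairwise Pearson correlations >= 0.5)
  yet jointly identifiable (full rank 5, condition number well under 1000),
  with naproxen and ibuprofen the weakest absorbers;
* the published 25-mixture five-factor five-level calibration design and the
  15-mixture external validation design, embedded verbatim;
* Beer-Lambert additive mixing D = C S^T plus Gaussian noise with an additive
  floor and a proportional term, mimicking a quiet double-beam instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ConcentrationTable, SpectraMatrix, WavelengthGrid

__all__ = [
    "WavelengthGrid",
    "GaussianBandSpec",
    "DesignTable",
    "NoiseModel",
    "ANALYTES",
    "CALIBRATION_RANGES",
    "PURE_BAND_CONSTANTS",
    "make_pure_spectrum",
    "default_pure_spectra",
    "calibration_design",
    "validation_design",
    "simulate_mixtures",
]

ANALYTES = ("PAR", "ASA", "CAF", "NPX", "IPF")

#: published linearity range (ug/mL) per analyte
CALIBRATION_RANGES = {
    "PAR": (0.5, 7.0),
    "ASA": (1.0, 15.0),
    "CAF": (0.5, 3.0),
    "NPX": (0.5, 3.5),
    "IPF": (1.0, 15.0),
}


@dataclass(frozen=True)
class GaussianBandSpec:
    """One Gaussian absorption band: centre (nm), sigma (nm), peak height
    (AU mL ug^-1)."""

    center_nm: float
    width_nm: float
    height: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Additive + proportional Gaussian absorbance noise.

    Each absorbance value receives one draw from
    ``Normal(0, additive_sd^2 + (proportional_sd * signal)^2)``.
    The defaults emulate a quiet double-beam UV instrument: 0.0005 AU
    baseline noise plus 0.2% photometric proportional noise.
    """

    additive_sd: float = 0.0005
    proportional_sd: float = 0.002
    seed: int = 1

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.proportional_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class DesignTable:
    """Mixture design: ordered analytes and a rows x analytes concentration
    matrix in ug/mL."""

    analyte_names: tuple[str, ...]
    rows: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=float))
        if self.rows.ndim != 2 or self.rows.shape[1] != len(self.analyte_names):
            raise ValueError("rows must be a matrix with one column per analyte")

    @property
    def n_mixtures(self) -> int:
        return self.rows.shape[0]

    def to_table(self, role: str, prefix: str = "mix") -> ConcentrationTable:
        ids = [f"{prefix}{i + 1}" for i in range(self.n_mixtures)]
        return ConcentrationTable(
            ids, list(self.analyte_names), self.rows.copy(),
            [role] * self.n_mixtures,
        )


# Frozen band constants (centre nm, sigma nm, peak height AU mL/ug) behind
# default_pure_spectra. Every analyte shares a curved envelope band at
# 229.5 nm — which is what keeps all pairwise Pearson correlations >= 0.5
# (severe overlap) — plus one narrower analyte-specific band at a staggered
# centre, which keeps the 5x26 matrix well conditioned (condition number
# ~21, far under the 1000 ceiling) so the mixture problem is hard but
# identifiable under realistic instrument noise. NPX and IPF carry the
# smallest mean absorptivities: they are the poor absorbers in this window.
PURE_BAND_CONSTANTS: dict[str, tuple[GaussianBandSpec, ...]] = {
    "PAR": (
        GaussianBandSpec(229.5, 4.1, 0.036),
        GaussianBandSpec(238.0, 2.7, 0.012),
    ),
    "ASA": (
        GaussianBandSpec(229.5, 4.1, 0.029),
        GaussianBandSpec(223.8, 1.9, 0.014),
    ),
    "CAF": (
        GaussianBandSpec(229.5, 4.1, 0.025),
        GaussianBandSpec(231.8, 1.8, 0.060),
    ),
    "NPX": (
        GaussianBandSpec(229.5, 4.1, 0.005),
        GaussianBandSpec(229.0, 1.8, 0.060),
    ),
    "IPF": (
        GaussianBandSpec(229.5, 4.1, 0.020),
        GaussianBandSpec(221.5, 2.2, 0.012),
    ),
}


def make_pure_spectrum(
    bands: list[GaussianBandSpec] | tuple[GaussianBandSpec, ...],
    grid: WavelengthGrid,
) -> np.ndarray:
    """Sum of Gaussian bands evaluated on the grid (always >= 0)."""
    if len(bands) == 0:
        raise ValueError("at least one band is required")
    lam = grid.points
    s = np.zeros(len(lam))
    for b in bands:
        s += b.height * np.exp(-((lam - b.center_nm) ** 2) / (2.0 * b.width_nm**2))
    return s


def default_pure_spectra(grid: WavelengthGrid | None = None) -> np.ndarray:
    """The five frozen pure spectra as an analytes x wavelengths matrix.

    Row order follows :data:`ANALYTES`.
    """
    grid = grid or WavelengthGrid()
    return np.array(
        [make_pure_spectrum(PURE_BAND_CONSTANTS[a], grid) for a in ANALYTES]
    )


# 25-mixture five-factor five-level calibration design, embedded verbatim.
# Mixture 8 PAR reads 3.5 in the published table even though the five-level
# scheme for PAR elsewhere uses 0.5/2.1/3.8/5.4/7.0; the printed value is
# kept as-is.
_CALIBRATION_DESIGN = np.array([
    # PAR   ASA   CAF   NPX   IPF
    [3.8,  8.0,  1.8,  2.0,  8.0],
    [3.8,  1.0,  0.5,  3.5,  4.5],
    [0.5,  1.0,  3.0,  1.3, 15.0],
    [0.5, 15.0,  1.1,  3.5,  8.0],
    [7.0,  4.5,  3.0,  2.0,  4.5],
    [2.1, 15.0,  1.8,  1.3,  4.5],
    [7.0,  8.0,  1.1,  1.3, 11.5],
    [3.5,  4.5,  1.1,  2.8, 15.0],
    [2.1,  4.5,  2.4,  3.5, 11.5],
    [2.1, 11.5,  3.0,  2.8,  8.0],
    [5.4, 15.0,  2.4,  2.0, 15.0],
    [7.0, 11.5,  1.8,  3.5, 15.0],
    [5.4,  8.0,  3.0,  3.5,  1.0],
    [3.8, 15.0,  3.0,  0.5, 11.5],
    [7.0, 15.0,  0.5,  2.8,  1.0],
    [7.0,  1.0,  2.4,  0.5,  8.0],
    [0.5, 11.5,  0.5,  2.0, 11.5],
    [5.4,  1.0,  1.8,  2.8, 11.5],
    [0.5,  8.0,  2.4,  2.8,  4.5],
    [3.8, 11.5,  2.4,  1.3,  1.0],
    [5.4, 11.5,  1.1,  0.5,  4.5],
    [5.4,  4.5,  0.5,  1.3,  8.0],
    [2.1,  1.0,  1.1,  2.0,  1.0],
    [0.5,  4.5,  1.8,  0.5,  1.0],
    [2.1,  8.0,  0.5,  0.5, 15.0],
])

# 15-mixture external validation design, embedded verbatim.
_VALIDATION_DESIGN = np.array([
    # PAR   ASA   CAF   NPX   IPF
    [3.5,  0.5,  2.0,  2.0,  8.5],
    [3.5,  2.0,  1.0,  2.0,  5.0],
    [1.0,  2.0,  3.0,  1.5, 15.0],
    [1.0, 15.0,  1.5,  3.0,  8.5],
    [6.0,  5.0,  3.0,  2.0,  5.0],
    [2.0, 15.0,  2.0,  1.5,  5.0],
    [6.0,  8.5,  1.5,  1.5, 12.0],
    [3.5,  5.0,  1.5,  2.5, 15.0],
    [2.0,  5.0,  2.5,  3.0, 12.0],
    [2.0, 12.0,  3.0,  2.5,  8.5],
    [5.0, 15.0,  2.5,  2.0, 15.0],
    [6.0, 12.0,  2.0,  3.0, 15.0],
    [5.0,  8.5,  3.0,  3.0,  2.0],
    [3.5, 15.0,  3.0,  1.0, 12.0],
    [6.0, 15.0,  1.0,  2.5,  2.0],
])


def calibration_design() -> DesignTable:
    """The 25-mixture calibration design (ug/mL)."""
    return DesignTable(ANALYTES, _CALIBRATION_DESIGN.copy())


def validation_design() -> DesignTable:
    """The 15-mixture external validation design (ug/mL)."""
    return DesignTable(ANALYTES, _VALIDATION_DESIGN.copy())


def simulate_mixtures(
    design: DesignTable,
    pure: np.ndarray,
    noise: NoiseModel | None = None,
    grid: WavelengthGrid | None = None,
    id_prefix: str = "mix",
) -> SpectraMatrix:
    """Beer-Lambert mixture spectra D = C S^T + E for a design table.

    ``pure`` is the analytes x wavelengths matrix of pure spectra (the S^T
    rows), ordered like ``design.analyte_names``. With both noise standard
    deviations zero, D equals the matrix product exactly. Noise may push an
    absorbance slightly negative; values are left as-is, as a real baseline
    can dip below zero.
    """
    grid = grid or WavelengthGrid()
    pure = np.asarray(pure, dtype=float)
    if pure.shape != (len(design.analyte_names), len(grid)):
        raise ValueError(
            f"pure spectra shape {pure.shape} does not match "
            f"{len(design.analyte_names)} analytes x {len(grid)} grid points"
        )
    clean = design.rows @ pure
    if noise is None or (noise.additive_sd == 0 and noise.proportional_sd == 0):
        D = clean.copy()
    else:
        rng = np.random.default_rng(noise.seed)
        sd = np.sqrt(noise.additive_sd**2 + (noise.proportional_sd * clean) ** 2)
        D = clean + rng.standard_normal(clean.shape) * sd
    ids = [f"{id_prefix}{i + 1}" for i in range(design.n_mixtures)]
    return SpectraMatrix(ids, grid, D)
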