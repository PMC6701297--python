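"""CSV input/output for spectra and concentration tables.

One canonical dialect only: comma separator, period decimal, UTF-8, LF line
endings. Spectra files carry a ``sample_id`` column followed by numeric
wavelength headers; concentration files carry ``sample_id`` followed by
analyte names and an optional ``role`` column. Files using semicolons or
comma decimals are rejected outright rather than sniffed — silent locale
mis-parsing corrupts absorbances.

Round trips are lossless: floats are written with shortest-repr precision,
so write -> read reproduces every value exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .datatypes import ConcentrationTable, SpectraMatrix, WavelengthGrid

__all__ = [
    "SpectraMatrix",
    "ConcentrationTable",
    "read_spectra",
    "write_spectra",
    "read_concentrations",
    "write_concentrations",
]


def _read_rows(path: str | Path) -> list[list[str]]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if ";" in text.split("\n", 1)[0]:
        raise ValueError(
            f"{path}: semicolon-delimited file rejected; the canonical dialect "
            "is comma-separated with period decimals"
        )
    return [row for row in csv.reader(text.splitlines()) if row]


def _parse_float(cell: str, where: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ValueError(
            f"{where}: cannot parse {cell!r} as a number (comma decimals are "
            "not accepted)"
        ) from None


def read_spectra(path: str | Path) -> SpectraMatrix:
    """Read a spectra CSV (header: sample_id, then wavelengths in nm)."""
    rows = _read_rows(path)
    if len(rows) < 2:
        raise ValueError(f"{path}: no data rows")
    header = rows[0]
    if header[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got {header[0]!r}")
    wavelengths = np.array(
        [_parse_float(h, f"{path} header column {j + 2}") for j, h in enumerate(header[1:])]
    )
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError(f"{path}: non-monotone wavelengths in header")
    grid = WavelengthGrid.from_points(wavelengths)

    ids: list[str] = []
    data = np.empty((len(rows) - 1, len(wavelengths)))
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path} row {i} (sample {row[0]!r}): expected "
                f"{len(header) - 1} absorbance values, found {len(row) - 1}"
            )
        ids.append(row[0])
        data[i - 2] = [_parse_float(c, f"{path} row {i}") for c in row[1:]]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample_ids {dupes}")
    return SpectraMatrix(ids, grid, data)


def write_spectra(spectra: SpectraMatrix, path: str | Path) -> None:
    path = Path(path)
    lines = ["sample_id," + ",".join(repr(float(w)) for w in spectra.grid.points)]
    for sid, row in zip(spectra.sample_ids, spectra.absorbance):
        lines.append(sid + "," + ",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_concentrations(path: str | Path) -> ConcentrationTable:
    """Read a concentration CSV (header: sample_id, analytes..., [role]).

    Blank cells mark unknown concentrations (NaN), never zero. Rows without
    an explicit role default to calibration when fully known, else unknown.
    """
    rows = _read_rows(path)
    if len(rows) < 2:
        raise ValueError(f"{path}: no data rows")
    header = rows[0]
    if header[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got {header[0]!r}")
    has_role = header[-1] == "role"
    analytes = header[1:-1] if has_role else header[1:]
    if not analytes:
        raise ValueError(f"{path}: no analyte columns")

    ids: list[str] = []
    roles: list[str] = []
    values = np.empty((len(rows) - 1, len(analytes)))
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path} row {i} (sample {row[0]!r}): expected {len(header) - 1} "
                f"values, found {len(row) - 1}"
            )
        ids.append(row[0])
        cells = row[1:-1] if has_role else row[1:]
        for j, cell in enumerate(cells):
            if cell.strip() == "":
                values[i - 2, j] = np.nan
            else:
                v = _parse_float(cell, f"{path} row {i} column {analytes[j]}")
                if v < 0:
                    raise ValueError(
                        f"{path} row {i} column {analytes[j]}: negative "
                        f"concentration {v}"
                    )
                values[i - 2, j] = v
        if has_role:
            roles.append(row[-1])
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample_ids {dupes}")
    return ConcentrationTable(ids, analytes, values, roles)


def write_concentrations(table: ConcentrationTable, path: str | Path) -> None:
    path = Path(path)
    lines = ["sample_id," + ",".join(table.analyte_names) + ",role"]
    for sid, row, role in zip(table.sample_ids, table.values, table.roles):
        cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
        lines.append(sid + "," + ",".join(cells) + f",{role}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
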