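"""Spectral containers, delimited-text I/O and FTIR preprocessing.

Serum FTIR absorption spectra come off the instrument on a uniform
wavenumber grid (cm^-1).  Before any statistics are computed, four steps
are applied in a fixed order:

1. add back a scaled reference water spectrum, undoing the instrument's
   tendency to overcompensate for the water background (serum is ~10%
   solid matter);
2. truncate to the informative mid-IR window (default 1000-3000 cm^-1);
3. remove the biologically "silent region" (default 1850-2800 cm^-1),
   which carries essentially no molecular absorption;
4. normalize each spectrum to unit Euclidean (L2) norm.

The silent region is treated as an OPEN interval: grid points landing
exactly on its endpoints are retained.  Truncation bounds are CLOSED.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SpectraMatrix",
    "PreprocessConfig",
    "read_spectra",
    "write_spectra",
    "add_water_reference",
    "truncate_and_remove_silent",
    "l2_normalize",
    "preprocess",
]


@dataclass(frozen=True)
class SpectraMatrix:
    """Subjects x wavenumbers absorbance matrix with subject identifiers.

    Attributes
    ----------
    subject_ids : list of str
        Unique opaque identifiers, one per row.
    wavenumbers : ndarray, shape (p,)
        Strictly increasing wavenumber grid in cm^-1.
    absorbance : ndarray, shape (n, p)
        Absorbance in arbitrary units; finite values only.
    """

    subject_ids: list[str]
    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        ids = list(self.subject_ids)
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")
        if wn.ndim != 1 or wn.size == 0:
            raise ValueError("wavenumbers must be a non-empty 1-D vector")
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if ab.shape != (len(ids), wn.size):
            raise ValueError(
                f"absorbance shape {ab.shape} does not match "
                f"{len(ids)} subjects x {wn.size} wavenumbers"
            )
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance contains non-finite values")
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_wavenumbers(self) -> int:
        return int(self.wavenumbers.size)

    def select_subjects(self, ids: Sequence[str]) -> "SpectraMatrix":
        """Row-subset (and reorder) by subject id."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown subject ids: {missing}")
        rows = [index[s] for s in ids]
        return SpectraMatrix(list(ids), self.wavenumbers, self.absorbance[rows])


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the four-step preprocessing chain.

    ``water_reference`` must live on the same grid as the spectra it
    corrects; ``water_scale`` is the amount of reference water added
    back per spectrum (a.u. multiplier).  The correction scale is a
    configuration constant, not estimated from data.
    """

    water_reference: np.ndarray | None = None
    water_scale: float = 0.0
    truncate_low: float = 1000.0
    truncate_high: float = 3000.0
    silent_low: float = 1850.0
    silent_high: float = 2800.0

    def __post_init__(self) -> None:
        if not (self.truncate_low < self.silent_low < self.silent_high < self.truncate_high):
            raise ValueError(
                "require truncate_low < silent_low < silent_high < truncate_high, got "
                f"{self.truncate_low}, {self.silent_low}, {self.silent_high}, {self.truncate_high}"
            )
        if self.water_reference is not None:
            object.__setattr__(
                self, "water_reference", np.asarray(self.water_reference, dtype=float)
            )


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def read_spectra(path: str | Path) -> SpectraMatrix:
    """Read a delimited-text spectral matrix.

    Format: UTF-8, comma- or tab-delimited (sniffed); header row is
    ``id`` followed by numeric wavenumbers; one row per subject, first
    column the subject id.  Malformed rows are rejected with their
    1-based row number.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        if header[0].strip().lower() != "id":
            raise ValueError(f"{path}: header must start with 'id', got {header[0]!r}")
        try:
            wn = np.array([float(h) for h in header[1:]], dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric wavenumber in header: {exc}") from exc
        if wn.size == 0:
            raise ValueError(f"{path}: header has no wavenumbers")
        if np.any(np.diff(wn) <= 0):
            raise ValueError(f"{path}: header wavenumbers not strictly increasing")
        ids: list[str] = []
        rows: list[list[float]] = []
        for rownum, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # trailing blank line
            if len(row) != wn.size + 1:
                raise ValueError(
                    f"{path}: row {rownum} has {len(row)} fields, expected {wn.size + 1}"
                )
            sid = row[0].strip()
            if sid in ids:
                raise ValueError(f"{path}: row {rownum} duplicates subject id {sid!r}")
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError:
                raise ValueError(f"{path}: row {rownum} (id {sid!r}) has a non-numeric cell")
            ids.append(sid)
        if not ids:
            raise ValueError(f"{path}: no data rows")
    return SpectraMatrix(ids, wn, np.array(rows, dtype=float))


def write_spectra(matrix: SpectraMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write a spectral matrix in the dialect that :func:`read_spectra` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["id"] + [repr(float(w)) for w in matrix.wavenumbers])
        for sid, row in zip(matrix.subject_ids, matrix.absorbance):
            writer.writerow([sid] + [repr(float(v)) for v in row])


def add_water_reference(matrix: SpectraMatrix, config: PreprocessConfig) -> SpectraMatrix:
    """Add ``water_scale * water_reference`` to every spectrum.

    Undoes instrument water overcompensation.  A zero scale (or absent
    reference) is the identity.
    """
    if config.water_scale == 0.0 or config.water_reference is None:
        return matrix
    water = np.asarray(config.water_reference, dtype=float)
    if water.shape != matrix.wavenumbers.shape:
        raise ValueError(
            f"water reference length {water.size} does not match grid "
            f"length {matrix.n_wavenumbers}"
        )
    return replace(matrix, absorbance=matrix.absorbance + config.water_scale * water)


def retained_mask(wavenumbers: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Boolean mask of grid points kept by truncation + silent-region removal.

    Pure function of the wavenumber grid.  Truncation keeps the closed
    interval [truncate_low, truncate_high]; the silent region removes
    the open interval (silent_low, silent_high), so endpoints on-grid
    survive.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    keep = (wn >= config.truncate_low) & (wn <= config.truncate_high)
    silent = (wn > config.silent_low) & (wn < config.silent_high)
    return keep & ~silent


def truncate_and_remove_silent(matrix: SpectraMatrix, config: PreprocessConfig) -> SpectraMatrix:
    mask = retained_mask(matrix.wavenumbers, config)
    if not mask.any():
        raise ValueError("no wavenumbers retained after truncation/silent-region removal")
    return SpectraMatrix(
        matrix.subject_ids, matrix.wavenumbers[mask], matrix.absorbance[:, mask]
    )


def l2_normalize(matrix: SpectraMatrix) -> SpectraMatrix:
    """Scale every spectrum to unit Euclidean norm."""
    norms = np.linalg.norm(matrix.absorbance, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        bad = [matrix.subject_ids[i] for i in zero]
        raise ValueError(f"cannot L2-normalize all-zero spectra for subjects: {bad}")
    return replace(matrix, absorbance=matrix.absorbance / norms[:, None])


def preprocess(matrix: SpectraMatrix, config: PreprocessConfig) -> SpectraMatrix:
    """Full chain: water correction, truncation + silent removal, L2 norm.

    The order is load-bearing: normalization does not commute with
    truncation, and water correction must precede both.
    """
    out = add_water_reference(matrix, config)
    out = truncate_and_remove_silent(out, config)
    return l2_normalize(out)
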