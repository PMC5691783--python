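"""Spectral data model, I/O, resampling and specimen-level averaging.

Reflectance spectra arrive from the spectrometer on a fine native grid
(~0.34 nm) relative to a white standard.  The pipeline's canonical
representation is a 1 nm grid spanning 300-700 nm inclusive (401 samples);
every downstream stage (quantum catches, colour space, discriminability)
assumes that grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "SpecimenSpectra",
    "StandardGrid",
    "read_spectra_table",
    "write_spectra_table",
    "resample_to_grid",
    "clean_reflectance",
    "average_specimen",
]


@dataclass(frozen=True)
class StandardGrid:
    """Canonical wavelength grid: 300-700 nm at 1 nm, endpoints inclusive."""

    start: float = 300.0
    stop: float = 700.0
    step: float = 1.0

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1


@dataclass
class Spectrum:
    """A sampled spectral curve.

    ``values`` are dimensionless: reflectance relative to a white standard,
    receptor sensitivity, or relative irradiance, depending on role.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D arrays")
        if self.wavelengths.shape != self.values.shape:
            raise ValueError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.values.size} values"
            )
        if self.wavelengths.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelengths.size

    def on_grid(self, grid: StandardGrid) -> bool:
        gw = grid.wavelengths
        return self.wavelengths.size == gw.size and np.allclose(
            self.wavelengths, gw
        )

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths.copy(), np.asarray(values, float),
                        self.name if name is None else name)


@dataclass
class SpecimenSpectra:
    """Repeated reflectance measurements of one specimen (e.g. six per larva)."""

    specimen_id: str
    treatment_code: str
    replicate_box: str
    spectra: list[Spectrum]
    segments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError(f"specimen {self.specimen_id}: needs >=1 spectrum")


def read_spectra_table(path, dialect: dict | None = None) -> list[Spectrum]:
    """Read spectra from a delimited text file.

    Wide layout (default): one wavelength column, one column per spectrum.
    Long layout (``dialect={"format": "long", ...}``): wavelength/value/id
    columns named by the dialect mapping.

    dialect keys (all optional): ``sep`` (default ``,``), ``wavelength``
    (column name; default = first column), ``values`` (list of value column
    names; default = all remaining), ``format`` ("wide"/"long"), ``value``
    and ``id`` (long layout column names).
    """
    d = dict(dialect or {})
    sep = d.get("sep", ",")
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a wavelength column and >=1 value column")

    wl_col = d.get("wavelength", df.columns[0])
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col]) if col != d.get("id") else df[col]
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad.index[0]) if len(bad) else -1
            raise ValueError(
                f"{path}: non-numeric cell in column '{col}', row {row}"
            ) from exc

    if d.get("format", "wide") == "long":
        val_col = d.get("value", "value")
        id_col = d.get("id", "id")
        out = []
        for sid, sub in df.groupby(id_col, sort=True):
            sub = sub.sort_values(wl_col)
            out.append(Spectrum(sub[wl_col].to_numpy(),
                                sub[val_col].to_numpy(), name=str(sid)))
        return out

    value_cols = d.get("values", [c for c in df.columns if c != wl_col])
    wl = df[wl_col].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        i = int(np.argmin(np.diff(wl)))
        raise ValueError(
            f"{path}: wavelengths not strictly increasing near row {i + 1} "
            f"({wl[i]} -> {wl[i + 1]})"
        )
    return [Spectrum(wl, df[c].to_numpy(dtype=float), name=str(c))
            for c in value_cols]


def write_spectra_table(spectra: list[Spectrum], path) -> None:
    """Write spectra as a wide CSV, wavelength first column.

    All spectra must share a common grid.  Values are written with 8
    significant digits, so a read/write round trip preserves at least 6.
    """
    if not spectra:
        raise ValueError("no spectra to write")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.size != wl.size or not np.allclose(s.wavelengths, wl):
            raise ValueError("spectra are not on a common grid")
    cols = {"wavelength": wl}
    for i, s in enumerate(spectra):
        cols[s.name or f"spectrum_{i}"] = s.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")


def resample_to_grid(s: Spectrum, grid: StandardGrid | None = None) -> Spectrum:
    """Reduce a spectrum to the canonical 1 nm grid.

    Each output sample is the bin mean over the 1 nm interval centred on the
    grid point: the exact average of the piecewise-linear interpolant of the
    source over that bin.  This suppresses fine-grid instrument noise like a
    plain sample mean but is insensitive to where the source samples fall
    within the bin, and degrades gracefully to linear interpolation for
    sources sparser than the target grid.  The source must cover the full
    grid span; edge bins are truncated to the source range.
    """
    grid = grid or StandardGrid()
    gw = grid.wavelengths
    if s.on_grid(grid):
        return s.copy_with(s.values)
    lo, hi = s.wavelengths[0], s.wavelengths[-1]
    if lo > grid.start or hi < grid.stop:
        missing = []
        if lo > grid.start:
            missing.append(f"[{grid.start}, {lo}) nm")
        if hi < grid.stop:
            missing.append(f"({hi}, {grid.stop}] nm")
        raise ValueError(
            f"spectrum '{s.name}' does not cover the grid; missing "
            + " and ".join(missing)
        )

    xs, ys = s.wavelengths, s.values
    seg = np.concatenate(
        [[0.0], np.cumsum(0.5 * (ys[1:] + ys[:-1]) * np.diff(xs))])

    def cum(x: np.ndarray) -> np.ndarray:
        # cumulative integral of the linear interpolant at arbitrary points
        x = np.clip(x, xs[0], xs[-1])
        i = np.clip(np.searchsorted(xs, x, side="right") - 1, 0, xs.size - 2)
        yx = np.interp(x, xs, ys)
        return seg[i] + 0.5 * (ys[i] + yx) * (x - xs[i])

    half = grid.step / 2.0
    lo_e = np.clip(gw - half, xs[0], xs[-1])
    hi_e = np.clip(gw + half, xs[0], xs[-1])
    out = (cum(hi_e) - cum(lo_e)) / (hi_e - lo_e)
    return Spectrum(gw, out, name=s.name)


def clean_reflectance(s: Spectrum) -> Spectrum:
    """Clip sub-zero reflectance (measurement noise) to 0."""
    n_neg = int(np.sum(s.values < 0))
    if n_neg:
        logger.info("clean_reflectance: clipped %d negative points in '%s'",
                    n_neg, s.name)
        warnings.warn(
            f"clipped {n_neg} negative reflectance value(s) in '{s.name}'",
            UserWarning,
            stacklevel=2,
        )
    return s.copy_with(np.clip(s.values, 0.0, None))


def average_specimen(ss: SpecimenSpectra, grid: StandardGrid | None = None) -> Spectrum:
    """Per-wavelength arithmetic mean over a specimen's repeated measurements.

    Averaging happens on spectra, before any visual modelling, so each
    specimen has a single canonical spectral representation.
    """
    grid = grid or StandardGrid()
    if not ss.spectra:
        raise ValueError("no spectra to average")
    for sp in ss.spectra:
        if not sp.on_grid(grid):
            raise ValueError(
                f"specimen {ss.specimen_id}: spectrum '{sp.name}' is not on "
                "the canonical grid; resample first"
            )
    stacked = np.vstack([sp.values for sp in ss.spectra])
    return Spectrum(grid.wavelengths, stacked.mean(axis=0),
                    name=ss.specimen_id)
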