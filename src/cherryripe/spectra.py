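"""Remission spectra and the two normalized ripeness indices.

A portable photodiode-array spectrometer pressed against the fruit peel
records the relative remission spectrum between 400 and 1100 nm.  Two
normalized difference indices summarize the pigment state of the peel:

* ``NDVI = (I780 - I660) / (I780 + I660)`` — tracks chlorophyll,
* ``NAI  = (I780 - I570) / (I780 + I570)`` — tracks anthocyanins,

where ``I_x`` is the remission intensity in a narrow band around ``x`` nm.
Both indices are confined to (-1, +1) for positive intensities.  During
cherry ripening chlorophyll is degraded and anthocyanins accumulate, so both
indices rise; the trajectory module turns per-date index records into fitted
ripening curves.

This module owns the spectrum/record data model, band extraction, index
algebra and the CSV interchange formats (long-format spectra, band triplets
and index records).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import BandRangeError, ValidationError

# Spectral range of the instrument (nm).
WAVELENGTH_MIN_NM = 400.0
WAVELENGTH_MAX_NM = 1100.0

#: Band centers (nm): anthocyanin absorption, red chlorophyll absorption,
#: near-infrared reference.
ANTHOCYANIN_BAND_NM = 570.0
RED_BAND_NM = 660.0
NIR_BAND_NM = 780.0

DateLike = "datetime.date | float | int | str"


def _parse_date(value):
    """Normalize a date cell: ISO-8601 string, datetime.date, or a number
    (days on an arbitrary relative axis, used by the simulator)."""
    if isinstance(value, datetime.datetime):
        return value.date()
    if isinstance(value, datetime.date):
        return value
    if isinstance(value, str):
        try:
            return datetime.date.fromisoformat(value)
        except ValueError:
            return float(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    raise ValidationError(f"unparseable date value: {value!r}")


@dataclass(frozen=True)
class BandConfig:
    """Extraction windows for the three index bands.

    The instrument reports band intensities; when full spectra are supplied
    instead, each band is the mean remission inside ``center ± half_width``.
    A 5 nm half-width keeps the window narrow while being robust to the
    sampling grid.
    """

    nai_center_nm: float = ANTHOCYANIN_BAND_NM
    red_center_nm: float = RED_BAND_NM
    nir_center_nm: float = NIR_BAND_NM
    half_width_nm: float = 5.0

    def __post_init__(self):
        if self.half_width_nm < 0:
            raise ValidationError("half_width_nm must be >= 0")


@dataclass(frozen=True)
class RemissionSpectrum:
    """One remission spectrum for one side of one fruit on one date."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    date: object
    fruit_id: str
    side: str

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise ValidationError("wavelengths and intensities must be 1-D and equal length")
        if wl.size < 2:
            raise ValidationError("a spectrum needs at least 2 samples")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if wl[0] < WAVELENGTH_MIN_NM or wl[-1] > WAVELENGTH_MAX_NM:
            raise ValidationError(
                f"wavelengths must lie within [{WAVELENGTH_MIN_NM:g}, {WAVELENGTH_MAX_NM:g}] nm"
            )
        if np.any(it < 0) or not np.all(np.isfinite(it)):
            raise ValidationError("intensities must be finite and non-negative")
        object.__setattr__(self, "date", _parse_date(self.date))


@dataclass(frozen=True)
class BandTriplet:
    """Remission intensities at the three index bands.

    Intensities must be strictly positive: a zero band would push an index
    onto the ±1 boundary, which for this instrument signals sensor failure
    rather than a measurement, so it is rejected instead of clamped.
    """

    i570: float
    i660: float
    i780: float

    def __post_init__(self):
        for name in ("i570", "i660", "i780"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"band intensity {name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class IndexRecord:
    """NAI/NDVI values for one side of one fruit on one date."""

    date: object
    fruit_id: str
    side: str
    nai: float
    ndvi: float

    def __post_init__(self):
        object.__setattr__(self, "date", _parse_date(self.date))
        for name in ("nai", "ndvi"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < -1.0 or v > 1.0:
                raise ValidationError(f"{name} must lie in [-1, 1], got {v!r}")


def extract_band(spectrum: RemissionSpectrum, center_nm: float, half_width_nm: float = 5.0) -> float:
    """Mean remission intensity in the closed window ``center ± half_width``.

    With ``half_width_nm = 0``, or when no sampled wavelength falls inside
    the window (a sparse grid), the intensity is linearly interpolated at
    the band center instead.

    Raises
    ------
    BandRangeError
        If the window does not overlap the measured spectral range.
    """
    if half_width_nm < 0:
        raise ValidationError("half_width_nm must be >= 0")
    wl = spectrum.wavelengths_nm
    lo, hi = center_nm - half_width_nm, center_nm + half_width_nm
    if hi < wl[0] or lo > wl[-1]:
        raise BandRangeError(
            f"band {center_nm:g} nm (window [{lo:g}, {hi:g}] nm) lies outside the "
            f"measured range [{wl[0]:g}, {wl[-1]:g}] nm"
        )
    mask = (wl >= lo) & (wl <= hi)
    if half_width_nm > 0 and np.any(mask):
        return float(np.mean(spectrum.intensities[mask]))
    # fall back to interpolation at the center
    if center_nm < wl[0] or center_nm > wl[-1]:
        raise BandRangeError(
            f"band center {center_nm:g} nm lies outside the measured range "
            f"[{wl[0]:g}, {wl[-1]:g}] nm and no sample falls in its window"
        )
    return float(np.interp(center_nm, wl, spectrum.intensities))


def bands_from_spectrum(spectrum: RemissionSpectrum, config: BandConfig | None = None) -> BandTriplet:
    """Extract the I570/I660/I780 triplet from a full spectrum."""
    cfg = config or BandConfig()
    return BandTriplet(
        i570=extract_band(spectrum, cfg.nai_center_nm, cfg.half_width_nm),
        i660=extract_band(spectrum, cfg.red_center_nm, cfg.half_width_nm),
        i780=extract_band(spectrum, cfg.nir_center_nm, cfg.half_width_nm),
    )


def compute_ndvi(bands: BandTriplet) -> float:
    """Normalized difference vegetation index (I780 - I660)/(I780 + I660)."""
    return (bands.i780 - bands.i660) / (bands.i780 + bands.i660)


def compute_nai(bands: BandTriplet) -> float:
    """Normalized anthocyanin index (I780 - I570)/(I780 + I570)."""
    return (bands.i780 - bands.i570) / (bands.i780 + bands.i570)


def batch_indices(
    spectra: Iterable[RemissionSpectrum], band_config: BandConfig | None = None
) -> list[IndexRecord]:
    """Compute one :class:`IndexRecord` per spectrum, preserving input order.

    Band-extraction failures are re-raised with the fruit/date context so a
    bad spectrum in a large batch is identifiable.
    """
    cfg = band_config or BandConfig()
    spectra = list(spectra)
    if not spectra:
        raise ValidationError("batch_indices requires at least one spectrum")
    records = []
    for sp in spectra:
        try:
            bands = bands_from_spectrum(sp, cfg)
        except BandRangeError as exc:
            raise BandRangeError(
                f"fruit {sp.fruit_id!r} side {sp.side!r} date {sp.date}: {exc}"
            ) from exc
        records.append(
            IndexRecord(
                date=sp.date,
                fruit_id=sp.fruit_id,
                side=sp.side,
                nai=compute_nai(bands),
                ndvi=compute_ndvi(bands),
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_spectra_csv(path) -> list[RemissionSpectrum]:
    """Read long-format spectra: columns date,fruit_id,side,wavelength_nm,intensity."""
    df = pd.read_csv(path)
    required = {"date", "fruit_id", "side", "wavelength_nm", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"spectrum CSV missing columns: {sorted(missing)}")
    spectra = []
    for (date, fruit, side), grp in df.groupby(["date", "fruit_id", "side"], sort=False):
        grp = grp.sort_values("wavelength_nm")
        spectra.append(
            RemissionSpectrum(
                wavelengths_nm=grp["wavelength_nm"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                date=date,
                fruit_id=str(fruit),
                side=str(side),
            )
        )
    if not spectra:
        raise ValidationError("spectrum CSV contains no rows")
    return spectra


def read_bands_csv(path) -> list[IndexRecord]:
    """Read band triplets (date,fruit_id,side,i570,i660,i780) and compute indices."""
    df = pd.read_csv(path)
    required = {"date", "fruit_id", "side", "i570", "i660", "i780"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"band CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        bands = BandTriplet(i570=row.i570, i660=row.i660, i780=row.i780)
        records.append(
            IndexRecord(
                date=row.date,
                fruit_id=str(row.fruit_id),
                side=str(row.side),
                nai=compute_nai(bands),
                ndvi=compute_ndvi(bands),
            )
        )
    if not records:
        raise ValidationError("band CSV contains no rows")
    return records


def records_to_frame(records: Sequence[IndexRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date": [r.date for r in records],
            "fruit_id": [r.fruit_id for r in records],
            "side": [r.side for r in records],
            "nai": [r.nai for r in records],
            "ndvi": [r.ndvi for r in records],
        }
    )


def write_indices_csv(records: Sequence[IndexRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_indices_csv(path) -> list[IndexRecord]:
    df = pd.read_csv(path)
    required = {"date", "fruit_id", "side", "nai", "ndvi"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"index CSV missing columns: {sorted(missing)}")
    return [
        IndexRecord(date=r.date, fruit_id=str(r.fruit_id), side=str(r.side), nai=r.nai, ndvi=r.ndvi)
        for r in df.itertuples(index=False)
    ]
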