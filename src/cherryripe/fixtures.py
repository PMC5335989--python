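"""Packaged reference tables: fruit quality and pigment chemistry.

Two small CSV fixtures transcribe the printed 2012 campaign tables —
per-date fruit size/weight/firmness and per-date pigment concentrations
(chlorophyll a/b, carotenoids, flavonoids, anthocyanins in nmol per gram of
fruit mash) for both cultivars (Bellise, Samba) with and without a
polytunnel cover.  A manifest with sha256 checksums guards against silent
corruption of the transcription.

Conventions: "n.d." (not detected) and blank trailing cells are missing
values, never zero; the firmness value 100 is the penetrometer ceiling and
is flagged rather than treated as a measurement.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import FixtureIntegrityError, NoDataError, ValidationError

PIGMENT_FIELDS = ("chl_a", "chl_b", "carotenoids", "flavonoids", "anthocyanins")
QUALITY_FIELDS = ("fruit_size_mm", "fruit_weight_g", "firmness_shore_a")

#: Shore A value printed for fruit too firm for the penetrometer.
FIRMNESS_CEILING = 100.0


@dataclass(frozen=True)
class QualityRecord:
    """One date of fruit-quality measurements for one cultivar/treatment."""

    cultivar: str
    cover: bool
    date: datetime.date
    fruit_size_mm: float
    fruit_size_sd: float
    fruit_weight_g: float
    fruit_weight_sd: float
    firmness_shore_a: float
    firmness_sd: float | None
    firmness_at_ceiling: bool

    def __post_init__(self):
        if self.fruit_size_mm <= 0 or self.fruit_weight_g <= 0:
            raise ValidationError("fruit size and weight must be positive")
        for sd in (self.fruit_size_sd, self.fruit_weight_sd, self.firmness_sd):
            if sd is not None and sd < 0:
                raise ValidationError("standard deviations must be non-negative")


@dataclass(frozen=True)
class PigmentRecord:
    """One date of pigment chemistry (nmol per g fruit mash); None = not detected."""

    cultivar: str
    cover: bool
    date: datetime.date
    chl_a: float | None
    chl_b: float | None
    carotenoids: float | None
    flavonoids: float | None
    anthocyanins: float | None

    def __post_init__(self):
        for name in PIGMENT_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative when present")


def _data_dir() -> Path:
    return Path(resources.files("cherryripe") / "data")


def _read_checked(filename: str, data_dir=None) -> pd.DataFrame:
    d = Path(data_dir) if data_dir is not None else _data_dir()
    manifest = json.loads((d / "manifest.json").read_text())
    expected = manifest["files"].get(filename)
    path = d / filename
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != expected:
        raise FixtureIntegrityError(
            f"{filename}: sha256 {digest} does not match manifest entry {expected}"
        )
    return pd.read_csv(path)


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _bool(value) -> bool:
    if isinstance(value, (bool,)) or hasattr(value, "dtype"):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise ValidationError(f"unparseable boolean cell: {value!r}")


def load_quality(data_dir=None) -> list[QualityRecord]:
    """All transcribed fruit-quality rows (29 cultivar/treatment/date rows)."""
    df = _read_checked("quality.csv", data_dir)
    return [
        QualityRecord(
            cultivar=str(r.cultivar),
            cover=_bool(r.cover),
            date=datetime.date.fromisoformat(str(r.date)),
            fruit_size_mm=float(r.fruit_size_mm),
            fruit_size_sd=float(r.fruit_size_sd),
            fruit_weight_g=float(r.fruit_weight_g),
            fruit_weight_sd=float(r.fruit_weight_sd),
            firmness_shore_a=float(r.firmness_shore_a),
            firmness_sd=_opt(r.firmness_sd),
            firmness_at_ceiling=_bool(r.firmness_at_ceiling),
        )
        for r in df.itertuples(index=False)
    ]


def load_pigments(data_dir=None) -> list[PigmentRecord]:
    """All transcribed pigment rows; "n.d." cells are None, never zero."""
    df = _read_checked("pigments.csv", data_dir)
    return [
        PigmentRecord(
            cultivar=str(r.cultivar),
            cover=_bool(r.cover),
            date=datetime.date.fromisoformat(str(r.date)),
            chl_a=_opt(r.chl_a),
            chl_b=_opt(r.chl_b),
            carotenoids=_opt(r.carotenoids),
            flavonoids=_opt(r.flavonoids),
            anthocyanins=_opt(r.anthocyanins),
        )
        for r in df.itertuples(index=False)
    ]


def series_max(records: Sequence, cultivar: str, cover: bool, field: str):
    """Date and value of the maximum of one field in one treatment series.

    Ties are broken by the earliest date.  Raises :class:`NoDataError` if the
    field is missing on every date of the series.
    """
    best = None
    for rec in records:
        if rec.cultivar != cultivar or rec.cover != cover:
            continue
        value = getattr(rec, field)
        if value is None:
            continue
        if best is None or value > best[1]:
            best = (rec.date, value)
    if best is None:
        raise NoDataError(
            f"no non-missing {field!r} values for {cultivar} (cover={cover})"
        )
    return best


# serializers used by the round-trip check and the CLI JSON/CSV export

def quality_to_frame(records: Sequence[QualityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cultivar": r.cultivar,
                "cover": r.cover,
                "date": r.date.isoformat(),
                "fruit_size_mm": r.fruit_size_mm,
                "fruit_size_sd": r.fruit_size_sd,
                "fruit_weight_g": r.fruit_weight_g,
                "fruit_weight_sd": r.fruit_weight_sd,
                "firmness_shore_a": r.firmness_shore_a,
                "firmness_sd": r.firmness_sd,
                "firmness_at_ceiling": r.firmness_at_ceiling,
            }
            for r in records
        ]
    )


def pigments_to_frame(records: Sequence[PigmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cultivar": r.cultivar,
                "cover": r.cover,
                "date": r.date.isoformat(),
                **{f: getattr(r, f) for f in PIGMENT_FIELDS},
            }
            for r in records
        ]
    )


def quality_from_frame(df: pd.DataFrame) -> list[QualityRecord]:
    return [
        QualityRecord(
            cultivar=str(r.cultivar),
            cover=_bool(r.cover),
            date=datetime.date.fromisoformat(str(r.date)),
            fruit_size_mm=float(r.fruit_size_mm),
            fruit_size_sd=float(r.fruit_size_sd),
            fruit_weight_g=float(r.fruit_weight_g),
            fruit_weight_sd=float(r.fruit_weight_sd),
            firmness_shore_a=float(r.firmness_shore_a),
            firmness_sd=_opt(r.firmness_sd),
            firmness_at_ceiling=_bool(r.firmness_at_ceiling),
        )
        for r in df.itertuples(index=False)
    ]


def pigments_from_frame(df: pd.DataFrame) -> list[PigmentRecord]:
    return [
        PigmentRecord(
            cultivar=str(r.cultivar),
            cover=_bool(r.cover),
            date=datetime.date.fromisoformat(str(r.date)),
            **{f: _opt(getattr(r, f)) for f in PIGMENT_FIELDS},
        )
        for r in df.itertuples(index=False)
    ]
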