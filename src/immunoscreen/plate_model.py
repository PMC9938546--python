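"""Domain types for plates, wells and GFP signal series, with CSV I/O.

The screen's raw data are (a) a plate map assigning each well a culture
type (cancer monoculture, PBMC monoculture, or co-culture), a treatment
and a donor, and (b) a long-format table of per-well GFP intensity
sampled on a fixed time grid (by default every 4 h for 96 h).  All
downstream stages (QC, viability, Bliss scoring) consume the
:class:`PlateSet` assembled here.
"""

from __future__ import annotations

import enum
import string
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    DuplicationError,
    GridError,
    PlateParseError,
    ValidationError,
)

__all__ = [
    "Culture",
    "VEHICLE",
    "UNTREATED",
    "CONTROL_TREATMENTS",
    "WellAnnotation",
    "SignalSeries",
    "PlateSet",
    "parse_well_label",
    "format_well_label",
    "default_grid",
    "read_plate_map",
    "write_plate_map",
    "read_signals",
    "write_signals",
]


class Culture(str, enum.Enum):
    """Culture type of a well."""

    CANCER_MONO = "CANCER_MONO"
    PBMC_MONO = "PBMC_MONO"
    COCULTURE = "COCULTURE"


#: Reserved treatment labels for control wells.
VEHICLE = "VEHICLE"
UNTREATED = "UNTREATED"
CONTROL_TREATMENTS = frozenset({VEHICLE, UNTREATED})

_ROWS_384 = string.ascii_uppercase[:16]  # A..P
_ROWS_96 = string.ascii_uppercase[:8]  # A..H


def parse_well_label(label: str, plate_format: int = 384) -> tuple[int, int]:
    """Parse a well label like ``"B03"`` into 0-based (row, column) indices.

    Accepts rows A..P / columns 1..24 for the 384-well format and
    A..H / 1..12 for 96-well.
    """
    n_rows, n_cols = (16, 24) if plate_format == 384 else (8, 12)
    if plate_format not in (96, 384):
        raise ValidationError(f"unsupported plate format: {plate_format}")
    if not label or len(label) < 2 or not label[0].isalpha():
        raise PlateParseError(f"malformed well label: {label!r}")
    row = ord(label[0].upper()) - ord("A")
    try:
        col = int(label[1:]) - 1
    except ValueError:
        raise PlateParseError(f"malformed well label: {label!r}") from None
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise PlateParseError(
            f"well label {label!r} outside {plate_format}-well bounds"
        )
    return row, col


def format_well_label(row: int, col: int) -> str:
    """Inverse of :func:`parse_well_label`: (1, 2) -> ``"B03"``."""
    if not (0 <= row < 16 and 0 <= col < 24):
        raise ValidationError(f"well indices out of range: ({row}, {col})")
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


def default_grid(end: float = 96.0, step: float = 4.0) -> np.ndarray:
    """The screen's observation grid: 0, 4, ..., 96 h."""
    return np.arange(0.0, end + step / 2, step)


@dataclass(frozen=True)
class WellAnnotation:
    """Plate-map entry for one well.

    ``ratio`` is the cancer:PBMC seeding ratio as a pair of positive
    integers (e.g. ``(1, 1)`` for the screen, ``(1, 4)`` for
    validation); ``None`` for monocultures.  ``donor_id`` is empty for
    cancer monocultures, which contain no PBMCs.
    """

    plate_id: str
    well: str
    culture: Culture
    treatment: str
    concentration: float = 0.0
    donor_id: str = ""
    ratio: tuple[int, int] | None = None
    plate_format: int = 384

    def __post_init__(self) -> None:
        parse_well_label(self.well, self.plate_format)
        if not isinstance(self.culture, Culture):
            object.__setattr__(self, "culture", Culture(self.culture))
        if self.concentration < 0:
            raise ValidationError(
                f"{self.key}: negative concentration {self.concentration}"
            )
        is_control = self.treatment in CONTROL_TREATMENTS
        if is_control != (self.concentration == 0):
            raise ValidationError(
                f"{self.key}: concentration must be 0 iff treatment is "
                f"VEHICLE/UNTREATED (got {self.treatment!r} at "
                f"{self.concentration} uM)"
            )
        if (self.culture is Culture.CANCER_MONO) != (self.donor_id == ""):
            raise ValidationError(
                f"{self.key}: donor_id must be empty iff culture is "
                f"CANCER_MONO (got culture={self.culture.value}, "
                f"donor={self.donor_id!r})"
            )
        if self.ratio is not None:
            a, b = self.ratio
            if a <= 0 or b <= 0:
                raise ValidationError(f"{self.key}: ratio parts must be positive")

    @property
    def key(self) -> tuple[str, str]:
        return (self.plate_id, self.well)

    @property
    def is_control(self) -> bool:
        return self.treatment in CONTROL_TREATMENTS


@dataclass(frozen=True)
class SignalSeries:
    """Per-well GFP intensity on a strictly increasing time grid (hours)."""

    plate_id: str
    well: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise ValidationError(
                f"{self.key}: times and values must be 1-D and equal length"
            )
        if len(times) == 0:
            raise ValidationError(f"{self.key}: empty series")
        if np.any(np.diff(times) <= 0):
            raise GridError(f"{self.key}: times must be strictly increasing")
        if np.any(np.isnan(values)) or np.any(values < 0):
            raise ValidationError(f"{self.key}: values must be >= 0 and not NaN")

    @property
    def key(self) -> tuple[str, str]:
        return (self.plate_id, self.well)

    def at(self, time: float) -> float:
        """Signal at an on-grid time; off-grid times raise ``GridError``."""
        idx = np.nonzero(np.isclose(self.times, time))[0]
        if len(idx) == 0:
            raise GridError(f"{self.key}: time {time} h not on grid")
        return float(self.values[idx[0]])


@dataclass
class PlateSet:
    """A set of annotated wells with their signal series on one shared grid."""

    annotations: dict[tuple[str, str], WellAnnotation]
    signals: dict[tuple[str, str], SignalSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = None
        for key, series in self.signals.items():
            if key not in self.annotations:
                raise ValidationError(f"signal for unannotated well {key}")
            if grid is None:
                grid = series.times
            elif len(series.times) != len(grid) or not np.allclose(
                series.times, grid
            ):
                raise GridError(f"{key}: time grid differs from the shared grid")

    @property
    def grid(self) -> np.ndarray:
        if not self.signals:
            raise ValidationError("plate set has no signals")
        return next(iter(self.signals.values())).times

    def wells(
        self,
        culture: Culture | None = None,
        treatment: str | None = None,
        donor_id: str | None = None,
    ) -> list[WellAnnotation]:
        """Annotations filtered by culture / treatment / donor."""
        out = []
        for ann in self.annotations.values():
            if culture is not None and ann.culture is not Culture(culture):
                continue
            if treatment is not None and ann.treatment != treatment:
                continue
            if donor_id is not None and ann.donor_id != donor_id:
                continue
            out.append(ann)
        return out

    def signal(self, ann: WellAnnotation) -> SignalSeries:
        return self.signals[ann.key]

    def compounds(self) -> list[str]:
        """Sorted non-control treatment identifiers present on the plates."""
        return sorted(
            {
                a.treatment
                for a in self.annotations.values()
                if not a.is_control
            }
        )

    def scaled(self, factor: float) -> "PlateSet":
        """A copy with every signal multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return PlateSet(
            annotations=dict(self.annotations),
            signals={
                k: replace(s, values=s.values * factor)
                for k, s in self.signals.items()
            },
        )


# ---------------------------------------------------------------------------
# CSV I/O

_MAP_COLUMNS = [
    "plate_id",
    "well",
    "culture",
    "treatment",
    "concentration_uM",
    "donor_id",
    "ratio",
]
_SIGNAL_COLUMNS = ["plate_id", "well", "time_h", "gfp_intensity"]


def _parse_ratio(text: str) -> tuple[int, int] | None:
    if not text:
        return None
    try:
        a, b = text.split(":")
        return int(a), int(b)
    except ValueError:
        raise PlateParseError(f"malformed ratio: {text!r}") from None


def read_plate_map(path) -> list[WellAnnotation]:
    """Read a plate-map CSV into a stable-ordered list of annotations.

    Expected header: ``plate_id,well,culture,treatment,concentration_uM,
    donor_id,ratio``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise PlateParseError(f"plate map missing columns: {missing}")
    out: list[WellAnnotation] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            culture = Culture(row.culture)
        except ValueError:
            raise ValidationError(
                f"row {i}: unknown culture {row.culture!r}"
            ) from None
        try:
            ann = WellAnnotation(
                plate_id=row.plate_id,
                well=row.well,
                culture=culture,
                treatment=row.treatment,
                concentration=float(row.concentration_uM or 0.0),
                donor_id=row.donor_id,
                ratio=_parse_ratio(row.ratio),
            )
        except PlateParseError as exc:
            raise PlateParseError(f"row {i}: {exc}") from None
        if ann.key in seen:
            raise DuplicationError(f"row {i}: duplicate well {ann.key}")
        seen.add(ann.key)
        out.append(ann)
    return out


def write_plate_map(annotations: Iterable[WellAnnotation], path) -> None:
    rows = [
        {
            "plate_id": a.plate_id,
            "well": a.well,
            "culture": a.culture.value,
            "treatment": a.treatment,
            "concentration_uM": a.concentration,
            "donor_id": a.donor_id,
            "ratio": "" if a.ratio is None else f"{a.ratio[0]}:{a.ratio[1]}",
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_MAP_COLUMNS).to_csv(path, index=False)


def read_signals(path) -> list[SignalSeries]:
    """Read a long-format signal CSV (one row per well x timepoint).

    Rows are grouped per (plate_id, well) and sorted by time; all wells
    must share one time grid.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    missing = [c for c in _SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise PlateParseError(f"signal file missing columns: {missing}")
    if df["gfp_intensity"].lt(0).any():
        raise ValidationError("negative gfp_intensity in signal file")
    out: list[SignalSeries] = []
    grid: np.ndarray | None = None
    for (plate_id, well), grp in df.groupby(["plate_id", "well"], sort=True):
        grp = grp.sort_values("time_h")
        series = SignalSeries(
            plate_id=plate_id,
            well=well,
            times=grp["time_h"].to_numpy(dtype=float),
            values=grp["gfp_intensity"].to_numpy(dtype=float),
        )
        if grid is None:
            grid = series.times
        elif len(series.times) != len(grid) or not np.allclose(series.times, grid):
            raise GridError(
                f"well ({plate_id}, {well}) is on a different time grid"
            )
        out.append(series)
    return out


def write_signals(series: Iterable[SignalSeries], path) -> None:
    """Write series in long format; round-trips through :func:`read_signals`."""
    rows = []
    for s in series:
        if np.any(np.isnan(s.values)):
            raise ValidationError(f"{s.key}: NaN not representable")
        for t, v in zip(s.times, s.values):
            rows.append((s.plate_id, s.well, t, v))
    df = pd.DataFrame(rows, columns=_SIGNAL_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def build_plateset(
    annotations: Iterable[WellAnnotation],
    signals: Iterable[SignalSeries],
) -> PlateSet:
    """Assemble and validate a :class:`PlateSet` from parsed pieces."""
    ann_map = {}
    for a in annotations:
        if a.key in ann_map:
            raise DuplicationError(f"duplicate annotation {a.key}")
        ann_map[a.key] = a
    sig_map = {}
    for s in signals:
        if s.key in sig_map:
            raise DuplicationError(f"duplicate signal series {s.key}")
        sig_map[s.key] = s
    return PlateSet(annotations=ann_map, signals=sig_map)
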