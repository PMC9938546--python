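"""Viability normalization: raw GFP signal -> fraction of control.

The screen's readout is "percent of control": each treated well's GFP
intensity divided by the mean intensity of control wells.  Two baseline
conventions are supported:

``OWN_CULTURE``
    Each well is normalized to controls of its own culture type — the
    convention used for reporting per-culture viabilities.

``MONOCULTURE``
    Every well is normalized to the untreated cancer-monoculture
    control mean.  Under this convention the activated PBMCs themselves
    have a well-defined single-agent "viability" (the untreated
    co-culture:monoculture ratio), which is what the Bliss scoring
    stage needs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GridError, MissingControlError, ValidationError
from .plate_model import UNTREATED, VEHICLE, Culture, PlateSet

__all__ = [
    "Baseline",
    "ViabilityRecord",
    "control_mean",
    "compute_viability",
    "mean_donor_viability",
    "viability_timecourse",
]


class Baseline(str, enum.Enum):
    OWN_CULTURE = "OWN_CULTURE"
    MONOCULTURE = "MONOCULTURE"


@dataclass(frozen=True)
class ViabilityRecord:
    """One well's viability fraction at one timepoint (1 = control level).

    Values above 1 are legitimate (growth stimulation or noise) and are
    never clipped here; display layers may clip.
    """

    compound_id: str
    culture: Culture
    concentration: float
    donor_id: str
    time: float
    viability: float

    def __post_init__(self) -> None:
        if self.viability < 0 or math.isnan(self.viability):
            raise ValidationError(
                f"viability must be >= 0, got {self.viability}"
            )


def control_mean(
    plateset: PlateSet,
    culture: Culture | str,
    time: float,
    control_kind: str = VEHICLE,
) -> float:
    """Arithmetic mean of control-well signals at an on-grid time.

    At least two control wells of the requested kind and culture type
    are required.
    """
    culture = Culture(culture)
    if control_kind not in (VEHICLE, UNTREATED):
        raise ValidationError(f"unknown control kind {control_kind!r}")
    wells = plateset.wells(culture=culture, treatment=control_kind)
    if len(wells) < 2:
        raise MissingControlError(
            f"need >= 2 {control_kind} {culture.value} control wells, "
            f"found {len(wells)}"
        )
    grid = plateset.grid
    if not np.any(np.isclose(grid, time)):
        raise GridError(f"time {time} h not on the shared grid")
    return float(np.mean([plateset.signal(w).at(time) for w in wells]))


def compute_viability(
    plateset: PlateSet,
    time: float = 72.0,
    baseline: Baseline | str = Baseline.OWN_CULTURE,
    control_kind: str = VEHICLE,
    subtract_background: bool = False,
) -> list[ViabilityRecord]:
    """Viability of every cancer-containing well at ``time``.

    PBMC-only wells carry no tumor reporter signal and are excluded
    from the output.  With ``subtract_background=True`` the PBMC-only
    mean is subtracted from every signal before ratioing (off by
    default; the screen normalizes raw intensities).
    """
    baseline = Baseline(baseline)
    background = 0.0
    if subtract_background:
        background = control_mean(
            plateset, Culture.PBMC_MONO, time, control_kind=UNTREATED
        )

    denominators: dict[Culture, float] = {}
    if baseline is Baseline.MONOCULTURE:
        mono = control_mean(
            plateset, Culture.CANCER_MONO, time, control_kind=UNTREATED
        )
        denominators[Culture.CANCER_MONO] = mono - background
        denominators[Culture.COCULTURE] = mono - background
    else:
        for culture in (Culture.CANCER_MONO, Culture.COCULTURE):
            if plateset.wells(culture=culture):
                denominators[culture] = (
                    control_mean(plateset, culture, time, control_kind)
                    - background
                )

    records: list[ViabilityRecord] = []
    for ann in plateset.annotations.values():
        if ann.culture is Culture.PBMC_MONO:
            continue
        denom = denominators[ann.culture]
        if denom <= 0:
            raise ValidationError(
                f"non-positive control mean for {ann.culture.value}"
            )
        signal = plateset.signal(ann).at(time) - background
        records.append(
            ViabilityRecord(
                compound_id=ann.treatment,
                culture=ann.culture,
                concentration=ann.concentration,
                donor_id=ann.donor_id,
                time=time,
                viability=max(signal, 0.0) / denom,
            )
        )
    return records


def mean_donor_viability(values: Sequence[float]) -> tuple[float, int]:
    """Mean of per-donor viability fractions, plus nearest-percent report.

    Rounding is half-away-from-zero to an integer percent, the
    convention used when quoting e.g. donor viabilities (0.51, 0.57,
    0.56) as an average of 55%.
    """
    values = list(values)
    if not values:
        raise ValidationError("mean_donor_viability requires >= 1 value")
    mean = float(np.mean(values))
    percent = int(math.floor(abs(mean) * 100 + 0.5)) * (1 if mean >= 0 else -1)
    return mean, percent


def viability_timecourse(
    plateset: PlateSet,
    compound_id: str,
    culture: Culture | str,
    control_kind: str = VEHICLE,
) -> list[tuple[float, float]]:
    """Per-timepoint viability of one compound in one culture type.

    Uses the OWN_CULTURE baseline at every grid time; replicate wells
    (e.g. across donors) are averaged.
    """
    culture = Culture(culture)
    known = {a.treatment for a in plateset.annotations.values()}
    if compound_id not in known:
        raise KeyError(f"unknown compound {compound_id!r}")
    out = []
    for t in plateset.grid:
        records = compute_viability(
            plateset, time=float(t), baseline=Baseline.OWN_CULTURE,
            control_kind=control_kind,
        )
        vals = [
            r.viability
            for r in records
            if r.compound_id == compound_id and r.culture is culture
        ]
        if vals:
            out.append((float(t), float(np.mean(vals))))
    return out
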