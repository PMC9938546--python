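"""Assay quality control via the screen's two Z statistics.

The classical Z-factor measures how well two control distributions
separate:  Z = 1 − 3(σ₁ + σ₂)/|μ₁ − μ₂|.  The screen tracks two
variants per timepoint, both computed on raw GFP intensity of
untreated wells:

* **Z_M** (immunomodulation window) — cancer monoculture vs PBMC
  monoculture: the assay's dynamic range.
* **Z_P** (immunopotentiation window) — co-culture vs PBMC
  monoculture: the headroom left for detecting treatment-enhanced
  immune killing.

Quality categories follow the standard screening convention: 1 is
ideal, [0.5, 1) excellent, [0, 0.5) marginal, negative means the
control signals may overlap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
import numpy as np

from .errors import (
    MissingControlError,
    NoValidTimepointError,
    UndefinedZError,
    ValidationError,
)
from .plate_model import UNTREATED, Culture, PlateSet

__all__ = [
    "AssayQuality",
    "GroupStats",
    "QCProfile",
    "z_factor",
    "qc_profile",
    "classify_assay",
    "select_evaluation_time",
]


class AssayQuality(str, enum.Enum):
    IDEAL = "IDEAL"
    EXCELLENT = "EXCELLENT"
    MARGINAL = "MARGINAL"
    OVERLAPPING = "OVERLAPPING"


@dataclass(frozen=True)
class GroupStats:
    """Mean/SD/count of untreated wells of one culture type at one time."""

    culture: Culture
    time: float
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n < 2:
            raise ValidationError("group needs n >= 2 wells")


@dataclass(frozen=True)
class QCProfile:
    """Per-timepoint Z_M and Z_P with the underlying group statistics."""

    times: tuple[float, ...]
    z_m: tuple[float, ...]
    z_p: tuple[float, ...]
    group_stats: tuple[GroupStats, ...]

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.z_m) == len(self.z_p)):
            raise ValidationError("profile arrays must be equal length")


def z_factor(
    mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float
) -> float:
    """Z = 1 − 3(sd_pos + sd_neg)/|mean_pos − mean_neg|.

    Orientation of "positive" vs "negative" is irrelevant because of
    the absolute value.  Equal means leave Z undefined.
    """
    if sd_pos < 0 or sd_neg < 0:
        raise ValidationError("standard deviations must be >= 0")
    separation = abs(mean_pos - mean_neg)
    if separation == 0:
        raise UndefinedZError("control means coincide: Z undefined")
    return 1.0 - 3.0 * (sd_pos + sd_neg) / separation


def _group_stats(
    plateset: PlateSet, culture: Culture, time: float
) -> GroupStats:
    wells = plateset.wells(culture=culture, treatment=UNTREATED)
    if len(wells) < 2:
        raise MissingControlError(
            f"QC needs >= 2 untreated {culture.value} wells, found {len(wells)}"
        )
    vals = np.array([plateset.signal(w).at(time) for w in wells])
    # Sample SD (n-1 denominator), the screening-QC convention.
    return GroupStats(
        culture=culture,
        time=time,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n=len(vals),
    )


def qc_profile(plateset: PlateSet) -> QCProfile:
    """Z_M and Z_P at every grid time, from untreated control wells."""
    times, z_m, z_p, stats = [], [], [], []
    for t in plateset.grid:
        t = float(t)
        pbmc = _group_stats(plateset, Culture.PBMC_MONO, t)
        cancer = _group_stats(plateset, Culture.CANCER_MONO, t)
        co = _group_stats(plateset, Culture.COCULTURE, t)
        times.append(t)
        z_m.append(z_factor(cancer.mean, cancer.sd, pbmc.mean, pbmc.sd))
        z_p.append(z_factor(co.mean, co.sd, pbmc.mean, pbmc.sd))
        stats.extend([pbmc, cancer, co])
    return QCProfile(
        times=tuple(times),
        z_m=tuple(z_m),
        z_p=tuple(z_p),
        group_stats=tuple(stats),
    )


def classify_assay(z: float) -> AssayQuality:
    """Map a Z value to the standard screening quality category."""
    if z > 1:
        raise ValidationError(f"Z cannot exceed 1, got {z}")
    if z == 1:
        return AssayQuality.IDEAL
    if z >= 0.5:
        return AssayQuality.EXCELLENT
    if z >= 0:
        return AssayQuality.MARGINAL
    return AssayQuality.OVERLAPPING


def select_evaluation_time(
    profile: QCProfile, z_m_min: float = 0.5
) -> float:
    """Evaluation timepoint: max Z_P among times with Z_M ≥ ``z_m_min``.

    Ties are broken toward the later time (later timepoints give the
    killing dynamics more room to separate treatments).
    """
    if not profile.times:
        raise ValidationError("empty QC profile")
    eligible = [
        (zp, t)
        for t, zm, zp in zip(profile.times, profile.z_m, profile.z_p)
        if zm >= z_m_min
    ]
    if not eligible:
        raise NoValidTimepointError(
            f"no timepoint with Z_M >= {z_m_min}"
        )
    best_zp = max(zp for zp, _ in eligible)
    return max(t for zp, t in eligible if zp == best_zp)
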