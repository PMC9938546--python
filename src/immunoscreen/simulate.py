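"""Synthetic plate-set generator for the tumor-immune co-culture screen.

The generator emulates the statistical structure the screen relies on:

* GFP-labeled cancer cells grow logistically in monoculture.
* Activated PBMCs kill cancer cells at a first-order rate ``k_imm``
  (modulated per donor), calibrated so that untreated co-culture
  viability at 72 h sits around 50-55% of the monoculture level.
* PBMC-only wells emit a near-constant background signal, since the
  effector cells carry no reporter.
* A compound can kill cancer cells directly (Hill-shaped rate with
  maximum ``d_max``) and/or potentiate immune killing (multiplying
  ``k_imm`` by up to ``1 + p_max``).
* Every observation carries independent multiplicative lognormal noise
  with a configurable coefficient of variation.

All randomness is driven by a single integer seed, so a given
configuration and layout reproduce bit-identical plate sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import LayoutError, ValidationError
from .plate_model import (
    UNTREATED,
    VEHICLE,
    Culture,
    PlateSet,
    SignalSeries,
    WellAnnotation,
    default_grid,
    format_well_label,
)

__all__ = [
    "SimulationConfig",
    "CompoundEffect",
    "integrate_well",
    "simulate_plateset",
    "make_screen_layout",
    "make_control_layout",
]

#: Baseline immune kill rate (per hour) calibrated once against the
#: noise-free model so untreated 1:1 co-culture viability at 72 h is
#: ~0.55 of monoculture (donor multipliers spread it over ~0.52-0.58).
DEFAULT_K_IMM = 0.0105

DEFAULT_DONOR_FACTORS: Mapping[str, float] = {"D1": 1.10, "D2": 0.92, "D3": 0.97}


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters for one simulated screen.

    Units: signal in arbitrary GFP units (AU), rates per hour, times in
    hours, concentrations in µM.
    """

    seed: int = 0
    g0: float = 1000.0
    r: float = 0.035
    K: float = 20_000.0
    pbmc_background: float = 50.0
    k_imm: float = DEFAULT_K_IMM
    donor_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DONOR_FACTORS)
    )
    noise_cv: float = 0.05
    dt: float = 0.5
    grid: tuple[float, ...] = tuple(default_grid())

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValidationError("growth rate r must be positive")
        if not (self.K > self.g0 > 0):
            raise ValidationError("need K > g0 > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        grid = np.asarray(self.grid, dtype=float)
        if len(grid) == 0 or grid[0] != 0 or np.any(np.diff(grid) <= 0):
            raise ValidationError("grid must start at 0 and increase")
        if len(grid) > 1 and self.dt > np.min(np.diff(grid)) + 1e-12:
            raise ValidationError("dt must not exceed the grid spacing")

    def donor_factor(self, donor_id: str) -> float:
        return float(self.donor_factors.get(donor_id, 1.0))


@dataclass(frozen=True)
class CompoundEffect:
    """Mechanistic drug action: direct kill and immune potentiation.

    ``d_max`` is the maximal direct kill rate (per hour) with Hill
    midpoint ``ec50_direct``; ``p_max`` the maximal fold-increase of the
    immune kill rate (0 for a non-potentiator) with midpoint
    ``ec50_pot``.
    """

    compound_id: str
    d_max: float = 0.0
    ec50_direct: float = 1.0
    p_max: float = 0.0
    ec50_pot: float = 1.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.d_max < 0 or self.p_max < 0:
            raise ValidationError("d_max and p_max must be >= 0")
        if self.ec50_direct <= 0 or self.ec50_pot <= 0:
            raise ValidationError("EC50 values must be positive")

    def direct_rate(self, conc: float) -> float:
        """Hill-shaped direct kill rate at concentration ``conc`` (µM)."""
        if conc <= 0:
            return 0.0
        ch = conc**self.hill
        return self.d_max * ch / (ch + self.ec50_direct**self.hill)

    def potentiation(self, conc: float) -> float:
        """Fold-multiplier on the immune kill rate (1 = no potentiation)."""
        if conc <= 0:
            return 1.0
        ch = conc**self.hill
        return 1.0 + self.p_max * ch / (ch + self.ec50_pot**self.hill)


INERT = CompoundEffect("inert")


def _ratio_scale(ratio: tuple[int, int] | None) -> float:
    # E:T hook: immune kill scales linearly with PBMC:cancer parts
    # relative to the 1:1 screen condition.
    if ratio is None:
        return 1.0
    cancer, pbmc = ratio
    return pbmc / cancer


def _effective_rates(
    config: SimulationConfig,
    effect: CompoundEffect | None,
    culture: Culture,
    concentration: float,
    donor_id: str,
    ratio: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """(direct drug kill rate, effective immune kill rate) for one well."""
    eff = effect or INERT
    d_drug = eff.direct_rate(concentration)
    if culture is Culture.COCULTURE:
        k_eff = (
            config.k_imm
            * config.donor_factor(donor_id)
            * _ratio_scale(ratio)
            * eff.potentiation(concentration)
        )
    else:
        k_eff = 0.0
    return d_drug, k_eff


def _integrate_batch(
    config: SimulationConfig, kill_rates: np.ndarray
) -> np.ndarray:
    """Euler-integrate logistic growth minus per-well kill rates.

    ``kill_rates`` has one total (drug + immune) rate per well; returns
    an array of shape (n_wells, n_gridpoints) sampled on ``config.grid``.
    """
    grid = np.asarray(config.grid, dtype=float)
    g = np.full(len(kill_rates), config.g0, dtype=float)
    out = np.empty((len(kill_rates), len(grid)))
    t = 0.0
    gi = 0
    if grid[0] == 0.0:
        out[:, 0] = g
        gi = 1
    while gi < len(grid):
        step = min(config.dt, grid[gi] - t)
        g = g + step * (config.r * g * (1 - g / config.K) - kill_rates * g)
        np.maximum(g, 0.0, out=g)
        t += step
        if abs(t - grid[gi]) < 1e-9:
            out[:, gi] = g
            gi += 1
    return out


def integrate_well(
    config: SimulationConfig,
    effect: CompoundEffect | None,
    culture: Culture | str,
    concentration: float = 0.0,
    donor_id: str = "",
    ratio: tuple[int, int] | None = None,
    plate_id: str = "SIM",
    well: str = "A01",
) -> SignalSeries:
    """Noise-free signal trace for a single well.

    Cancer-containing wells follow
    ``dG/dt = r G (1 - G/K) - (d_drug(c) + k_eff) G``; PBMC-only wells
    return the constant background level.
    """
    culture = Culture(culture)
    if concentration < 0:
        raise ValidationError("concentration must be >= 0")
    grid = np.asarray(config.grid, dtype=float)
    if culture is Culture.PBMC_MONO:
        values = np.full(len(grid), config.pbmc_background)
    else:
        d_drug, k_eff = _effective_rates(
            config, effect, culture, concentration, donor_id, ratio
        )
        values = _integrate_batch(config, np.array([d_drug + k_eff]))[0]
    return SignalSeries(plate_id=plate_id, well=well, times=grid, values=values)


def simulate_plateset(
    config: SimulationConfig,
    layout: Sequence[WellAnnotation],
    effects: Mapping[str, CompoundEffect] | None = None,
) -> PlateSet:
    """Simulate every well in ``layout`` and add multiplicative noise.

    Each observation is multiplied by an independent lognormal factor
    with mean 1 and coefficient of variation ``config.noise_cv``.
    Deterministic given ``config.seed``.
    """
    effects = effects or {}
    for ann in layout:
        if not ann.is_control and ann.treatment not in effects:
            raise KeyError(f"no CompoundEffect for compound {ann.treatment!r}")

    grid = np.asarray(config.grid, dtype=float)
    # Batch all cancer-containing wells through one vectorized Euler pass.
    cancer_wells = [a for a in layout if a.culture is not Culture.PBMC_MONO]
    rates = np.array(
        [
            sum(
                _effective_rates(
                    config,
                    effects.get(a.treatment),
                    a.culture,
                    a.concentration,
                    a.donor_id,
                    a.ratio,
                )
            )
            for a in cancer_wells
        ]
    )
    traces = (
        _integrate_batch(config, rates)
        if len(cancer_wells)
        else np.empty((0, len(grid)))
    )

    clean: dict[tuple[str, str], np.ndarray] = {}
    for ann, trace in zip(cancer_wells, traces):
        clean[ann.key] = trace
    for ann in layout:
        if ann.culture is Culture.PBMC_MONO:
            clean[ann.key] = np.full(len(grid), config.pbmc_background)

    rng = np.random.default_rng(config.seed)
    signals: dict[tuple[str, str], SignalSeries] = {}
    # Iterate in layout order so the noise stream is layout-stable.
    for ann in layout:
        values = clean[ann.key]
        if config.noise_cv > 0:
            sigma = np.sqrt(np.log1p(config.noise_cv**2))
            factors = rng.lognormal(
                mean=-(sigma**2) / 2, sigma=sigma, size=len(grid)
            )
            values = values * factors
        signals[ann.key] = SignalSeries(
            plate_id=ann.plate_id, well=ann.well, times=grid, values=values
        )
    return PlateSet(annotations={a.key: a for a in layout}, signals=signals)


def make_screen_layout(
    n_compounds: int,
    n_controls: int = 16,
    ratio: tuple[int, int] = (1, 1),
    donors: Sequence[str] = ("D1",),
    concentration: float = 10.0,
    compound_ids: Sequence[str] | None = None,
    plate_format: int = 384,
) -> list[WellAnnotation]:
    """Single-dose screen layout: paired mono/co-culture wells per compound.

    For each compound, one CANCER_MONO and one COCULTURE well at the
    screening dose (default 10 µM).  Each culture type additionally gets
    ``n_controls`` control wells, split evenly between vehicle and
    untreated.  Wells are assigned row-major; layouts exceeding one
    plate spill onto plates "P2", "P3", ...
    """
    if n_compounds < 0 or n_controls < 0:
        raise ValidationError("counts must be >= 0")
    if n_compounds > 0 and n_controls > 0 and n_controls < 2:
        raise LayoutError("need at least 2 control wells per culture type")
    if compound_ids is None:
        width = max(3, len(str(max(n_compounds, 1))))
        compound_ids = [f"C{i + 1:0{width}d}" for i in range(n_compounds)]
    elif len(compound_ids) != n_compounds:
        raise ValidationError("compound_ids length must equal n_compounds")

    capacity = 384 if plate_format == 384 else 96
    n_cols = 24 if plate_format == 384 else 12
    counter = 0

    def next_well() -> tuple[str, str]:
        nonlocal counter
        plate = counter // capacity + 1
        idx = counter % capacity
        counter += 1
        return f"P{plate}", format_well_label(idx // n_cols, idx % n_cols)

    donors = list(donors)
    if not donors:
        raise ValidationError("at least one donor required")
    layout: list[WellAnnotation] = []

    # Controls first (row-major block), per culture type.
    n_vehicle = (n_controls + 1) // 2
    for culture in (Culture.CANCER_MONO, Culture.PBMC_MONO, Culture.COCULTURE):
        for i in range(n_controls):
            plate, well = next_well()
            treatment = VEHICLE if i < n_vehicle else UNTREATED
            donor = "" if culture is Culture.CANCER_MONO else donors[i % len(donors)]
            layout.append(
                WellAnnotation(
                    plate_id=plate,
                    well=well,
                    culture=culture,
                    treatment=treatment,
                    concentration=0.0,
                    donor_id=donor,
                    ratio=ratio if culture is Culture.COCULTURE else None,
                    plate_format=plate_format,
                )
            )

    for i, cid in enumerate(compound_ids):
        donor = donors[i % len(donors)]
        plate, well = next_well()
        layout.append(
            WellAnnotation(
                plate_id=plate,
                well=well,
                culture=Culture.CANCER_MONO,
                treatment=cid,
                concentration=concentration,
                donor_id="",
                ratio=None,
                plate_format=plate_format,
            )
        )
        plate, well = next_well()
        layout.append(
            WellAnnotation(
                plate_id=plate,
                well=well,
                culture=Culture.COCULTURE,
                treatment=cid,
                concentration=concentration,
                donor_id=donor,
                ratio=ratio,
                plate_format=plate_format,
            )
        )
    return layout


def make_control_layout(
    wells_per_group: int = 64,
    ratio: tuple[int, int] = (1, 1),
    donors: Sequence[str] = ("D1",),
) -> list[WellAnnotation]:
    """Untreated-controls-only layout for QC profiling.

    ``wells_per_group`` untreated wells for each of the three culture
    types; the default 64 matches a full QC run of the screen.
    """
    layout = make_screen_layout(
        n_compounds=0, n_controls=2 * wells_per_group, ratio=ratio, donors=donors
    )
    return layout
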