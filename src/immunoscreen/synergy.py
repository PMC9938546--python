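"""Bliss immunopotentiation scoring and screen operating characteristics.

Under Bliss independence, two agents that do not interact satisfy
V₁₊₂ = V₁·V₂ on surviving fractions.  Treating the activated PBMCs as
"drug 2", a compound's immunopotentiation score is

    B = V_drug(mono) · V_PBMC − V_drug+PBMC(co-culture)

with every viability expressed relative to the untreated cancer
monoculture.  B > 0 means the combination kills more cancer cells than
independent action predicts — the compound potentiates immune killing.
B isolates potentiation: a purely cytotoxic compound depresses the
mono and co-culture terms proportionally and scores ~0.

The operating-characteristics layer runs whole simulated screens with
planted potentiators to measure how reliably top-N Bliss ranking
recovers them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import PairingError, ValidationError
from .plate_model import Culture, PlateSet
from .simulate import (
    CompoundEffect,
    SimulationConfig,
    make_screen_layout,
    simulate_plateset,
)
from .viability import Baseline, compute_viability

__all__ = [
    "BlissRecord",
    "ScreenOCResult",
    "bliss_score",
    "score_screen",
    "rank_hits",
    "screen_operating_characteristics",
]


@dataclass(frozen=True)
class BlissRecord:
    """Per-compound viabilities and Bliss score; rank filled by ranking."""

    compound_id: str
    v_drug_mono: float
    v_pbmc: float
    v_combination: float
    bliss_score: float
    rank: int = 0

    def __post_init__(self) -> None:
        expected = self.v_drug_mono * self.v_pbmc - self.v_combination
        if abs(self.bliss_score - expected) > 1e-12:
            raise ValidationError("bliss_score inconsistent with viabilities")


@dataclass(frozen=True)
class ScreenOCResult:
    """Sensitivity / false-discovery of top-N hit calling over replicates."""

    n_compounds: int
    n_planted: int
    top_n: int
    sensitivity: float
    false_discovery: float
    replicates: int
    per_replicate_sensitivity: tuple[float, ...]
    per_replicate_fdr: tuple[float, ...]

    @property
    def sensitivity_sd(self) -> float:
        vals = np.array(self.per_replicate_sensitivity)
        return float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def bliss_score(
    v_drug_mono: float, v_pbmc: float, v_combination: float
) -> float:
    """B = v_drug_mono · v_pbmc − v_combination.

    Positive B indicates synergy (the combination is more lethal than
    independence predicts), zero independence, negative antagonism.
    """
    for name, v in (
        ("v_drug_mono", v_drug_mono),
        ("v_pbmc", v_pbmc),
        ("v_combination", v_combination),
    ):
        if v < 0 or np.isnan(v):
            raise ValidationError(f"{name} must be >= 0, got {v}")
    return v_drug_mono * v_pbmc - v_combination


def score_screen(plateset: PlateSet, time: float = 72.0) -> list[BlissRecord]:
    """Bliss-score every compound on the plate set at ``time``.

    All three viabilities entering B use the untreated cancer
    monoculture as denominator, so the PBMC single-agent term
    v_pbmc = mean(untreated co-culture) / mean(untreated monoculture)
    is itself a viability under the same baseline.  Replicate wells of
    a compound are averaged before scoring (score of means).
    """
    records = compute_viability(
        plateset, time=time, baseline=Baseline.MONOCULTURE
    )
    untreated_co = [
        r.viability
        for r in records
        if r.culture is Culture.COCULTURE and r.compound_id == "UNTREATED"
    ]
    if not untreated_co:
        raise PairingError("no untreated co-culture wells for the PBMC term")
    v_pbmc = float(np.mean(untreated_co))

    mono: dict[str, list[float]] = {}
    combo: dict[str, list[float]] = {}
    for r in records:
        if r.compound_id in ("UNTREATED", "VEHICLE"):
            continue
        bucket = mono if r.culture is Culture.CANCER_MONO else combo
        bucket.setdefault(r.compound_id, []).append(r.viability)

    out = []
    for cid in sorted(set(mono) | set(combo)):
        if cid not in mono or cid not in combo:
            missing = "monoculture" if cid not in mono else "co-culture"
            raise PairingError(f"compound {cid!r} lacks its {missing} well")
        v1 = float(np.mean(mono[cid]))
        v12 = float(np.mean(combo[cid]))
        out.append(
            BlissRecord(
                compound_id=cid,
                v_drug_mono=v1,
                v_pbmc=v_pbmc,
                v_combination=v12,
                bliss_score=bliss_score(v1, v_pbmc, v12),
            )
        )
    return out


def rank_hits(
    records: Sequence[BlissRecord], top_n: int = 25
) -> list[BlissRecord]:
    """Top-``top_n`` compounds by descending Bliss score.

    Ties break by ascending combination viability (deader is better),
    then lexicographic compound id.  Returned records carry 1-based
    ranks.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    if not records:
        raise ValidationError("no records to rank")
    ordered = sorted(
        records,
        key=lambda r: (-r.bliss_score, r.v_combination, r.compound_id),
    )
    return [
        replace(r, rank=i) for i, r in enumerate(ordered[:top_n], start=1)
    ]


def screen_operating_characteristics(
    config: SimulationConfig,
    n_compounds: int = 320,
    frac_potentiators: float = 0.05,
    effect_grid: Sequence[float] = (3.0,),
    top_n: int = 25,
    replicates: int = 50,
    seed: int = 7,
    time: float = 72.0,
    frac_cytotoxic: float = 0.0,
    d_max_cytotoxic: float = 0.03,
) -> ScreenOCResult:
    """Sensitivity and false discovery of top-N Bliss hit calling.

    Each replicate simulates a fresh single-dose screen in which
    ``frac_potentiators`` of the compounds are planted immune
    potentiators (``p_max`` cycled through ``effect_grid``); the rest
    are inert unless ``frac_cytotoxic`` plants direct cytotoxins among
    them.  Planted identities are shuffled per replicate.  Deterministic
    given ``seed``.
    """
    if n_compounds < 1 or replicates < 1:
        raise ValidationError("n_compounds and replicates must be positive")
    if not (0 < frac_potentiators < 1):
        raise ValidationError("frac_potentiators must lie in (0, 1)")
    n_planted = max(1, round(frac_potentiators * n_compounds))

    master = np.random.default_rng(seed)
    sens, fdr = [], []
    for _ in range(replicates):
        rep_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        ids = [f"C{i + 1:04d}" for i in range(n_compounds)]
        planted = set(rng.choice(ids, size=n_planted, replace=False))
        remaining = [c for c in ids if c not in planted]
        n_tox = round(frac_cytotoxic * len(remaining))
        toxic = set(rng.choice(remaining, size=n_tox, replace=False)) if n_tox else set()

        effects: dict[str, CompoundEffect] = {}
        grid_iter = 0
        for cid in ids:
            if cid in planted:
                p_max = float(effect_grid[grid_iter % len(effect_grid)])
                grid_iter += 1
                effects[cid] = CompoundEffect(cid, p_max=p_max)
            elif cid in toxic:
                effects[cid] = CompoundEffect(
                    cid, d_max=float(rng.uniform(0, d_max_cytotoxic))
                )
            else:
                effects[cid] = CompoundEffect(cid)

        layout = make_screen_layout(n_compounds, compound_ids=ids)
        rep_config = replace(config, seed=rep_seed)
        plates = simulate_plateset(rep_config, layout, effects)
        hits = rank_hits(score_screen(plates, time=time), top_n=top_n)
        hit_ids = {h.compound_id for h in hits}
        recovered = len(hit_ids & planted)
        sens.append(recovered / n_planted)
        fdr.append(1 - recovered / len(hit_ids) if hit_ids else 0.0)

    return ScreenOCResult(
        n_compounds=n_compounds,
        n_planted=n_planted,
        top_n=top_n,
        sensitivity=float(np.mean(sens)),
        false_discovery=float(np.mean(fdr)),
        replicates=replicates,
        per_replicate_sensitivity=tuple(sens),
        per_replicate_fdr=tuple(fdr),
    )
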