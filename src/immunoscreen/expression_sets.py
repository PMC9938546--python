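"""Differential-expression set logic on fold-change tables.

Works on signed linear fold changes (the microarray-console
convention: +2 means doubled, −2 means halved; the open interval
(−1, 1) is not representable).  A gene is differentially expressed
(DEG) when |fold change| meets a threshold, 2 by default.  The module
then supports the set operations used to summarize multi-condition
experiments: per-condition DEG sets, common genes across conditions
(optionally direction-aware), genes unique to one condition, and
2- or 3-way Venn region counts.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DuplicationError, ValidationError
from .plate_model import Culture

__all__ = [
    "Direction",
    "FoldChangeRecord",
    "DEGSet",
    "read_fold_changes",
    "deg_select",
    "common_degs",
    "unique_degs",
    "venn_counts",
]


class Direction(str, enum.Enum):
    ANY = "ANY"
    UP = "UP"
    DOWN = "DOWN"
    CONCORDANT = "CONCORDANT"


@dataclass(frozen=True)
class FoldChangeRecord:
    """Gene-level signed linear fold change for one culture/dose condition."""

    gene: str
    culture: Culture
    dose: float
    fold_change: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("empty gene symbol")
        if -1 < self.fold_change < 1:
            raise ValidationError(
                f"{self.gene}: signed linear fold change cannot lie in "
                f"(-1, 1), got {self.fold_change}"
            )

    @property
    def condition(self) -> str:
        return condition_label(self.culture, self.dose)


def condition_label(culture: Culture | str, dose: float) -> str:
    return f"{Culture(culture).value}@{dose:g}uM"


@dataclass(frozen=True)
class DEGSet:
    """Up/down-regulated gene sets for one condition label."""

    condition: str
    genes_up: frozenset[str] = frozenset()
    genes_down: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes_up", frozenset(self.genes_up))
        object.__setattr__(self, "genes_down", frozenset(self.genes_down))
        overlap = self.genes_up & self.genes_down
        if overlap:
            raise ValidationError(
                f"{self.condition}: genes both up and down: {sorted(overlap)}"
            )

    def select(self, direction: Direction | str) -> frozenset[str]:
        """Genes selected under a direction rule (CONCORDANT = ANY here)."""
        direction = Direction(direction)
        if direction is Direction.UP:
            return self.genes_up
        if direction is Direction.DOWN:
            return self.genes_down
        return self.genes_up | self.genes_down

    def direction_of(self, gene: str) -> Direction | None:
        if gene in self.genes_up:
            return Direction.UP
        if gene in self.genes_down:
            return Direction.DOWN
        return None

    def __len__(self) -> int:
        return len(self.genes_up) + len(self.genes_down)


def read_fold_changes(path, log2: bool = False) -> list[FoldChangeRecord]:
    """Read a TSV with columns gene, culture, dose_uM, fold_change.

    With ``log2=True`` the fold_change column holds log2 ratios and is
    converted to the signed linear convention.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "culture": str})
    required = ["gene", "culture", "dose_uM", "fold_change"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"fold-change table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        fc = float(row.fold_change)
        if log2:
            linear = 2.0**fc
            fc = linear if linear >= 1 else -1.0 / linear
        records.append(
            FoldChangeRecord(
                gene=row.gene,
                culture=Culture(row.culture),
                dose=float(row.dose_uM),
                fold_change=fc,
            )
        )
    return records


def deg_select(
    records: Iterable[FoldChangeRecord], threshold: float = 2.0
) -> dict[str, DEGSet]:
    """Per-condition DEG sets at a fold-change threshold.

    A gene is up if fold_change ≥ threshold, down if ≤ −threshold;
    everything in between is excluded.  The boundary is inclusive: on
    continuous data "fold change > 2" and "≥ 2" coincide except on a
    measure-zero set, and the closed rule is stable under rounding.
    """
    if threshold <= 1:
        raise ValidationError("threshold must exceed 1")
    seen: set[tuple[str, str]] = set()
    ups: dict[str, set[str]] = {}
    downs: dict[str, set[str]] = {}
    for rec in records:
        key = (rec.gene, rec.condition)
        if key in seen:
            raise DuplicationError(
                f"duplicate fold-change row for gene {rec.gene!r} in "
                f"condition {rec.condition}"
            )
        seen.add(key)
        ups.setdefault(rec.condition, set())
        downs.setdefault(rec.condition, set())
        if rec.fold_change >= threshold:
            ups[rec.condition].add(rec.gene)
        elif rec.fold_change <= -threshold:
            downs[rec.condition].add(rec.gene)
    return {
        cond: DEGSet(cond, frozenset(ups[cond]), frozenset(downs[cond]))
        for cond in ups
    }


def common_degs(
    sets: Sequence[DEGSet], direction: Direction | str = Direction.ANY
) -> frozenset[str]:
    """Genes selected in every set under the direction rule.

    CONCORDANT additionally requires the same direction in every set
    (a gene up in one condition and down in another is dropped).
    """
    direction = Direction(direction)
    if len(sets) < 2:
        raise ValidationError("common_degs needs >= 2 sets")
    common = frozenset.intersection(*(s.select(direction) for s in sets))
    if direction is Direction.CONCORDANT:
        common = frozenset(
            g
            for g in common
            if len({s.direction_of(g) for s in sets}) == 1
        )
    return common


def unique_degs(
    target: DEGSet,
    others: Sequence[DEGSet],
    direction: Direction | str = Direction.ANY,
) -> frozenset[str]:
    """Genes selected in ``target`` and entirely absent from every other set.

    "Absent" means not differentially expressed in any direction — a
    gene down elsewhere is not unique here.
    """
    if not others:
        raise ValidationError("unique_degs needs >= 1 other set")
    selected = target.select(direction)
    for other in others:
        selected = selected - other.select(Direction.ANY)
    return frozenset(selected)


def venn_counts(
    sets: Sequence[DEGSet], direction: Direction | str = Direction.ANY
) -> dict[frozenset[str], int]:
    """Disjoint-region counts of a 2- or 3-way Venn diagram.

    Keys are frozensets of condition labels naming each region (e.g.
    ``{A}``, ``{A, B}``); counts cover every nonempty membership
    pattern, including zero-count regions.  For ANY/UP/DOWN, region
    counts sum to the union size.  For CONCORDANT, genes whose
    direction differs across the sets containing them are excluded
    from the diagram entirely.
    """
    direction = Direction(direction)
    if not 2 <= len(sets) <= 3:
        raise ValidationError("venn_counts supports 2 or 3 sets")
    labels = [s.condition for s in sets]
    if len(set(labels)) != len(labels):
        raise ValidationError("condition labels must be distinct")

    membership: dict[str, frozenset[str]] = {}
    base = Direction.ANY if direction is Direction.CONCORDANT else direction
    for s in sets:
        for g in s.select(base):
            membership[g] = membership.get(g, frozenset()) | {s.condition}

    if direction is Direction.CONCORDANT:
        by_label = {s.condition: s for s in sets}
        membership = {
            g: labs
            for g, labs in membership.items()
            if len({by_label[l].direction_of(g) for l in labs}) == 1
        }

    counts: dict[frozenset[str], int] = {
        frozenset(combo): 0
        for k in range(1, len(labels) + 1)
        for combo in itertools.combinations(labels, k)
    }
    for labs in membership.values():
        counts[labs] += 1
    return counts
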