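"""End-to-end screen analysis: simulate/load -> QC -> viability -> rank.

``run_pipeline`` wires the stages together behind one config object
and writes a reproducible report bundle (QC TSV, viability TSV,
ranked-hit TSV, JSON manifest).  Identical config + seed produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .assay_qc import classify_assay, qc_profile, select_evaluation_time
from .errors import ValidationError
from .plate_model import (
    PlateSet,
    build_plateset,
    read_plate_map,
    read_signals,
)
from .simulate import (
    CompoundEffect,
    SimulationConfig,
    make_screen_layout,
    simulate_plateset,
)
from .synergy import rank_hits, score_screen
from .viability import Baseline, compute_viability

logger = logging.getLogger("immunoscreen")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either ``map_path``/``signals_path`` point at existing files, or
    ``simulate`` is true and a screen is generated from the embedded
    scenario parameters.
    """

    out_dir: str = "results"
    map_path: str | None = None
    signals_path: str | None = None
    simulate: bool = False
    seed: int = 0
    n_compounds: int = 320
    frac_potentiators: float = 0.05
    p_max: float = 3.0
    noise_cv: float = 0.05
    evaluation_time: float = 72.0
    z_m_min: float = 0.5
    top_n: int = 25
    baseline_control: str = "VEHICLE"

    def validate(self) -> None:
        if not self.simulate:
            for label, p in (("map", self.map_path), ("signals", self.signals_path)):
                if p is None or not Path(p).exists():
                    raise ValidationError(f"{label} file missing: {p}")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _planted_effects(config: PipelineConfig) -> dict[str, CompoundEffect]:
    rng = np.random.default_rng(config.seed)
    ids = [f"C{i + 1:04d}" for i in range(config.n_compounds)]
    n_planted = max(1, round(config.frac_potentiators * config.n_compounds))
    planted = set(rng.choice(ids, size=n_planted, replace=False))
    return {
        cid: CompoundEffect(cid, p_max=config.p_max if cid in planted else 0.0)
        for cid in ids
    }


def _load_or_simulate(config: PipelineConfig) -> PlateSet:
    if config.simulate:
        sim = SimulationConfig(seed=config.seed, noise_cv=config.noise_cv)
        layout = make_screen_layout(
            config.n_compounds,
            compound_ids=sorted(_planted_effects(config)),
        )
        return simulate_plateset(sim, layout, _planted_effects(config))
    annotations = read_plate_map(config.map_path)
    signals = read_signals(config.signals_path)
    return build_plateset(annotations, signals)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run QC, viability and Bliss ranking; write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``) with
    the config hash, selected/used evaluation time and output paths.
    If the QC-selected timepoint differs from the configured
    evaluation time, the configured value wins and a warning is logged.
    """
    config.validate()
    grid_check = config.evaluation_time
    plates = _load_or_simulate(config)
    if not np.any(np.isclose(plates.grid, grid_check)):
        raise ValidationError(
            f"evaluation_time {grid_check} h is not on the signal grid"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    profile = qc_profile(plates)
    qc_df = pd.DataFrame(
        {
            "time_h": profile.times,
            "z_m": profile.z_m,
            "z_p": profile.z_p,
            "category_m": [classify_assay(min(z, 1.0)).value for z in profile.z_m],
            "category_p": [classify_assay(min(z, 1.0)).value for z in profile.z_p],
        }
    )
    qc_path = out / "qc.tsv"
    qc_df.to_csv(qc_path, sep="\t", index=False, float_format="%.6g")

    selected = select_evaluation_time(profile, z_m_min=config.z_m_min)
    if selected != config.evaluation_time:
        logger.warning(
            "QC-selected timepoint %.0f h differs from configured %.0f h; "
            "using the configured value",
            selected,
            config.evaluation_time,
        )

    via = compute_viability(
        plates,
        time=config.evaluation_time,
        baseline=Baseline.OWN_CULTURE,
        control_kind=config.baseline_control,
    )
    via_df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "culture": r.culture.value,
                "concentration_uM": r.concentration,
                "donor_id": r.donor_id,
                "time_h": r.time,
                "viability": r.viability,
            }
            for r in via
        ]
    ).sort_values(["compound_id", "culture", "donor_id"])
    via_path = out / "viability.tsv"
    via_df.to_csv(via_path, sep="\t", index=False, float_format="%.6g")

    hits = rank_hits(
        score_screen(plates, time=config.evaluation_time), top_n=config.top_n
    )
    hits_df = pd.DataFrame(
        [
            {
                "rank": h.rank,
                "compound_id": h.compound_id,
                "v_drug_mono": h.v_drug_mono,
                "v_pbmc": h.v_pbmc,
                "v_combination": h.v_combination,
                "bliss_score": h.bliss_score,
            }
            for h in hits
        ]
    )
    hits_path = out / "hits.tsv"
    hits_df.to_csv(hits_path, sep="\t", index=False, float_format="%.6g")

    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "evaluation_time_h": config.evaluation_time,
        "qc_selected_time_h": selected,
        "n_wells": len(plates.annotations),
        "n_compounds_scored": len(set(h.compound_id for h in hits)),
        "outputs": {
            "qc": str(qc_path),
            "viability": str(via_path),
            "hits": str(hits_path),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
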