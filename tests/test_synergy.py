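"""Bliss scoring, hit ranking, and screen operating characteristics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoscreen import (
    BlissRecord,
    CompoundEffect,
    Culture,
    SimulationConfig,
    bliss_score,
    make_screen_layout,
    rank_hits,
    score_screen,
    screen_operating_characteristics,
    simulate_plateset,
)
from immunoscreen.errors import PairingError, ValidationError

NOISELESS = SimulationConfig(seed=0, noise_cv=0.0)

fractions = st.floats(0, 2, allow_nan=False)


class TestBlissScore:
    def test_inert_drug_independence(self):
        assert bliss_score(1.0, 0.55, 0.55) == pytest.approx(0.0, abs=1e-12)

    def test_pitavastatin_worked_example(self):
        """Mono 28%, PBMC-alone 55%, combination 11% -> B = 0.044."""
        assert bliss_score(0.28, 0.55, 0.11) == pytest.approx(0.044, abs=1e-12)

    @given(v1=fractions, v2=fractions)
    def test_independence_identity(self, v1, v2):
        """B = 0 exactly when the combination equals the product."""
        assert bliss_score(v1, v2, v1 * v2) == pytest.approx(0.0, abs=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            bliss_score(-0.1, 0.5, 0.5)


class TestScoreScreen:
    def test_matches_hand_computation(self, noisefree_plates):
        """Scores on the 3-compound toy plate equal hand-derived B."""
        grid_time = 72.0
        mono_ctrl = np.mean([
            noisefree_plates.signal(w).at(grid_time)
            for w in noisefree_plates.wells(Culture.CANCER_MONO, "UNTREATED")
        ])
        co_ctrl = np.mean([
            noisefree_plates.signal(w).at(grid_time)
            for w in noisefree_plates.wells(Culture.COCULTURE, "UNTREATED")
        ])
        v_pbmc = co_ctrl / mono_ctrl
        records = {r.compound_id: r for r in score_screen(noisefree_plates)}
        for cid in ("cytotox", "potentiator", "inert"):
            mono = next(
                a for a in noisefree_plates.wells(Culture.CANCER_MONO, cid)
            )
            co = next(a for a in noisefree_plates.wells(Culture.COCULTURE, cid))
            v1 = noisefree_plates.signal(mono).at(grid_time) / mono_ctrl
            v12 = noisefree_plates.signal(co).at(grid_time) / mono_ctrl
            expected = v1 * v_pbmc - v12
            assert records[cid].bliss_score == pytest.approx(expected, abs=1e-12)
            assert records[cid].v_pbmc == pytest.approx(v_pbmc, rel=1e-12)

    def test_inert_compound_scores_zero(self, noisefree_plates):
        records = {r.compound_id: r for r in score_screen(noisefree_plates)}
        assert records["inert"].bliss_score == pytest.approx(0.0, abs=1e-12)

    def test_pure_cytotoxin_scores_near_zero(self, noisefree_plates):
        """Direct kill hits mono and co-culture near-proportionally.

        Bliss multiplicativity is exact only for log-linear kinetics;
        logistic saturation leaves a small positive residual, an order
        of magnitude below a genuine potentiator's score.
        """
        records = {r.compound_id: r for r in score_screen(noisefree_plates)}
        b_tox = records["cytotox"].bliss_score
        b_pot = records["potentiator"].bliss_score
        assert abs(b_tox) < 0.02
        assert abs(b_tox) < 0.05 * b_pot

    def test_cytotoxin_residual_shrinks_in_log_linear_regime(self):
        """Raising K toward the exponential regime collapses the
        cytotoxin's Bliss residual toward the discretization floor."""
        layout = make_screen_layout(1, n_controls=4, compound_ids=["tox"])
        effects = {"tox": CompoundEffect("tox", d_max=0.03, ec50_direct=2.0)}
        residuals = []
        for K in (2e4, 2e6):
            config = SimulationConfig(seed=0, noise_cv=0.0, K=K)
            plates = simulate_plateset(config, layout, effects)
            residuals.append(abs(score_screen(plates)[0].bliss_score))
        assert residuals[1] < residuals[0] / 5
        assert residuals[1] < 2e-3

    def test_pure_potentiator_scores_positive(self, noisefree_plates):
        records = {r.compound_id: r for r in score_screen(noisefree_plates)}
        assert records["potentiator"].bliss_score > 0.1

    def test_monotone_in_p_max(self):
        layout = make_screen_layout(1, n_controls=4, compound_ids=["x"])
        scores = []
        for p_max in (0.0, 0.5, 1.5, 3.0):
            plates = simulate_plateset(
                NOISELESS, layout, {"x": CompoundEffect("x", p_max=p_max)}
            )
            scores.append(score_screen(plates)[0].bliss_score)
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_scale_invariance(self, noisy_plates):
        base = score_screen(noisy_plates)
        scaled = score_screen(noisy_plates.scaled(7.0))
        for a, b in zip(base, scaled):
            assert b.bliss_score == pytest.approx(a.bliss_score, rel=1e-9, abs=1e-12)

    def test_missing_pair_named(self, noisefree_plates):
        from immunoscreen import PlateSet

        pruned = {
            k: v
            for k, v in noisefree_plates.annotations.items()
            if not (v.treatment == "cytotox" and v.culture is Culture.COCULTURE)
        }
        subset = PlateSet(
            annotations=pruned,
            signals={k: noisefree_plates.signals[k] for k in pruned},
        )
        with pytest.raises(PairingError, match="cytotox"):
            score_screen(subset)


def _record(cid, b, v12=0.5):
    return BlissRecord(
        compound_id=cid,
        v_drug_mono=1.0,
        v_pbmc=1.0,
        v_combination=v12,
        bliss_score=1.0 - v12 if b is None else b,
    )


class TestRankHits:
    def _make(self, cid, b, v12):
        # construct a consistent record with the desired (b, v12)
        return BlissRecord(cid, v12 + b, 1.0, v12, b)

    def test_tie_breaks_by_combination_viability(self):
        records = [
            self._make("a", 0.3, 0.2),
            self._make("b", 0.1, 0.5),
            self._make("c", 0.3, 0.1),
        ]
        ranked = rank_hits(records, top_n=3)
        assert [r.compound_id for r in ranked] == ["c", "a", "b"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_top_n_larger_than_n(self):
        records = [self._make("a", 0.2, 0.1), self._make("b", 0.1, 0.1)]
        assert len(rank_hits(records, top_n=10)) == 2

    def test_final_tie_lexicographic(self):
        records = [self._make(c, 0.2, 0.3) for c in ("z", "m", "a")]
        ranked = rank_hits(records, top_n=3)
        assert [r.compound_id for r in ranked] == ["a", "m", "z"]

    def test_invalid_top_n(self):
        with pytest.raises(ValidationError):
            rank_hits([self._make("a", 0.1, 0.1)], top_n=0)


class TestOperatingCharacteristics:
    def test_noiseless_recovery_is_perfect(self):
        res = screen_operating_characteristics(
            SimulationConfig(noise_cv=0.0),
            n_compounds=60,
            frac_potentiators=0.1,
            top_n=6,
            replicates=2,
            seed=3,
        )
        assert res.sensitivity == 1.0
        assert res.false_discovery == 0.0

    def test_null_planting_matches_random_ranking(self):
        """With p_max=0 'planted' compounds, recovery is chance-level.

        Oracle: a random permutation puts top_n/n of any fixed subset
        in the top n on average.
        """
        res = screen_operating_characteristics(
            SimulationConfig(noise_cv=0.05),
            n_compounds=100,
            frac_potentiators=0.05,
            effect_grid=(0.0,),
            top_n=25,
            replicates=200,
            seed=5,
        )
        expected = 25 / 100
        se = np.std(res.per_replicate_sensitivity) / np.sqrt(res.replicates)
        assert res.sensitivity == pytest.approx(expected, abs=max(4 * se, 0.05))

    def test_deterministic_given_seed(self):
        kwargs = dict(
            n_compounds=40, frac_potentiators=0.1, top_n=4, replicates=3, seed=9
        )
        a = screen_operating_characteristics(SimulationConfig(), **kwargs)
        b = screen_operating_characteristics(SimulationConfig(), **kwargs)
        assert a.per_replicate_sensitivity == b.per_replicate_sensitivity
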