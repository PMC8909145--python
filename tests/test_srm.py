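"""Two-stage CE schedules, ranking, curation, and panel assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neosrm.chem import heavy_peptide
from neosrm.srm import (
    CE_FLOOR,
    SrmError,
    build_panel,
    curate_matrix,
    make_transitions,
    optimize_stage2,
    rank_stage1,
    read_transition_list,
    schedule_table,
    stage1_grid,
    stage2_grid,
    theoretical_ce,
    write_transition_list,
)

from conftest import mhc_length_sequences


# build a transition at a chosen theoretical CE by overriding the CE model
def _one_transition(ce, target="T"):
    t = make_transitions(target, "VVGAVGVGK", (2,), ce_params={2: (0.0, ce)})[0]
    assert t.ce == ce
    return t


class TestTheoreticalCe:
    def test_linear_model(self):
        assert theoretical_ce(500.0, 2, {2: (0.031, 1.0)}) == pytest.approx(16.5)

    def test_degenerate_model_is_constant(self):
        for mz in (100.0, 500.0, 1400.0):
            assert theoretical_ce(mz, 2, {2: (0.0, 20.0)}) == 20.0

    def test_floor(self):
        assert theoretical_ce(0.0, 2, {2: (0.031, 0.0)}) == CE_FLOOR

    def test_missing_charge_is_configuration_error(self):
        with pytest.raises(SrmError, match="charge 4"):
            theoretical_ce(500.0, 4)


class TestCeGrids:
    def test_stage1_values(self):
        assert stage1_grid(_one_transition(20.0)).ce_values == (15.0, 20.0, 25.0)

    def test_stage1_clamped_at_floor(self):
        assert stage1_grid(_one_transition(5.0)).ce_values == (2.0, 5.0, 10.0)

    def test_stage2_values(self):
        assert stage2_grid(_one_transition(20.0)).ce_values == (
            12.0, 14.0, 16.0, 18.0, 20.0, 22.0, 24.0, 26.0, 28.0,
        )

    @given(seq=mhc_length_sequences, ce=st.floats(10.0, 60.0))
    @settings(max_examples=100, derandomize=True)
    def test_grid_cardinality_and_symmetry(self, seq, ce):
        """Stage 1 has 3 points symmetric about the theoretical CE; stage 2
        has 9 points at exact 2 eV spacing, for any transition."""
        t = make_transitions("T", seq, (2,), ce_params={2: (0.0, ce)})[0]
        g1, g2 = stage1_grid(t).ce_values, stage2_grid(t).ce_values
        assert len(g1) == 3
        assert g1[1] - g1[0] == pytest.approx(g1[2] - g1[1]) == pytest.approx(5.0)
        assert len(g2) == 9
        assert all(b - a == pytest.approx(2.0) for a, b in zip(g2, g2[1:]))
        assert g2[4] == pytest.approx(t.ce)


def _measurements(rows):
    return pd.DataFrame(
        rows, columns=["target_id", "transition_key", "ce", "intensity", "is_blank", "replicate"]
    )


class TestRankStage1:
    def test_higher_max_intensity_ranks_first(self):
        transitions = make_transitions("T", heavy_peptide("VVGAVGVGK"), (2,))
        k1, k2 = transitions[0].key, transitions[1].key
        rows = [
            ("T", k1, 15.0, 50.0, False, 1),
            ("T", k1, 20.0, 100.0, False, 1),
            ("T", k2, 20.0, 70.0, False, 1),
        ]
        ranked = rank_stage1(_measurements(rows), transitions)
        assert list(ranked["transition_key"][:2]) == [k1, k2]

    def test_top_twenty_advance_per_charge(self):
        transitions = make_transitions("T", heavy_peptide("VVVGAVGVGLLK"), (2,))
        assert len(transitions) == 22  # 2 * (12 - 1) singly charged b/y
        rows = [("T", t.key, t.ce, 100.0 + i, False, 1) for i, t in enumerate(transitions)]
        ranked = rank_stage1(_measurements(rows), transitions)
        assert len(ranked) == 20
        assert set(ranked["precursor_charge"]) == {2}

    def test_ties_break_toward_high_mz_y_low_ordinal(self):
        transitions = make_transitions("T", heavy_peptide("VVGAVGVGK"), (2,))
        rows = [("T", t.key, t.ce, 100.0, False, 1) for t in transitions]
        ranked = rank_stage1(_measurements(rows), transitions)
        mz = list(ranked["product_mz"])
        assert mz == sorted(mz, reverse=True)

    def test_auc_scoring_flag(self):
        """AUC scoring can rank a broad weak response above a narrow
        spike that wins on max intensity."""
        transitions = make_transitions("T", heavy_peptide("VVGAVGVGK"), (2,))
        k1, k2 = transitions[0].key, transitions[1].key
        rows = [
            ("T", k1, 15.0, 0.0, False, 1),
            ("T", k1, 20.0, 100.0, False, 1),
            ("T", k1, 25.0, 0.0, False, 1),
            ("T", k2, 15.0, 80.0, False, 1),
            ("T", k2, 20.0, 80.0, False, 1),
            ("T", k2, 25.0, 80.0, False, 1),
        ]
        by_max = rank_stage1(_measurements(rows), transitions)
        by_auc = rank_stage1(_measurements(rows), transitions, score="auc")
        assert by_max.loc[0, "transition_key"] == k1
        assert by_auc.loc[0, "transition_key"] == k2

    def test_empty_measurements_error(self):
        transitions = make_transitions("T", heavy_peptide("VVGAVGVGK"), (2,))
        with pytest.raises(SrmError):
            rank_stage1(_measurements([]), transitions)


class TestOptimizeStage2:
    def test_noiseless_unimodal_argmax(self):
        grid = stage2_grid(_one_transition(20.0))
        rows = [
            ("T", "z2/y1^1", ce, math.exp(-((ce - 18.0) ** 2) / 50.0), False, 1)
            for ce in grid.ce_values
        ]
        best = optimize_stage2(_measurements(rows))
        assert best.loc[0, "optimal_ce"] == 18.0

    def test_flat_response_takes_lowest_ce(self):
        grid = stage2_grid(_one_transition(20.0))
        rows = [("T", "z2/y1^1", ce, 5.0, False, 1) for ce in grid.ce_values]
        assert optimize_stage2(_measurements(rows)).loc[0, "optimal_ce"] == 12.0

    def test_off_grid_optimum_resolved_to_nearest_grid_step(self):
        """A response peaking at 17.2 eV must pick 16 or 18 on the 2 eV
        grid; verified against brute-force evaluation of the curve."""
        true_opt, width = 17.2, 5.0
        grid = stage2_grid(_one_transition(20.0))
        response = lambda ce: math.exp(-((ce - true_opt) ** 2) / (2 * width**2))
        rows = [("T", "z2/y1^1", ce, response(ce), False, 1) for ce in grid.ce_values]
        chosen = optimize_stage2(_measurements(rows)).loc[0, "optimal_ce"]
        brute = max(grid.ce_values, key=response)
        assert chosen == brute
        assert chosen in (16.0, 18.0)

    def test_partial_grid_warns(self):
        t = _one_transition(20.0)
        grid = stage2_grid(t)
        rows = [("T", t.key, ce, 1.0, False, 1) for ce in grid.ce_values[:5]]
        with pytest.warns(UserWarning, match="unmeasured"):
            optimize_stage2(_measurements(rows), {t.key: grid})


def _panel_transitions():
    # 2 charges x 16 singly charged b/y ions = 32 candidate transitions
    return make_transitions("T", heavy_peptide("VVGAVGVGK"), (2, 3))


def _optimized(n, intensity0=1000.0):
    keys = [t.key for t in _panel_transitions()][:n] if n else []
    return pd.DataFrame(
        {
            "transition_key": keys,
            "optimal_ce": [20.0] * n,
            "best_intensity": [intensity0 - 10 * i for i in range(n)],
        }
    )


class TestCurateMatrix:
    def test_clean_blank_drops_nothing(self):
        opt = _optimized(5)
        blanks = _measurements([("T", k, 20.0, 0.0, True, 1) for k in opt["transition_key"]])
        kept, dropped = curate_matrix(opt, blanks)
        assert len(kept) == 5 and dropped.empty

    def test_blank_equal_to_signal_dropped(self):
        opt = _optimized(2)
        key = opt.loc[0, "transition_key"]
        blanks = _measurements([("T", key, 20.0, 1000.0, True, 1)])
        kept, dropped = curate_matrix(opt, blanks)
        assert list(dropped["transition_key"]) == [key]
        assert "ratio" in dropped.loc[0, "reason"]

    def test_zero_threshold_drops_any_blank_signal(self):
        opt = _optimized(3)
        key = opt.loc[1, "transition_key"]
        blanks = _measurements([("T", key, 20.0, 1e-9, True, 1)])
        kept, _ = curate_matrix(opt, blanks, ratio_threshold=0.0)
        assert key not in set(kept["transition_key"])


class TestBuildPanel:
    def _transitions(self):
        return make_transitions("T", heavy_peptide("VVGAVGVGK"), (2,))

    def test_fifteen_survivors_panel_of_ten(self):
        panel = build_panel(_optimized(15), self._transitions())
        assert len(panel) == 10 and not panel.degraded

    def test_six_survivors_degraded_with_warning(self):
        with pytest.warns(UserWarning, match="degraded"):
            panel = build_panel(_optimized(6), self._transitions())
        assert len(panel) == 6 and panel.degraded

    def test_zero_survivors_hard_error(self):
        with pytest.raises(SrmError, match="unmeasurable"):
            build_panel(_optimized(0), self._transitions())

    def test_intensities_non_increasing(self):
        panel = build_panel(_optimized(12), self._transitions())
        intensities = [e.best_intensity for e in panel.entries]
        assert intensities == sorted(intensities, reverse=True)


class TestCeRecoveryUnderNoise:
    def test_noisy_recovery_within_two_grid_steps(self):
        """With 10% multiplicative intensity noise the chosen CE stays
        within 4 eV (two grid steps) of the true optimum in >= 95/100
        seeded trials."""
        import random

        from neosrm.simulate import random_response_model, simulate_ce_response

        rng = random.Random(811)
        hits = 0
        for trial in range(100):
            seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(9))
            t = rng.choice(make_transitions("T", seq, (2,)))
            model = random_response_model([t], seed=trial, noise_cv=0.10)
            best = optimize_stage2(simulate_ce_response(model, [stage2_grid(t)]))
            dev = abs(best.loc[0, "optimal_ce"] - model.responses[t.key].optimal_ce)
            hits += dev <= 4.0
        assert hits >= 95


class TestTransitionList:
    def test_stage1_schedule_row_count(self, tmp_path):
        """A 9-mer at 2 precursor charges, full singly charged b/y: 2 x 16
        transitions x 3 CEs = 96 schedule rows."""
        transitions = make_transitions("T", heavy_peptide("VVGAVGVGK"), (2, 3))
        frame = write_transition_list(
            [stage1_grid(t) for t in transitions], tmp_path / "s1.csv"
        )
        assert len(frame) == 96

    def test_round_trip_preserves_mz_to_5dp(self, tmp_path):
        transitions = make_transitions("T", heavy_peptide("VVGAVGVGK"), (2,))
        path = tmp_path / "s1.csv"
        written = write_transition_list([stage1_grid(t) for t in transitions], path)
        read = read_transition_list(path)
        assert np.allclose(read["precursor_mz"], written["precursor_mz"], atol=5e-6)
        assert np.allclose(read["product_mz"], written["product_mz"], atol=5e-6)

    def test_heavy_light_rows_differ_by_label_shift_over_charge(self):
        """Heavy rows shift by label/charge on the precursor and on every
        label-containing product, verified against the mass bookkeeping."""
        shift = 8.014199
        light = make_transitions("T", "VVGAVGVGK", (2,))
        heavy = make_transitions("T", heavy_peptide("VVGAVGVGK"), (2,))
        for lt, ht in zip(light, heavy):
            assert ht.precursor_mz - lt.precursor_mz == pytest.approx(shift / 2)
            # the label sits on the C-terminal residue: every y ion carries
            # it, no b ion does (b only reaches ordinal n-1)
            expected = shift / ht.product.charge if ht.product.series == "y" else 0.0
            assert ht.product.mz - lt.product.mz == pytest.approx(expected)

    def test_schedule_table_determinism(self):
        transitions = make_transitions("T", heavy_peptide("VVGAVGVGK"), (2, 3))
        a = schedule_table([stage2_grid(t) for t in transitions])
        b = schedule_table([stage2_grid(t) for t in transitions])
        assert a.equals(b)
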