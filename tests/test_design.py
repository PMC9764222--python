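"""Design generation: pairings, hazard probabilities, amplitude models,
run schedules, and event tables."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oddball_fmri import design


class TestStimulusPairings:
    def test_pure_tone_deltas(self):
        pairings = design.build_stimulus_pairings(design.default_pure_tones())
        assert len(pairings) == 6
        assert sorted({p.delta for p in pairings}) == [45.0, 100.0, 145.0]

    def test_sweep_deltas_match_hand_computation(self):
        sweeps = design.default_fm_sweeps()
        pairings = design.build_stimulus_pairings(sweeps)
        spans = {s.label: s.span_hz for s in sweeps}
        for p in pairings:
            assert p.delta == abs(spans[p.deviant.label]
                                  - spans[p.standard.label])
        assert sorted({p.delta for p in pairings}) == [20.0, 160.0, 180.0]

    def test_identity_pairing_forbidden(self):
        s = design.default_pure_tones()[0]
        with pytest.raises(ValueError):
            design.StimulusPairing(s, s)

    def test_mixed_kinds_rejected(self):
        mix = design.default_pure_tones()[:2] + [design.default_fm_sweeps()[0]]
        with pytest.raises(ValueError, match="same kind"):
            design.build_stimulus_pairings(mix)

    def test_duplicate_stimuli_rejected(self):
        s = design.default_pure_tones()
        with pytest.raises(ValueError):
            design.build_stimulus_pairings([s[0], s[0], s[1]])


class TestPredictability:
    @pytest.mark.parametrize("position,deviant,expected", [
        (4, 4, Fraction(1, 3)),
        (5, 5, Fraction(1, 2)),
        (6, 6, Fraction(1)),
        (4, 5, Fraction(2, 3)),          # standard heard at position 4
        (4, 6, Fraction(2, 3)),
        (5, 6, Fraction(1, 2)),
        (1, 4, Fraction(1, 2)),          # either pairing member may start
        (2, 4, Fraction(1)),
        (7, 4, Fraction(1)),             # deviant already heard
    ])
    def test_hazard_values(self, position, deviant, expected):
        assert design.predictability(position, deviant, exact=True) == expected

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            design.predictability(9, 4)
        with pytest.raises(ValueError):
            design.predictability(4, 7)


TABLE_H1 = {
    4: [1, Fraction(1, 2), Fraction(1, 3), 1, Fraction(1, 3), Fraction(1, 4),
        Fraction(1, 5), Fraction(1, 6)],
    5: [1, Fraction(1, 2), Fraction(1, 3), Fraction(1, 4), 1, Fraction(1, 4),
        Fraction(1, 5), Fraction(1, 6)],
    6: [1, Fraction(1, 2), Fraction(1, 3), Fraction(1, 4), Fraction(1, 5), 1,
        Fraction(1, 5), Fraction(1, 6)],
}
TABLE_H2 = {
    4: [Fraction(1, 2), 1, 1, Fraction(1, 3), 1, 1, 1, 1],
    5: [Fraction(1, 2), 1, 1, Fraction(2, 3), Fraction(1, 2), 1, 1, 1],
    6: [Fraction(1, 2), 1, 1, Fraction(2, 3), Fraction(1, 2), 1, 1, 1],
}


class TestAmplitudeModels:
    @pytest.mark.parametrize("deviant", [4, 5, 6])
    def test_h1_exact_rationals(self, deviant):
        assert list(design.h1_amplitudes(deviant, exact=True)) == \
            TABLE_H1[deviant]

    @pytest.mark.parametrize("deviant", [4, 5, 6])
    def test_h2_exact_rationals(self, deviant):
        assert list(design.h2_amplitudes(deviant, exact=True)) == \
            TABLE_H2[deviant]

    def test_h2_positions_5_and_6_identical(self):
        assert np.array_equal(design.h2_amplitudes(5), design.h2_amplitudes(6))

    @pytest.mark.parametrize("deviant", [4, 5, 6])
    def test_h2_equals_predictability_positionwise(self, deviant):
        expected = [design.predictability(p, deviant, exact=True)
                    for p in range(1, 9)]
        assert list(design.h2_amplitudes(deviant, exact=True)) == expected

    def test_amplitudes_in_unit_interval(self):
        for fn in (design.h1_amplitudes, design.h2_amplitudes):
            for d in (4, 5, 6):
                a = fn(d)
                assert np.all(a > 0) and np.all(a <= 1)

    def test_invalid_position_rejected(self):
        with pytest.raises(ValueError):
            design.h1_amplitudes(3)
        with pytest.raises(ValueError):
            design.amplitude_model("h3")


class TestBuildRun:
    def test_counts_and_blocks(self, schedule):
        assert len(schedule.trials) == 60
        counts = np.bincount(schedule.deviant_positions(), minlength=7)
        assert tuple(counts[4:7]) == (20, 20, 20)
        assert len(schedule.blocks) == 6
        assert all(len(b) == 10 for b in schedule.blocks)

    def test_iti_bounds_and_onsets(self, schedule):
        assert schedule.itis.min() >= 1.5
        assert schedule.itis.max() <= 11.0
        assert np.all(np.diff(schedule.trial_onsets) > 0)

    def test_seeded_determinism(self):
        a = design.build_run(seed=7)
        b = design.build_run(seed=7)
        assert np.array_equal(a.trial_onsets, b.trial_onsets)
        assert np.array_equal(a.itis, b.itis)
        assert a.deviant_positions().tolist() == b.deviant_positions().tolist()
        assert [t.pairing.name for t in a.trials] == \
            [t.pairing.name for t in b.trials]

    def test_different_seeds_differ(self):
        a = design.build_run(seed=7)
        b = design.build_run(seed=8)
        assert a.deviant_positions().tolist() != b.deviant_positions().tolist()

    def test_max_consecutive_constraint(self):
        for seed in range(20):
            seq = design.build_run(seed=seed).deviant_positions()
            runs = np.diff(np.flatnonzero(np.concatenate(
                ([True], seq[1:] != seq[:-1], [True]))))
            assert runs.max() <= 3

    def test_pairing_cells_balanced(self):
        run = design.build_run(seed=5)
        counts = {}
        for t in run.trials:
            counts[(t.pairing.name, t.deviant_position)] = \
                counts.get((t.pairing.name, t.deviant_position), 0) + 1
        assert set(counts.values()) <= {3, 4}
        # every pairing appears 10 times per run
        by_pairing = {}
        for (name, _), c in counts.items():
            by_pairing[name] = by_pairing.get(name, 0) + c
        assert set(by_pairing.values()) == {10}

    def test_deviant_positions_uniform_over_runs(self):
        # order statistics of the shuffled positions across many runs
        first_positions = [design.build_run(seed=s).trials[0].deviant_position
                           for s in range(300)]
        counts = np.bincount(first_positions, minlength=7)[4:7]
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            design.build_run(design.RunParams(deviant_sep_sd=0.0), seed=1)


class TestTrialSequence:
    def test_labels_and_modulators(self):
        pairing = design.build_stimulus_pairings(design.default_pure_tones())[0]
        t = design.TrialSequence(pairing, 4)
        assert t.condition_labels == ("std0", "std1", "std1", "dev4",
                                      "std2", "std2", "std2", "std2")
        assert t.modulators == (0, 1, 2, 0, 1, 2, 3, 4)
        assert sum(lab.startswith("dev") for lab in t.condition_labels) == 1

    @given(st.integers(min_value=4, max_value=6))
    @settings(max_examples=3, deadline=None)
    def test_deviant_predictability_matches_hazard(self, d):
        pairing = design.build_stimulus_pairings(design.default_pure_tones())[0]
        t = design.TrialSequence(pairing, d)
        assert t.predictabilities[d - 1] == \
            pytest.approx({4: 1 / 3, 5: 1 / 2, 6: 1.0}[d])


class TestEventTable:
    def test_row_counts(self, schedule):
        ev = design.event_table(schedule)
        assert len(ev) == 480
        assert (ev.trial_type == "std0").sum() == 60
        assert ev.trial_type.value_counts()[["dev4", "dev5", "dev6"]].sum() == 60

    def test_modulators_for_deviant4_trial(self, schedule):
        ev = design.event_table(schedule)
        trial = next(i for i, t in enumerate(schedule.trials)
                     if t.deviant_position == 4)
        rows = ev[ev.trial == trial]
        assert rows[rows.trial_type == "std1"].modulator.tolist() == [1.0, 2.0]
        assert rows[rows.trial_type == "std2"].modulator.tolist() == \
            [1.0, 2.0, 3.0, 4.0]

    def test_sound_onsets_spacing(self, schedule):
        ev = design.event_table(schedule)
        rows = ev[ev.trial == 0].sort_values("onset")
        assert np.allclose(np.diff(rows.onset), 0.750)
        assert rows.onset.iloc[0] == pytest.approx(schedule.trial_onsets[0])

    def test_events_roundtrip_tsv(self, schedule, tmp_path):
        ev = design.event_table(schedule)
        path = tmp_path / "events.tsv"
        design.write_events(ev, path)
        back = design.read_events(path)
        assert back.shape == ev.shape
        pd.testing.assert_series_equal(back.onset, ev.onset,
                                       check_exact=False)
        assert back.modulator.isna().sum() == ev.modulator.isna().sum()
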