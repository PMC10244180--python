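"""Start-sequence extraction, transition matrices and permutation nulls."""

import numpy as np
import pytest

from conftest import make_ethogram, set_active
from ovipost.ethogram import LABELS, LABEL_INDEX, BehaviorBout, Ethogram, to_bouts
from ovipost.transitions import (
    StartSequence,
    behavior_time_course,
    estimate_transitions,
    extract_start_sequence,
    first_occurrence_order,
    permutation_test,
    progression_probability,
    sequences_from_ethograms,
)


NON_EGG = tuple(l for l in LABELS if l != "egg_out")


def seq(labels, event_id="ev", spacing=10):
    items = [(lab, i * spacing) for i, lab in enumerate(labels)]
    return StartSequence(event_id=event_id, items=items)


class TestExtraction:
    def test_close_pe_onsets_are_merged_by_spacing_filter(self):
        # two proboscis extensions 0.3 mm apart: the second is not counted
        bouts = [BehaviorBout("pe", 0, 5), BehaviorBout("pe", 50, 55)]
        loc = np.zeros((100, 2))
        loc[50:, 0] = 0.3
        s = extract_start_sequence(bouts, location=loc, min_pe_spacing=0.5)
        assert [lab for lab, _ in s.items] == ["pe"]
        loc[50:, 0] = 0.7  # far enough: both count
        s = extract_start_sequence(bouts, location=loc, min_pe_spacing=0.5)
        assert [lab for lab, _ in s.items] == ["pe", "pe"]

    def test_pe_during_other_behavior_is_dropped(self):
        bouts = sorted(
            [BehaviorBout("walk", 0, 20), BehaviorBout("pe", 5, 8), BehaviorBout("pe", 30, 33)],
            key=lambda b: b.start,
        )
        s = extract_start_sequence(bouts, min_pe_spacing=0.0)
        assert [lab for lab, _ in s.items] == ["walk", "pe"]

    def test_sustained_bend_counts_once_despite_burrow_restarts(self):
        _, act = make_ethogram(120)
        set_active(act, "bend", 0, 100)
        set_active(act, "burrow", 10, 20)
        set_active(act, "burrow", 40, 60)
        s = extract_start_sequence(to_bouts(Ethogram(activity=act)), min_pe_spacing=0.0)
        labs = [lab for lab, _ in s.items]
        assert labs == ["bend", "burrow", "burrow"]

    def test_no_bouts_gives_empty_sequence(self):
        s = extract_start_sequence([], min_pe_spacing=0.0)
        assert s.items == []

    def test_missing_location_skips_filter_with_warning(self):
        bouts = [BehaviorBout("pe", 0, 5), BehaviorBout("pe", 50, 55)]
        with pytest.warns(UserWarning, match="spacing filter skipped"):
            s = extract_start_sequence(bouts, location=None, min_pe_spacing=0.5)
        assert len(s.items) == 2
        assert any("skipped" in msg for msg in s.provenance)


class TestEstimation:
    def test_alternating_sequence_gives_unit_probabilities(self):
        tm = estimate_transitions([seq(["walk", "pe", "walk", "pe"])], phase="pre")
        assert tm.probs[LABEL_INDEX["walk"], LABEL_INDEX["pe"]] == 1.0
        assert tm.probs[LABEL_INDEX["pe"], LABEL_INDEX["walk"]] == 1.0

    def test_self_transition_counted_on_diagonal(self):
        tm = estimate_transitions([seq(["burrow", "burrow"])], phase="pre")
        assert tm.counts[LABEL_INDEX["burrow"], LABEL_INDEX["burrow"]] == 1

    def test_pooled_counts_match_brute_force_pair_tally(self):
        rng = np.random.default_rng(11)
        seqs = [
            seq(rng.choice(LABELS[:4], size=rng.integers(2, 12)).tolist(), event_id=f"e{i}")
            for i in range(10)
        ]
        tm = estimate_transitions(seqs, phase="pre")
        brute = np.zeros((7, 7), dtype=int)
        for s in seqs:
            labs = [lab for lab, _ in s.items]
            for a, b in zip(labs, labs[1:]):
                brute[LABEL_INDEX[a], LABEL_INDEX[b]] += 1
        assert np.array_equal(tm.counts, brute)

    def test_rows_are_stochastic_or_zero(self):
        rng = np.random.default_rng(12)
        seqs = [seq(rng.choice(NON_EGG, size=20).tolist()) for _ in range(5)]
        tm = estimate_transitions(seqs, phase="all")
        sums = tm.probs.sum(axis=1)
        assert np.all(np.isclose(sums, 1.0) | np.isclose(sums, 0.0))

    def test_phase_split_at_egg_out(self):
        s = seq(["walk", "bend", "burrow", "egg_out", "detach", "groom"])
        assert s.labels("pre") == ["walk", "bend", "burrow", "egg_out"]
        assert s.labels("post") == ["egg_out", "detach", "groom"]

    def test_initial_distribution_counts_first_onsets(self):
        tm = estimate_transitions([seq(["walk", "pe"]), seq(["pe", "walk"])], phase="pre")
        assert tm.initial_distribution[LABEL_INDEX["walk"]] == 0.5
        assert tm.initial_distribution[LABEL_INDEX["pe"]] == 0.5


class TestPermutation:
    def test_deterministic_alternation_reaches_minimum_p(self):
        # 40 transitions of strict pe->walk alternation: no shuffle can do
        # better, so p is the add-one minimum (1+0)/(1+n_perm)
        s = seq(["pe", "walk"] * 20 + ["pe"])
        tm = estimate_transitions([s], phase="pre")
        res = permutation_test(tm, [s], n_perm=199, seed=5)
        assert res.pvals[LABEL_INDEX["pe"], LABEL_INDEX["walk"]] == pytest.approx(1 / 200)

    def test_same_seed_gives_identical_pvals(self):
        rng = np.random.default_rng(13)
        seqs = [seq(rng.choice(NON_EGG[:5], size=15).tolist()) for _ in range(6)]
        tm = estimate_transitions(seqs, phase="pre")
        a = permutation_test(tm, seqs, n_perm=200, seed=9)
        b = permutation_test(tm, seqs, n_perm=200, seed=9)
        assert np.array_equal(a.pvals, b.pvals)

    def test_low_probability_transitions_never_significant(self):
        # one stray groom->pe among many groom->walk: prob < 0.04 floor
        labels = ["groom", "walk"] * 30 + ["groom", "pe"]
        s = seq(labels)
        tm = estimate_transitions([s], phase="pre")
        res = permutation_test(tm, [s], n_perm=99, alpha=0.99, prob_floor=0.04, seed=1)
        gi, pi = LABEL_INDEX["groom"], LABEL_INDEX["pe"]
        assert tm.probs[gi, pi] < 0.04
        assert not res.significant[gi, pi]

    def test_invalid_parameters_rejected(self):
        s = seq(["walk", "pe"])
        tm = estimate_transitions([s], phase="pre")
        with pytest.raises(ValueError):
            permutation_test(tm, [s], n_perm=0)
        with pytest.raises(ValueError):
            permutation_test(tm, [s], alpha=1.5)

    def test_null_pvalues_are_valid_on_shuffled_data(self):
        # under i.i.d. labels the rejection rate at alpha must not exceed
        # alpha by more than sampling error (validity, not exact calibration)
        rng = np.random.default_rng(21)
        alpha = 0.1
        hits = total = 0
        for _ in range(60):
            seqs = [seq(rng.choice(NON_EGG, size=40).tolist()) for _ in range(8)]
            tm = estimate_transitions(seqs, phase="all")
            res = permutation_test(tm, seqs, n_perm=99, seed=int(rng.integers(2**31)))
            hits += int((res.pvals <= alpha).sum())
            total += res.pvals.size
        rate = hits / total
        se = np.sqrt(alpha * (1 - alpha) / total)
        assert rate <= alpha + 2 * se


class TestOrderingAndTimecourse:
    def test_every_event_starting_pe_puts_pe_first(self):
        seqs = [seq(list(LABELS)) for _ in range(4)]
        table = first_occurrence_order(seqs)
        assert table.loc["pe", 1] == 1.0
        assert np.allclose(table.sum(axis=1), 1.0)

    def test_hand_tally_of_three_events(self):
        s1 = seq(["pe", "walk", "bend", "burrow", "egg_out", "detach", "groom"])
        s2 = seq(["walk", "pe", "bend", "burrow", "egg_out", "detach", "groom"])
        s3 = seq(["pe", "walk", "bend", "burrow", "egg_out", "groom", "detach"])
        table = first_occurrence_order([s1, s2, s3])
        assert table.loc["pe", 1] == pytest.approx(2 / 3)
        assert table.loc["walk", 1] == pytest.approx(1 / 3)
        assert table.loc["detach", 6] == pytest.approx(2 / 3)
        assert table.loc["groom", 6] == pytest.approx(1 / 3)

    def test_events_missing_a_component_are_excluded(self):
        full = seq(list(LABELS))
        partial = seq(["pe", "walk", "bend"])  # lacks groom etc.
        table = first_occurrence_order([full, partial])
        assert table.attrs["n_events"] == 1
        with pytest.raises(ValueError):
            first_occurrence_order([partial])

    def test_single_event_time_course_equals_its_own_window(self):
        _, act = make_ethogram(200)
        set_active(act, "walk", 0, 50)
        act[100, LABEL_INDEX["egg_out"]] = True
        e = Ethogram(activity=act, egg_out_frame=100)
        times, frac = behavior_time_course([e], window_s=2.0)
        w = 40
        window = act[100 - w : 100 + w + 1]
        assert np.array_equal(frac.to_numpy(), window.T.astype(float))

    def test_fraction_is_half_when_one_of_two_events_active(self):
        es = []
        for active in (True, False):
            _, act = make_ethogram(200)
            if active:
                set_active(act, "walk", 60, 81)
            act[100, LABEL_INDEX["egg_out"]] = True
            es.append(Ethogram(activity=act, egg_out_frame=100))
        times, frac = behavior_time_course(es, window_s=2.0)
        at_minus_1s = frac.loc["walk"].to_numpy()[40 - 20]
        assert at_minus_1s == 0.5

    def test_egg_out_fraction_is_one_at_zero_on_cohort(self, cohort):
        ethos, _ = cohort
        times, frac = behavior_time_course(ethos, window_s=5.0)
        mid = len(times) // 2
        assert times[mid] == 0.0
        assert frac.loc["egg_out"].iloc[mid] == 1.0

    def test_no_anchor_raises(self):
        e, _ = make_ethogram(50)
        with pytest.raises(ValueError):
            behavior_time_course([e])


class TestProgression:
    def _fly(self, fly_id, bend_spans, burrow_spans, egg=None, n=400):
        _, act = make_ethogram(n)
        for s, t in bend_spans:
            set_active(act, "bend", s, t)
        for s, t in burrow_spans:
            set_active(act, "burrow", s, t)
        if egg is not None:
            act[egg, LABEL_INDEX["egg_out"]] = True
        return Ethogram(activity=act, egg_out_frame=egg, fly_id=fly_id)

    def test_three_of_four_bend_bouts_contain_burrow(self):
        e = self._fly(
            "f1",
            bend_spans=[(0, 50), (60, 110), (120, 170), (180, 230)],
            burrow_spans=[(10, 20), (70, 80), (130, 140)],
        )
        table = progression_probability([e], "bend", "burrow", min_bouts=3)
        assert table.loc[0, "probability"] == 0.75

    def test_every_burrow_bout_expelling_gives_one(self):
        e = self._fly("f1", bend_spans=[], burrow_spans=[(10, 40)], egg=40)
        table = progression_probability([e], "burrow", "egg_out", min_bouts=1)
        assert table.loc[0, "probability"] == 1.0

    def test_fly_below_min_bouts_excluded(self):
        e = self._fly("f1", bend_spans=[(0, 30), (40, 70)], burrow_spans=[(10, 20)])
        table = progression_probability([e], "bend", "burrow", min_bouts=3)
        assert table.empty

    def test_unsupported_pair_rejected(self):
        with pytest.raises(ValueError):
            progression_probability([], "walk", "groom")


def test_parameter_recovery_on_simulated_cohort(cohort):
    """Estimated pre-phase probabilities approach the generating matrix."""
    ethos, truths = cohort
    seqs = sequences_from_ethograms(ethos, min_pe_spacing=0.0)
    tm = estimate_transitions(seqs, phase="pre")
    truth = truths[0].transition_matrix
    rows = tm.counts.sum(axis=1) >= 50
    assert rows.sum() >= 3
    assert np.abs(tm.probs[rows] - truth[rows]).max() < 0.15  # loose at n=20 events
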