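"""Accuracy labeling, update-weight estimation, and outlier screening."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialrl import (
    ChoiceTrial,
    FACE_IDS,
    FacePair,
    ItemValence,
    Outcome,
    Phase,
    SpeechItem,
    ValidationError,
    accuracy_table,
    aggregate_weights,
    classify_pe,
    item_weight,
    label_test_trial,
    screen_outliers,
    weights_table,
)
from socialrl.metrics import SCHEMES, TrialLabel, UndefinedWeightError


def make_tt(face_a, face_b, chosen, idx=0, subject="X", session=1):
    return ChoiceTrial(
        subject, session, Phase.TEST, idx, FacePair.of(face_a, face_b), chosen,
        Outcome.NONE,
    )


class TestLabeling:
    @pytest.mark.parametrize(
        "fa, fb, chosen, label, correct",
        [
            ("p80", "p60", "p80", TrialLabel.CHOOSE_REWARD, True),
            ("p80", "p70", "p70", TrialLabel.CHOOSE_REWARD, False),
            ("p20", "p30", "p30", TrialLabel.AVOID_PUNISH, True),
            ("p40", "p20", "p20", TrialLabel.AVOID_PUNISH, False),
            ("p80", "p20", "p80", TrialLabel.EXCLUDED, None),
            ("p70", "p40", "p70", TrialLabel.EXCLUDED, None),
        ],
    )
    def test_label_rules(self, fa, fb, chosen, label, correct):
        lab = label_test_trial(make_tt(fa, fb, chosen))
        assert lab.label is label
        assert lab.correct is correct

    def test_training_trial_rejected(self):
        t = ChoiceTrial(
            "X", 1, Phase.TRAIN, 0, FacePair.of("p80", "p20"), "p80", Outcome.HAPPY
        )
        with pytest.raises(ValidationError):
            label_test_trial(t)

    def test_partition_over_all_pairs(self):
        """Every recombined pair gets exactly one label; the counts match the
        pair combinatorics (4 choose-reward, 4 avoid-punish, 7 excluded)."""
        counts = {lab: 0 for lab in TrialLabel}
        for fa, fb in itertools.combinations(FACE_IDS, 2):
            lab = label_test_trial(make_tt(fa, fb, fa))
            counts[lab.label] += 1
        assert counts[TrialLabel.CHOOSE_REWARD] == 4
        assert counts[TrialLabel.AVOID_PUNISH] == 4
        assert counts[TrialLabel.EXCLUDED] == 7


class TestAccuracy:
    def test_hand_counted_fixture(self):
        trials = [
            make_tt("p80", "p70", "p80", 0),  # reward, correct
            make_tt("p80", "p60", "p60", 1),  # reward, wrong
            make_tt("p80", "p40", "p80", 2),  # reward, correct
            make_tt("p80", "p30", "p80", 3),  # reward, correct
            make_tt("p20", "p70", "p70", 4),  # punish, correct
            make_tt("p20", "p60", "p20", 5),  # punish, wrong
            make_tt("p20", "p40", "p20", 6),  # punish, wrong
            make_tt("p80", "p20", "p80", 7),  # excluded
        ]
        cells, records = accuracy_table(trials)
        assert len(records) == 7
        by_type = cells.set_index("trial_type")
        assert by_type.loc["choose_reward", "accuracy"] == pytest.approx(3 / 4)
        assert by_type.loc["avoid_punish", "accuracy"] == pytest.approx(1 / 3)

    def test_perfect_subject(self):
        trials = [
            make_tt("p80", f, "p80", i) for i, f in enumerate(["p70", "p60"])
        ] + [
            make_tt("p20", f, f, i + 2) for i, f in enumerate(["p40", "p30"])
        ]
        cells, _ = accuracy_table(trials)
        assert (cells.accuracy == 1.0).all()

    def test_empty_cell_flagged_missing(self):
        trials = [make_tt("p80", "p70", "p80", 0)]
        cells, _ = accuracy_table(trials)
        missing = cells[cells.trial_type == "avoid_punish"]
        assert missing.missing.all()
        assert missing.accuracy.isna().all()


def item(valence, pre, feedback, post, item_id=1, subject="X"):
    return SpeechItem(subject, item_id, ItemValence(valence), pre, feedback, post)


class TestPEClassification:
    @pytest.mark.parametrize(
        "valence, pre, feedback, expected",
        [
            ("good", 40, 70, "positive"),
            ("good", 70, 40, "negative"),
            ("poor", 60, 30, "positive"),  # less 'poor' than feared
            ("poor", 30, 60, "negative"),
            ("good", 50, 50, "zero"),
            ("poor", 50, 50, "zero"),
        ],
    )
    def test_sign_convention(self, valence, pre, feedback, expected):
        assert classify_pe(item(valence, pre, feedback, 50)) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(pre=st.integers(20, 80), delta=st.integers(-20, 20))
    def test_antisymmetric_under_valence_flip_and_reflection(self, pre, delta):
        """Flipping item valence and reflecting feedback about the pre-rating
        leaves the PE class unchanged (the two reversals cancel)."""
        a = classify_pe(item("good", pre, pre + delta, 50))
        b = classify_pe(item("poor", pre, pre - delta, 50))
        assert a == b
        flipped = classify_pe(item("poor", pre, pre + delta, 50))
        swap = {"positive": "negative", "negative": "positive", "zero": "zero"}
        assert flipped == swap[a]


class TestItemWeight:
    @pytest.mark.parametrize(
        "pre, feedback, post, expected",
        [
            (40, 80, 40, 0.0),
            (40, 80, 80, 1.0),
            (40, 80, 60, 0.5),
            (60, 20, 50, 0.25),
            (50, 70, 90, 2.0),  # overshoot is representable, not clipped
            (50, 70, 40, -0.5),  # counter-updating likewise
        ],
    )
    def test_ratio(self, pre, feedback, post, expected):
        assert item_weight(item("good", pre, feedback, post)) == pytest.approx(expected)

    def test_zero_pe_is_undefined(self):
        with pytest.raises(UndefinedWeightError):
            item_weight(item("good", 50, 50, 60))


def make_subject_items(w_by_cell, subject="X", noise_rng=None, noise_sd=0.0):
    """Noiseless (or noisy) items with known per-cell weights; interior
    values so nothing clips."""
    items = []
    item_id = 1
    for valence in ("good", "poor"):
        for k in range(10):
            pre = 40 + k
            fb = pre + (10 if k % 2 == 0 else -10)
            raw = fb - pre
            signed = raw if valence == "good" else -raw
            pe = "positive" if signed > 0 else "negative"
            w = w_by_cell[(pe, valence)]
            post = pre + w * raw
            if noise_rng is not None:
                post += noise_rng.normal(0, noise_sd)
            items.append(item(valence, pre, fb, float(np.clip(post, 0, 100)),
                              item_id, subject))
            item_id += 1
    return items


class TestAggregation:
    def test_uniform_weights_under_every_scheme(self):
        cells = {(pe, iv): 0.5 for pe in ("positive", "negative")
                 for iv in ("good", "poor")}
        items = make_subject_items(cells)
        for scheme in SCHEMES:
            ws = aggregate_weights(items, scheme)
            assert all(w == pytest.approx(0.5) for w in ws.weights.values())
            assert not ws.missing

    def test_one_weight_is_count_weighted_mean_of_pe_cells(self):
        cells = {("positive", "good"): 0.2, ("positive", "poor"): 0.2,
                 ("negative", "good"): 0.7, ("negative", "poor"): 0.7}
        items = make_subject_items(cells)
        one = aggregate_weights(items, "one")
        pe = aggregate_weights(items, "pe_valence")
        expected = sum(
            pe.weights[c] * pe.n_items[c] for c in pe.weights
        ) / sum(pe.n_items.values())
        assert one.weights["all"] == pytest.approx(expected, abs=1e-12)

    def test_noiseless_round_trip_recovers_truth_exactly(self):
        cells = {("positive", "good"): 0.3, ("positive", "poor"): 0.3,
                 ("negative", "good"): 0.6, ("negative", "poor"): 0.6}
        # same weight by item valence: truth 0.3 good / 0.6 poor is not this
        cells = {("positive", "good"): 0.3, ("negative", "good"): 0.3,
                 ("positive", "poor"): 0.6, ("negative", "poor"): 0.6}
        items = make_subject_items(cells)
        ws = aggregate_weights(items, "item_valence")
        assert ws.weights["good"] == pytest.approx(0.3, abs=1e-12)
        assert ws.weights["poor"] == pytest.approx(0.6, abs=1e-12)
        four = aggregate_weights(items, "four")
        for (pe, iv), w in cells.items():
            assert four.weights[f"{pe}_{iv}"] == pytest.approx(w, abs=1e-12)

    def test_zero_pe_items_excluded_with_reason(self):
        cells = {(pe, iv): 0.5 for pe in ("positive", "negative")
                 for iv in ("good", "poor")}
        items = make_subject_items(cells)
        items[0] = item("good", 40, 40, 40.0, 1)
        ws = aggregate_weights(items, "one")
        assert ws.excluded_items == [
            {"item_id": 1, "reason": "zero prediction error"}
        ]
        assert sum(ws.n_items.values()) == 19

    def test_unbiased_under_symmetric_noise(self, rng):
        """Mean item weight converges to truth with interior noisy values."""
        cells = {(pe, iv): 0.4 for pe in ("positive", "negative")
                 for iv in ("good", "poor")}
        weights = []
        for s in range(500):  # 10^4 items
            items = make_subject_items(cells, f"S{s}", rng, noise_sd=3.0)
            weights.extend(item_weight(it) for it in items)
        assert np.mean(weights) == pytest.approx(0.4, abs=0.02)


class TestOutlierScreening:
    @staticmethod
    def clean_table(rng, n=40):
        rows = []
        for i in range(n):
            cond = "CBM-I" if i % 2 else "EMA-only"
            base = rng.normal(0.5, 0.08)
            for cat in ("positive", "negative"):
                rows.append(
                    {"subject_id": f"S{i}", "condition": cond, "category": cat,
                     "weight": base + rng.normal(0, 0.05), "n_items": 10}
                )
        return pd.DataFrame(rows)

    def test_planted_extreme_weight_is_removed(self, rng):
        table = self.clean_table(rng)
        table.loc[3, "weight"] = 5.0
        retained, removed = screen_outliers(table)
        assert 3 in removed.index
        assert removed.loc[3, "influence"] > 0
        assert 3 not in retained.index

    def test_infinite_threshold_removes_nothing(self, rng):
        table = self.clean_table(rng)
        table.loc[3, "weight"] = 5.0
        retained, removed = screen_outliers(table, threshold=np.inf)
        assert len(removed) == 0
        assert len(retained) == len(table)

    def test_single_pass_stabilizes(self, rng):
        """The planted outlier never reappears, and a second pass on the
        screened table removes at most the ordinary-tail fraction a 4/n
        Cook's threshold always flags (~5% of continuous data)."""
        table = self.clean_table(rng)
        table.loc[5, "weight"] = 4.0
        retained, removed = screen_outliers(table)
        assert 5 in removed.index
        again, removed_again = screen_outliers(retained)
        assert len(removed_again) <= 0.08 * len(retained)
        assert (removed_again.get("weight", pd.Series()) < 2).all()


class TestWeightsTable:
    def test_long_format_across_subjects(self, small_study):
        cond = {d.subject_id: d.condition for d in small_study.designs}
        table = weights_table(small_study.speech, "pe_valence", cond)
        assert set(table.columns) == {
            "subject_id", "condition", "category", "weight", "n_items"
        }
        assert set(table.category) <= {"positive", "negative"}
        assert table.subject_id.nunique() == len(small_study.designs)
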