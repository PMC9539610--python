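"""Category-boundary and prototype derivation from hue-labeling data."""

import numpy as np
import pandas as pd
import pytest

from pupilwm.categories import (CategorySolution, circular_max_error,
                                derive_categories, find_boundaries,
                                find_prototypes, modal_labels,
                                rater_agreement, response_frequencies)
from pupilwm.synth import generate_category_structure, simulate_categorization


class TestGenerateStructure:
    def test_equal_spacing_four(self):
        s = generate_category_structure(4, jitter=0.0, seed=0)
        assert s.boundaries == pytest.approx([0, 90, 180, 270])
        assert s.prototypes == pytest.approx([45, 135, 225, 315])

    def test_equal_spacing_seven_gaps(self):
        s = generate_category_structure(7, jitter=0.0, seed=0)
        gaps = np.diff(np.concatenate([s.boundaries, [s.boundaries[0] + 360]]))
        assert gaps == pytest.approx(np.full(7, 360 / 7))

    def test_jitter_stays_within_three_sigma(self):
        s = generate_category_structure(7, jitter=5.0, seed=1)
        base = 360 / 7 * np.arange(7)
        assert circular_max_error(s.boundaries, base) <= 15.0

    def test_too_few_categories(self):
        with pytest.raises(ValueError):
            generate_category_structure(1)


class TestSimulateCategorization:
    def test_noiseless_labels_are_truth(self, structure7):
        rec = simulate_categorization(structure7, 3, 0.0, seed=1)
        assert (rec["label"] ==
                np.asarray(structure7.label_of(rec["hue"].to_numpy()))).all()

    def test_record_count(self, structure7):
        rec = simulate_categorization(structure7, 27, 0.1, seed=2)
        assert len(rec) == 27 * 360
        assert rec.groupby("participant")["hue"].nunique().eq(360).all()

    def test_mislabel_fraction(self, structure7):
        rec = simulate_categorization(structure7, 30, 0.2, seed=7)
        truth = np.asarray(structure7.label_of(rec["hue"].to_numpy()))
        frac = np.mean(rec["label"].to_numpy() != truth)
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_mislabels_go_to_adjacent_category(self, structure7):
        rec = simulate_categorization(structure7, 5, 0.3, seed=3)
        true_idx = structure7.category_of(rec["hue"].to_numpy())
        labels = list(structure7.labels)
        got_idx = rec["label"].map(labels.index).to_numpy()
        delta = (got_idx - true_idx) % 7
        assert set(np.unique(delta)) <= {0, 1, 6}


class TestResponseFrequencies:
    def test_counts(self):
        rec = pd.DataFrame({"participant": [0, 1], "hue": [0, 0],
                            "label": ["red", "red"]})
        table = response_frequencies(rec, labels=["red", "orange"])
        assert table.loc[0, "red"] == 2
        assert table.loc[0, "orange"] == 0

    def test_total_27_participants(self, structure7):
        rec = simulate_categorization(structure7, 27, 0.0, seed=0)
        assert response_frequencies(rec).to_numpy().sum() == 9720

    def test_noiseless_single_nonzero_per_row(self, structure7):
        rec = simulate_categorization(structure7, 4, 0.0, seed=0)
        table = response_frequencies(rec)
        assert ((table.to_numpy() > 0).sum(axis=1) == 1).all()

    def test_unknown_label_named(self):
        rec = pd.DataFrame({"participant": [0], "hue": [5],
                            "label": ["maroon"]})
        with pytest.raises(ValueError, match="maroon"):
            response_frequencies(rec, labels=["red"])


class TestModalLabels:
    def test_plain_majority(self):
        counts = pd.DataFrame(0, index=range(360), columns=["red", "orange"])
        counts["red"] = 20
        counts.loc[5, "orange"] = 25
        modal = modal_labels(counts)
        assert modal[5] == "orange" and modal[4] == "red"

    def test_tie_keeps_previous_label(self):
        counts = pd.DataFrame(0, index=range(360), columns=["red", "orange"])
        counts["red"] = 10
        counts.loc[100, "orange"] = 10      # tie at hue 100, red before it
        modal = modal_labels(counts)
        assert modal[100] == "red"

    def test_empty_row_rejected(self):
        counts = pd.DataFrame(1, index=range(360), columns=["red"])
        counts.loc[17] = 0
        with pytest.raises(ValueError, match="17"):
            modal_labels(counts)


class TestFindBoundaries:
    def test_two_halves(self):
        modal = np.array(["A"] * 180 + ["B"] * 180, dtype=object)
        assert find_boundaries(modal).tolist() == [179.5, 359.5]

    def test_constant_has_no_boundary(self):
        assert find_boundaries(np.array(["A"] * 360, dtype=object)).size == 0

    def test_persistence_filter_ignores_flicker(self):
        modal = np.array(["A"] * 180 + ["B"] * 180, dtype=object)
        modal[90] = "B"          # 1-hue flicker inside A
        modal[183] = "A"         # 1-hue flicker inside B
        assert find_boundaries(modal, persistence=3).tolist() == [179.5, 359.5]

    def test_roundtrip_noiseless(self, structure7):
        rec = simulate_categorization(structure7, 10, 0.0, seed=0)
        modal = modal_labels(response_frequencies(rec))
        got = find_boundaries(modal)
        assert got.size == 7
        assert circular_max_error(got, structure7.boundaries) <= 0.5


class TestFindPrototypes:
    def test_simple_pair(self):
        protos = find_prototypes([10, 50])
        assert protos == pytest.approx([30, 210])

    def test_wrap_through_zero(self):
        protos = find_prototypes([350, 10])
        assert 0.0 in np.round(protos, 6)

    def test_equal_spacing_offsets_by_half_gap(self):
        b = 360 / 7 * np.arange(7)
        assert find_prototypes(b) == pytest.approx(b + 360 / 14)

    def test_requires_two(self):
        with pytest.raises(ValueError):
            find_prototypes([42.0])


class TestRaterAgreement:
    def test_perfect_and_random_raters(self, structure7):
        rec = simulate_categorization(structure7, 8, 0.0, seed=0)
        rng = np.random.default_rng(1)
        rogue = pd.DataFrame({
            "participant": 99, "hue": np.arange(360),
            "label": rng.choice(structure7.labels, 360)})
        scores = rater_agreement(pd.concat([rec, rogue], ignore_index=True))
        clean = scores[scores.participant != 99]
        assert (clean.agreement == 1.0).all() and not clean.flagged.any()
        rogue_score = scores.loc[scores.participant == 99, "agreement"].iloc[0]
        assert rogue_score == pytest.approx(1 / 7, abs=0.07)
        assert scores.loc[scores.participant == 99, "flagged"].iloc[0]

    def test_single_participant_rejected(self, structure7):
        rec = simulate_categorization(structure7, 1, 0.0, seed=0)
        with pytest.raises(ValueError):
            rater_agreement(rec)


class TestEndToEndRecovery:
    def test_boundaries_and_prototypes_interleave(self, structure7):
        rec = simulate_categorization(structure7, 27, 0.1, seed=5)
        sol = derive_categories(rec)
        order = np.sort(np.concatenate([sol.boundaries, sol.prototypes]))
        merged = np.concatenate([[b_or_p for pair in
                                  zip(np.sort(sol.boundaries),
                                      np.sort(sol.prototypes))
                                  for b_or_p in pair]])
        # strictly alternating when both are sorted from the first boundary
        assert np.all(np.diff(order) > 0)
        assert np.allclose(order, np.sort(merged))

    def test_json_roundtrip(self, structure7, tmp_path):
        path = tmp_path / "cats.json"
        structure7.to_json(path)
        back = CategorySolution.from_json(path)
        assert back.boundaries == pytest.approx(structure7.boundaries)
        assert back.prototypes == pytest.approx(structure7.prototypes)
        assert back.labels == list(structure7.labels)
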