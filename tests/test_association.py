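import numpy as np
import pandas as pd
import pytest

from circa.association import (ModalBayesClassifier, VoteTable, bayes_classify,
                               chance_accuracy, phi_matrix, typicality_subsets)


def votes_from_modal(modal: dict, n_votes: int = 5) -> VoteTable:
    """VoteTable in which every item gets unanimous votes for its modal label."""
    rows = [{"item": it, "dimension": dim, "category": cat, "count": n_votes}
            for it, dims in modal.items() for dim, cat in dims.items()]
    return VoteTable.from_counts(pd.DataFrame(rows))


class TestVoteTable:
    def test_modal_and_agreement(self):
        rows = [{"participant": f"p{i}", "item": "a", "dimension": "sem",
                 "category": "beach" if i < 3 else "road"} for i in range(4)]
        votes = VoteTable.from_long(pd.DataFrame(rows))
        assert votes.modal("sem").loc["a"] == "beach"
        assert votes.agreement("sem").loc["a"] == pytest.approx(0.75)

    def test_modal_tie_breaks_lexicographically(self):
        rows = [{"item": "a", "dimension": "sem", "category": c, "count": 2}
                for c in ("road", "beach")]
        votes = VoteTable.from_counts(pd.DataFrame(rows))
        assert votes.modal("sem").loc["a"] == "beach"

    def test_negative_counts_rejected(self):
        df = pd.DataFrame([{"item": "a", "dimension": "d", "category": "x",
                            "count": -1}])
        with pytest.raises(ValueError):
            VoteTable.from_counts(df)


class TestPhiMatrix:
    def test_identical_indicators_score_one(self):
        a = pd.Series({"i1": "x", "i2": "x", "i3": "y", "i4": "y"})
        phi = phi_matrix(a, a)
        assert phi.loc["x", "x"] == pytest.approx(1.0)
        assert phi.loc["x", "y"] == pytest.approx(-1.0)  # complementary

    def test_hand_computed_two_by_two(self):
        # contingency (a,b,c,d) = (30,10,10,30) over 80 items -> phi = 0.5
        items = [f"i{k}" for k in range(80)]
        a = pd.Series(["x"] * 40 + ["other"] * 40, index=items)
        b_vals = (["u"] * 30 + ["other"] * 10) + (["u"] * 10 + ["other"] * 30)
        b = pd.Series(b_vals, index=items)
        assert phi_matrix(a, b).loc["x", "u"] == pytest.approx(0.5)

    def test_constant_indicator_reported_missing(self):
        a = pd.Series({"i1": "x", "i2": "x"})
        b = pd.Series({"i1": "u", "i2": "v"})
        assert np.isnan(phi_matrix(a, b).loc["x", "u"])


class TestModalBayesClassifier:
    def test_deterministic_predictor_reaches_perfect_accuracy(self):
        X = np.array([["a"], ["a"], ["b"], ["b"]] * 5, dtype=object)
        y = np.array(["A", "A", "B", "B"] * 5, dtype=object)
        for mode in ("naive", "joint"):
            clf = ModalBayesClassifier(mode=mode, alpha=0.01).fit(X, y)
            assert (clf.predict(X) == y).all()

    def test_prior_only_predicts_modal_class(self):
        X = np.array([["a"], ["b"], ["a"], ["b"], ["a"]], dtype=object)
        y = np.array(["A", "A", "A", "B", "B"], dtype=object)
        clf = ModalBayesClassifier(mode="prior_only").fit(X, y)
        assert (clf.predict(X) == "A").all()

    def test_single_predictor_naive_equals_joint(self, rng):
        X = rng.choice(["a", "b", "c"], size=(60, 1)).astype(object)
        y = rng.choice(["A", "B"], size=60).astype(object)
        naive = ModalBayesClassifier(mode="naive").fit(X, y).predict(X)
        joint = ModalBayesClassifier(mode="joint").fit(X, y).predict(X)
        assert (naive == joint).all()

    def test_factorized_table_makes_naive_equal_joint(self, rng):
        # predictors conditionally independent given the target by construction
        n = 400
        y = rng.choice(["A", "B"], size=n)
        p1 = {"A": ["a"] * 8 + ["b"] * 2, "B": ["a"] * 2 + ["b"] * 8}
        p2 = {"A": ["u"] * 7 + ["v"] * 3, "B": ["u"] * 3 + ["v"] * 7}
        X = np.array([[rng.choice(p1[c]), rng.choice(p2[c])] for c in y],
                     dtype=object)
        naive = ModalBayesClassifier(mode="naive", alpha=0.5).fit(X, y)
        joint = ModalBayesClassifier(mode="joint", alpha=0.5).fit(X, y)
        grid = np.array([[a, u] for a in "ab" for u in "uv"], dtype=object)
        assert (naive.predict(grid) == joint.predict(grid)).all()

    def test_probability_rows_sum_to_one(self, rng):
        X = rng.choice(["a", "b"], size=(30, 2)).astype(object)
        y = rng.choice(["A", "B", "C"], size=30).astype(object)
        clf = ModalBayesClassifier(mode="joint").fit(X, y)
        for table in clf.joint_.values():
            assert table.sum() == pytest.approx(1.0)
        assert clf.class_prior_.sum() == pytest.approx(1.0)


class TestBayesClassifyLoocv:
    def make_votes(self):
        # target 'sem' fully determined by predictor 'str'
        modal = {}
        for k in range(24):
            cat = "A" if k < 12 else "B"
            modal[f"i{k}"] = {"sem": cat, "str": cat.lower(), "app": "z"}
        return votes_from_modal(modal)

    def test_images_loocv_perfect_when_determined(self):
        report = bayes_classify(self.make_votes(), "sem", ["str"], mode="joint",
                                loocv="images", alpha=0.01)
        assert report.accuracy == pytest.approx(1.0)

    def test_prior_only_accuracy_is_modal_frequency(self):
        modal = {f"i{k}": {"sem": "A" if k < 15 else "B", "str": "x"}
                 for k in range(20)}
        report = bayes_classify(votes_from_modal(modal), "sem", ["str"],
                                mode="prior_only", loocv="images")
        # per left-out item the training majority is still the global mode
        assert report.accuracy == pytest.approx(15 / 20)

    def test_confusion_matrix_bookkeeping(self):
        report = bayes_classify(self.make_votes(), "sem", ["str", "app"],
                                mode="naive", loocv="images", alpha=0.01)
        cm = report.confusion
        assert cm.to_numpy().sum() == 24
        assert cm.sum(axis=1).loc["A"] == 12  # row sums = per-category counts
        assert np.trace(cm.to_numpy()) / 24 == pytest.approx(report.accuracy)

    def test_participants_loocv_scores_raw_labels(self, rng):
        rows = []
        for p in range(4):
            for k in range(16):
                cat = "A" if k < 8 else "B"
                # one participant deviates on item i0
                sem = "B" if (p == 3 and k == 0) else cat
                rows.append({"participant": f"p{p}", "item": f"i{k:02d}",
                             "dimension": "sem", "category": sem})
                rows.append({"participant": f"p{p}", "item": f"i{k:02d}",
                             "dimension": "str", "category": cat.lower()})
        votes = VoteTable.from_long(pd.DataFrame(rows))
        report = bayes_classify(votes, "sem", ["str"], mode="joint",
                                loocv="participants", alpha=0.01)
        # every response except p3's deviant one is predicted correctly
        assert report.accuracy == pytest.approx(63 / 64)


class TestTypicalitySubsets:
    def make_votes(self, n_per_cat=6):
        rows = []
        for c, cat in enumerate(["A", "B"]):
            for k in range(n_per_cat):
                it = f"{cat}{k}"
                # agreement decreases with k; majority always the own category
                rows.append({"item": it, "dimension": "sem", "category": cat,
                             "count": 12 - k})
                rows.append({"item": it, "dimension": "sem",
                             "category": "B" if cat == "A" else "A", "count": k})
        return VoteTable.from_counts(pd.DataFrame(rows))

    def test_monotone_agreement_selects_extremes(self):
        votes = self.make_votes()
        subsets = typicality_subsets(votes, "sem", m=2, seed=0)
        assert subsets["typical"] == ["A0", "A1", "B0", "B1"]
        assert subsets["atypical"] == ["A5", "A4", "B5", "B4"]

    def test_uniform_agreement_falls_back_to_item_order(self):
        rows = [{"item": f"i{k}", "dimension": "sem", "category": "A", "count": 3}
                for k in range(5)]
        votes = VoteTable.from_counts(pd.DataFrame(rows))
        subsets = typicality_subsets(votes, "sem", m=2, seed=1)
        assert subsets["typical"] == ["i0", "i1"]

    def test_random_subset_is_seeded(self):
        votes = self.make_votes()
        a = typicality_subsets(votes, "sem", m=3, seed=42)
        b = typicality_subsets(votes, "sem", m=3, seed=42)
        assert a["random"] == b["random"]

    def test_small_category_rejected(self):
        votes = self.make_votes(n_per_cat=2)
        with pytest.raises(ValueError):
            typicality_subsets(votes, "sem", m=3, seed=0)

    def test_planted_typicality_improves_accuracy(self, rng):
        # items with high agreement follow the cross-dimension rule; items
        # with low agreement are scrambled: typical subset must classify
        # at least as well as the atypical one
        rows = []
        for c, cat in enumerate(["A", "B", "C"]):
            for k in range(12):
                it = f"{cat}{k:02d}"
                agree = 10 if k < 6 else 6
                rows.append({"item": it, "dimension": "sem", "category": cat,
                             "count": agree})
                rows.append({"item": it, "dimension": "sem",
                             "category": "ABC"[(c + 1) % 3], "count": 10 - agree})
                pred = cat.lower() if k < 6 else rng.choice(["a", "b", "c"])
                rows.append({"item": it, "dimension": "str", "category": pred,
                             "count": 10})
        votes = VoteTable.from_counts(pd.DataFrame(rows))
        subsets = typicality_subsets(votes, "sem", m=6, seed=0)
        acc = {}
        for role in ("typical", "atypical"):
            report = bayes_classify(votes, "sem", ["str"], mode="joint",
                                    loocv="images", items=subsets[role])
            acc[role] = report.accuracy
        assert acc["typical"] >= acc["atypical"]


def test_chance_accuracy_is_inverse_category_count():
    assert chance_accuracy(6) == pytest.approx(100 / 6)
    assert chance_accuracy(4) == 25.0
    with pytest.raises(ValueError):
        chance_accuracy(0)
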