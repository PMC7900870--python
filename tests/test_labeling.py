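import numpy as np
import pytest
from scipy.stats import f_oneway
from sklearn.metrics import adjusted_rand_score

from circa.datatypes import ParticipantSort, Partition
from circa.labeling import (TableEmbeddingProvider, WordVectorSet,
                            centroid_label, f_ratio, partial_category_ari,
                            score_and_assign_labels, stem_label)


def P(labels, k=None):
    labels = np.asarray(labels)
    return Partition(labels, k or int(labels.max()) + 1)


class TestStemming:
    @pytest.mark.parametrize("raw, expected", [
        ("Farm", "farm"),
        ("Farms", "farm"),
        ("Farming", "farm"),
        ("  Car Parks ", "car park"),
        ("beaches", "beach"),
        ("grass", "grass"),  # double-s guard: not a plural
    ])
    def test_common_variants_share_a_stem(self, raw, expected):
        assert stem_label(raw) == expected


class TestPartialCategoryAri:
    def test_identical_memberships_score_one(self):
        group = P([0, 0, 1, 1, 2, 2])
        assert partial_category_ari(group, 0, group, 0) == pytest.approx(1.0)

    def test_disjoint_equal_categories_match_binarized_ari(self):
        # n=8: group category {0..3} vs participant category {4..7}
        group = P([0, 0, 0, 0, 1, 1, 1, 1])
        sort = P([1, 1, 1, 1, 0, 0, 0, 0])
        expected = adjusted_rand_score([1, 1, 1, 1, 0, 0, 0, 0],
                                       [0, 0, 0, 0, 1, 1, 1, 1])
        assert partial_category_ari(group, 0, sort, 0) == pytest.approx(expected)
        assert expected == pytest.approx(1.0)  # binary complements agree perfectly

    def test_multi_category_sides_are_merged(self):
        group = P([0, 0, 1, 1, 2, 2])
        sort = P([0, 0, 1, 2, 1, 2])
        expected = adjusted_rand_score((group.assignments == 0).astype(int),
                                       (sort.assignments == 0).astype(int))
        assert partial_category_ari(group, 0, sort, 0) == pytest.approx(expected)

    def test_exhaustive_category_rejected(self):
        whole = P([0, 0, 0, 0], k=1)
        with pytest.raises(ValueError):
            partial_category_ari(whole, 0, P([0, 0, 1, 1]), 0)


GROUP3 = P([0, 0, 0, 1, 1, 1, 2, 2, 2])


def simple_sorts(labels_by_participant):
    """Participants agreeing on the three-way split of 9 items, given labels."""
    return [ParticipantSort(GROUP3, labs) for labs in labels_by_participant]


class TestLabelAssignment:
    def test_unanimous_label_wins_without_secondary(self):
        sorts = simple_sorts([{0: ["beach"], 1: ["road"], 2: ["tree"]}] * 3)
        table = score_and_assign_labels(GROUP3, sorts)
        assert table.primary == {0: "beach", 1: "road", 2: "tree"}
        assert table.secondary == {0: None, 1: None, 2: None}

    def test_stem_variants_pool_their_credit(self):
        sorts = simple_sorts([{0: ["Farm"], 1: ["road"], 2: ["tree"]},
                              {0: ["Farms"], 1: ["road"], 2: ["tree"]},
                              {0: ["Farming"], 1: ["road"], 2: ["tree"]}])
        table = score_and_assign_labels(GROUP3, sorts)
        rows = {r.stemmed_label: r for r in table.category_rows(0)}
        assert table.primary[0] == "farm"
        # each use contributed a partial ARI of 1, summed across participants
        assert rows["farm"].summed_ari == pytest.approx(3.0)

    @pytest.mark.parametrize("sim_ab, expect_secondary", [(0.4, "quiet"),
                                                          (0.6, None)])
    def test_secondary_label_threshold_logic(self, sim_ab, expect_secondary):
        # category 0 credits: beach 3 uses, quiet 2 uses (normalized 2/3),
        # road/tree 0 - the secondary hinges on similarity(beach, quiet)
        sorts = simple_sorts([{0: ["beach"], 1: ["road"], 2: ["tree"]},
                              {0: ["beach", "quiet"], 1: ["road"], 2: ["tree"]},
                              {0: ["beach", "quiet"], 1: ["road"], 2: ["tree"]}])
        provider = TableEmbeddingProvider({
            "beach": [1.0, 0.0],
            "quiet": [sim_ab, np.sqrt(1 - sim_ab ** 2)],
            "road": [-1.0, 0.0],
            "tree": [0.0, 1.0],
        })
        table = score_and_assign_labels(GROUP3, sorts, sim=provider)
        rows = {r.stemmed_label: r for r in table.category_rows(0)}
        assert table.primary[0] == "beach"
        assert rows["quiet"].normalized_ari >= 0.65
        assert provider.similarity("beach", "quiet") == pytest.approx(sim_ab)
        assert table.secondary[0] == expect_secondary

    def test_participant_order_invariance(self):
        sorts = simple_sorts([{0: ["beach"], 1: ["road"], 2: ["tree"]},
                              {0: ["sand"], 1: ["street"], 2: ["tree"]},
                              {0: ["beach"], 1: ["lane"], 2: ["wood"]}])
        t1 = score_and_assign_labels(GROUP3, sorts)
        t2 = score_and_assign_labels(GROUP3, sorts[::-1])
        assert t1.primary == t2.primary
        assert sorted((r.stemmed_label, r.summed_ari) for r in t1.rows) == \
               sorted((r.stemmed_label, r.summed_ari) for r in t2.rows)


class TestCentroidLabel:
    def test_single_label_category_returns_it(self):
        vecs = WordVectorSet(np.array([[1.0, 0.0]]), np.array([0]))
        vocab = {"alpha": [1.0, 0.0], "beta": [0.0, 1.0]}
        assert centroid_label(vecs, vocab) == {0: "alpha"}

    def test_bisector_word_wins(self):
        # two orthogonal member vectors; the bisector vocabulary entry is closest
        vecs = WordVectorSet(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0, 0]))
        inv = 1 / np.sqrt(2)
        vocab = {"x": [1.0, 0.0], "y": [0.0, 1.0], "mid": [inv, inv]}
        assert centroid_label(vecs, vocab) == {0: "mid"}

    def test_duplicates_pull_the_centroid(self):
        vecs = WordVectorSet(np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
                             np.array([0, 0, 0]))
        vocab = {"x": [1.0, 0.0], "y": [0.0, 1.0]}
        assert centroid_label(vecs, vocab) == {0: "x"}

    def test_empty_vocabulary_rejected(self):
        vecs = WordVectorSet(np.array([[1.0, 0.0]]), np.array([0]))
        with pytest.raises(ValueError):
            centroid_label(vecs, {})


class TestFRatio:
    def test_identical_vectors_give_zero(self):
        v = np.tile([1.0, 0.0], (6, 1))
        assert f_ratio(WordVectorSet(v, np.array([0, 0, 0, 1, 1, 1]))) == 0.0

    def test_zero_within_spread_is_infinite(self):
        v = np.array([[1.0, 0], [1.0, 0], [1, 0.0], [0, 1.0], [0, 1], [0, 1.0]])
        assert f_ratio(WordVectorSet(v, np.array([0, 0, 0, 1, 1, 1]))) == np.inf

    def test_matches_one_way_anova_on_line_embedding(self):
        # unit vectors confined to the x-axis: F must equal the 1-D ANOVA F
        xs = np.array([1, 1, -1, -1, -1, 1], dtype=float)
        v = np.column_stack([xs, np.zeros(6)])
        cats = np.array([0, 0, 0, 1, 1, 1])
        expected = f_oneway(xs[:3], xs[3:]).statistic
        assert f_ratio(WordVectorSet(v, cats)) == pytest.approx(expected)

    def test_rotation_invariance(self, rng):
        raw = rng.normal(size=(12, 3))
        cats = np.repeat([0, 1, 2], 4)
        vecs = WordVectorSet.from_raw(raw, cats)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        rotated = WordVectorSet(vecs.vectors @ rot.T, cats)
        assert f_ratio(rotated) == pytest.approx(f_ratio(vecs))

    def test_separation_monotonicity(self):
        # pulling the two category means apart at fixed within-spread raises F
        previous = -np.inf
        for gap in (0.2, 0.5, 0.9):
            base = np.array([gap, np.sqrt(1 - gap ** 2)])
            members = []
            for sign in (1, -1):
                center = np.array([sign * base[0], base[1]])
                for jitter in (-0.05, 0.0, 0.05):
                    ang = np.arctan2(center[1], center[0]) + jitter
                    members.append([np.cos(ang), np.sin(ang)])
            f = f_ratio(WordVectorSet(np.array(members), np.repeat([0, 1], 3)))
            assert f > previous
            previous = f

    def test_degenerate_inputs_rejected(self):
        v = np.array([[1.0, 0], [0, 1.0]])
        with pytest.raises(ValueError):
            f_ratio(WordVectorSet(v, np.array([0, 1])))  # N <= k
        with pytest.raises(ValueError):
            f_ratio(WordVectorSet(v, np.array([0, 0])))  # single category
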