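"""Cross-dimension association analyses of category memberships.

Participants assign every item a category along several dimensions (e.g.
semantic, 3-D structure, 2-D appearance).  Votes are tallied per item and
dimension; the modal category defines the item's membership and the modal
vote share its interparticipant agreement.  The analyses here quantify how
predictable one dimension is from the others:

* ``phi_matrix`` — Pearson correlations between binary category indicators;
* ``ModalBayesClassifier`` / ``bayes_classify`` — prior-only, naive
  (factored posteriors) and non-naive (joint-conditional) Bayes
  classifiers, evaluated by leave-one-out cross-validation over items or
  over participants;
* ``typicality_subsets`` — typical / atypical / random item subsets by
  interparticipant agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "VoteTable",
    "phi_matrix",
    "ModalBayesClassifier",
    "bayes_classify",
    "ClassificationReport",
    "typicality_subsets",
    "chance_accuracy",
]


def chance_accuracy(k: int) -> float:
    """Chance classification accuracy (percent) for a k-category system, 100/k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 100.0 / k


class VoteTable:
    """Per-(item, dimension) category vote counts across participants.

    Construct from a long table with columns ``participant, item, dimension,
    category`` (one row per response) via :meth:`from_long`, or from
    pre-tallied counts (``item, dimension, category, count``) via
    :meth:`from_counts`.  Modal categories break ties lexicographically.
    """

    def __init__(self, counts: pd.DataFrame, raw: Optional[pd.DataFrame] = None):
        required = {"item", "dimension", "category", "count"}
        if not required.issubset(counts.columns):
            raise ValueError(f"counts table needs columns {sorted(required)}")
        if (counts["count"] < 0).any():
            raise ValueError("vote counts must be non-negative")
        self.counts = counts[counts["count"] > 0].reset_index(drop=True)
        self.raw = raw  # long per-participant responses, if available

    @classmethod
    def from_long(cls, responses: pd.DataFrame) -> "VoteTable":
        required = {"participant", "item", "dimension", "category"}
        if not required.issubset(responses.columns):
            raise ValueError(f"long table needs columns {sorted(required)}")
        counts = (responses.groupby(["item", "dimension", "category"])
                  .size().rename("count").reset_index())
        return cls(counts, raw=responses.copy())

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "VoteTable":
        return cls(counts.copy())

    @property
    def dimensions(self) -> List[str]:
        return sorted(self.counts["dimension"].unique())

    def items(self) -> List:
        return sorted(self.counts["item"].unique())

    def categories(self, dimension: str) -> List:
        sub = self.counts[self.counts["dimension"] == dimension]
        return sorted(sub["category"].unique())

    def modal(self, dimension: str, exclude_participant=None) -> pd.Series:
        """Modal category per item (ties lexicographic, hence stable).

        ``exclude_participant`` recomputes the mode without that
        participant's responses (requires raw responses).
        """
        if exclude_participant is not None:
            if self.raw is None:
                raise ValueError("per-participant responses not available")
            sub = self.raw[(self.raw["dimension"] == dimension)
                           & (self.raw["participant"] != exclude_participant)]
            counts = (sub.groupby(["item", "category"]).size()
                      .rename("count").reset_index())
        else:
            counts = self.counts[self.counts["dimension"] == dimension]
        # sort: count descending then category ascending -> first row per item wins
        counts = counts.sort_values(["item", "count", "category"],
                                    ascending=[True, False, True])
        return counts.groupby("item").first()["category"]

    def agreement(self, dimension: str) -> pd.Series:
        """Modal vote share per item (in (0, 1])."""
        counts = self.counts[self.counts["dimension"] == dimension]
        total = counts.groupby("item")["count"].sum()
        top = counts.groupby("item")["count"].max()
        return top / total


def phi_matrix(memberships_a: pd.Series, memberships_b: pd.Series) -> pd.DataFrame:
    """Phi coefficients between all category pairs of two membership vectors.

    Each membership series maps item -> category; per category pair the
    Pearson correlation of the two binary indicator vectors is returned.
    Undefined coefficients (a constant indicator) are reported as NaN.
    """
    common = memberships_a.index.intersection(memberships_b.index)
    if len(common) < 2:
        raise ValueError("need at least two shared items")
    a = memberships_a.loc[common]
    b = memberships_b.loc[common]
    cats_a = sorted(a.unique())
    cats_b = sorted(b.unique())
    out = pd.DataFrame(index=cats_a, columns=cats_b, dtype=float)
    for ca in cats_a:
        x = (a == ca).to_numpy(dtype=float)
        for cb in cats_b:
            y = (b == cb).to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                out.loc[ca, cb] = np.nan
            else:
                out.loc[ca, cb] = float(np.corrcoef(x, y)[0, 1])
    return out


class ModalBayesClassifier(ClassifierMixin, BaseEstimator):
    """Categorical Bayes classifier over modal category labels.

    Three modes: ``prior_only`` always predicts the most probable target
    category; ``naive`` multiplies the per-predictor posteriors
    ``prod_d p(target | predictor_d)``; ``joint`` uses the full joint
    conditional ``p(target | predictor_1, ..., predictor_D)``.  All
    probability tables use add-``alpha`` (Laplace) smoothing.  MAP ties break
    toward the higher-prior category, then lexicographically.

    With a single predictor the naive and joint modes coincide.
    """

    def __init__(self, mode: str = "joint", alpha: float = 1.0):
        self.mode = mode
        self.alpha = alpha

    def fit(self, X, y) -> "ModalBayesClassifier":
        if self.mode not in ("prior_only", "naive", "joint"):
            raise ValueError(f"unknown mode {self.mode!r}")
        X = np.asarray(X, dtype=object)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=object)
        if X.shape[0] != y.size:
            raise ValueError("X and y must have the same length")
        self.classes_ = np.array(sorted(set(y.tolist())), dtype=object)
        if self.classes_.size < 2:
            raise ValueError("need at least two target categories")
        n_classes = self.classes_.size
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[v] for v in y])

        counts = np.bincount(y_idx, minlength=n_classes).astype(float)
        self.class_prior_ = (counts + self.alpha) / (counts + self.alpha).sum()

        self.predictor_levels_ = [np.array(sorted(set(col.tolist())), dtype=object)
                                  for col in X.T]
        # per-predictor posterior tables p(target | predictor_d = v)
        self.conditional_: List[Dict[object, np.ndarray]] = []
        for d, levels in enumerate(self.predictor_levels_):
            table: Dict[object, np.ndarray] = {}
            for v in levels:
                mask = X[:, d] == v
                c = np.bincount(y_idx[mask], minlength=n_classes).astype(float)
                table[v] = (c + self.alpha) / (c + self.alpha).sum()
            self.conditional_.append(table)
        # joint posterior table p(target | predictor combination)
        self.joint_: Dict[Tuple, np.ndarray] = {}
        for combo in product(*self.predictor_levels_):
            mask = np.all(X == np.array(combo, dtype=object), axis=1)
            c = np.bincount(y_idx[mask], minlength=n_classes).astype(float)
            self.joint_[tuple(combo)] = (c + self.alpha) / (c + self.alpha).sum()
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=object)
        if X.ndim == 1:
            X = X[:, None]
        n_classes = self.classes_.size
        uniform = np.full(n_classes, 1.0 / n_classes)
        out = np.empty((X.shape[0], n_classes))
        for i, row in enumerate(X):
            if self.mode == "prior_only":
                p = self.class_prior_.copy()
            elif self.mode == "naive":
                p = np.ones(n_classes)
                for d, v in enumerate(row):
                    p *= self.conditional_[d].get(v, uniform)
            else:
                p = self.joint_.get(tuple(row), uniform).copy()
            total = p.sum()
            out[i] = p / total if total > 0 else uniform
        return out

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        preds = np.empty(proba.shape[0], dtype=object)
        for i, p in enumerate(proba):
            best = np.flatnonzero(p >= p.max() - 1e-12)
            if best.size > 1:  # tie: higher prior, then lexicographic (classes sorted)
                best = best[np.argsort(-self.class_prior_[best], kind="stable")]
                preds[i] = self.classes_[best[0]]
            else:
                preds[i] = self.classes_[best[0]]
        return preds


@dataclass
class ClassificationReport:
    """LOOCV accuracy plus a (true x predicted) confusion matrix."""

    accuracy: float
    confusion: pd.DataFrame
    mode: str
    loocv: str

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.accuracy


def _confusion(true: Sequence, pred: Sequence, classes: Sequence) -> pd.DataFrame:
    cm = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(true, pred):
        cm.loc[t, p] += 1
    return cm


def bayes_classify(
    votes: VoteTable,
    target_dim: str,
    predictor_dims: Sequence[str],
    mode: str = "joint",
    loocv: str = "images",
    alpha: float = 1.0,
    items: Optional[Sequence] = None,
) -> ClassificationReport:
    """LOOCV evaluation of a Bayes classifier between category dimensions.

    ``loocv="images"``: leave one item out, fit the probability tables on the
    remaining items' modal labels, predict the held-out item's target
    category by MAP.  ``loocv="participants"``: leave one participant out,
    fit on the modal labels of the remaining participants (predictors at
    test time are those training modes), and score predictions against the
    left-out participant's raw target responses.  ``items`` restricts the
    evaluation to a subset (e.g. typical exemplars).
    """
    modal_target = votes.modal(target_dim)
    modal_preds = {d: votes.modal(d) for d in predictor_dims}
    universe = modal_target.index
    for d in predictor_dims:
        universe = universe.intersection(modal_preds[d].index)
    if items is not None:
        universe = universe.intersection(pd.Index(items))
    universe = sorted(universe)
    if not universe:
        raise ValueError("no items with modal labels on every dimension")
    X = np.array([[modal_preds[d].loc[it] for d in predictor_dims]
                  for it in universe], dtype=object)
    y = np.array([modal_target.loc[it] for it in universe], dtype=object)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two target categories")

    if loocv == "images":
        preds = np.empty(len(universe), dtype=object)
        for i in range(len(universe)):
            mask = np.ones(len(universe), dtype=bool)
            mask[i] = False
            clf = ModalBayesClassifier(mode=mode, alpha=alpha).fit(X[mask], y[mask])
            preds[i] = clf.predict(X[i:i + 1])[0]
        acc = float(np.mean(preds == y))
        cm = _confusion(y, preds, classes)
        return ClassificationReport(acc, cm, mode, loocv)

    if loocv == "participants":
        if votes.raw is None:
            raise ValueError("participants-mode LOOCV needs per-participant responses")
        participants = sorted(votes.raw["participant"].unique())
        if len(participants) < 2:
            raise ValueError("need at least two participants")
        correct = 0
        total = 0
        all_true: List = []
        all_pred: List = []
        item_pos = {it: i for i, it in enumerate(universe)}
        for p in participants:
            modal_t_rest = votes.modal(target_dim, exclude_participant=p)
            train_items = [it for it in universe if it in modal_t_rest.index]
            Xtr = X[[item_pos[it] for it in train_items]]
            ytr = np.array([modal_t_rest.loc[it] for it in train_items], dtype=object)
            if len(set(ytr.tolist())) < 2:
                continue
            clf = ModalBayesClassifier(mode=mode, alpha=alpha).fit(Xtr, ytr)
            held = votes.raw[(votes.raw["participant"] == p)
                             & (votes.raw["dimension"] == target_dim)]
            held = held[held["item"].isin(item_pos)]
            if held.empty:
                continue
            Xte = X[[item_pos[it] for it in held["item"]]]
            pred = clf.predict(Xte)
            truth = held["category"].to_numpy(dtype=object)
            correct += int((pred == truth).sum())
            total += len(truth)
            all_true.extend(truth.tolist())
            all_pred.extend(pred.tolist())
        if total == 0:
            raise ValueError("no scoreable responses in participants-mode LOOCV")
        cm_classes = sorted(set(all_true) | set(all_pred))
        return ClassificationReport(correct / total,
                                    _confusion(all_true, all_pred, cm_classes),
                                    mode, loocv)

    raise ValueError(f"unknown loocv mode {loocv!r}")


def typicality_subsets(votes: VoteTable, target_dim: str, m: int,
                       seed: Optional[int] = None) -> Dict[str, List]:
    """Typical / atypical / random item subsets of size m per category.

    Typical items have the highest interparticipant agreement within their
    modal category (ties by item id); atypical the lowest; the random subset
    is a seeded uniform draw per category.
    """
    modal = votes.modal(target_dim)
    agree = votes.agreement(target_dim)
    rng = np.random.default_rng(seed)
    out: Dict[str, List] = {"typical": [], "atypical": [], "random": []}
    for cat in sorted(modal.unique()):
        items = sorted(modal.index[modal == cat])
        if len(items) < m:
            raise ValueError(f"category {cat!r} has fewer than {m} items")
        ag = agree.loc[items]
        order_desc = sorted(items, key=lambda it: (-ag.loc[it], it))
        order_asc = sorted(items, key=lambda it: (ag.loc[it], it))
        out["typical"].extend(order_desc[:m])
        out["atypical"].extend(order_asc[:m])
        picks = rng.choice(len(items), size=m, replace=False)
        out["random"].extend(items[i] for i in sorted(picks))
    return out
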