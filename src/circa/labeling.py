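"""Assign participant-generated labels to group-level categories.

Each group-level category is scored against every raw participant category
by a *partial* ARI: both partitions are binarized (the target category
versus everything else merged into one block) and the hard ARI of the two
two-block partitions is taken.  Every label attached to the participant
category is credited with that ARI; labels sharing a stem are merged
(case-folded, lightweight suffix stripping) and credits are summed across
participants and uses.  The top-scoring stem becomes the category's primary
label; a secondary label is added only if it is semantically distinct from
the primary (embedding cosine < 0.50) and still strongly associated with the
category (min-max normalized score >= 0.65).

Word-vector utilities for labelled categories: per-category centroid labels
over unit vectors, and the between/within F-ratio measuring how much
variance in label meaning a category system captures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Protocol, Sequence

import numpy as np

from .agreement import adjusted_rand_index
from .datatypes import ParticipantSort, Partition

__all__ = [
    "stem_label",
    "EmbeddingProvider",
    "TableEmbeddingProvider",
    "LabelScore",
    "LabelScoreTable",
    "partial_category_ari",
    "score_and_assign_labels",
    "WordVectorSet",
    "centroid_label",
    "f_ratio",
]

SECONDARY_SIMILARITY_MAX = 0.50
SECONDARY_NORMALIZED_MIN = 0.65


# ---------------------------------------------------------------------------
# stemming


def _stem_token(token: str) -> str:
    # lightweight suffix stripping: plurals and common verbal/adjectival
    # endings collapse ("farm"/"farms"/"farming" share a stem)
    t = token
    if t.endswith("'s"):
        t = t[:-2]
    for suffix in ("ies", "ing", "ed", "es", "s"):
        if t.endswith(suffix) and len(t) - len(suffix) >= 3:
            if suffix == "s" and t.endswith("ss"):
                continue
            if suffix == "ies":
                return t[:-3] + "i"
            return t[: -len(suffix)]
    return t


def stem_label(label: str) -> str:
    """Case-fold, trim, and stem each token of a (possibly multi-word) label."""
    tokens = re.split(r"\s+", label.strip().lower())
    return " ".join(_stem_token(t) for t in tokens if t)


# ---------------------------------------------------------------------------
# embeddings


class EmbeddingProvider(Protocol):
    """Pluggable word-embedding backend (label -> unit vector, pair -> cosine)."""

    def vector(self, label: str) -> np.ndarray: ...

    def similarity(self, a: str, b: str) -> float: ...


class TableEmbeddingProvider:
    """Deterministic embedding provider backed by an explicit table.

    ``table`` maps labels (or stems) to vectors; lookups are stemmed before
    resolution.  ``strict=True`` raises on unknown labels, otherwise unknown
    pairs score 0 similarity.
    """

    def __init__(self, table: Mapping[str, Sequence[float]], strict: bool = True):
        self._table = {stem_label(k): np.asarray(v, dtype=np.float64)
                       for k, v in table.items()}
        self.strict = strict

    @classmethod
    def from_tsv(cls, path, strict: bool = True) -> "TableEmbeddingProvider":
        table: Dict[str, List[float]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2:
                    table[parts[0]] = [float(x) for x in parts[1:]]
        return cls(table, strict=strict)

    def vector(self, label: str) -> np.ndarray:
        key = stem_label(label)
        if key not in self._table:
            if self.strict:
                raise KeyError(f"no embedding for label {label!r}")
            return np.zeros(1)
        v = self._table[key]
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v

    def similarity(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        if va.size != vb.size or not va.any() or not vb.any():
            return 0.0
        return float(np.dot(va, vb))


# ---------------------------------------------------------------------------
# partial ARIs and label assignment


def _binarize(p: Partition, cluster: int) -> Partition:
    members = p.assignments == cluster
    if members.all() or not members.any():
        raise ValueError(
            "partial ARI needs a non-empty, non-exhaustive target category")
    return Partition(members.astype(np.int64), 2)


def partial_category_ari(group: Partition, g: int, sort: Partition, c: int) -> float:
    """ARI between one group category and one participant category.

    All other categories on each side are merged into a single second block
    ("partialling out"), and the hard ARI of the two binary partitions is
    returned.
    """
    return float(adjusted_rand_index(_binarize(group, g), _binarize(sort, c)))


@dataclass
class LabelScore:
    group_category: int
    stemmed_label: str
    summed_ari: float
    normalized_ari: float = np.nan
    display_label: str = ""


@dataclass
class LabelScoreTable:
    """Per-category label scores plus the primary/secondary assignment."""

    rows: List[LabelScore]
    primary: Dict[int, str] = field(default_factory=dict)
    secondary: Dict[int, Optional[str]] = field(default_factory=dict)

    def category_rows(self, g: int) -> List[LabelScore]:
        return [r for r in self.rows if r.group_category == g]


def score_and_assign_labels(
    group: Partition,
    sorts: Sequence[ParticipantSort],
    sim: Optional[EmbeddingProvider] = None,
) -> LabelScoreTable:
    """Score every stemmed label against every group category and assign names.

    For each group category the credit of a stem is the sum, over all
    participant categories carrying a label with that stem (multiple uses
    included), of the partial ARI between group category and participant
    category.  The primary label is the argmax stem.  A secondary label is
    the best-scoring other stem whose embedding similarity to the primary is
    below 0.50 and whose min-max-normalized credit is at least 0.65; without
    an embedding provider no secondary labels are assigned.
    Invariant to participant order.
    """
    rows: List[LabelScore] = []
    table = LabelScoreTable(rows)
    group_cats = np.unique(group.assignments)
    for g in group_cats:
        credits: Dict[str, float] = {}
        display: Dict[str, str] = {}
        for sort in sorts:
            for c in np.unique(sort.partition.assignments):
                a = partial_category_ari(group, int(g), sort.partition, int(c))
                for label in sort.labels.get(int(c), []):
                    stem = stem_label(label)
                    credits[stem] = credits.get(stem, 0.0) + a
                    display.setdefault(stem, label)
        if not credits:
            continue
        vals = np.array(list(credits.values()))
        lo, hi = float(vals.min()), float(vals.max())
        span = hi - lo
        cat_rows = []
        for stem, score in credits.items():
            norm = (score - lo) / span if span > 0 else 1.0
            cat_rows.append(LabelScore(int(g), stem, score, norm, display[stem]))
        # deterministic order: score descending, then stem
        cat_rows.sort(key=lambda r: (-r.summed_ari, r.stemmed_label))
        rows.extend(cat_rows)
        primary = cat_rows[0].stemmed_label
        table.primary[int(g)] = primary
        secondary = None
        if sim is not None:
            for r in cat_rows[1:]:
                if r.normalized_ari < SECONDARY_NORMALIZED_MIN:
                    break  # sorted by score, nothing further qualifies
                if sim.similarity(primary, r.stemmed_label) < SECONDARY_SIMILARITY_MAX:
                    secondary = r.stemmed_label
                    break
        table.secondary[int(g)] = secondary
    return table


# ---------------------------------------------------------------------------
# word-vector analyses


@dataclass
class WordVectorSet:
    """Unit word vectors with a category assignment per vector."""

    vectors: np.ndarray  # (N, d)
    categories: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.categories = np.asarray(self.categories, dtype=np.int64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != self.categories.size:
            raise ValueError("vectors must be (N, d) with one category per vector")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("vectors must be unit-normalized")

    @property
    def n(self) -> int:
        return int(self.vectors.shape[0])

    @property
    def k(self) -> int:
        return int(np.unique(self.categories).size)

    @classmethod
    def from_raw(cls, vectors: np.ndarray, categories: Sequence[int]) -> "WordVectorSet":
        vectors = np.asarray(vectors, dtype=np.float64)
        norms = np.linalg.norm(vectors, axis=1, keepdims=True)
        if (norms == 0).any():
            raise ValueError("cannot normalize a zero vector")
        return cls(vectors / norms, np.asarray(categories))


def centroid_label(vectors: WordVectorSet,
                   vocabulary: Mapping[str, Sequence[float]]) -> Dict[int, str]:
    """Nearest-vocabulary-word label for each category's mean word vector.

    The centroid is the (unnormalized) mean of the member unit vectors; the
    winning label maximizes cosine similarity to the centroid, ties broken
    lexicographically.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    words = sorted(vocabulary)
    mat = np.asarray([vocabulary[w] for w in words], dtype=np.float64)
    norms = np.linalg.norm(mat, axis=1)
    if (norms == 0).any():
        raise ValueError("vocabulary contains a zero vector")
    mat = mat / norms[:, None]
    out: Dict[int, str] = {}
    for cat in np.unique(vectors.categories):
        centroid = vectors.vectors[vectors.categories == cat].mean(axis=0)
        cnorm = np.linalg.norm(centroid)
        if cnorm == 0:
            out[int(cat)] = words[0]
            continue
        cos = mat @ (centroid / cnorm)
        out[int(cat)] = words[int(np.argmax(cos))]  # argmax = lexicographic tie-break
    return out


def f_ratio(vectors: WordVectorSet, size_weighted: bool = True) -> float:
    """Between/within variance ratio of label embeddings under a category system.

    ``D_between`` sums squared Euclidean distances from the grand-mean vector
    to the category means (weighted by category size by default, matching the
    one-way ANOVA between-group sum of squares); ``D_within`` sums squared
    distances from each vector to its category mean.  The ratio is
    ``(D_between / (k - 1)) / (D_within / (N - k))``.  Internally identical
    categories with distinct means give infinite F.
    """
    N, k = vectors.n, vectors.k
    if k < 2:
        raise ValueError("need at least two categories")
    if N <= k:
        raise ValueError("need more vectors than categories")
    grand = vectors.vectors.mean(axis=0)
    d_between = 0.0
    d_within = 0.0
    for cat in np.unique(vectors.categories):
        members = vectors.vectors[vectors.categories == cat]
        mean = members.mean(axis=0)
        w = members.shape[0] if size_weighted else 1.0
        d_between += w * float(((mean - grand) ** 2).sum())
        d_within += float(((members - mean) ** 2).sum())
    if d_within == 0.0:
        return float("inf") if d_between > 0 else 0.0
    return (d_between / (k - 1)) / (d_within / (N - k))
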