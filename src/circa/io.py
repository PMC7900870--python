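"""Readers and writers for the package's CSV formats, plus run manifests.

Formats (all UTF-8, dot-decimal CSV):

* sorts:       ``participant,item,cluster`` (+ optional labels file
               ``participant,cluster,label``)
* trials:      ``item_i,item_j,same`` (+ optional ``participant,left_label``)
* similarity:  sparse triplets ``i,j,value,count``
* clustering:  ``item,cluster[,primary_label,secondary_label]``

Item and category ids are strings externally and dense 0-based integers
internally; the mapping travels with the returned objects / output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import ParticipantSort, Partition, SimilarityMatrix, TrialRecord

__all__ = [
    "read_sorts",
    "write_sorts",
    "read_trials",
    "write_trials",
    "read_similarity",
    "write_similarity",
    "read_clustering",
    "write_clustering",
    "RunManifest",
]


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # surface the offending line
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def read_sorts(path, labels_path=None) -> Tuple[List[ParticipantSort], List[str]]:
    """Load participant sorts from a long-form CSV.

    Returns ``(sorts, item_ids)`` with items unioned across participants and
    ordered by first appearance.  Every participant must assign every item
    exactly once; duplicates and omissions are errors naming the row.
    """
    df = _read_csv(path)
    required = {"participant", "item", "cluster"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sorts file needs columns {sorted(required)}")
    item_ids = list(dict.fromkeys(df["item"]))
    item_index = {it: i for i, it in enumerate(item_ids)}
    dup = df.duplicated(["participant", "item"])
    if dup.any():
        line = int(dup.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: duplicate (participant, item) at line {line}")

    labels_by_participant: Dict[str, Dict[str, List[str]]] = {}
    if labels_path is not None:
        ldf = _read_csv(labels_path)
        lreq = {"participant", "cluster", "label"}
        if not lreq.issubset(ldf.columns):
            raise ValueError(f"{labels_path}: labels file needs columns {sorted(lreq)}")
        for _, row in ldf.iterrows():
            labels_by_participant.setdefault(row["participant"], {}).setdefault(
                row["cluster"], []).append(row["label"])

    sorts = []
    for participant, group in df.groupby("participant", sort=True):
        if len(group) != len(item_ids):
            missing = set(item_ids) - set(group["item"])
            raise ValueError(
                f"{path}: participant {participant!r} is missing items {sorted(missing)[:5]}")
        cluster_ids = list(dict.fromkeys(group["cluster"]))
        cluster_index = {c: i for i, c in enumerate(cluster_ids)}
        assignments = np.empty(len(item_ids), dtype=np.int64)
        for _, row in group.iterrows():
            assignments[item_index[row["item"]]] = cluster_index[row["cluster"]]
        plabels = labels_by_participant.get(participant, {})
        label_map = {cluster_index[c]: labs for c, labs in plabels.items()
                     if c in cluster_index}
        if not label_map:  # labels optional: fall back to the external cluster id
            label_map = {i: [c] for c, i in cluster_index.items()}
        sorts.append(ParticipantSort(Partition(assignments, len(cluster_ids)), label_map))
    return sorts, item_ids


def write_sorts(sorts: Sequence[ParticipantSort], path, labels_path=None,
                item_ids: Optional[Sequence[str]] = None) -> None:
    rows, label_rows = [], []
    for p, sort in enumerate(sorts):
        pid = f"p{p:03d}"
        for i, c in enumerate(sort.partition.assignments):
            item = item_ids[i] if item_ids is not None else f"item{i:04d}"
            rows.append({"participant": pid, "item": item, "cluster": f"c{int(c)}"})
        for c, labs in sorted(sort.labels.items()):
            for lab in labs:
                label_rows.append({"participant": pid, "cluster": f"c{int(c)}",
                                   "label": lab})
    pd.DataFrame(rows).to_csv(path, index=False)
    if labels_path is not None:
        pd.DataFrame(label_rows).to_csv(labels_path, index=False)


def read_trials(path) -> Tuple[List[TrialRecord], List[str]]:
    """Load same-different trials; returns ``(trials, item_ids)``."""
    df = _read_csv(path)
    required = {"item_i", "item_j", "same"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trials file needs columns {sorted(required)}")
    item_ids = list(dict.fromkeys(pd.concat([df["item_i"], df["item_j"]])))
    index = {it: i for i, it in enumerate(item_ids)}
    trials = []
    for pos, row in df.iterrows():
        if row["same"] not in ("0", "1"):
            raise ValueError(f"{path}: 'same' must be 0/1 at line {int(pos) + 2}")
        trials.append(TrialRecord(
            index[row["item_i"]], index[row["item_j"]], row["same"] == "1",
            participant=row.get("participant") or None,
            left_label=row.get("left_label") or None))
    return trials, item_ids


def write_trials(trials: Sequence[TrialRecord], path,
                 item_ids: Optional[Sequence[str]] = None) -> None:
    def name(i: int) -> str:
        return item_ids[i] if item_ids is not None else f"item{i:04d}"

    rows = [{"item_i": name(t.item_i), "item_j": name(t.item_j),
             "same": int(t.same), "participant": t.participant or "",
             "left_label": t.left_label or ""} for t in trials]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_similarity(S: SimilarityMatrix, path) -> None:
    """Sparse triplet CSV ``i,j,value,count`` over observed upper-triangle pairs."""
    iu, ju, s = S.observed_pairs()
    ids = S.item_ids or [f"item{i:04d}" for i in range(S.n)]
    df = pd.DataFrame({"i": [ids[i] for i in iu], "j": [ids[j] for j in ju],
                       "value": s, "count": S.counts[iu, ju]})
    df.to_csv(path, index=False, float_format="%.10g")


def read_similarity(path) -> SimilarityMatrix:
    df = _read_csv(path)
    required = {"i", "j", "value", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: similarity file needs columns {sorted(required)}")
    ids = list(dict.fromkeys(pd.concat([df["i"], df["j"]])))
    index = {it: i for i, it in enumerate(ids)}
    n = len(ids)
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    observed = np.zeros((n, n), dtype=bool)
    for _, row in df.iterrows():
        a, b = index[row["i"]], index[row["j"]]
        v, c = float(row["value"]), int(row["count"])
        values[a, b] = values[b, a] = v
        counts[a, b] = counts[b, a] = c
        observed[a, b] = observed[b, a] = True
    return SimilarityMatrix(values, observed, counts, item_ids=ids)


def write_clustering(partition: Partition, path,
                     labels: Optional[Dict[int, Tuple[str, Optional[str]]]] = None,
                     item_ids: Optional[Sequence[str]] = None) -> None:
    """CSV ``item,cluster[,primary_label,secondary_label]``, ordered by item."""
    rows = []
    for i, c in enumerate(partition.assignments):
        item = item_ids[i] if item_ids is not None else f"item{i:04d}"
        row = {"item": item, "cluster": int(c)}
        if labels is not None:
            primary, secondary = labels.get(int(c), ("", None))
            row["primary_label"] = primary
            row["secondary_label"] = secondary or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clustering(path) -> Tuple[Partition, List[str]]:
    df = _read_csv(path)
    if not {"item", "cluster"}.issubset(df.columns):
        raise ValueError(f"{path}: clustering file needs columns ['cluster', 'item']")
    item_ids = df["item"].tolist()
    clusters = df["cluster"].astype(int).to_numpy()
    return Partition(clusters, int(clusters.max()) + 1), item_ids


@dataclass
class RunManifest:
    """Reproducibility record written once per CLI run."""

    command: str
    config: dict
    seed: Optional[int]
    inputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: List[str] = field(default_factory=list)
    package_version: str = ""

    @staticmethod
    def digest(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()

    def add_input(self, path) -> None:
        self.inputs[str(path)] = self.digest(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
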