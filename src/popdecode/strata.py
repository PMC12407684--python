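"""Hierarchical stratified sampling into cross-validation folds.

Trials are grouped by recursively refining on a ranked list of
covariates: (1) the chosen labelset (shape+pattern+color+arms values),
(2) the brain areas recorded in the trial's session, (3) trial outcome,
(4) gain/loss condition, (5) learning status, (6) session name.  A group
refines to the next rank only while it holds more trials than there are
folds; otherwise it receives a terminal label.  Members of one group are
then scattered across distinct folds (round-robin with reshuffle for
groups larger than the fold count), which keeps per-fold class
proportions close to the global ones.  Folds rotate into 80/10/10
train/validation/test splits for ten-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default ranked covariate list; each entry maps a metadata row to a key.
DEFAULT_RANK_LIST = [
    "labelset",
    "areas",
    "outcome",
    "gain_loss",
    "learned",
    "session_id",
]


def _key_func(rank: str, feature_cols: list[str]):
    if rank == "labelset":
        return lambda row: tuple(int(row[c]) for c in feature_cols)
    if rank == "areas":
        # areas present in the trial's session (constant per session here;
        # carried in an 'areas' column when provided, else the session id
        # stands in for the recording configuration)
        return lambda row: row.get("areas", row["session_id"])
    if rank == "gain_loss":
        return lambda row: (int(row["gain"]), int(row["loss"]))
    return lambda row: row[rank]


@dataclass
class FoldAssignment:
    fold_of: np.ndarray  # (n_trials,) fold index
    group_of: np.ndarray  # (n_trials,) group label (string)
    n_folds: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group_label": self.group_of, "fold": self.fold_of}
        ).rename_axis("trial_id")


def assign_groups(
    metadata: pd.DataFrame,
    rank_list: list[str] | None = None,
    n_folds: int = 10,
    feature_cols: list[str] | None = None,
) -> np.ndarray:
    """Assign a hierarchical group label to each trial.

    A group is refined by the next covariate on the rank list only while
    its size strictly exceeds ``n_folds``; refinement stops at the end
    of the list.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rank_list = list(rank_list or DEFAULT_RANK_LIST)
    feature_cols = feature_cols or [
        c for c in metadata.columns if c.startswith("feature_")
    ]
    labels = np.empty(len(metadata), dtype=object)
    rows = metadata.to_dict("records")

    def refine(indices: list[int], depth: int, prefix: str) -> None:
        if len(indices) <= n_folds or depth >= len(rank_list):
            for i in indices:
                labels[i] = prefix
            return
        key = _key_func(rank_list[depth], feature_cols)
        buckets: dict = {}
        for i in indices:
            buckets.setdefault(key(rows[i]), []).append(i)
        for k, (bucket_key, members) in enumerate(sorted(buckets.items(), key=lambda kv: str(kv[0]))):
            refine(members, depth + 1, f"{prefix}/{rank_list[depth]}={bucket_key}")

    refine(list(range(len(rows))), 0, "g")
    return labels


def partition_folds(
    group_labels: np.ndarray, n_folds: int = 10, seed: int = 0
) -> FoldAssignment:
    """Scatter each group's members over distinct folds.

    Members are visited in random order and dealt onto a random
    permutation of folds; groups larger than ``n_folds`` wrap around
    after a fresh reshuffle of the fold order, so trials sharing a group
    land in different folds whenever the group fits.
    """
    group_labels = np.asarray(group_labels, dtype=object)
    rng = np.random.default_rng(seed)
    fold_of = np.full(group_labels.size, -1, dtype=int)
    for g in sorted(set(group_labels.tolist()), key=str):
        members = np.flatnonzero(group_labels == g)
        rng.shuffle(members)
        assigned = 0
        while assigned < members.size:
            order = rng.permutation(n_folds)
            take = min(n_folds, members.size - assigned)
            fold_of[members[assigned : assigned + take]] = order[:take]
            assigned += take
    return FoldAssignment(fold_of=fold_of, group_of=group_labels, n_folds=n_folds)


def stratify(
    metadata: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    rank_list: list[str] | None = None,
) -> FoldAssignment:
    """Group assignment followed by fold partitioning."""
    groups = assign_groups(metadata, rank_list=rank_list, n_folds=n_folds)
    return partition_folds(groups, n_folds=n_folds, seed=seed)


def make_split(
    assignment: FoldAssignment, test_fold: int, val_fold: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(train, validation, test) trial-index lists for one fold rotation."""
    if test_fold == val_fold:
        raise ValueError("test and validation folds must differ")
    test = np.flatnonzero(assignment.fold_of == test_fold)
    val = np.flatnonzero(assignment.fold_of == val_fold)
    train = np.flatnonzero(
        (assignment.fold_of != test_fold) & (assignment.fold_of != val_fold)
    )
    return train, val, test


def rotations(n_folds: int = 10):
    """The ten (test, validation) fold pairs enumerating cross-validation."""
    return [(k, (k + 1) % n_folds) for k in range(n_folds)]
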