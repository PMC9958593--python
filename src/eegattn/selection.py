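"""Filter, wrapper and embedded feature selection over the ten feature groups.

Selection operates on whole feature groups: group Fk is the block of that
feature's columns across all channels (10 columns on the default montage),
so k selected groups give a ``n x 10k`` design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.feature_selection import mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.preprocessing import StandardScaler

from .features import GROUP_IDS
from .io import METADATA_COLUMNS

Evaluator = Callable[[Sequence[str]], float]


def group_index(group_id: str) -> int:
    return int(group_id[1:]) - 1


def feature_groups(n_channels: int = 10) -> dict[str, np.ndarray]:
    """Map each group id to its column indices in a feature-major matrix."""
    return {
        gid: np.arange(group_index(gid) * n_channels,
                       (group_index(gid) + 1) * n_channels)
        for gid in GROUP_IDS
    }


def group_columns(subset: Sequence[str], n_channels: int = 10) -> np.ndarray:
    """Column indices of a subset of groups, in the subset's order."""
    groups = feature_groups(n_channels)
    return np.concatenate([groups[g] for g in subset])


def split_feature_frame(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) from a feature table produced by ``features.extract_batch``."""
    feature_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    return df[feature_cols].to_numpy(dtype=float), df["label"].to_numpy()


@dataclass(frozen=True)
class SfsStep:
    added: str
    subset: tuple[str, ...]
    accuracy: float
    retained: bool


@dataclass(frozen=True)
class SelectionResult:
    candidate_order: tuple[str, ...]
    steps: tuple[SfsStep, ...]
    final_subset: tuple[str, ...]
    final_accuracy: float

    def to_dict(self) -> dict:
        return {
            "candidate_order": list(self.candidate_order),
            "steps": [
                {
                    "added": s.added,
                    "subset": list(s.subset),
                    "accuracy_pct": s.accuracy,
                    "retained": s.retained,
                }
                for s in self.steps
            ],
            "final_subset": list(self.final_subset),
            "final_accuracy_pct": self.final_accuracy,
        }


def rank_by_single_group_accuracy(
    evaluator: Evaluator, groups: Sequence[str] = GROUP_IDS
) -> list[tuple[str, float]]:
    """Evaluate each group alone and sort by accuracy descending.

    Ties keep the input order (index-ascending for the default F1..F10).
    """
    scored = []
    for gid in groups:
        try:
            acc = float(evaluator((gid,)))
        except Exception as exc:
            raise RuntimeError(f"evaluator failed on single group {gid}") from exc
        scored.append((gid, acc))
    scored.sort(key=lambda t: -t[1])  # stable: ties keep input order
    return scored


def sfs(candidate_order: Sequence[str], evaluator: Evaluator) -> SelectionResult:
    """Greedy sequential forward selection with strict-improvement retention.

    The first candidate seeds the subset; each later candidate is kept only
    if adding it strictly increases the evaluator accuracy over the best
    subset so far.
    """
    order = tuple(candidate_order)
    if not order:
        raise ValueError("candidate_order is empty")
    seed = order[0]
    try:
        best = float(evaluator((seed,)))
    except Exception as exc:
        raise RuntimeError(f"evaluator failed on seed {seed}") from exc
    subset: tuple[str, ...] = (seed,)
    steps = [SfsStep(added=seed, subset=subset, accuracy=best, retained=True)]
    for candidate in order[1:]:
        trial = subset + (candidate,)
        try:
            acc = float(evaluator(trial))
        except Exception as exc:
            raise RuntimeError(
                f"evaluator failed on subset {trial}; steps so far: {steps}"
            ) from exc
        keep = acc > best
        steps.append(SfsStep(added=candidate, subset=trial, accuracy=acc, retained=keep))
        if keep:
            subset = trial
            best = acc
    return SelectionResult(
        candidate_order=order,
        steps=tuple(steps),
        final_subset=subset,
        final_accuracy=best,
    )


def _minmax_scale_columns(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    return (X - lo) / span


def filter_rank(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "chi2",
    n_channels: int = 10,
    random_state: int = 0,
) -> list[tuple[str, float]]:
    """Rank feature groups by a per-column filter score aggregated per group.

    ``chi2`` operates on min-max scaled columns (the test requires
    non-negative inputs); ``mutual_info`` estimates mutual information
    between each column and the class label.  The group score is the mean
    over the group's columns.
    """
    X = np.asarray(X, dtype=float)
    if method == "chi2":
        scores, _ = sk_chi2(_minmax_scale_columns(X), y)
        scores = np.nan_to_num(scores, nan=0.0)
    elif method == "mutual_info":
        scores = mutual_info_classif(X, y, random_state=random_state)
    else:
        raise ValueError(f"unknown filter method {method!r}")
    groups = feature_groups(n_channels)
    ranked = [(gid, float(scores[cols].mean())) for gid, cols in groups.items()]
    ranked.sort(key=lambda t: (-t[1], group_index(t[0])))
    return ranked


def sweep_k(
    ranking: Sequence[str], evaluator: Evaluator, k_max: int = 10
) -> tuple[list[float], int]:
    """Accuracy of the top-k prefix for k = 1..k_max; returns (curve, best k).

    Ties on the curve resolve to the smallest k.
    """
    ranking = list(ranking)
    if k_max > len(ranking):
        raise ValueError(f"k_max={k_max} exceeds ranking length {len(ranking)}")
    curve = [float(evaluator(tuple(ranking[:k]))) for k in range(1, k_max + 1)]
    best_k = int(np.argmax(curve)) + 1  # argmax returns the first maximum
    return curve, best_k


def embedded_select(
    X: np.ndarray,
    y: np.ndarray,
    importance_threshold: float = 0.5,
    method: str = "l1",
    n_channels: int = 10,
    random_state: int = 0,
) -> list[tuple[str, float]]:
    """Groups whose fitted importance exceeds ``threshold x max importance``.

    ``l1`` fits an L1-penalized linear classifier on standardized columns and
    uses mean |coefficient| per group; ``tree`` uses impurity importances of
    an extra-trees ensemble.
    """
    X = np.asarray(X, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes for embedded selection")
    if method == "l1":
        Xs = StandardScaler().fit_transform(X)
        model = LogisticRegression(
            l1_ratio=1.0, C=1.0, solver="saga", max_iter=5000, tol=1e-3,
            random_state=random_state,
        )
        model.fit(Xs, y)
        col_importance = np.abs(model.coef_).mean(axis=0)
    elif method == "tree":
        model = ExtraTreesClassifier(n_estimators=200, random_state=random_state)
        model.fit(X, y)
        col_importance = model.feature_importances_
    else:
        raise ValueError(f"unknown embedded method {method!r}")
    groups = feature_groups(n_channels)
    importances = {gid: float(col_importance[cols].mean()) for gid, cols in groups.items()}
    cutoff = importance_threshold * max(importances.values())
    if importance_threshold == 0:
        selected = [(gid, imp) for gid, imp in importances.items() if imp > 0]
    else:
        selected = [(gid, imp) for gid, imp in importances.items() if imp > cutoff]
    selected.sort(key=lambda t: (-t[1], group_index(t[0])))
    return selected
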