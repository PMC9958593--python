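"""SVM training/evaluation protocols and the before/after paired comparison."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class SplitSpec:
    """Pooled random split: 60% train / 20% validation / 20% test by default."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be three positive numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass(frozen=True)
class SvmParams:
    C: float = 1.0
    gamma: str | float = "scale"  # 1 / (d * mean column variance)
    kernel: str = "rbf"


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> np.ndarray:
    """Integer split sizes summing to n, by largest-remainder rounding."""
    raw = np.asarray(fractions) * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def split_dataset(
    y: np.ndarray, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation/test index sets.

    Stratified by default: each class is shuffled and split with
    largest-remainder rounding so per-class proportions are within one
    sample of the global fractions.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(spec.seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    if spec.stratified:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            if len(idx) < 3:
                raise ValueError(
                    f"class {cls!r} has {len(idx)} samples; cannot stratify"
                )
            rng.shuffle(idx)
            counts = _largest_remainder_counts(len(idx), spec.fractions)
            if (counts == 0).any():
                raise ValueError(
                    f"class {cls!r} too small for a sample in every split"
                )
            bounds = np.cumsum(counts)[:-1]
            for part, chunk in zip(parts, np.split(idx, bounds)):
                part.append(chunk)
    else:
        idx = rng.permutation(len(y))
        counts = _largest_remainder_counts(len(idx), spec.fractions)
        bounds = np.cumsum(counts)[:-1]
        for part, chunk in zip(parts, np.split(idx, bounds)):
            part.append(chunk)
    train, val, test = (np.sort(np.concatenate(p)) for p in parts)
    return train, val, test


def train_and_eval(
    X: np.ndarray,
    y: np.ndarray,
    columns: np.ndarray | None = None,
    spec: SplitSpec = SplitSpec(),
    svm: SvmParams = SvmParams(),
    split: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
):
    """Fit an RBF SVM on the train split; report train/val/test accuracy (%).

    Columns are z-scored with statistics fit on the training split only.
    A precomputed ``split`` can be supplied so several feature subsets are
    compared on identical partitions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if columns is not None:
        X = X[:, np.asarray(columns)]
    if split is None:
        split = split_dataset(y, spec)
    train, val, test = split
    if len(np.unique(y[train])) < 2:
        raise ValueError("training split contains a single class")
    scaler = StandardScaler().fit(X[train])
    model = SVC(C=svm.C, gamma=svm.gamma, kernel=svm.kernel)
    model.fit(scaler.transform(X[train]), y[train])
    accs = {
        name: float(np.mean(model.predict(scaler.transform(X[part])) == y[part])) * 100.0
        for name, part in (("train", train), ("validation", val), ("test", test))
    }
    return model, accs


def make_subset_evaluator(
    X: np.ndarray,
    y: np.ndarray,
    split: tuple[np.ndarray, np.ndarray, np.ndarray],
    svm: SvmParams = SvmParams(),
    n_channels: int = 10,
    metric: str = "validation",
):
    """Evaluator mapping a feature-group subset to its accuracy (%) on a
    fixed split — the wrapper criterion used for ranking and SFS."""
    from .selection import group_columns

    def evaluate(subset: Sequence[str]) -> float:
        cols = group_columns(tuple(subset), n_channels)
        _, accs = train_and_eval(X, y, columns=cols, svm=svm, split=split)
        return accs[metric]

    return evaluate


def subject_holdout_eval(
    features: pd.DataFrame,
    columns: np.ndarray | None = None,
    svm: SvmParams = SvmParams(),
) -> pd.DataFrame:
    """Per-subject accuracy: train on session 1, test on session 2.

    ``features`` is a feature table with label/subject/session metadata.
    """
    from .selection import split_feature_frame

    X, y = split_feature_frame(features)
    if columns is not None:
        X = X[:, np.asarray(columns)]
    subjects = sorted(features["subject"].unique())
    rows = []
    session = features["session"].to_numpy()
    subj_col = features["subject"].to_numpy()
    for subject in subjects:
        train_mask = (subj_col == subject) & (session == 1)
        test_mask = (subj_col == subject) & (session == 2)
        if not train_mask.any() or not test_mask.any():
            raise ValueError(f"subject {subject!r} is missing a session")
        if len(np.unique(y[train_mask])) < 2:
            raise ValueError(f"subject {subject!r} has a single-class session 1")
        scaler = StandardScaler().fit(X[train_mask])
        model = SVC(C=svm.C, gamma=svm.gamma, kernel=svm.kernel)
        model.fit(scaler.transform(X[train_mask]), y[train_mask])
        pred = model.predict(scaler.transform(X[test_mask]))
        rows.append(
            {"subject": subject, "accuracy": float(np.mean(pred == y[test_mask])) * 100.0}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paired before/after statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedStats:
    n: int
    mean_before: float
    mean_after: float
    sd_before: float
    sd_after: float
    mean_diff: float
    sd_diff: float
    n_improved: int
    t_stat: float
    df: int
    p_value: float
    sw_p_value: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def paired_comparison(
    before: Sequence[float], after: Sequence[float]
) -> PairedStats:
    """Two-sided paired t-test plus Shapiro-Wilk normality of the differences.

    Standard deviations use the n-1 (sample) denominator.  Raises when the
    differences have zero variance (t undefined) or there are fewer than
    2 pairs; the Shapiro-Wilk p is NaN below 3 pairs (test undefined there).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after length mismatch")
    n = before.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = after - before
    sd_diff = float(diff.std(ddof=1))
    if sd_diff == 0.0:
        raise ValueError("zero-variance differences: paired t undefined")
    t_stat, p_value = stats.ttest_rel(after, before)
    sw_p = stats.shapiro(diff)[1] if n >= 3 else float("nan")
    return PairedStats(
        n=n,
        mean_before=float(before.mean()),
        mean_after=float(after.mean()),
        sd_before=float(before.std(ddof=1)),
        sd_after=float(after.std(ddof=1)),
        mean_diff=float(diff.mean()),
        sd_diff=sd_diff,
        n_improved=int((diff > 0).sum()),
        t_stat=float(t_stat),
        df=n - 1,
        p_value=float(p_value),
        sw_p_value=float(sw_p),
    )


def summarize_table7(table) -> PairedStats:
    """Summary statistics of a packaged before/after accuracy table."""
    return paired_comparison(table.accuracy_before, table.accuracy_after)


@dataclass
class EvalReport:
    """Aggregated pipeline outcome: pooled accuracies, selection and stats."""

    pooled_before: dict = field(default_factory=dict)
    pooled_after: dict = field(default_factory=dict)
    selected_groups: list = field(default_factory=list)
    per_subject: pd.DataFrame | None = None
    paired: PairedStats | None = None

    def to_dict(self) -> dict:
        out = {
            "pooled_before": self.pooled_before,
            "pooled_after": self.pooled_after,
            "selected_groups": list(self.selected_groups),
        }
        if self.per_subject is not None:
            out["per_subject"] = self.per_subject.to_dict(orient="records")
        if self.paired is not None:
            out["paired"] = self.paired.to_dict()
        return out
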