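"""Classification metrics and the group-power nonparametric comparison.

AUC is computed from the rank statistic (the Mann-Whitney formulation):
the probability that a random positive scores above a random negative,
with ties counted half.  Multiclass problems use unweighted (macro)
averaging: per-class one-vs-rest AUCs and per-class precision/recall are
averaged without class-size weights.  Confusion matrices are expressed as
percentages of the test set.

The spectral-power comparison (used for gender analysis) aggregates Welch
total power per subject within each of the 19 electrode groups and applies
the Mann-Whitney U test: exact p-values by enumeration for small samples
(both n <= 8, no ties), tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .clustering import ClusterAssignment
from .swd import SWDParams, welch_psd

__all__ = [
    "EvaluationReport",
    "binary_metrics",
    "multiclass_metrics",
    "group_band_power",
    "mann_whitney_u",
    "rank_auc",
]


class MetricsError(ValueError):
    """Invalid metric input."""


@dataclass
class EvaluationReport:
    """Per-split metrics plus a percentage confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    auc: float
    confusion: np.ndarray  # k x k, percentages of the test set
    classes: list[str] = field(default_factory=list)
    per_class_auc: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = float(np.sum(self.confusion))
        if abs(total - 100.0) > 0.1:
            raise MetricsError(f"confusion percentages sum to {total}, not 100")

    def confusion_table(self) -> str:
        """Render the confusion matrix in the percentage-table layout."""
        names = self.classes or [str(i) for i in range(len(self.confusion))]
        width = max(8, max(len(n) for n in names) + 2)
        lines = [" " * width + "".join(f"{n:>{width}}" for n in names)
                 + f"{'Total':>{width}}"]
        for i, name in enumerate(names):
            row = self.confusion[i]
            lines.append(f"{name:>{width}}"
                         + "".join(f"{v:>{width}.1f}" for v in row)
                         + f"{row.sum():>{width}.1f}")
        col_tot = self.confusion.sum(axis=0)
        lines.append(f"{'Total':>{width}}"
                     + "".join(f"{v:>{width}.1f}" for v in col_tot)
                     + f"{self.confusion.sum():>{width}.1f}")
        return "\n".join(lines)


def rank_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) statistic, ties counted half."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = y_true.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricsError("AUC undefined: only one class present")
    ranks = stats.rankdata(y_score)  # midranks for ties
    r_pos = float(np.sum(ranks[y_true == 1]))
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def _confusion_percent(y_true: np.ndarray, y_pred: np.ndarray,
                       k: int) -> np.ndarray:
    counts = np.zeros((k, k))
    for t, p in zip(y_true, y_pred):
        counts[int(t), int(p)] += 1
    return 100.0 * counts / counts.sum()


def binary_metrics(y_true, y_score, threshold: float = 0.5,
                   classes: tuple[str, str] = ("NoBul", "Bul"),
                   ) -> EvaluationReport:
    """Accuracy, precision, recall, rank AUC and percentage confusion for a
    binary problem.  Class 1 (``Bul``, the detection target) is positive.

    ``y_score`` is the positive-class probability; prediction is
    ``score >= threshold``.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape:
        raise MetricsError("y_true and y_score length mismatch")
    if np.any((y_score < 0) | (y_score > 1)):
        raise MetricsError("scores must lie in [0, 1]")
    y_pred = (y_score >= threshold).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    accuracy = float(np.mean(y_pred == y_true))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    auc = rank_auc(y_true, y_score)
    # confusion laid out with the positive (Bul) class first
    remap = {1: 0, 0: 1}
    conf = _confusion_percent([remap[t] for t in y_true],
                              [remap[p] for p in y_pred], 2)
    return EvaluationReport(accuracy=accuracy, precision=precision,
                            recall=recall, auc=auc, confusion=conf,
                            classes=[classes[1], classes[0]])


def multiclass_metrics(y_true, y_scores, classes: list[str] | None = None,
                       ) -> EvaluationReport:
    """Macro-averaged metrics for the 4-class problem.

    Accuracy by argmax; precision/recall as unweighted means of per-class
    values; AUC as the unweighted mean of one-vs-rest rank AUCs.  A class
    absent from ``y_true`` has undefined AUC: it is excluded from the mean
    with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_scores = np.asarray(y_scores, dtype=float)
    k = y_scores.shape[1]
    if not np.allclose(y_scores.sum(axis=1), 1.0, atol=1e-6):
        raise MetricsError("score rows must sum to 1")
    y_pred = np.argmax(y_scores, axis=1)
    accuracy = float(np.mean(y_pred == y_true))

    precisions, recalls, aucs = [], [], []
    for c in range(k):
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
        if np.any(y_true == c):
            aucs.append(rank_auc((y_true == c).astype(int), y_scores[:, c]))
        else:
            warnings.warn(f"class {c} absent from y_true; AUC excluded",
                          stacklevel=2)
    conf = _confusion_percent(y_true, y_pred, k)
    return EvaluationReport(
        accuracy=accuracy, precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)), auc=float(np.mean(aucs)),
        confusion=conf, classes=classes or [str(i) for i in range(k)],
        per_class_auc=[float(a) for a in aucs],
    )


def group_band_power(dataset, assignment: ClusterAssignment,
                     params: SWDParams = SWDParams()) -> np.ndarray:
    """Per-subject, per-group average spectral power, shape (subjects, 19).

    For each subject and electrode group: the mean over member channels and
    trials of Welch total power (PSD integrated over frequency).
    """
    group_of = assignment.group_of
    if np.unique(group_of).size != 19:
        raise MetricsError("assignment must have 19 non-empty groups")
    subjects = sorted(set(dataset.subject_ids))
    out = np.zeros((len(subjects), 19))
    for si, subj in enumerate(subjects):
        idx = [i for i, s in enumerate(dataset.subject_ids) if s == subj]
        data = np.stack([dataset.trials[i].data for i in idx])  # (t, ch, s)
        freqs, psd = welch_psd(data, params)
        total = np.trapezoid(psd, freqs, axis=-1)  # (trials, channels)
        for g in range(1, 20):
            out[si, g - 1] = total[:, group_of == g].mean()
    return out


def _exact_mwu_p(u: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    """Two-sided exact p by enumerating all assignments of ranks to group 1."""
    ranks = stats.rankdata(pooled)
    const = n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    stat = abs(min(u, n1 * n2 - u) - mu)
    count = 0
    total = comb(n1 + n2, n1)
    for subset in combinations(range(n1 + n2), n1):
        u_s = float(np.sum(ranks[list(subset)])) - const
        if abs(min(u_s, n1 * n2 - u_s) - mu) >= stat - 1e-12:
            count += 1
    return count / total


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U (group A) with a two-sided p-value.

    Exact p by enumeration when both samples have at most 8 observations;
    tie-corrected normal approximation (with continuity correction)
    otherwise.  U is computed from rank sums with midrank ties.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MetricsError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(np.sum(ranks[:a.size])) - a.size * (a.size + 1) / 2.0
    if a.size <= 8 and b.size <= 8:
        p = _exact_mwu_p(u_a, a.size, b.size, pooled)
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic")
        p = float(p)
    return u_a, min(p, 1.0)
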