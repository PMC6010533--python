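"""ROC/AUC machinery, per-study benchmarking and threshold calibration.

Validation of an epitope predictor against literature screening studies
is done per study: each study contributes its own ROC AUC, methods are
compared by the unweighted mean AUC across studies and by a paired
Wilcoxon signed-rank test with Pratt's treatment of zero differences,
and operating thresholds on the 0-100 combined percentile score are
calibrated by averaging sensitivity/specificity across studies.

Score orientation: percentile-type scores (Imm, HLA, combined) are
*lower* for predicted epitopes, raw network output is *higher*; the
``orientation`` argument handles both uniformly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudySet",
    "ConfusionCounts",
    "roc_points",
    "auc",
    "per_study_auc",
    "wilcoxon_pratt",
    "confusion_at_threshold",
    "sensitivity",
    "specificity",
    "fraction_synthesized",
    "threshold_table",
]


@dataclass
class StudySet:
    """One validation study: its positive and negative peptides."""

    study_id: str
    positives: list[str]
    negatives: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(
                f"study {self.study_id}: peptides appear as both positive and "
                f"negative: {sorted(overlap)[:3]}..."
            )

    @property
    def peptides(self) -> list[str]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.positives) + [0] * len(self.negatives))


def study_sets_from_frame(df: pd.DataFrame) -> list[StudySet]:
    """Build StudySets from a long table with columns study_id, peptide, label."""
    out = []
    for sid, g in df.groupby("study_id", sort=True):
        pos = g.loc[g["label"] == 1, "peptide"].tolist()
        neg = g.loc[g["label"] == 0, "peptide"].tolist()
        out.append(StudySet(str(sid), pos, neg))
    return out


def _oriented(scores: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "higher":
        return scores
    if orientation == "lower":
        return -scores
    raise ValueError(f"orientation must be 'higher' or 'lower', got {orientation!r}")


def roc_points(
    scores: Sequence[float], labels: Sequence[int], orientation: str = "higher"
) -> np.ndarray:
    """ROC staircase as an array of (FPR, TPR) rows from (0,0) to (1,1).

    Tied scores are grouped at a single cutoff.  ``orientation="lower"``
    treats smaller scores as more positive (percentile-type scores).
    """
    s = _oriented(np.asarray(scores, dtype=float), orientation)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # group ties: emit a point after each distinct score value
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    cut_ends = np.append(distinct, len(s) - 1)
    tp = np.cumsum(y == 1)[cut_ends]
    fp = np.cumsum(y == 0)[cut_ends]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    return np.column_stack([fpr, tpr])


def auc(
    scores: Sequence[float], labels: Sequence[int], orientation: str = "higher"
) -> float:
    """Area under the ROC curve by trapezoidal integration.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one half (Mann-Whitney identity); 0.5 is
    random, 1.0 perfect.
    """
    pts = roc_points(scores, labels, orientation)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def per_study_auc(
    study_sets: Sequence[StudySet],
    scores: Mapping[str, float],
    orientation: str = "lower",
) -> tuple[pd.DataFrame, float]:
    """Per-study AUC table plus the unweighted mean across valid studies.

    ``scores`` maps peptide sequence to its score.  Studies with a single
    class (or unscorable) are reported with NaN and excluded from the
    mean, with a warning.
    """
    rows = []
    for st in study_sets:
        try:
            vals = np.array([scores[p] for p in st.peptides], dtype=float)
            a = auc(vals, st.labels, orientation)
        except (KeyError, ValueError) as exc:
            warnings.warn(f"study {st.study_id} skipped: {exc}", stacklevel=2)
            a = float("nan")
        rows.append({"study_id": st.study_id, "auc": a})
    df = pd.DataFrame(rows)
    return df, float(df["auc"].mean(skipna=True))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test, Pratt zero handling


def _pratt_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks of |d| including zeros; returns (ranks, nonzero mask)."""
    ad = np.abs(diffs)
    order = np.argsort(ad, kind="stable")
    ranks = np.empty(len(ad))
    sorted_ad = ad[order]
    i = 0
    while i < len(ad):
        j = i
        while j + 1 < len(ad) and sorted_ad[j + 1] == sorted_ad[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks, diffs != 0


def wilcoxon_pratt(auc_a: Sequence[float], auc_b: Sequence[float]) -> float:
    """Two-sided matched-pair signed-rank test with Pratt's zero method.

    Zero differences are ranked together with the rest and then dropped
    from the statistic.  For n <= 12 pairs the p-value is computed by
    exact enumeration of all sign assignments of the nonzero ranks;
    beyond that a normal approximation with tie and zero corrections is
    used.  All-zero differences give p = 1.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    n = d.size
    ranks, nonzero = _pratt_ranks(d)
    r = ranks[nonzero]
    signs_pos = d[nonzero] > 0
    m = r.size
    if m == 0:
        return 1.0
    w_plus = float(r[signs_pos].sum())
    total = float(r.sum())
    center = total / 2.0
    dev = abs(w_plus - center)

    if n <= 12:
        # exact: enumerate all 2^m sign assignments of the nonzero ranks
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=m):
            w = float(np.dot(signs, r))
            if abs(w - center) >= dev - 1e-12:
                count += 1
        return count / 2.0**m

    # normal approximation (Pratt): zeros contribute to ranks but not W
    all_ranks = ranks
    mn = (all_ranks.sum() - ranks[~nonzero].sum()) / 2.0  # = total/2
    var = float(np.sum(r**2)) / 4.0
    if var == 0:
        return 1.0
    z = (w_plus - mn) / np.sqrt(var)
    from scipy.stats import norm

    return float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Threshold calibration


@dataclass
class ConfusionCounts:
    """Confusion-matrix counts at one decision threshold."""

    tp: int
    fp: int
    tn: int
    fn: int


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Confusion counts on the 0-100 combined scale.

    A peptide is predicted immunogenic iff its score is <= threshold
    (low percentile = predicted epitope).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = s <= threshold
    return ConfusionCounts(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        tn=int((~pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN) x 100."""
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: no positive peptides")
    return 100.0 * c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP) x 100."""
    if c.tn + c.fp == 0:
        raise ValueError("specificity undefined: no negative peptides")
    return 100.0 * c.tn / (c.tn + c.fp)


def fraction_synthesized(c: ConfusionCounts) -> float:
    """(TP + FP) / (TP + TN + FP + FN) x 100 — peptides one would synthesize."""
    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        raise ValueError("fraction undefined: no peptides")
    return 100.0 * (c.tp + c.fp) / total


def threshold_table(
    study_sets: Sequence[StudySet],
    combined_scores: Mapping[str, float],
    cutoffs: Sequence[float] = (8, 18, 36, 43, 66),
) -> pd.DataFrame:
    """Average operating characteristics across studies at each cutoff.

    For each cutoff, sensitivity, specificity and the fraction of
    peptides to synthesize are computed per study and averaged
    (unweighted); studies where a ratio is undefined are skipped for
    that column.
    """
    rows = []
    for t in cutoffs:
        sens, spec, frac = [], [], []
        for st in study_sets:
            vals = [combined_scores[p] for p in st.peptides]
            c = confusion_at_threshold(vals, st.labels, t)
            try:
                sens.append(sensitivity(c))
            except ValueError:
                pass
            try:
                spec.append(specificity(c))
            except ValueError:
                pass
            try:
                frac.append(fraction_synthesized(c))
            except ValueError:
                pass
        rows.append(
            {
                "threshold": t,
                "avg_sensitivity": float(np.mean(sens)) if sens else float("nan"),
                "avg_specificity": float(np.mean(spec)) if spec else float("nan"),
                "avg_fraction_synthesized": float(np.mean(frac)) if frac else float("nan"),
            }
        )
    return pd.DataFrame(rows)
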