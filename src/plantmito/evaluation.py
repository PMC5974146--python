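"""Performance measurement: confusion metrics, ROC/PR curves, trapezoidal
AUC, bootstrap AUC comparison, table reconstruction from printed rates, and
the N-terminal window-length sweep."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import models
from .features import FeatureConfig, ProfileMatrix, assemble_features, scale_profile
from .seqdata import ProteinRecord


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """Six standard binary-classification metrics.

    ``undefined`` names metrics whose denominator was zero (reported as NaN,
    except MCC which falls back to 0 by convention).
    """

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    mcc: float
    undefined: tuple[str, ...] = ()


def confusion(labels: Sequence[int], calls: Sequence[int]) -> ConfusionCounts:
    y = np.asarray(labels, dtype=int)
    c = np.asarray(calls, dtype=int)
    if y.shape != c.shape:
        raise EvaluationError("labels and calls differ in length")
    return ConfusionCounts(
        tp=int(((y == 1) & (c == 1)).sum()),
        fp=int(((y == 0) & (c == 1)).sum()),
        tn=int(((y == 0) & (c == 0)).sum()),
        fn=int(((y == 1) & (c == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, accuracy, precision, F1 and MCC.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), 0 when the
    denominator vanishes (flagged undefined).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    acc = ratio(tp + tn, tp + fp + tn + fn, "accuracy")
    prec = ratio(tp, tp + fp, "precision")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricsReport(sens, spec, acc, prec, f1, mcc, tuple(undefined))


def counts_from_rates(sensitivity: float, specificity: float,
                      n_pos: int, n_neg: int) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed rates (round-half-up).

    Used to recover the full metric set behind published sensitivity/
    specificity pairs at known class sizes.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise EvaluationError("rates must be in [0, 1]")
    tp = math.floor(sensitivity * n_pos + 0.5)
    tn = math.floor(specificity * n_neg + 0.5)
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def _check_scores(labels, scores):
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise EvaluationError("labels and scores differ in length")
    if len(np.unique(y)) < 2:
        raise EvaluationError("need at least one example of each class")
    return y, s


def roc_points(labels: Sequence[int], scores: Sequence[float]) -> list[tuple[float, float]]:
    """(FPR, TPR) points, one per distinct score threshold plus endpoints.

    Tied scores are grouped at a single threshold (call rule: score >=
    threshold is positive), so the curve steps diagonally through ties.
    """
    y, s = _check_scores(labels, scores)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    points = [(0.0, 0.0)]
    order = np.argsort(-s, kind="stable")
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[order[j]] == s[order[i]]:
            tp += int(y[order[j]] == 1)
            fp += int(y[order[j]] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return points


def pr_points(labels: Sequence[int], scores: Sequence[float]) -> list[tuple[float, float]]:
    """(recall, precision) points per distinct threshold, ties grouped."""
    y, s = _check_scores(labels, scores)
    n_pos = int((y == 1).sum())
    order = np.argsort(-s, kind="stable")
    points = []
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[order[j]] == s[order[i]]:
            tp += int(y[order[j]] == 1)
            fp += int(y[order[j]] == 0)
            j += 1
        points.append((tp / n_pos, tp / (tp + fp)))
        i = j
    return points


def auc_trapezoid(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal-rule area under a curve given as x-ordered (x, y) points.

    On ROC points from tie-free scores this equals the rank-based
    concordance probability (the Mann-Whitney statistic)."""
    pts = np.asarray(points, dtype=float)
    if (np.diff(pts[:, 0]) < 0).any():
        raise EvaluationError("points must be ordered by x")
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    return auc_trapezoid(roc_points(labels, scores))


def bootstrap_auc_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """One-sided paired bootstrap p-value for AUC(a) > AUC(b).

    Examples are resampled with replacement within each class (keeping both
    classes represented, the paired stratified design); p is the fraction of
    replicates where AUC(a) fails to exceed AUC(b), with exact AUC ties
    contributing one half.  Small p supports the claim that scorer a ranks
    better than scorer b.  Deterministic for a fixed seed.
    """
    y, sa = _check_scores(labels, scores_a)
    _, sb = _check_scores(labels, scores_b)
    if n_boot < 100:
        import warnings

        warnings.warn("n_boot < 100 gives a very coarse p-value", stacklevel=2)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    worse = 0.0
    for _ in range(n_boot):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        auc_a = roc_auc(y[idx], sa[idx])
        auc_b = roc_auc(y[idx], sb[idx])
        if auc_a < auc_b:
            worse += 1.0
        elif auc_a == auc_b:
            worse += 0.5
    return worse / n_boot


def window_sweep(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, ProfileMatrix],
    windows: Sequence[int] = range(5, 51),
    svm_config: models.SVMConfig | None = None,
    seed: int = 0,
    k: int = 10,
    blocks: tuple[str, ...] = ("AAFreq.NT", "PSSM.NT"),
) -> pd.DataFrame:
    """Mean CV AUC of the N-terminal blocks at each window length.

    Reproduces the window-length experiment shape: for every window L the
    N-terminal frequency and profile features are rebuilt and scored by
    stratified k-fold SVM cross-validation.  Returns a (window, mean_cv_auc)
    table.
    """
    labeled = [r for r in records if r.label in ("positive", "negative")]
    y = np.array([1 if r.label == "positive" else 0 for r in labeled])
    scaled = {pid: (p if p.scaled else scale_profile(p)) for pid, p in profiles.items()}
    rows = []
    for L in windows:
        config = FeatureConfig(nterm_window=L, blocks_enabled=blocks)
        X = np.vstack([
            assemble_features(r, scaled.get(r.id), None, config).values for r in labeled
        ])
        cv = models.run_cv(X, y, kind="svm", svm_config=svm_config, k=k, seed=seed)
        rows.append({"window": int(L), "mean_cv_auc": cv.mean_auc})
    return pd.DataFrame(rows)


# --- score-table IO ---------------------------------------------------------

def write_scores(path: str | Path, ids: Sequence[str], labels: Sequence[int] | None,
                 scores: Sequence[float]) -> None:
    """Delimited score file (protein_id, label, score); label -1 if unknown.
    This is also the import format for third-party tool scores."""
    with open(path, "w") as fh:
        fh.write("protein_id\tlabel\tscore\n")
        for i, pid in enumerate(ids):
            lab = -1 if labels is None else int(labels[i])
            fh.write(f"{pid}\t{lab}\t{float(scores[i])!r}\n")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "label", "score"}
    if not required <= set(df.columns):
        raise EvaluationError(f"{path}: expected columns {sorted(required)}")
    return df
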