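"""Specificity-calibrated decision thresholds.

Raw classifier scores are converted into decisions at a requested estimated
specificity using the empirical score distribution of a held-out negative
set (the specificity-estimation set).  The table stores the raw scores, not
a parametric fit; thresholds are step-function quantiles, handled
conservatively at ties (every score equal to the threshold counts as a
positive call).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

STANDARD_LEVELS = (0.90, 0.95, 0.99)


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationTable:
    """Sorted (descending) scores of the calibration negatives."""

    scores: np.ndarray
    n_negatives: int

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))[::-1]
        if self.n_negatives != len(self.scores):
            raise CalibrationError("n_negatives must equal the stored score count")


def build_calibration(scores: Sequence[float]) -> CalibrationTable:
    """Store the negative-score distribution.  Warns (via a flag in the
    returned table) below 100 scores, where quantiles are coarse."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise CalibrationError("no scores to calibrate on")
    if not np.isfinite(scores).all():
        raise CalibrationError("non-finite calibration scores")
    table = CalibrationTable(scores, len(scores))
    table.small_sample = len(scores) < 100
    return table


def threshold_for_specificity(table: CalibrationTable, level: float) -> float:
    """Smallest threshold t with (negatives scoring >= t) / n <= 1 - level.

    By construction the empirical specificity on the calibration set at t is
    >= level.  If even the maximum score is exceeded too often (level close
    to 1 with few negatives), t lies strictly above the maximum negative
    score, making the calibration-set specificity exactly 1.
    """
    if not (0 < level < 1):
        raise CalibrationError("specificity level must be in (0, 1)")
    n = table.n_negatives
    # floor of (1-level)*n; the epsilon guards binary-float artifacts such as
    # (1 - 0.9) * 10 evaluating just below 1
    allowed = math.floor((1.0 - level) * n + 1e-9)
    ascending = table.scores[::-1]
    values, first_idx = np.unique(ascending, return_index=True)
    counts_ge = n - first_idx  # negatives scoring >= each unique value
    # smallest threshold whose false-positive count fits the budget; ties at
    # a value all count as above it, so a tied block either fits or is skipped
    for v, c in zip(values, counts_ge):
        if c <= allowed:
            return float(v)
    top = float(values[-1])
    return top + max(1e-9, 1e-9 * abs(top))


def classify(scores: Sequence[float], threshold: float) -> np.ndarray:
    """Binary calls: score >= threshold -> positive (boundary inclusive)."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def empirical_specificity(table: CalibrationTable, threshold: float) -> float:
    return float((table.scores < threshold).mean())


def write_calibration(path: str | Path, table: CalibrationTable,
                      levels: Sequence[float] = STANDARD_LEVELS) -> None:
    """Serialize thresholds for the standard levels plus the raw scores."""
    with open(path, "w") as fh:
        fh.write("# level\tthreshold\n")
        for level in levels:
            fh.write(f"{level}\t{float(threshold_for_specificity(table, level))!r}\n")
        fh.write("# scores\n")
        for s in table.scores:
            fh.write(f"{float(s)!r}\n")


def read_calibration(path: str | Path) -> CalibrationTable:
    scores = []
    in_scores = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("# scores"):
            in_scores = True
            continue
        if in_scores and line.strip():
            scores.append(float(line))
    return build_calibration(scores)
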