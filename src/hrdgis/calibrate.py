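"""Cutoff calibration against a reference HRD assay, plus a depth helper.

Given per-sample scores and reference HRD labels, the calibration sweeps an
integer cutoff grid, computes Cohen's kappa and the usual confusion
statistics at every cutoff, and selects the lower end of the maximal
contiguous kappa-maximizing interval — the choice that classifies the most
samples as positive, i.e. maximizes the number of patients eligible for
therapy among equally concordant cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "CalibrationError",
    "ConfusionTable",
    "CutoffScan",
    "cohens_kappa",
    "confusion_stats",
    "scan_cutoffs",
    "min_depth_for_detection",
]

DEFAULT_GRID = range(0, 301)


class CalibrationError(ValueError):
    """Raised for degenerate calibration input."""


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 agreement table; *positive* means HRD by the reference assay."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise CalibrationError("negative cell count")
        if self.total == 0:
            raise CalibrationError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def cohens_kappa(t: ConfusionTable) -> float:
    """Chance-corrected agreement, (p_o - p_e) / (1 - p_e).

    p_o is observed agreement; p_e is the agreement expected from the two
    raters' marginals. When all mass sits in one cell (p_e == 1), kappa is
    1 for perfect agreement and undefined otherwise.
    """
    n = t.total
    p_o = (t.tp + t.tn) / n
    p_e = ((t.tp + t.fp) * (t.tp + t.fn) + (t.fn + t.tn) * (t.fp + t.tn)) / (n * n)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise CalibrationError("kappa undefined: all mass in one cell without agreement")
    return (p_o - p_e) / (1.0 - p_e)


def confusion_stats(t: ConfusionTable) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV and raw concordance.

    A statistic whose denominator is empty is reported as None, never as 0.
    """
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(t.tp, t.tp + t.fn),
        "specificity": ratio(t.tn, t.tn + t.fp),
        "ppv": ratio(t.tp, t.tp + t.fp),
        "npv": ratio(t.tn, t.tn + t.fn),
        "concordance": (t.tp + t.tn) / t.total,
    }


_POSITIVE_LABELS = {"positive", "pos", "hrd", "deficient", "1", "true", True, 1}
_NEGATIVE_LABELS = {"negative", "neg", "hrp", "proficient", "0", "false", False, 0}


def _as_bool_label(value) -> bool:
    v = value.strip().lower() if isinstance(value, str) else value
    if v in _POSITIVE_LABELS:
        return True
    if v in _NEGATIVE_LABELS:
        return False
    raise CalibrationError(f"unrecognized reference label {value!r}")


@dataclass
class CutoffScan:
    """Per-cutoff concordance curve and the selected cutoff."""

    cutoffs: np.ndarray
    kappa: np.ndarray
    stats: list[dict[str, float | None]]
    max_interval: tuple[int, int]
    selected_cutoff: int
    n_used: int
    n_dropped: int
    dropped_samples: tuple[str, ...] = ()

    @property
    def max_kappa(self) -> float:
        return float(np.max(self.kappa))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats)
        df.insert(0, "kappa", self.kappa)
        df.insert(0, "cutoff", self.cutoffs)
        return df

    def summary(self) -> dict:
        return {
            "selected_cutoff": self.selected_cutoff,
            "max_kappa": self.max_kappa,
            "max_interval": list(self.max_interval),
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "stats_at_selected": self.stats[
                int(np.flatnonzero(self.cutoffs == self.selected_cutoff)[0])
            ],
        }


def _pairs(data) -> list[tuple[str, object]]:
    if isinstance(data, Mapping):
        return list(data.items())
    if isinstance(data, pd.DataFrame):
        return list(data.itertuples(index=False, name=None))
    return [(str(s), v) for s, v in data]


def scan_cutoffs(
    scores: Iterable[tuple[str, float]] | Mapping[str, float] | pd.DataFrame,
    labels: Iterable[tuple[str, object]] | Mapping[str, object] | pd.DataFrame,
    grid: Sequence[int] = DEFAULT_GRID,
) -> CutoffScan:
    """Sweep integer cutoffs and select the kappa-maximizing one.

    Prediction at cutoff c is ``gis >= c``. Samples with an undefined
    (None/NaN) score are dropped and counted; duplicated sample ids and
    single-class reference labels are rejected.
    """
    score_pairs = _pairs(scores)
    label_pairs = _pairs(labels)
    if len({s for s, _ in score_pairs}) != len(score_pairs):
        raise CalibrationError("duplicated sample ids in scores")
    if len({s for s, _ in label_pairs}) != len(label_pairs):
        raise CalibrationError("duplicated sample ids in labels")
    label_map = {s: _as_bool_label(v) for s, v in label_pairs}
    missing = [s for s, _ in score_pairs if s not in label_map]
    if missing:
        raise CalibrationError(f"samples without reference label: {missing[:5]}")
    used_scores: list[float] = []
    used_labels: list[bool] = []
    dropped: list[str] = []
    for sample, value in score_pairs:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            dropped.append(sample)
            continue
        used_scores.append(float(value))
        used_labels.append(label_map[sample])
    if not used_scores:
        raise CalibrationError("no evaluable scores")
    y = np.asarray(used_labels, dtype=bool)
    s = np.asarray(used_scores, dtype=float)
    if y.all() or (~y).all():
        raise CalibrationError(
            "single-class reference labels: kappa is degenerate at every cutoff"
        )
    grid_arr = np.asarray(list(grid), dtype=int)
    if grid_arr.size == 0:
        raise CalibrationError("empty cutoff grid")
    kappas = np.empty(grid_arr.size, dtype=float)
    stats: list[dict[str, float | None]] = []
    for i, c in enumerate(grid_arr):
        pred = s >= c
        t = ConfusionTable(
            tp=int(np.sum(pred & y)),
            fp=int(np.sum(pred & ~y)),
            fn=int(np.sum(~pred & y)),
            tn=int(np.sum(~pred & ~y)),
        )
        kappas[i] = cohens_kappa(t)
        stats.append(confusion_stats(t))
    max_kappa = np.max(kappas)
    at_max = kappas == max_kappa
    # first maximal contiguous run attaining the maximum
    lo = int(np.flatnonzero(at_max)[0])
    hi = lo
    while hi + 1 < grid_arr.size and at_max[hi + 1]:
        hi += 1
    return CutoffScan(
        cutoffs=grid_arr,
        kappa=kappas,
        stats=stats,
        max_interval=(int(grid_arr[lo]), int(grid_arr[hi])),
        selected_cutoff=int(grid_arr[lo]),
        n_used=int(s.size),
        n_dropped=len(dropped),
        dropped_samples=tuple(dropped),
    )


def min_depth_for_detection(
    af: float, min_alt_reads: int, sensitivity: float
) -> int:
    """Smallest read depth detecting a variant of allele fraction *af*.

    Returns the smallest N such that P(X >= min_alt_reads) >= sensitivity
    for X ~ Binomial(N, af) — the exact binomial tail, no approximation.
    """
    if not 0.0 < af <= 1.0:
        raise ValueError(f"allele fraction {af} not in (0, 1]")
    if min_alt_reads < 1:
        raise ValueError("min_alt_reads must be >= 1")
    if not 0.0 < sensitivity < 1.0:
        raise ValueError(f"sensitivity {sensitivity} not in (0, 1)")

    def ok(n: int) -> bool:
        return binom.sf(min_alt_reads - 1, n, af) >= sensitivity

    lo = min_alt_reads
    if ok(lo):
        return lo
    hi = lo
    while not ok(hi):
        hi *= 2
    # tail probability is non-decreasing in N for fixed k, so bisect
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi
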