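"""Single-metric threshold classification of delivery outcome, scored by MCC.

The classifier is deliberately minimal: one metric, one cut value, one
direction.  Preterm delivery (PTD) is the positive class throughout, so
sensitivity is the fraction of preterm samples flagged and PPV the fraction
of flags that are truly preterm.  The best threshold is found by an
exhaustive scan over candidate cuts (midpoints between consecutive sorted
unique values, plus -inf/+inf sentinels) in both directions, maximizing the
Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with MCC = 0 when any factor of the denominator vanishes.  Accuracy,
sensitivity, specificity, PPV and NPV are read off the same confusion
matrix; 0/0 rates are reported as missing.

The extent of segregation (ES) complements MCC for perfectly separating
metrics: it is the smaller of the two cross-class extreme-value gaps
|max D_TERM - min D_PTD| and |max D_PTD - min D_TERM| divided by the
larger, times 100.  Higher ES means a wider no-man's-land between the two
value sets relative to their overall spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import PTD, TERM

PTD_IF_BELOW = "ptd_if_below"
PTD_IF_ABOVE = "ptd_if_above"
DIRECTIONS = (PTD_IF_BELOW, PTD_IF_ABOVE)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with PTD as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_ptd(self) -> int:
        return self.tp + self.fn

    @property
    def n_term(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ThresholdRule:
    """metric + cut value + direction; applying it yields exactly one label.

    Values exactly equal to the threshold fall on the above-or-equal side:
    under ``ptd_if_below`` a sample is called PTD iff value < threshold,
    under ``ptd_if_above`` iff value >= threshold.
    """

    metric: str
    threshold: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    def predict(self, values) -> np.ndarray:
        """Boolean array: True where the rule calls PTD."""
        v = np.asarray(values, dtype=float)
        if self.direction == PTD_IF_BELOW:
            return v < self.threshold
        return v >= self.threshold

    def predict_labels(self, values) -> np.ndarray:
        return np.where(self.predict(values), PTD, TERM)


@dataclass
class EvalReport:
    """The six confusion-derived evaluation parameters plus ES."""

    metric: str
    counts: ConfusionCounts
    mcc: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    es: float = float("nan")
    threshold: float = float("nan")
    direction: str = ""

    @property
    def n_ptd(self) -> int:
        return self.counts.n_ptd

    @property
    def n_term(self) -> int:
        return self.counts.n_term

    @classmethod
    def from_counts(
        cls,
        counts: ConfusionCounts,
        metric: str = "",
        es: float = float("nan"),
        threshold: float = float("nan"),
        direction: str = "",
    ) -> "EvalReport":
        return cls(
            metric=metric,
            counts=counts,
            mcc=mcc(counts),
            accuracy=accuracy(counts),
            sensitivity=sensitivity(counts),
            specificity=specificity(counts),
            ppv=ppv(counts),
            npv=npv(counts),
            es=es,
            threshold=threshold,
            direction=direction,
        )

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n_ptd": self.n_ptd,
            "n_term": self.n_term,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "mcc": self.mcc,
            "es": self.es,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "threshold": self.threshold,
            "direction": self.direction,
        }


# ---------------------------------------------------------------------------
# Confusion matrix and the evaluation parameters
# ---------------------------------------------------------------------------

def _align(values, labels) -> tuple[np.ndarray, np.ndarray]:
    values = pd.Series(values, dtype=float)
    labels = pd.Series(labels)
    if not values.index.equals(labels.index):
        labels = labels.reindex(values.index)
        if labels.isna().any():
            missing = list(labels.index[labels.isna()][:10])
            raise ValueError(f"labels missing for samples: {missing}")
    bad = set(labels.unique()) - {TERM, PTD}
    if bad:
        raise ValueError(f"labels must be TERM/PTD, got extras: {sorted(bad)}")
    ok = values.notna()
    return values[ok].to_numpy(), (labels[ok] == PTD).to_numpy()


def confusion(rule: ThresholdRule, values, labels) -> ConfusionCounts:
    """Apply a rule to metric values and tabulate the confusion matrix.

    Samples with a missing metric value are excluded (and simply not
    counted); values exactly at the threshold go to the above-or-equal
    side.
    """
    v, is_ptd = _align(values, labels)
    if len(v) == 0:
        raise ValueError("no valued samples to classify")
    pred = rule.predict(v)
    tp = int((pred & is_ptd).sum())
    fp = int((pred & ~is_ptd).sum())
    fn = int((~pred & is_ptd).sum())
    tn = int((~pred & ~is_ptd).sum())
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total)


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp)


def ppv(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def npv(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fn)


def extent_of_segregation(d_td: Iterable[float], d_ptd: Iterable[float]) -> float:
    """Extent of Segregation between the term and preterm value sets.

    ES = min(g1, g2) / max(g1, g2) * 100 with g1 = |max D_TD - min D_PTD|
    and g2 = |max D_PTD - min D_TD|.  Symmetric under swapping the sets;
    returns NaN when both gaps are zero (all values identical).
    """
    a = np.asarray(list(d_td), dtype=float)
    b = np.asarray(list(d_ptd), dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both outcome groups must be non-empty")
    g1 = abs(a.max() - b.min())
    g2 = abs(b.max() - a.min())
    hi = max(g1, g2)
    if hi == 0:
        return float("nan")
    return min(g1, g2) / hi * 100.0


# ---------------------------------------------------------------------------
# Exhaustive threshold fit
# ---------------------------------------------------------------------------

def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _scan_mcc(values: np.ndarray, is_ptd: np.ndarray, cands: np.ndarray,
              direction: str) -> np.ndarray:
    """Vectorized MCC for every candidate threshold in one direction."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = is_ptd[order]
    p_total = int(y.sum())
    n_total = len(y) - p_total
    # number of samples strictly below each candidate
    k = np.searchsorted(v, cands, side="left")
    ptd_below = np.concatenate(([0], np.cumsum(y)))[k]
    below = k
    if direction == PTD_IF_BELOW:
        tp = ptd_below
        fp = below - ptd_below
    else:
        tp = p_total - ptd_below
        fp = (len(y) - below) - (p_total - ptd_below)
    fn = p_total - tp
    tn = n_total - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(denom.astype(float)), 0.0)
    return out


def fit_best_threshold(
    values,
    labels,
    metric: str = "",
    compute_es: bool = True,
) -> tuple[ThresholdRule, EvalReport]:
    """Exhaustively find the MCC-maximizing threshold rule for one metric.

    Candidates are the midpoints between consecutive sorted unique values
    plus -inf/+inf sentinels, scanned in both directions.  Ties are broken
    deterministically: larger ES first (ES depends only on the two class
    value-sets, so within one fit this never discriminates), then the
    smaller threshold, then ``ptd_if_below`` before ``ptd_if_above``.
    """
    v, is_ptd = _align(values, labels)
    if len(v) == 0:
        raise ValueError("no valued samples")
    if is_ptd.all() or not is_ptd.any():
        raise ValueError("both outcome classes must be present to fit a threshold")
    cands = _candidate_thresholds(v)
    best_mcc = -2.0
    best_thr = math.inf
    best_dir = PTD_IF_BELOW
    for direction in DIRECTIONS:
        scores = _scan_mcc(v, is_ptd, cands, direction)
        i = int(np.argmax(scores))
        # among equal-score candidates in this direction, take the smallest cut
        ties = np.flatnonzero(scores == scores[i])
        thr = float(cands[ties[0]])
        if scores[i] > best_mcc + 1e-15 or (
            abs(scores[i] - best_mcc) <= 1e-15 and thr < best_thr
        ):
            best_mcc, best_thr, best_dir = float(scores[i]), thr, direction
    rule = ThresholdRule(metric=metric, threshold=best_thr, direction=best_dir)
    counts = confusion(rule, pd.Series(v), pd.Series(np.where(is_ptd, PTD, TERM)))
    es = extent_of_segregation(v[~is_ptd], v[is_ptd]) if compute_es else float("nan")
    report = EvalReport.from_counts(
        counts, metric=metric, es=es, threshold=best_thr, direction=best_dir
    )
    return rule, report


# ---------------------------------------------------------------------------
# Model / Results presentation
# ---------------------------------------------------------------------------

class ThresholdClassifier:
    """Threshold model for one metric, in the model-object idiom.

    Parameters
    ----------
    values
        Metric value per sample (Series or mapping sample_id -> value).
    labels
        Outcome label per sample (TERM / PTD), aligned with ``values``.
    metric
        Name of the metric, carried into reports.
    """

    def __init__(self, values, labels, metric: str = ""):
        self.values = pd.Series(values, dtype=float)
        self.labels = pd.Series(labels).reindex(self.values.index)
        self.metric = metric

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, metric: str,
                       label_col: str = "outcome") -> "ThresholdClassifier":
        return cls(frame[metric], frame[label_col], metric=metric)

    def fit(self, compute_es: bool = True) -> "ThresholdResults":
        rule, report = fit_best_threshold(
            self.values, self.labels, metric=self.metric, compute_es=compute_es
        )
        return ThresholdResults(model=self, rule=rule, report=report)


@dataclass
class ThresholdResults:
    """Fitted threshold rule plus its in-sample evaluation."""

    model: ThresholdClassifier
    rule: ThresholdRule
    report: EvalReport

    def predict(self, values) -> np.ndarray:
        return self.rule.predict_labels(values)

    def evaluate(self, values, labels) -> EvalReport:
        """Score the frozen rule on new data."""
        counts = confusion(self.rule, values, labels)
        return EvalReport.from_counts(
            counts,
            metric=self.rule.metric,
            threshold=self.rule.threshold,
            direction=self.rule.direction,
        )

    def summary(self) -> str:
        r = self.report
        lines = [
            "Threshold classifier results",
            "=" * 44,
            f"metric:        {self.rule.metric or '(unnamed)'}",
            f"threshold:     {self.rule.threshold:.6g}",
            f"direction:     {self.rule.direction}",
            f"n (PTD/TERM):  {r.n_ptd}/{r.n_term}",
            "-" * 44,
            f"MCC:           {r.mcc:.4f}",
            f"accuracy:      {r.accuracy:.4f}",
            f"sensitivity:   {r.sensitivity:.4f}",
            f"specificity:   {r.specificity:.4f}",
            f"PPV:           {r.ppv:.4f}",
            f"NPV:           {r.npv:.4f}",
        ]
        if not math.isnan(r.es):
            lines.append(f"ES:            {r.es:.2f}")
        return "\n".join(lines)
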