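"""Internal repeated-holdout validation, external threshold transfer,
week-wise sweeps and paired metric comparisons.

The internal protocol repeatedly splits the early-pregnancy sample set
(all samples taken at or before a gestational-week cutoff, 15 or 20) into
a 2/3 training and 1/3 test corpus, refits the best threshold per metric
on the training corpus, and scores the frozen rule on the test corpus;
means and standard deviations over iterations summarize out-of-sample
performance, and the mean threshold plus majority direction constitute
the transferable rule for external validation on an independent cohort.

Paired comparisons between metrics (per iteration, or per Week_N row of a
sweep) use the two-sided Wilcoxon signed-rank test with Benjamini-Hochberg
correction across competitors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, PTD, TERM, cumulative_week_groups, sliding_week_windows
from .metrics import METRICS, compute_all
from .threshold import (
    EvalReport,
    ThresholdRule,
    confusion,
    extent_of_segregation,
    fit_best_threshold,
)

logger = logging.getLogger(__name__)

PARAMETERS = ("mcc", "accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass
class CVConfig:
    """Settings for the repeated-holdout internal validation."""

    train_fraction: float = 2.0 / 3.0
    n_iterations: int = 1000
    stratified: bool = True
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class CVResult:
    """Per-iteration reports and their summary for one metric."""

    metric: str
    iterations: pd.DataFrame  # columns: threshold, direction, six parameters
    n_retries: int = 0

    def summary(self) -> pd.DataFrame:
        """Mean and SD of the six evaluation parameters over iterations."""
        stats_ = self.iterations[list(PARAMETERS)].agg(["mean", "std"])
        return stats_

    @property
    def mean_threshold(self) -> float:
        return float(self.iterations["threshold"].mean())

    @property
    def majority_direction(self) -> str:
        counts = self.iterations["direction"].value_counts()
        return str(counts.idxmax())

    @property
    def direction_agreement(self) -> float:
        counts = self.iterations["direction"].value_counts()
        return float(counts.max() / counts.sum())

    def mean_rule(self) -> ThresholdRule:
        """The transferable rule: mean threshold + majority direction."""
        agree = self.direction_agreement
        if agree < 1.0:
            logger.info(
                "metric %s: direction disagreement across iterations "
                "(majority %.0f%%)", self.metric, 100 * agree,
            )
        return ThresholdRule(
            metric=self.metric,
            threshold=self.mean_threshold,
            direction=self.majority_direction,
        )


def _split(
    rng: np.random.Generator,
    is_ptd: np.ndarray,
    train_fraction: float,
    stratified: bool,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(is_ptd)
    if stratified:
        tr_parts, te_parts = [], []
        for cls in (True, False):
            idx = np.flatnonzero(is_ptd == cls)
            perm = rng.permutation(idx)
            k = round(len(idx) * train_fraction)
            tr_parts.append(perm[:k])
            te_parts.append(perm[k:])
        return np.concatenate(tr_parts), np.concatenate(te_parts)
    perm = rng.permutation(n)
    k = round(n * train_fraction)
    return perm[:k], perm[k:]


def internal_cv(
    cohort: Cohort,
    week_cutoff: float,
    metrics: Sequence[str] = METRICS,
    config: CVConfig | None = None,
    epsilon: float = 0.5,
    tcs_variant: str = "default",
    metric_table: pd.DataFrame | None = None,
) -> dict[str, CVResult]:
    """Repeated 2/3-1/3 holdout validation on samples taken at or before
    ``week_cutoff``.

    For every iteration and metric, the best threshold is refit on the
    training corpus and the frozen rule is scored on the test corpus.
    Iterations whose train or test corpus ends up single-class (possible
    only without stratification) are resampled, up to
    ``config.max_retries`` extra draws per iteration.
    """
    config = config or CVConfig()
    cohort._require_metadata()
    ids = list(cohort.metadata.index[cohort.weeks <= week_cutoff])
    if not ids:
        raise ValueError(f"no samples at or before week {week_cutoff}")
    sub = cohort.subset(ids)
    if metric_table is None:
        metric_table = compute_all(sub, metrics, epsilon, tcs_variant)
    else:
        metric_table = metric_table.loc[ids, list(metrics)]
    labels = sub.outcomes
    is_ptd = (labels == PTD).to_numpy()
    if is_ptd.all() or not is_ptd.any():
        raise ValueError("both outcome classes must be present")
    if config.stratified:
        for cls, n_cls in (("PTD", int(is_ptd.sum())), ("TERM", int((~is_ptd).sum()))):
            k = round(n_cls * config.train_fraction)
            if k == 0 or k == n_cls:
                raise ValueError(
                    f"only {n_cls} {cls} sample(s) at or before week "
                    f"{week_cutoff}: stratified {config.train_fraction:.2f} "
                    "splits cannot place the class in both corpuses"
                )

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_iterations)
    rows: dict[str, list[dict]] = {m: [] for m in metrics}
    total_retries = 0
    values_np = {m: metric_table[m].to_numpy() for m in metrics}
    labels_np = labels.to_numpy()

    for it, child in enumerate(children):
        rng = np.random.default_rng(child)
        for attempt in range(config.max_retries + 1):
            tr, te = _split(rng, is_ptd, config.train_fraction, config.stratified)
            ok = (
                is_ptd[tr].any() and not is_ptd[tr].all()
                and is_ptd[te].any() and not is_ptd[te].all()
            )
            if ok:
                break
            total_retries += 1
            logger.info("iteration %d: single-class split, resampling", it)
        else:
            raise RuntimeError(
                f"iteration {it}: could not draw a two-class split in "
                f"{config.max_retries} retries"
            )
        for m in metrics:
            v = values_np[m]
            rule, _ = fit_best_threshold(
                pd.Series(v[tr]), pd.Series(labels_np[tr]),
                metric=m, compute_es=False,
            )
            counts = confusion(rule, pd.Series(v[te]), pd.Series(labels_np[te]))
            rep = EvalReport.from_counts(
                counts, metric=m,
                threshold=rule.threshold, direction=rule.direction,
            )
            rows[m].append(
                {
                    "iteration": it,
                    "threshold": rule.threshold,
                    "direction": rule.direction,
                    **{p: getattr(rep, p) for p in PARAMETERS},
                }
            )

    return {
        m: CVResult(
            metric=m,
            iterations=pd.DataFrame(rows[m]).set_index("iteration"),
            n_retries=total_retries,
        )
        for m in metrics
    }


def external_validate(
    rules: Mapping[str, ThresholdRule] | Iterable[ThresholdRule],
    cohort: Cohort,
    week_cutoff: float,
    epsilon: float = 0.5,
    tcs_variant: str = "default",
) -> dict[str, EvalReport]:
    """Apply frozen mean-threshold rules to an external cohort.

    Only samples taken at or before ``week_cutoff`` are scored.  Rates
    whose denominator is empty (e.g. an external cohort missing a class)
    come back as NaN.
    """
    if not isinstance(rules, Mapping):
        rules = {r.metric: r for r in rules}
    cohort._require_metadata()
    ids = list(cohort.metadata.index[cohort.weeks <= week_cutoff])
    if not ids:
        raise ValueError(f"external cohort has no samples at or before week {week_cutoff}")
    sub = cohort.subset(ids)
    table = compute_all(sub, list(rules), epsilon, tcs_variant)
    labels = sub.outcomes
    out = {}
    for m, rule in rules.items():
        counts = confusion(rule, table[m], labels)
        out[m] = EvalReport.from_counts(
            counts, metric=m, threshold=rule.threshold, direction=rule.direction
        )
    return out


# ---------------------------------------------------------------------------
# Statistics: Wilcoxon signed-rank and Benjamini-Hochberg
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired observations.

    Zero differences are dropped (standard signed-rank convention); all
    differences zero gives p = 1.  The exact null distribution is used for
    n <= 25 retained pairs, the normal approximation with continuity
    correction beyond that.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    if len(d) < 5:
        raise ValueError("fewer than 5 nonzero paired differences")
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=True, method=method,
        alternative="two-sided",
    )
    return float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


@dataclass
class ComparisonResult:
    """Reference-vs-competitor paired comparisons with BH correction."""

    reference: str
    table: pd.DataFrame  # index: competitor; columns: p_raw, p_adjusted, direction


def compare_paired(
    data: pd.DataFrame,
    reference: str,
    competitors: Sequence[str] | None = None,
) -> ComparisonResult:
    """Wilcoxon-compare a reference column against every competitor column,
    pairing on the index, with BH correction across competitors."""
    competitors = [c for c in (competitors or data.columns) if c != reference]
    raws, dirs = [], []
    for c in competitors:
        paired = data[[reference, c]].dropna()
        try:
            p = wilcoxon_signed_rank(paired[reference], paired[c])
        except ValueError:
            # heavily tied pair (fewer than 5 nonzero differences): no test
            p = float("nan")
            logger.info("comparison %s vs %s: too few nonzero differences", reference, c)
        raws.append(p)
        diff = float((paired[reference] - paired[c]).mean())
        dirs.append(
            "reference_higher" if diff > 0
            else "reference_lower" if diff < 0 else "equal"
        )
    raws_arr = np.asarray(raws, dtype=float)
    adj = np.full_like(raws_arr, np.nan)
    valid = ~np.isnan(raws_arr)
    if valid.any():
        adj[valid] = benjamini_hochberg(raws_arr[valid])
    table = pd.DataFrame(
        {"p_raw": raws, "p_adjusted": adj, "direction": dirs},
        index=pd.Index(competitors, name="competitor"),
    )
    return ComparisonResult(reference=reference, table=table)


def compare_metric_mcc_over_weeks(
    mcc_matrix: pd.DataFrame,
    reference_metric: str = "tcs",
    week_min: int = 8,
    week_cap: int = 20,
) -> ComparisonResult:
    """Paired comparison of week-wise MCC (or ES) columns against a
    reference metric over Week_{week_min}..Week_{week_cap}."""
    labels = [f"Week_{n}" for n in range(week_min, week_cap + 1)]
    present = [l for l in labels if l in mcc_matrix.index]
    if len(present) < 5:
        raise ValueError(
            f"need at least 5 week rows between Week_{week_min} and "
            f"Week_{week_cap}; found {len(present)}"
        )
    return compare_paired(mcc_matrix.loc[present], reference_metric)


# ---------------------------------------------------------------------------
# Week-wise sweep (reporting-table machinery)
# ---------------------------------------------------------------------------

@dataclass
class SweepReport:
    """Best-threshold results for every Week_N group x metric."""

    counts: pd.DataFrame      # index Week_N; columns n_ptd, n_term, n_total
    mcc: pd.DataFrame         # index Week_N; one column per metric
    es: pd.DataFrame
    thresholds: pd.DataFrame
    directions: pd.DataFrame

    def to_table(self, decimals: int = 3) -> pd.DataFrame:
        """Printable table: MCC per cell, ES appended in brackets whenever a
        threshold separates the classes completely (MCC = 1); the best
        metric of each row is flagged with ``*``."""
        out = self.counts.copy()
        scored = self.mcc.dropna(how="all")
        best = scored.idxmax(axis=1).reindex(self.mcc.index)
        for m in self.mcc.columns:
            col = []
            for week in self.mcc.index:
                v = self.mcc.at[week, m]
                if np.isnan(v):
                    col.append("NA")
                    continue
                cell = f"{v:.{decimals}f}"
                if v == 1.0 and not np.isnan(self.es.at[week, m]):
                    cell += f" ({self.es.at[week, m]:.2f})"
                if best.at[week] == m:
                    cell += "*"
                col.append(cell)
            out[m] = col
        return out


def week_sweep(
    cohort: Cohort,
    metrics: Sequence[str] = METRICS,
    n_min: int = 8,
    n_max: int = 40,
    epsilon: float = 0.5,
    tcs_variant: str = "default",
    metric_table: pd.DataFrame | None = None,
) -> SweepReport:
    """Fit the best threshold for every metric in every cumulative Week_N
    group and record MCC and ES; rows for empty or single-class groups are
    emitted as missing."""
    cohort._require_metadata()
    if metric_table is None:
        metric_table = compute_all(cohort, metrics, epsilon, tcs_variant)
    groups = cumulative_week_groups(cohort, n_min, n_max)
    labels = cohort.outcomes
    idx = pd.Index([g.label for g in groups], name="week_group")
    counts = pd.DataFrame(index=idx, columns=["n_ptd", "n_term", "n_total"], dtype=int)
    shells = {
        name: pd.DataFrame(index=idx, columns=list(metrics), dtype=float)
        for name in ("mcc", "es", "thresholds")
    }
    directions = pd.DataFrame(index=idx, columns=list(metrics), dtype=object)
    for g in groups:
        members = list(g.members)
        lab = labels.loc[members]
        n_ptd = int((lab == PTD).sum())
        n_term = int((lab == TERM).sum())
        counts.loc[g.label] = [n_ptd, n_term, n_ptd + n_term]
        if n_ptd == 0 or n_term == 0:
            logger.info("%s: single-class or empty group, skipped", g.label)
            continue
        for m in metrics:
            vals = metric_table.loc[members, m]
            if vals.dropna().empty:
                continue
            rule, rep = fit_best_threshold(vals, lab, metric=m)
            shells["mcc"].at[g.label, m] = rep.mcc
            shells["es"].at[g.label, m] = rep.es
            shells["thresholds"].at[g.label, m] = rule.threshold
            directions.at[g.label, m] = rule.direction
    return SweepReport(
        counts=counts,
        mcc=shells["mcc"],
        es=shells["es"],
        thresholds=shells["thresholds"],
        directions=directions,
    )


def week_trend(
    cohort: Cohort,
    metric_values: pd.Series,
    n_windows: int = 15,
    width: float = 6.0,
    step: float = 2.5,
    start: float = 1.0,
) -> pd.DataFrame:
    """Arm-wise mean of a metric over overlapping gestational-age windows
    (the week-resolved trend view: PTD diversity sits below TERM early in
    pregnancy and converges later)."""
    windows = sliding_week_windows(cohort, n_windows, width, step, start)
    labels = cohort.outcomes
    rows = []
    for w in windows:
        lo = float(w.label.split("_")[1].split("-")[0])
        members = list(w.members)
        vals = metric_values.loc[members]
        lab = labels.loc[members]
        rows.append(
            {
                "window": w.label,
                "week_mid": lo + width / 2.0,
                "mean_term": float(vals[lab == TERM].mean()) if (lab == TERM).any() else float("nan"),
                "mean_ptd": float(vals[lab == PTD].mean()) if (lab == PTD).any() else float("nan"),
                "n_term": int((lab == TERM).sum()),
                "n_ptd": int((lab == PTD).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("window")
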