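"""Per-sample diversity and inequality metrics for taxonomic profiles.

Vaginal microbiomes are typically dominated by a single *Lactobacillus*
taxon, so the ordered abundance distribution resembles a highly skewed
Lorenz curve.  This module therefore computes, side by side, classical
alpha-diversity indices (Shannon, Simpson, Chao1) and econometric
inequality measures (Gini, Ricci-Schutz/Pietra, Atkinson, Theil T,
decile ratio) on each sample's abundance vector, plus the taxonomic
composition skew (TCS) statistic.

Conventions, applied uniformly:

* natural logarithms throughout;
* diversity indices consume relative abundances; Chao1 alone requires
  integer counts (it is undefined on proportions);
* inequality indices are computed over the *full* vector of the cohort's
  taxon universe, zeros included, mirroring inequality-package behaviour
  on a fixed population; the decile ratio alone restricts to nonzero
  abundances to avoid division by zero;
* all metrics except Chao1 are scale-invariant, so counts and relative
  abundances give identical values.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .cohort import Cohort, TaxonomicProfile

logger = logging.getLogger(__name__)

#: Canonical metric order (mirrors the reporting-table layout).
METRICS = (
    "tcs",
    "shannon",
    "simpson",
    "chao1",
    "gini",
    "ricci_schutz",
    "atkinson",
    "theil",
    "decile_ratio",
)


def _as_vector(profile) -> np.ndarray:
    """Accept a TaxonomicProfile or a bare abundance/count vector."""
    if isinstance(profile, TaxonomicProfile):
        x = np.asarray(profile.counts, dtype=float)
    else:
        x = np.asarray(profile, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    return x


def _rel(profile) -> np.ndarray:
    x = _as_vector(profile)
    total = x.sum()
    if total == 0:
        raise ValueError("zero-depth profile: no assigned reads")
    return x / total


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon(profile) -> float:
    """Shannon entropy H = -sum p_i ln p_i over nonzero p_i (natural log)."""
    p = _rel(profile)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(profile, inverse: bool = False) -> float:
    """Gini-Simpson index 1 - sum p_i^2 (or inverse Simpson 1/sum p_i^2)."""
    p = _rel(profile)
    ss = float((p**2).sum())
    return 1.0 / ss if inverse else 1.0 - ss


def chao1(profile) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the singleton and doubleton counts; requires integer
    counts (undefined on relative abundances).  An all-zero profile has
    richness 0 by the empty-community convention.
    """
    if isinstance(profile, TaxonomicProfile):
        c = np.asarray(profile.counts)
    else:
        c = np.asarray(profile)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if not np.all(np.equal(np.mod(c, 1), 0)):
        raise ValueError("chao1 requires integer counts, not relative abundances")
    c = c.astype(np.int64)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


# ---------------------------------------------------------------------------
# Inequality measures
# ---------------------------------------------------------------------------

def gini(profile) -> float:
    """Gini coefficient via the mean absolute difference,
    sum_ij |x_i - x_j| / (2 n^2 mu), zeros included."""
    x = np.sort(_rel(profile))
    n = len(x)
    mu = x.mean()
    # O(n log n) identity for the pairwise-difference sum on sorted data
    i = np.arange(1, n + 1)
    pair_sum = 2.0 * float(((2 * i - n - 1) * x).sum())
    return pair_sum / (2.0 * n * n * mu)


def ricci_schutz(profile) -> float:
    """Ricci-Schutz (Pietra/Schutz) coefficient sum |x_i - mu| / (2 n mu)."""
    x = _rel(profile)
    mu = x.mean()
    return float(np.abs(x - mu).sum() / (2.0 * len(x) * mu))


def atkinson(profile, epsilon: float = 0.5) -> float:
    """Atkinson inequality index with aversion parameter epsilon.

    A(eps) = 1 - [ (1/n) sum x_i^(1-eps) ]^(1/(1-eps)) / mu for eps != 1;
    at eps = 1 the geometric-mean limit 1 - GM(x)/mu is used.  Any zero
    abundance drives the index to 1 when eps >= 1 (the documented limit
    convention).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    x = _rel(profile)
    mu = x.mean()
    if epsilon == 1.0:
        if np.any(x == 0):
            return 1.0
        gm = math.exp(float(np.log(x).mean()))
        return 1.0 - gm / mu
    if epsilon > 1.0 and np.any(x == 0):
        return 1.0
    ede = float(np.mean(x ** (1.0 - epsilon))) ** (1.0 / (1.0 - epsilon))
    return 1.0 - ede / mu


def theil(profile) -> float:
    """Theil T index (1/n) sum (x_i/mu) ln(x_i/mu), with 0 ln 0 = 0."""
    x = _rel(profile)
    r = x / x.mean()
    nz = r > 0
    return float((r[nz] * np.log(r[nz])).sum() / len(x))


def decile_ratio(profile) -> float:
    """90:10 percentile ratio of the *nonzero* abundances.

    Linear-interpolation quantiles.  With fewer than two nonzero taxa the
    ratio is undefined and reported as missing (NaN), not an exception.
    """
    x = _rel(profile)
    nz = x[x > 0]
    if len(nz) < 2:
        return float("nan")
    p90, p10 = np.percentile(nz, [90, 10])
    return float(p90 / p10)


# ---------------------------------------------------------------------------
# Taxonomic composition skew
# ---------------------------------------------------------------------------

def _tcs_moment_skewness(p: np.ndarray) -> float:
    # Fisher-Pearson g1 = m3 / m2^(3/2); a (numerically) constant vector
    # gives 0 by convention -- the m2 cutoff absorbs normalization noise
    d = p - p.mean()
    m2 = float((d**2).mean())
    if m2 <= (100 * np.finfo(float).eps * float(p.max() or 1.0)) ** 2:
        return 0.0
    m3 = float((d**3).mean())
    return m3 / m2**1.5


def _tcs_supplementary(p: np.ndarray) -> float:
    raise NotImplementedError(
        "the 'supplementary' TCS variant is a reserved slot for the exact "
        "published formula; register it via register_tcs_variant()"
    )


#: Pluggable TCS strategies, keyed by variant name.
TCS_VARIANTS: dict[str, Callable[[np.ndarray], float]] = {
    "default": _tcs_moment_skewness,
    "supplementary": _tcs_supplementary,
}


def register_tcs_variant(name: str, func: Callable[[np.ndarray], float]) -> None:
    """Register a TCS strategy (a function of the relative-abundance vector)."""
    TCS_VARIANTS[name] = func


def tcs(profile, variant: str = "default") -> float:
    """Taxonomic composition skew of the full relative-abundance vector.

    The shipped default is the Fisher-Pearson sample skewness
    g1 = m3 / m2^(3/2) computed over the cohort taxon universe, zeros
    included: a community with one dominant taxon and a long tail of rare
    taxa is strongly right-skewed, and the more extreme the dominance the
    larger the skew.  Alternative formulas plug in by ``variant``.
    """
    if variant not in TCS_VARIANTS:
        raise KeyError(
            f"unknown TCS variant {variant!r}; available: {sorted(TCS_VARIANTS)}"
        )
    return float(TCS_VARIANTS[variant](_rel(profile)))


# ---------------------------------------------------------------------------
# Cohort-level computation
# ---------------------------------------------------------------------------

_METRIC_FUNCS: dict[str, Callable] = {
    "shannon": shannon,
    "simpson": simpson,
    "chao1": chao1,
    "gini": gini,
    "ricci_schutz": ricci_schutz,
    "atkinson": atkinson,
    "theil": theil,
    "decile_ratio": decile_ratio,
    "tcs": tcs,
}


def compute_metric(profile, metric: str, epsilon: float = 0.5,
                   tcs_variant: str = "default") -> float:
    """Evaluate one named metric on a profile."""
    if metric not in _METRIC_FUNCS:
        raise KeyError(f"unknown metric {metric!r}; available: {sorted(_METRIC_FUNCS)}")
    if metric == "atkinson":
        return atkinson(profile, epsilon=epsilon)
    if metric == "tcs":
        return tcs(profile, variant=tcs_variant)
    return _METRIC_FUNCS[metric](profile)


def compute_all(
    cohort: Cohort,
    metrics: Iterable[str] = METRICS,
    epsilon: float = 0.5,
    tcs_variant: str = "default",
) -> pd.DataFrame:
    """Compute every requested metric for every sample in the cohort.

    Returns a samples x metrics DataFrame; undefined values (e.g. the
    decile ratio of a single-taxon sample) appear as NaN and are excluded
    pairwise downstream.
    """
    if cohort.n_samples == 0:
        raise ValueError("cohort is empty")
    metrics = list(metrics)
    values = {m: [] for m in metrics}
    for prof in cohort.profiles():
        for m in metrics:
            values[m].append(compute_metric(prof, m, epsilon, tcs_variant))
    out = pd.DataFrame(values, index=pd.Index(cohort.sample_ids, name="sample_id"))
    return out


def metrics_long(table: pd.DataFrame) -> pd.DataFrame:
    """Reshape a samples x metrics table to long format
    (sample_id, metric, value)."""
    long = table.reset_index().melt(
        id_vars="sample_id", var_name="metric", value_name="value"
    )
    return long


def rarefy(cohort: Cohort, depth: int, seed: int = 0) -> Cohort:
    """Optional preprocessor: subsample every profile to a fixed depth
    without replacement; samples shallower than ``depth`` are dropped
    (logged).  Off by default in every pipeline."""
    rng = np.random.default_rng(seed)
    keep = cohort.depths >= depth
    dropped = int((~keep).sum())
    if dropped:
        logger.info("rarefy(%d): dropping %d samples below depth", depth, dropped)
    sub = cohort.subset(list(cohort.counts.columns[keep]))
    new_counts = {}
    for sid in sub.sample_ids:
        c = sub.counts[sid].to_numpy()
        new_counts[sid] = rng.multivariate_hypergeometric(c, depth)
    counts = pd.DataFrame(new_counts, index=sub.counts.index)
    counts.index.name = "#OTU_ID"
    return Cohort(counts, sub.metadata)
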