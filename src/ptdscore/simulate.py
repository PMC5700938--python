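"""Seeded synthetic vaginal-microbiome cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline is testable without access to the
original sequencing studies:

* compositions are Dirichlet-multinomial with one dominant component (the
  *Lactobacillus* surrogate, always the first taxon) and a long tail of
  rare taxa, which yields the highly skewed, Lorenz-curve-like rank
  abundance profiles characteristic of vaginal communities;
* the preterm (PTD) arm has a *less even* tail than the term arm early in
  pregnancy — hence lower diversity on every evenness-sensitive metric —
  with the gap closing by a configurable convergence week, after which the
  two arms are generated identically;
* samples are conditionally independent given arm and week (no attempt at
  longitudinal autocorrelation within a subject).

The default cohort has 300 subjects with a 13.8% preterm fraction and
read depths that always clear the 500-read inclusion filter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, PTD, TERM

logger = logging.getLogger(__name__)

#: Default nuisance-parameter perturbation used for external-validation
#: cohorts: shallower sequencing and slightly stronger dominance, mimicking
#: protocol and primer differences between studies.
DEFAULT_EXTERNAL_SHIFT: dict = {
    "depth_range": (500, 25000),
    "dominance_scale": 1.1,
}


@dataclass
class SyntheticConfig:
    """Generator parameters for one synthetic cohort.

    The effect is carried entirely by the tail-evenness concentration:
    ``evenness_alpha_ptd_early`` < ``evenness_alpha_term`` encodes lower
    early-pregnancy diversity in the preterm arm; the PTD tail
    concentration returns to the term value at ``convergence_week``.
    """

    n_subjects: int = 300
    ptd_fraction: float = 0.138
    n_taxa: int = 200
    depth_range: tuple[int, int] = (500, 50_000)
    dominance_alpha: float = 40.0
    evenness_alpha_term: float = 0.15
    evenness_alpha_ptd_early: float = 0.002
    plateau_week: float = 15.0
    convergence_week: float = 20.0
    samples_per_subject: tuple[int, int] = (1, 3)
    week_range: tuple[float, float] = (4.0, 40.0)
    study_id: str = "STUDY1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ptd_fraction < 1:
            raise ValueError("ptd_fraction must be in (0, 1)")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] < 1:
            raise ValueError("invalid depth_range")
        if self.week_range[0] > self.week_range[1]:
            raise ValueError("empty week range")
        if self.evenness_alpha_ptd_early > self.evenness_alpha_term:
            raise ValueError(
                "evenness_alpha_ptd_early must not exceed evenness_alpha_term "
                "(the preterm arm is the less diverse one early in pregnancy)"
            )
        if not self.plateau_week <= self.convergence_week:
            raise ValueError("plateau_week must not exceed convergence_week")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def effect_trajectory(week: float, config: SyntheticConfig) -> float:
    """PTD-arm tail concentration as a function of gestational week.

    Constant at ``evenness_alpha_ptd_early`` through ``plateau_week``, then
    log-linear interpolation up to ``evenness_alpha_term`` at
    ``convergence_week``, constant afterwards.  Monotone non-decreasing.
    """
    lo = config.evenness_alpha_ptd_early
    hi = config.evenness_alpha_term
    if week <= config.plateau_week or lo == hi:
        return lo
    if week >= config.convergence_week:
        return hi
    f = (week - config.plateau_week) / (config.convergence_week - config.plateau_week)
    return float(np.exp((1 - f) * np.log(lo) + f * np.log(hi)))


def _taxon_ids(n_taxa: int) -> list[str]:
    # the first OTU is the dominant (Lactobacillus-like) component
    return [f"OTU_{i:04d}" for i in range(1, n_taxa + 1)]


def generate_cohort(config: SyntheticConfig | None = None) -> Cohort:
    """Draw a complete synthetic cohort; bit-identical under a fixed seed.

    Per subject: the delivery outcome is Bernoulli(ptd_fraction), the
    number of sampling visits uniform over ``samples_per_subject`` and
    visit weeks uniform over ``week_range`` (rounded to 0.1 week).  Per
    sample: a composition is drawn from a Dirichlet whose first component
    has concentration ``dominance_alpha`` and whose remaining components
    share the arm- and week-specific tail concentration; counts are then
    multinomial at a depth uniform over ``depth_range``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    taxa = _taxon_ids(config.n_taxa)
    lo_w, hi_w = config.week_range
    lo_k, hi_k = config.samples_per_subject

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for s in range(config.n_subjects):
        subject = f"SUB{s:04d}"
        outcome = PTD if rng.random() < config.ptd_fraction else TERM
        k = int(rng.integers(lo_k, hi_k + 1))
        weeks = np.round(rng.uniform(lo_w, hi_w, size=k), 1)
        for visit, week in enumerate(sorted(weeks), start=1):
            tail = (
                effect_trajectory(week, config)
                if outcome == PTD
                else config.evenness_alpha_term
            )
            alpha = np.full(config.n_taxa, tail)
            alpha[0] = config.dominance_alpha
            composition = rng.dirichlet(alpha)
            depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
            counts = rng.multinomial(depth, composition)
            sid = f"{subject}_T{visit}"
            columns[sid] = counts
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subject,
                    "study_id": config.study_id,
                    "gestation_week": float(week),
                    "outcome": outcome,
                }
            )
    counts = pd.DataFrame(columns, index=pd.Index(taxa, name="#OTU_ID"))
    metadata = pd.DataFrame(meta_rows)
    logger.info(
        "generated cohort: %d samples from %d subjects (%.1f%% PTD samples)",
        len(meta_rows), config.n_subjects,
        100 * np.mean([r["outcome"] == PTD for r in meta_rows]),
    )
    return Cohort(counts, metadata)


def generate_external_cohort(
    config: SyntheticConfig | None = None,
    shift: dict | None = DEFAULT_EXTERNAL_SHIFT,
) -> Cohort:
    """Generate a distribution-shifted hold-out cohort.

    The outcome-effect structure (tail-evenness gap and its trajectory) is
    kept; only nuisance parameters move, modelling between-study protocol
    differences.  ``shift`` may contain absolute overrides for any
    SyntheticConfig field plus the conveniences ``dominance_scale`` and
    ``depth_scale``.  An empty shift reproduces :func:`generate_cohort`
    exactly (same seed, same draws).
    """
    config = config or SyntheticConfig()
    shift = dict(shift or {})
    changes: dict = {"study_id": shift.pop("study_id", "EXTERNAL")}
    if "dominance_scale" in shift:
        changes["dominance_alpha"] = config.dominance_alpha * shift.pop("dominance_scale")
    if "depth_scale" in shift:
        scale = shift.pop("depth_scale")
        lo, hi = config.depth_range
        changes["depth_range"] = (max(1, round(lo * scale)), max(1, round(hi * scale)))
    for key, value in shift.items():
        if not hasattr(config, key):
            raise KeyError(f"unknown perturbation field {key!r}")
        changes[key] = value
    perturbed = dataclasses.replace(config, **changes)
    return generate_cohort(perturbed)


def write_manifest(config: SyntheticConfig, path: str | Path,
                   extra: dict | None = None) -> None:
    """Record the full generator configuration (and seed) next to the data."""
    doc = {"generator": "ptdscore.simulate", "config": config.to_dict()}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
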