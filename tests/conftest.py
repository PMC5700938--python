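"""Shared fixtures: synthetic cohorts and derived tables reused across tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ptdscore as ps

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

#: Seed for the study-conditions cohort used by the structural tests.
DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort() -> ps.Cohort:
    """The default-effect synthetic cohort (300 subjects, 13.8% PTD)."""
    return ps.generate_cohort(ps.SyntheticConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def metric_table(default_cohort) -> pd.DataFrame:
    return ps.compute_all(default_cohort)


@pytest.fixture(scope="session")
def null_cohort() -> ps.Cohort:
    """No arm effect: PTD tail evenness equals the TERM value."""
    cfg = ps.SyntheticConfig(seed=DEFAULT_SEED + 100)
    cfg = ps.SyntheticConfig(
        seed=DEFAULT_SEED + 100,
        evenness_alpha_ptd_early=cfg.evenness_alpha_term,
    )
    return ps.generate_cohort(cfg)


@pytest.fixture(scope="session")
def external_cohort() -> ps.Cohort:
    """Default-shift external cohort (shallower depth, stronger dominance)."""
    return ps.generate_external_cohort(
        ps.SyntheticConfig(seed=DEFAULT_SEED + 200), ps.DEFAULT_EXTERNAL_SHIFT
    )


@pytest.fixture(scope="session")
def small_cohort() -> ps.Cohort:
    """A fast 40-subject cohort for IO/CLI-level tests."""
    return ps.generate_cohort(ps.SyntheticConfig(n_subjects=40, n_taxa=50, seed=7))


def make_toy_cohort(values_by_outcome: dict, week: float = 8.0) -> ps.Cohort:
    """Build a minimal 3-taxon cohort whose samples carry given outcomes.

    Count vectors are arbitrary but valid; useful when only metadata and
    sample identity matter (metric values are supplied separately).
    """
    rng = np.random.default_rng(0)
    cols, meta = {}, []
    i = 0
    for outcome, n in values_by_outcome.items():
        for _ in range(n):
            sid = f"S{i:03d}"
            cols[sid] = rng.integers(1, 50, size=3)
            meta.append(
                {
                    "sample_id": sid,
                    "subject_id": f"P{i:03d}",
                    "study_id": "TOY",
                    "gestation_week": week,
                    "outcome": outcome,
                }
            )
            i += 1
    counts = pd.DataFrame(cols, index=pd.Index(["OTU_a", "OTU_b", "OTU_c"], name="#OTU_ID"))
    return ps.Cohort(counts, pd.DataFrame(meta))
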