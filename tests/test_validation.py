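"""Internal CV, external transfer, week sweeps and the paired statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import ptdscore as ps
from ptdscore.cohort import PTD, TERM
from ptdscore.threshold import PTD_IF_ABOVE, PTD_IF_BELOW

from conftest import make_toy_cohort


def exact_signed_rank_p(diffs) -> float:
    """Oracle: exhaustive enumeration of all 2^n sign assignments.

    Two-sided symmetric-tail p for the signed-rank sum of the observed
    differences (assumed free of zero diffs and rank ties).
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    ranks = np.empty(n)
    ranks[np.argsort(np.abs(d))] = np.arange(1, n + 1)
    w_obs = ranks[d > 0].sum()
    total = n * (n + 1) / 2
    hi = max(w_obs, total - w_obs)
    lo = min(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        if w >= hi or w <= lo:
            count += 1
    return min(count / 2**n, 1.0)


class TestWilcoxon:
    def test_identical_vectors(self):
        assert ps.wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_constant_shift_exact(self):
        a = np.arange(1, 11.0)
        # all ten differences positive with tied magnitudes: p = 2/2^10
        assert ps.wilcoxon_signed_rank(a + 1, a) == pytest.approx(
            0.001953125, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        d = rng.normal(size=n)
        d = np.sign(d) * (np.abs(d) + np.linspace(0.1, 1, n))  # distinct magnitudes
        a = rng.normal(size=n)
        assert ps.wilcoxon_signed_rank(a + d, a) == pytest.approx(
            exact_signed_rank_p(d), abs=1e-9
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="fewer than 5"):
            ps.wilcoxon_signed_rank([1, 2, 3], [0, 1, 2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ps.wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestBenjaminiHochberg:
    @staticmethod
    def step_up_oracle(p):
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, i in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    def test_single_p_unchanged(self):
        assert ps.benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_textbook_case(self):
        assert ps.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 12))
            assert ps.benjamini_hochberg(p) == pytest.approx(
                self.step_up_oracle(p), abs=1e-9
            )

    def test_never_decreases_and_clipped(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=20)
        adj = ps.benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()

    def test_order_invariance(self):
        p = np.array([0.5, 0.01, 0.2, 0.04])
        perm = np.array([2, 0, 3, 1])
        adj = ps.benjamini_hochberg(p)
        assert ps.benjamini_hochberg(p[perm]) == pytest.approx(adj[perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ps.benjamini_hochberg([0.5, 1.5])


def _separable_cohort(n_ptd=6, n_term=12, week=8.0):
    """PTD samples are single-taxon (Shannon 0), TERM samples even (ln 3)."""
    cols, meta = {}, []
    for i in range(n_ptd + n_term):
        is_ptd = i < n_ptd
        cols[f"S{i:03d}"] = [600, 0, 0] if is_ptd else [200, 200, 200]
        meta.append(
            {
                "sample_id": f"S{i:03d}",
                "subject_id": f"P{i:03d}",
                "study_id": "TOY",
                "gestation_week": week,
                "outcome": PTD if is_ptd else TERM,
            }
        )
    counts = pd.DataFrame(cols, index=pd.Index(["a", "b", "c"], name="#OTU_ID"))
    return ps.Cohort(counts, pd.DataFrame(meta))


class TestInternalCV:
    def test_separable_cohort_gives_perfect_mcc(self):
        cohort = _separable_cohort()
        config = ps.CVConfig(n_iterations=10, seed=0)
        results = ps.internal_cv(cohort, 15, ["shannon"], config)
        mccs = results["shannon"].iterations["mcc"]
        assert (mccs == 1.0).all()
        assert results["shannon"].summary().at["std", "mcc"] == 0.0

    def test_deterministic_under_fixed_seed(self, default_cohort, metric_table):
        config = ps.CVConfig(n_iterations=5, seed=3)
        a = ps.internal_cv(default_cohort, 15, ["shannon"], config,
                           metric_table=metric_table)
        b = ps.internal_cv(default_cohort, 15, ["shannon"], config,
                           metric_table=metric_table)
        pd.testing.assert_frame_equal(a["shannon"].iterations, b["shannon"].iterations)

    def test_stratified_splits_never_retry(self, default_cohort, metric_table):
        config = ps.CVConfig(n_iterations=50, seed=4)
        results = ps.internal_cv(default_cohort, 15, ["shannon"], config,
                                 metric_table=metric_table)
        assert results["shannon"].n_retries == 0

    def test_matches_independent_reimplementation(self, default_cohort, metric_table):
        """Mean test MCC agrees with a plain second implementation of the loop."""
        cutoff = 20
        config = ps.CVConfig(n_iterations=50, seed=5)
        results = ps.internal_cv(default_cohort, cutoff, ["tcs"], config,
                                 metric_table=metric_table)
        mean_pkg = results["tcs"].summary().at["mean", "mcc"]
        sd_pkg = results["tcs"].summary().at["std", "mcc"]

        ids = list(default_cohort.metadata.index[default_cohort.weeks <= cutoff])
        v = metric_table.loc[ids, "tcs"].to_numpy()
        y = (default_cohort.outcomes.loc[ids] == PTD).to_numpy()
        rng = np.random.default_rng(999)  # independent randomness
        mccs = []
        for _ in range(50):
            idx_p, idx_n = np.flatnonzero(y), np.flatnonzero(~y)
            tr = np.r_[rng.permutation(idx_p)[: round(len(idx_p) * 2 / 3)],
                       rng.permutation(idx_n)[: round(len(idx_n) * 2 / 3)]]
            te = np.setdiff1d(np.arange(len(y)), tr)
            rule, _ = ps.fit_best_threshold(
                pd.Series(v[tr]), pd.Series(np.where(y[tr], PTD, TERM))
            )
            c = ps.confusion(rule, pd.Series(v[te]),
                             pd.Series(np.where(y[te], PTD, TERM)))
            mccs.append(ps.mcc(c))
        assert abs(mean_pkg - np.mean(mccs)) <= 3 * max(sd_pkg, np.std(mccs), 0.01)

    def test_mean_rule_carries_majority_direction(self):
        cohort = _separable_cohort()
        results = ps.internal_cv(cohort, 15, ["shannon"], ps.CVConfig(n_iterations=5, seed=1))
        rule = results["shannon"].mean_rule()
        assert rule.direction == PTD_IF_BELOW  # preterm samples are the low-diversity ones
        assert 0 < rule.threshold < math.log(3)

    def test_unstratified_mode_runs(self, default_cohort, metric_table):
        config = ps.CVConfig(n_iterations=5, seed=6, stratified=False)
        results = ps.internal_cv(default_cohort, 15, ["shannon"], config,
                                 metric_table=metric_table)
        assert len(results["shannon"].iterations) == 5


class TestExternalValidate:
    def test_perfect_rule_on_separable_cohort(self):
        cohort = _separable_cohort()
        rule = ps.ThresholdRule("shannon", 0.5, PTD_IF_BELOW)
        reports = ps.external_validate({"shannon": rule}, cohort, 15)
        rep = reports["shannon"]
        for p in ("mcc", "accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert getattr(rep, p) == 1.0

    def test_label_independent_rule_gives_majority_accuracy(self):
        cohort = _separable_cohort(n_ptd=4, n_term=16)
        # threshold below every value: everything is called TERM
        rule = ps.ThresholdRule("shannon", -1.0, PTD_IF_BELOW)
        rep = ps.external_validate({"shannon": rule}, cohort, 15)["shannon"]
        assert rep.accuracy == pytest.approx(16 / 20)
        assert math.isnan(rep.ppv)  # no positive calls: 0/0

    def test_missing_class_yields_missing_rates(self):
        cohort = _separable_cohort(n_ptd=0, n_term=8)
        rule = ps.ThresholdRule("shannon", 0.5, PTD_IF_BELOW)
        rep = ps.external_validate({"shannon": rule}, cohort, 15)["shannon"]
        assert math.isnan(rep.sensitivity)
        assert rep.specificity == 1.0

    def test_week_cutoff_respected(self):
        early = _separable_cohort(week=10.0)
        late = _separable_cohort(week=30.0)
        rule = ps.ThresholdRule("shannon", 0.5, PTD_IF_BELOW)
        with pytest.raises(ValueError, match="no samples"):
            ps.external_validate({"shannon": rule}, late, 15)
        assert ps.external_validate({"shannon": rule}, early, 15)


class TestWeekSweep:
    def test_counts_monotone_and_row_shape(self, small_cohort):
        report = ps.week_sweep(small_cohort, ["shannon", "tcs"], 8, 20)
        assert len(report.mcc) == 13
        assert report.counts["n_total"].is_monotonic_increasing

    def test_single_class_rows_missing(self):
        cohort = _separable_cohort(n_ptd=0, n_term=5, week=9.0)
        report = ps.week_sweep(cohort, ["shannon"], 8, 10)
        assert report.mcc["shannon"].isna().all()
        assert (report.counts["n_term"] == [0, 5, 5]).all()

    def test_printable_table_brackets_es_at_complete_separation(self):
        cohort = _separable_cohort(week=9.0)
        report = ps.week_sweep(cohort, ["shannon"], 8, 10)
        table = report.to_table()
        cell = table.loc["Week_9", "shannon"]
        assert cell.startswith("1.000 (") and cell.endswith("*")


class TestComparisons:
    def test_dominating_reference_significant(self):
        weeks = [f"Week_{n}" for n in range(8, 21)]
        rng = np.random.default_rng(20)
        base = rng.uniform(0.3, 0.6, size=len(weeks))
        data = {f"m{j}": base + rng.uniform(0.0, 0.05, size=len(weeks)) for j in range(8)}
        data["tcs"] = base + 0.2
        matrix = pd.DataFrame(data, index=weeks)
        result = ps.compare_metric_mcc_over_weeks(matrix, "tcs", 8, 20)
        assert (result.table["p_adjusted"] < 0.05).all()
        assert (result.table["direction"] == "reference_higher").all()

    def test_equal_competitor_p_one(self):
        weeks = [f"Week_{n}" for n in range(8, 21)]
        col = np.linspace(0.3, 0.9, len(weeks))
        matrix = pd.DataFrame({"tcs": col, "same": col, "worse": col - 0.1}, index=weeks)
        result = ps.compare_metric_mcc_over_weeks(matrix, "tcs", 8, 20)
        assert result.table.at["same", "p_raw"] == 1.0

    def test_week_order_irrelevant(self):
        weeks = [f"Week_{n}" for n in range(8, 21)]
        rng = np.random.default_rng(21)
        matrix = pd.DataFrame(
            {"tcs": rng.uniform(size=13), "other": rng.uniform(size=13)}, index=weeks
        )
        shuffled = matrix.sample(frac=1, random_state=1)
        a = ps.compare_metric_mcc_over_weeks(matrix, "tcs", 8, 20).table
        b = ps.compare_metric_mcc_over_weeks(shuffled, "tcs", 8, 20).table
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_weeks_rejected(self):
        matrix = pd.DataFrame(
            {"tcs": [0.5, 0.6], "other": [0.4, 0.5]}, index=["Week_8", "Week_9"]
        )
        with pytest.raises(ValueError, match="at least 5"):
            ps.compare_metric_mcc_over_weeks(matrix, "tcs", 8, 20)


class TestWeekTrend:
    def test_ptd_below_term_early(self, default_cohort, metric_table):
        trend = ps.week_trend(default_cohort, metric_table["shannon"])
        early = trend[trend["week_mid"] <= 14]
        assert (early["mean_ptd"] < early["mean_term"]).all()
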