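"""Behavioral statistics battery against closed-form and permutation oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from numerest import (condition_means, exclude_subjects, one_sample_test,
                      paired_tests, run_battery, sequential_correlations,
                      signed_rank_test)
from numerest.stats import _sequential_pairs
from numerest.task import TRIAL_COLUMNS


def make_table(rows):
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["response"] = pd.to_numeric(df["response"])
    return df


def simple_trials(subject, responses, trial_type="baseline", cond="high",
                  experiment="exp1", block=0, colors=None, types=None,
                  true_counts=None):
    rows = []
    for i, r in enumerate(responses):
        rows.append({
            "subject_id": subject, "experiment": experiment,
            "block_index": block, "condition_label": cond,
            "trial_index_in_block": i,
            "trial_type": types[i] if types else trial_type,
            "color": colors[i] if colors else 1,
            "true_count": true_counts[i] if true_counts else 65,
            "response": r, "valid": r is not None and not pd.isna(r),
        })
    return rows


class TestExclusion:
    def _pool(self, rng, n_good=8, bad=False):
        rows = []
        for s in range(n_good):
            for exp, alt_mean, cond in [("exp1", 55, "high"), ("exp2", 35, "high_var"),
                                        ("exp3", 60, "low")]:
                resp = np.rint(rng.normal(alt_mean, 3, size=20))
                rows += simple_trials(f"s{s}", resp, "alternative", cond, exp)
        if bad:
            resp = rng.integers(10, 100, size=60)  # random responder
            rows += (simple_trials("bad", resp[:20], "alternative", "high", "exp1")
                     + simple_trials("bad", resp[20:40], "alternative", "high_var", "exp2")
                     + simple_trials("bad", resp[40:], "alternative", "low", "exp3"))
        return make_table(rows)

    def test_random_responder_excluded(self, rng):
        kept, excluded, scores = exclude_subjects(self._pool(rng, bad=True))
        assert excluded == ["bad"]
        assert "bad" not in kept

    def test_identical_errors_none_excluded(self):
        rows = []
        for s in range(5):
            rows += simple_trials(f"s{s}", [57] * 10, "alternative", "high", "exp1")
        kept, excluded, _ = exclude_subjects(make_table(rows))
        assert excluded == [] and len(kept) == 5

    def test_row_order_invariant(self, rng):
        df = self._pool(rng, bad=True)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert exclude_subjects(df)[1] == exclude_subjects(shuffled)[1]

    def test_too_few_subjects(self, rng):
        df = make_table(simple_trials("only", [55] * 5, "alternative"))
        with pytest.raises(ValueError, match="at least 3"):
            exclude_subjects(df)


class TestConditionMeans:
    def test_group_mean_averages_subjects_not_trials(self):
        # unbalanced: s0 has 2 trials at 60, s1 has 8 trials at 70
        rows = (simple_trials("s0", [60, 60]) + simple_trials("s1", [70] * 8))
        per, mean, sem = condition_means(make_table(rows), "baseline", "high")
        assert mean == pytest.approx(65.0)  # not the pooled 68
        assert per.tolist() == [60.0, 70.0]

    def test_single_subject_sem_zero_with_warning(self):
        df = make_table(simple_trials("s0", [60, 62]))
        with pytest.warns(UserWarning, match="SEM undefined"):
            _, mean, sem = condition_means(df, "baseline", "high")
        assert (mean, sem) == (61.0, 0.0)

    def test_empty_cell_raises(self):
        df = make_table(simple_trials("s0", [60]))
        with pytest.raises(ValueError, match="no valid responded"):
            condition_means(df, "alternative", "high")


class TestPairedTests:
    def test_hand_oracle(self):
        # diffs = [1, 1, 1, 2]: t = mean/ (sd/sqrt(n))
        a = np.array([5.0, 6.0, 7.0, 8.0])
        b = a - np.array([1.0, 1.0, 1.0, 2.0])
        res = paired_tests(a, b)
        d = np.array([1.0, 1.0, 1.0, 2.0])
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(4))
        assert res["t"] == pytest.approx(t_hand)
        assert res["df"] == 3
        assert res["d"] == pytest.approx(d.mean() / d.std(ddof=1))
        assert res["p"] == pytest.approx(
            2 * sps.t.sf(abs(t_hand), 3))

    def test_sign_flip_symmetry(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        r1, r2 = paired_tests(a, b), paired_tests(b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_zero_variance_signaled(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_cohens_d_equals_t_over_sqrt_n(self, rng):
        a, b = rng.normal(0, 1, 14), rng.normal(0.4, 1, 14)
        res = paired_tests(a, b)
        assert res["d"] == pytest.approx(res["t"] / math.sqrt(14))


class TestSequentialCorrelations:
    def test_boundary_and_recency_rules(self):
        # block: b a b b a b -> alt->base pairs: (a0,b1), (a0,b2), (a1,b3);
        # the first baseline trial has no preceding alternative and is skipped
        types = ["baseline", "alternative", "baseline", "baseline",
                 "alternative", "baseline"]
        resp = [10, 20, 30, 40, 50, 60]
        df = make_table(simple_trials("s0", resp, types=types))
        pairs = _sequential_pairs(df, "alt_to_base")
        assert pairs == [(20, 30), (20, 40), (50, 60)]
        pairs_rev = _sequential_pairs(df, "base_to_alt")
        assert pairs_rev == [(10, 20), (40, 50)]

    def test_invalid_trials_skipped(self):
        types = ["alternative", "baseline", "baseline"]
        df = make_table(simple_trials("s0", [20, None, 30], types=types))
        assert _sequential_pairs(df, "alt_to_base") == [(20, 30)]

    def test_shared_drift_detected(self, rng):
        """A slow within-block drift shared by both trial types yields
        positive group-level Fisher-z correlations."""
        rows = []
        for s in range(12):
            for b in range(6):
                drift = rng.normal(0, 6)
                types = list(rng.permutation(["baseline"] * 5
                                             + ["alternative"] * 5))
                resp = [65 + drift + rng.normal(0, 1.5) for _ in types]
                rows += simple_trials(f"s{s}", np.rint(resp), types=types,
                                      block=b)
        z, test = sequential_correlations(make_table(rows), "alt_to_base")
        assert len(z) == 12
        assert test["p"] < 0.01 and test["t"] > 0

    def test_independent_responses_near_zero(self, rng):
        rows = []
        for s in range(10):
            for b in range(6):
                types = list(rng.permutation(["baseline"] * 5
                                             + ["alternative"] * 5))
                resp = np.rint(rng.normal(65, 5, size=10))
                rows += simple_trials(f"s{s}", resp, types=types, block=b)
        z, test = sequential_correlations(make_table(rows), "alt_to_base")
        assert abs(z.mean()) < 0.2


class TestSignedRank:
    def test_all_positive_small_p(self, rng):
        vals = rng.uniform(0.5, 3.0, size=14)
        res = signed_rank_test(vals)
        assert res["statistic"] == 0.0  # all ranks on the positive side
        assert res["p"] < 0.001

    def test_symmetric_values_large_p(self):
        vals = np.array([-3, 3, -2, 2, -1, 1, -0.5, 0.5])
        assert signed_rank_test(vals)["p"] > 0.9

    def test_matches_permutation_oracle(self, rng):
        """Exact sign-flip distribution of W+ computed by dynamic
        programming over the rank generating function."""
        for _ in range(20):
            vals = rng.normal(0.3, 1.0, size=14)
            res = signed_rank_test(vals)
            ranks = sps.rankdata(np.abs(vals))
            w_obs = ranks[vals > 0].sum()
            # polynomial DP: product over ranks of (1 + x^rank) / 2
            max_w = int(round(ranks.sum()))
            dist = np.zeros(max_w + 1)
            dist[0] = 1.0
            for r in ranks:
                r = int(round(r))
                nxt = dist.copy()
                nxt[r:] += dist[:max_w + 1 - r]
                dist = nxt / 2.0
            lo = dist[:int(round(w_obs)) + 1].sum()
            hi = dist[int(round(w_obs)):].sum()
            p_perm = min(1.0, 2 * min(lo, hi))
            assert res["p"] == pytest.approx(p_perm, abs=0.02)

    def test_minimum_n(self):
        with pytest.raises(ValueError, match="at least 5"):
            signed_rank_test([1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def exp1_table():
    from numerest import ResponderSpec, simulate_experiment
    spec = ResponderSpec(n_particles=120)
    return simulate_experiment("exp1", 8, seed=21, responder=spec)


class TestBattery:
    def test_report_structure_and_row_order_invariance(self, exp1_table):
        rep = run_battery(exp1_table)
        assert rep.n_subjects == 8
        assert set(rep.baseline_means) == {"high", "low"}
        assert rep.paired_baseline["df"] == 7
        shuffled = exp1_table.sample(frac=1.0, random_state=3)
        rep2 = run_battery(shuffled)
        assert rep2.paired_baseline["t"] == pytest.approx(
            rep.paired_baseline["t"])
        assert rep2.baseline_means == rep.baseline_means
        # serializations render
        assert rep.to_json() and rep.to_text()

    def test_baseline_estimates_below_truth_in_overlap_condition(self, exp1_table):
        """Ideal-observer responses on high-overlap blocks are biased
        below the true baseline mean (regularization toward the lower
        alternative)."""
        rep = run_battery(exp1_table)
        one = rep.one_sample_baseline["high"]
        assert one["t"] < 0 and one["p"] < 0.05

    def test_mixed_experiment_table_rejected(self, exp1_table):
        df = exp1_table.copy()
        df.loc[df.index[:100], "experiment"] = "exp2"
        with pytest.raises(ValueError, match="single-experiment"):
            run_battery(df)
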