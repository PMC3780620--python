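"""Behavioral statistics battery for trial tables (human or simulated).

Implements the analyses reported for the three estimation experiments:
subject exclusion by alternative-trial error, per-condition baseline means,
paired and one-sample t-tests with Cohen's d, within-block sequential
correlations (Fisher z-transformed, tested at the group level), and the
Wilcoxon signed-rank test used for log Bayes factors.

All statistics operate on subject-level aggregates (never pooled trials),
use two-sided tests, ignore invalid (timed-out) trials, and are invariant
to the row order of the input table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import make_design

__all__ = [
    "exclude_subjects", "condition_means", "paired_tests",
    "one_sample_test", "sequential_correlations", "signed_rank_test",
    "run_battery", "StatsReport",
]


def _valid(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["valid"] & df["response"].notna()]


def _alt_means(experiment: str) -> dict:
    design = make_design(experiment)
    return {c.label: c.alt_mean for c in design.conditions}


def exclude_subjects(df: pd.DataFrame):
    """Exclusion rule applied to the pooled trials of *all* experiments.

    A subject's error score is the mean absolute distance of their valid
    alternative-trial responses from the alternative distribution's true
    mean; subjects scoring more than two standard deviations above the
    across-subject mean are excluded.

    Returns ``(kept_ids, excluded_ids, scores)``.
    """
    v = _valid(df)
    alt = v[v["trial_type"] == "alternative"].copy()
    if alt["subject_id"].nunique() < 3:
        raise ValueError("need at least 3 subjects for the exclusion rule")
    true_mean = {exp: _alt_means(exp) for exp in alt["experiment"].unique()}
    alt["err"] = [
        abs(r.response - true_mean[r.experiment][r.condition_label])
        for r in alt.itertuples(index=False)]
    scores = alt.groupby("subject_id")["err"].mean().sort_index()
    thresh = scores.mean() + 2.0 * scores.std(ddof=1)
    if scores.std(ddof=1) == 0 or np.isnan(thresh):
        excluded = []
    else:
        excluded = list(scores.index[scores > thresh])
    kept = [s for s in scores.index if s not in excluded]
    return kept, excluded, scores


def condition_means(df: pd.DataFrame, trial_type: str, condition_label: str):
    """Subject-level mean responses in one cell, plus group mean and SEM.

    The group mean averages subject means (not pooled trials).
    """
    v = _valid(df)
    cell = v[(v["trial_type"] == trial_type)
             & (v["condition_label"] == condition_label)]
    if cell.empty:
        raise ValueError(
            f"no valid responded trials for {trial_type}/{condition_label}")
    per_subject = cell.groupby("subject_id")["response"].mean().sort_index()
    n = len(per_subject)
    if n == 1:
        warnings.warn("single subject: SEM undefined, reported as 0")
        sem = 0.0
    else:
        sem = float(per_subject.std(ddof=1) / np.sqrt(n))
    return per_subject, float(per_subject.mean()), sem


def paired_tests(a, b):
    """Paired two-sided t-test with Cohen's d = mean(diff)/SD(diff).

    Returns a dict with ``t, df, p, d``; raises on zero-variance differences
    (t undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two paired vectors of equal length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    res = sps.ttest_rel(a, b)
    return {"t": float(res.statistic), "df": len(a) - 1,
            "p": float(res.pvalue), "d": float(diff.mean() / sd)}


def one_sample_test(values, popmean: float):
    """One-sample two-sided t-test vs. ``popmean`` with d = mean dev / SD."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t undefined")
    res = sps.ttest_1samp(values, popmean)
    return {"t": float(res.statistic), "df": len(values) - 1,
            "p": float(res.pvalue),
            "d": float((values.mean() - popmean) / sd)}


def _sequential_pairs(block: pd.DataFrame, direction: str):
    """(predecessor response, successor response) pairs within one block.

    ``alt_to_base``: each baseline trial paired with the most recent
    preceding alternative trial; ``base_to_alt`` the reverse.  Pairs never
    cross block boundaries; trials at the start of a block with no preceding
    other-type trial are skipped, as are invalid trials.
    """
    succ_type = "baseline" if direction == "alt_to_base" else "alternative"
    pred_type = "alternative" if direction == "alt_to_base" else "baseline"
    pairs = []
    last_pred = None
    for r in block.sort_values("trial_index_in_block").itertuples(index=False):
        usable = r.valid and not pd.isna(r.response)
        if r.trial_type == pred_type and usable:
            last_pred = r.response
        elif r.trial_type == succ_type and usable and last_pred is not None:
            pairs.append((last_pred, r.response))
    return pairs


def sequential_correlations(df: pd.DataFrame, direction: str,
                            condition_label: str | None = None,
                            min_pairs: int = 3):
    """Per-subject Fisher-z sequential correlations and their group t-test.

    For every usable trial of the successor type, the most recent preceding
    trial of the other type *in the same block* provides the predictor; the
    per-subject Pearson correlation over those pairs is z-transformed
    (atanh) and the z values are tested against 0 across subjects.
    """
    if direction not in ("alt_to_base", "base_to_alt"):
        raise ValueError("direction must be 'alt_to_base' or 'base_to_alt'")
    d = df if condition_label is None else df[df["condition_label"] == condition_label]
    zs = {}
    for sid, sub in d.groupby("subject_id"):
        pairs = []
        for _, block in sub.groupby("block_index"):
            pairs.extend(_sequential_pairs(block, direction))
        if len(pairs) < min_pairs:
            warnings.warn(f"subject {sid}: only {len(pairs)} sequential pairs; dropped")
            continue
        x, y = np.array(pairs).T
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"subject {sid}: constant responses; dropped")
            continue
        r = float(sps.pearsonr(x, y).statistic)
        zs[sid] = float(np.arctanh(np.clip(r, -0.999999, 0.999999)))
    z = pd.Series(zs).sort_index()
    test = one_sample_test(z.values, 0.0) if len(z) >= 2 and z.std(ddof=1) > 0 \
        else {"t": np.nan, "df": max(len(z) - 1, 0), "p": np.nan, "d": np.nan}
    return z, test


def signed_rank_test(values):
    """Two-sided Wilcoxon signed-rank test of ``values`` against zero.

    Zeros are discarded and ties handled by the standard mid-rank correction
    (normal approximation when exact enumeration is unavailable).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        raise ValueError("need at least 5 values")
    res = sps.wilcoxon(values, alternative="two-sided")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


@dataclass
class StatsReport:
    """Results battery for a single experiment's trial table."""

    experiment: str
    n_subjects: int
    excluded_subjects: list
    baseline_means: dict        # condition -> {mean, sem}
    alternative_means: dict     # condition -> {mean, sem}
    paired_baseline: dict       # t/df/p/d for condition A vs B baseline means
    one_sample_baseline: dict   # condition -> t-test vs true baseline mean
    sequential: dict            # direction -> condition -> {z_mean, t, df, p, d, n}

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=float, indent=2)

    def to_text(self) -> str:
        L = [f"Experiment {self.experiment}: {self.n_subjects} subjects "
             f"({len(self.excluded_subjects)} excluded)"]
        L.append("Baseline estimates by condition:")
        for c, v in self.baseline_means.items():
            L.append(f"  {c:<10} mean={v['mean']:7.2f}  sem={v['sem']:.2f}")
        p = self.paired_baseline
        L.append(f"Paired t ({p['labels'][0]} - {p['labels'][1]}): "
                 f"t({p['df']})={p['t']:.2f}, p={p['p']:.4f}, d={p['d']:.2f}")
        L.append("One-sample t vs true baseline mean:")
        for c, v in self.one_sample_baseline.items():
            L.append(f"  {c:<10} t({v['df']})={v['t']:.2f}, p={v['p']:.4f}, "
                     f"d={v['d']:.2f}")
        L.append("Sequential Fisher-z correlations (group test vs 0):")
        for direction, conds in self.sequential.items():
            for c, v in conds.items():
                L.append(f"  {direction:<12} {c:<10} z̄={v['z_mean']:+.3f} "
                         f"t({v['df']})={v['t']:.2f}, p={v['p']:.4f} (n={v['n']})")
        return "\n".join(L)


def run_battery(df: pd.DataFrame, apply_exclusion: bool = False) -> StatsReport:
    """Run the full per-experiment battery on a single-experiment table."""
    exps = df["experiment"].unique()
    if len(exps) != 1:
        raise ValueError(f"expected a single-experiment table, got {list(exps)}")
    experiment = str(exps[0])
    excluded: list = []
    if apply_exclusion:
        _, excluded, _ = exclude_subjects(df)
        df = df[~df["subject_id"].isin(excluded)]
    design = make_design(experiment)
    labels = [c.label for c in design.conditions]

    base_means, alt_means, one_sample = {}, {}, {}
    per_subject = {}
    for cond in design.conditions:
        ps, m, sem = condition_means(df, "baseline", cond.label)
        per_subject[cond.label] = ps
        base_means[cond.label] = {"mean": m, "sem": sem}
        _, am, asem = condition_means(df, "alternative", cond.label)
        alt_means[cond.label] = {"mean": am, "sem": asem}
        one_sample[cond.label] = one_sample_test(ps.values, cond.baseline_mean)

    a, b = per_subject[labels[0]].align(per_subject[labels[1]], join="inner")
    paired = paired_tests(a.values, b.values)
    paired["labels"] = labels

    sequential = {}
    for direction in ("alt_to_base", "base_to_alt"):
        sequential[direction] = {}
        for lab in labels:
            z, test = sequential_correlations(df, direction, lab)
            sequential[direction][lab] = {
                "z_mean": float(z.mean()) if len(z) else np.nan,
                "n": len(z), **test}

    return StatsReport(
        experiment=experiment,
        n_subjects=int(df["subject_id"].nunique()),
        excluded_subjects=list(excluded),
        baseline_means=base_means,
        alternative_means=alt_means,
        paired_baseline=paired,
        one_sample_baseline=one_sample,
        sequential=sequential,
    )
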