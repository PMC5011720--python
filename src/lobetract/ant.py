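"""Attention Network Test quality control and ratio scoring.

The Attention Network Test (ANT) crosses a warning cue (none / center /
spatial) with a flanker congruency manipulation, separating three attention
subnetworks in a single task.  This module implements the trial-level
cleaning rules (accuracy gate, RT window, post-error removal) and the three
ratio scores:

    alerting  = (mean RT no-cue  - mean RT center-cue ) / D
    orienting = (mean RT center  - mean RT spatial-cue) / D
    EC        = (mean RT incongruent - mean RT congruent) / D

with D the subject's overall mean retained RT by default (the conventional
ratio-score denominator; a per-component baseline denominator is available
and every ScoreSet records which convention produced it).  Higher EC scores
mean a larger congruency cost, i.e. poorer executive control.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QCReport",
    "GateDecision",
    "ScoreSet",
    "qc_trials",
    "subject_gate",
    "ratio_scores",
    "score_subject",
    "score_descriptives",
]

REQUIRED_COLUMNS = ("block", "trial", "cue", "flanker", "rt_ms", "correct")
CUE_LEVELS = ("none", "center", "spatial")
FLANKER_LEVELS = ("congruent", "incongruent")


@dataclass
class QCReport:
    n_total: int
    n_incorrect: int
    n_rt_out_of_range: int
    n_post_error: int
    n_retained: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GateDecision:
    accuracy: float
    threshold: float
    excluded: bool


@dataclass
class ScoreSet:
    alerting: float
    orienting: float
    ec: float
    accuracy: float
    mean_rt: float
    n_retained: int
    denominator: str

    def to_dict(self) -> dict:
        return asdict(self)


def _check_columns(trials: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")


def _check_ordered(trials: pd.DataFrame) -> None:
    """The post-error rule needs the original presentation order."""
    if "subject" in trials.columns:
        groups = [g for _, g in trials.groupby("subject", sort=False)]
    else:
        groups = [trials]
    for g in groups:
        block = g["block"].to_numpy()
        trial = g["trial"].to_numpy()
        order = np.lexsort((trial, block))
        if not np.array_equal(order, np.arange(len(g))):
            raise ValueError(
                "trials must be ordered by block then trial index; the "
                "post-error removal rule is order-sensitive")


def qc_trials(trials: pd.DataFrame, rt_min: float = 200.0,
              rt_max: float = 1500.0) -> tuple[pd.DataFrame, QCReport]:
    """Apply trial-level exclusion rules, returning retained trials + report.

    Removal rules, applied to the original trial sequence and attributed in
    this order: (1) incorrect responses; (2) RTs strictly below ``rt_min`` ms
    or strictly above ``rt_max`` ms (trials at exactly the bound are kept);
    (3) trials whose immediately preceding trial within the same block was
    incorrect (post-error slowing).  The post-error test always uses original
    correctness and adjacency, so QC is idempotent but order-sensitive.
    """
    _check_columns(trials)
    _check_ordered(trials)
    t = trials.reset_index(drop=True)
    incorrect = ~t["correct"].astype(bool)
    out_of_range = (t["rt_ms"] < rt_min) | (t["rt_ms"] > rt_max)
    group_cols = ["subject", "block"] if "subject" in t.columns else ["block"]
    prev_incorrect = (incorrect.groupby([t[c] for c in group_cols])
                      .shift(1, fill_value=False))
    # attribute each removed trial to the first applicable rule
    r_incorrect = incorrect
    r_rt = out_of_range & ~r_incorrect
    r_post = prev_incorrect & ~r_incorrect & ~r_rt
    removed = r_incorrect | r_rt | r_post
    retained = t.loc[~removed].reset_index(drop=True)
    report = QCReport(
        n_total=len(t),
        n_incorrect=int(r_incorrect.sum()),
        n_rt_out_of_range=int(r_rt.sum()),
        n_post_error=int(r_post.sum()),
        n_retained=len(retained),
    )
    return retained, report


def subject_gate(trials: pd.DataFrame, threshold: float = 0.80) -> GateDecision:
    """Exclude a subject whose raw overall accuracy is strictly below threshold."""
    _check_columns(trials)
    if len(trials) == 0:
        raise ValueError("cannot gate a subject with zero trials")
    acc = float(trials["correct"].astype(bool).mean())
    return GateDecision(accuracy=acc, threshold=threshold,
                        excluded=acc < threshold)


def _cell_means(retained: pd.DataFrame) -> tuple[dict, dict]:
    cue_mean = {}
    for c in CUE_LEVELS:
        sel = retained["cue"] == c
        if not sel.any():
            raise ValueError(f"no retained trials in cue condition '{c}'")
        cue_mean[c] = float(retained.loc[sel, "rt_ms"].mean())
    fl_mean = {}
    for f in FLANKER_LEVELS:
        sel = retained["flanker"] == f
        if not sel.any():
            raise ValueError(f"no retained trials in flanker condition '{f}'")
        fl_mean[f] = float(retained.loc[sel, "rt_ms"].mean())
    return cue_mean, fl_mean


def ratio_scores(retained: pd.DataFrame, denominator: str = "overall",
                 accuracy: float = float("nan")) -> ScoreSet:
    """Compute the three attention ratio scores from retained trials.

    ``denominator='overall'`` divides each RT difference by the subject's
    overall mean retained RT; ``denominator='baseline'`` divides each
    difference by its own slower reference condition (no-cue, center-cue and
    congruent mean respectively).  The choice is recorded in the result.
    """
    _check_columns(retained)
    if len(retained) == 0:
        raise ValueError("no retained trials to score")
    cue_mean, fl_mean = _cell_means(retained)
    overall = float(retained["rt_ms"].mean())
    if denominator == "overall":
        d_alert = d_orient = d_ec = overall
    elif denominator == "baseline":
        d_alert = cue_mean["none"]
        d_orient = cue_mean["center"]
        d_ec = fl_mean["congruent"]
    else:
        raise ValueError("denominator must be 'overall' or 'baseline'")
    return ScoreSet(
        alerting=(cue_mean["none"] - cue_mean["center"]) / d_alert,
        orienting=(cue_mean["center"] - cue_mean["spatial"]) / d_orient,
        ec=(fl_mean["incongruent"] - fl_mean["congruent"]) / d_ec,
        accuracy=accuracy,
        mean_rt=overall,
        n_retained=len(retained),
        denominator=denominator,
    )


def score_subject(trials: pd.DataFrame, denominator: str = "overall",
                  gate_threshold: float = 0.80,
                  rt_min: float = 200.0, rt_max: float = 1500.0
                  ) -> tuple[ScoreSet | None, QCReport, GateDecision]:
    """Full per-subject pipeline: accuracy gate, trial QC, ratio scores.

    Returns ``(None, report, decision)`` for a gated-out subject.
    """
    decision = subject_gate(trials, threshold=gate_threshold)
    retained, report = qc_trials(trials, rt_min=rt_min, rt_max=rt_max)
    if decision.excluded:
        return None, report, decision
    scores = ratio_scores(retained, denominator=denominator,
                          accuracy=decision.accuracy)
    return scores, report, decision


@dataclass
class Descriptives:
    correlations: pd.DataFrame
    group_tests: pd.DataFrame
    group_means: pd.DataFrame


def score_descriptives(scores: pd.DataFrame,
                       zygosity_col: str = "zygosity",
                       score_cols: tuple = ("alerting", "orienting", "ec")
                       ) -> Descriptives:
    """Cohort descriptives: score inter-correlations and MZ vs DZ t-tests.

    Pearson correlations carry two-tailed p-values; a constant score vector
    yields an undefined (NaN) correlation flagged in the ``note`` column.
    Group comparisons use independent-samples two-tailed t-tests.
    """
    for c in score_cols:
        if c not in scores.columns:
            raise ValueError(f"missing score column '{c}'")
    groups = scores[zygosity_col].unique() if zygosity_col in scores.columns else []
    corr_rows = []
    for i, a in enumerate(score_cols):
        for b in score_cols[i + 1:]:
            x, y = scores[a].to_numpy(float), scores[b].to_numpy(float)
            tol = 1e-12
            if (np.std(x) <= tol * (1 + abs(x.mean()))
                    or np.std(y) <= tol * (1 + abs(y.mean()))):
                corr_rows.append({"score_a": a, "score_b": b, "r": np.nan,
                                  "p": np.nan, "note": "constant score vector"})
            else:
                r, p = stats.pearsonr(x, y)
                corr_rows.append({"score_a": a, "score_b": b, "r": float(r),
                                  "p": float(p), "note": ""})
    correlations = pd.DataFrame(corr_rows)

    test_rows, mean_rows = [], []
    if len(groups) == 2:
        g1, g2 = sorted(groups)
        for c in score_cols:
            x = scores.loc[scores[zygosity_col] == g1, c].to_numpy(float)
            y = scores.loc[scores[zygosity_col] == g2, c].to_numpy(float)
            if min(len(x), len(y)) < 3:
                raise ValueError("need >=3 subjects per zygosity group")
            t, p = stats.ttest_ind(x, y)
            test_rows.append({"score": c, "group_a": g1, "group_b": g2,
                              "t": float(t), "p": float(p)})
            mean_rows.append({"score": c,
                              f"mean_{g1}": x.mean(), f"sd_{g1}": x.std(ddof=1),
                              f"mean_{g2}": y.mean(), f"sd_{g2}": y.std(ddof=1)})
    return Descriptives(correlations=correlations,
                        group_tests=pd.DataFrame(test_rows),
                        group_means=pd.DataFrame(mean_rows))
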