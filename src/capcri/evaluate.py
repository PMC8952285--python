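"""Metrics, group statistics and the cross-validation driver.

The confusion matrix uses the canonical 18-class order with rows = actual
and columns = predicted.  Per-class F1 is the harmonic mean of precision
and recall; the headline score is the unweighted mean over supported
classes, with a support-weighted mean reported alongside because the two
conventions differ on imbalanced data.  Collapsed views (sleep-wake,
6-stage, per-stage A/NA) are computed by summing matrix blocks before
scoring, which is identical to collapsing the label sequences first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .labels import (NREM_STAGES, REM, STAGE_LABELS, WAKE, is_a_phase,
                     macro_label)

N = len(STAGE_LABELS)


def confusion(actual, predicted, labels=STAGE_LABELS) -> pd.DataFrame:
    """Count matrix with rows = actual class, columns = predicted class."""
    actual = [str(l) for l in actual]
    predicted = [str(l) for l in predicted]
    if len(actual) != len(predicted):
        raise ValueError("sequences must be equally long")
    index = {lab: i for i, lab in enumerate(labels)}
    unknown = (set(actual) | set(predicted)) - set(labels)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for a, p in zip(actual, predicted):
        cm[index[a], index[p]] += 1
    return pd.DataFrame(cm, index=list(labels), columns=list(labels))


def _score_matrix(cm: np.ndarray, labels) -> pd.DataFrame:
    """Per-class precision/recall/F1 from a counts matrix."""
    cm = np.asarray(cm, dtype=float)
    tp = np.diag(cm)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, np.nan)
        recall = np.where(support > 0, tp / support, np.nan)
        f1 = np.where((precision + recall) > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    f1 = np.where(np.isnan(precision) | np.isnan(recall),
                  np.where(support > 0, 0.0, np.nan), f1)
    return pd.DataFrame({"precision": precision, "recall": recall,
                         "f1": f1, "support": support.astype(int)},
                        index=list(labels))


@dataclass
class MetricsReport:
    """Per-class and aggregate scores plus collapsed views."""

    per_class: pd.DataFrame
    macro_f1: float
    weighted_f1: float
    zero_support: tuple = ()
    collapsed: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "zero_support": list(self.zero_support),
            "per_class": self.per_class.to_dict(orient="index"),
            "collapsed": {k: v.to_dict(orient="index")
                          for k, v in self.collapsed.items()},
        }


def _aggregate(per_class: pd.DataFrame) -> tuple[float, float, tuple]:
    scored = per_class.dropna(subset=["f1"])
    zero = tuple(per_class.index[per_class["support"] == 0])
    scored = scored[scored["support"] > 0]
    if scored.empty:
        return np.nan, np.nan, zero
    macro = float(scored["f1"].mean())
    weighted = float(np.average(scored["f1"], weights=scored["support"]))
    return macro, weighted, zero


def _collapse(cm: pd.DataFrame, mapping: dict, order) -> pd.DataFrame:
    """Sum matrix blocks according to a label -> group mapping."""
    groups = [mapping[l] for l in cm.index]
    out = pd.DataFrame(0, index=list(order), columns=list(order), dtype=int)
    for gi, row in zip(groups, cm.to_numpy()):
        for gj, v in zip(groups, row):
            out.loc[gi, gj] += int(v)
    return out


def f1_report(cm: pd.DataFrame) -> MetricsReport:
    """Scores of an 18-class confusion matrix plus collapsed views.

    Classes with zero support are excluded from the macro mean and
    reported in ``zero_support``.
    """
    if int(cm.to_numpy().sum()) == 0:
        raise ValueError("empty confusion matrix")
    per_class = _score_matrix(cm.to_numpy(), cm.index)
    macro, weighted, zero = _aggregate(per_class)
    if zero:
        warnings.warn(f"classes with zero support excluded: {zero}",
                      stacklevel=2)
    collapsed = {}
    if set(cm.index) == set(STAGE_LABELS):
        sw_map = {l: ("wake" if l == WAKE else "sleep") for l in cm.index}
        collapsed["sleep_wake"] = _score_matrix(
            _collapse(cm, sw_map, ["wake", "sleep"]).to_numpy(),
            ["wake", "sleep"])
        st_map = {l: macro_label(l) for l in cm.index}
        order6 = [WAKE, REM] + list(NREM_STAGES)
        collapsed["stage6"] = _score_matrix(
            _collapse(cm, st_map, order6).to_numpy(), order6)
        for stage in NREM_STAGES:
            rows = [l for l in cm.index if macro_label(l) == stage]
            sub = cm.loc[rows, rows]
            an_map = {l: ("A" if is_a_phase(l) else "NA") for l in rows}
            collapsed[f"{stage}_a_na"] = _score_matrix(
                _collapse(sub, an_map, ["A", "NA"]).to_numpy(), ["A", "NA"])
    return MetricsReport(per_class, macro, weighted, zero, collapsed)


def a_phase_rates(cm: pd.DataFrame) -> pd.DataFrame:
    """Two readings of the per-stage A-phase recognition rate.

    ``recall``: recall of the merged A class within the stage's actual
    epochs; ``binary_accuracy``: A/NA accuracy within the stage.  Both
    are reported because either could be called a "recognition rate".
    """
    rows = {}
    for stage in NREM_STAGES:
        labs = [l for l in cm.index if macro_label(l) == stage]
        sub = cm.loc[labs, labs]
        an_map = {l: ("A" if is_a_phase(l) else "NA") for l in labs}
        c2 = _collapse(sub, an_map, ["A", "NA"]).to_numpy(dtype=float)
        a_support = c2[0].sum()
        recall = c2[0, 0] / a_support if a_support > 0 else np.nan
        total = c2.sum()
        acc = (c2[0, 0] + c2[1, 1]) / total if total > 0 else np.nan
        rows[stage] = {"recall": recall, "binary_accuracy": acc}
    return pd.DataFrame(rows).T


def group_stats(values_by_group: dict, alpha: float = 0.05) -> dict:
    """One-way ANOVA across groups plus Dunnett-style pairwise decisions.

    The first group in the dict is the control.  Each comparison reports
    the mean difference, the least significant range (LSR, the half-width
    of the Dunnett simultaneous confidence interval at ``alpha``) and a
    significance flag: significant iff |mean difference| > LSR.
    """
    names = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("degenerate variance in every group")
    f_stat, p = stats.f_oneway(*samples)
    control, treatments = samples[0], samples[1:]
    comparisons = {}
    if treatments and np.ptp(np.concatenate(samples)) > 0:
        res = stats.dunnett(*treatments, control=control, alternative="two-sided")
        ci = res.confidence_interval(confidence_level=1 - alpha)
        for k, g in enumerate(names[1:]):
            diff = float(np.mean(treatments[k]) - np.mean(control))
            lsr = float((ci.high[k] - ci.low[k]) / 2.0)
            comparisons[f"{g}_vs_{names[0]}"] = {
                "mean_difference": diff,
                "lsr": lsr,
                "significant": bool(abs(diff) > lsr),
                "p_value": float(res.pvalue[k]),
            }
    return {"anova_F": float(f_stat), "anova_p": float(p),
            "alpha": alpha, "comparisons": comparisons}


def crossvalidate(feature_frames: dict, stager_factory, folds: int = 7,
                  seed: int = 0):
    """Subject-level k-fold cross-validation of a stager.

    ``feature_frames`` maps subject id -> DataFrame with the 23
    characteristics and a ``label`` column; ``stager_factory()`` builds a
    fresh unfitted stager per fold.  Returns ``(fold_reports,
    pooled_report, pooled_confusion)``; the pooled matrix is the sum of
    the fold matrices.
    """
    subjects = sorted(feature_frames)
    if folds > len(subjects):
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignment = {subjects[i]: k % folds for k, i in enumerate(order)}
    pooled = pd.DataFrame(0, index=list(STAGE_LABELS),
                          columns=list(STAGE_LABELS))
    fold_reports = []
    for k in range(folds):
        test_ids = [s for s in subjects if assignment[s] == k]
        train_ids = [s for s in subjects if assignment[s] != k]
        train = pd.concat([feature_frames[s] for s in train_ids],
                          ignore_index=True)
        stager = stager_factory()
        stager.fit(train, train["label"])
        cm_fold = pd.DataFrame(0, index=list(STAGE_LABELS),
                               columns=list(STAGE_LABELS))
        for s in test_ids:
            df = feature_frames[s]
            pred = stager.predict(df)
            cm_fold += confusion(df["label"], pred)
        pooled += cm_fold
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_reports.append(f1_report(cm_fold))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled_report = f1_report(pooled)
    return fold_reports, pooled_report, pooled
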