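"""Subject-level screening for insomnia and narcolepsy.

A staged recording is collapsed into an order-free summary vector: per
macro stage the mean and variance of the 23 characteristics, the
deep-sleep (S3+S4) CRI profile, and the per-stage A-vs-NA CRA contrast.
Group statistics motivate these blocks: insomnia shows a large A/NA CRA
swing with high non-A coupling, narcolepsy a globally low coupling depth
and width (high damping).  An RBF-kernel SVM over standardized summaries
performs the three-group decision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.impute import SimpleImputer
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .labels import (DEEP_STAGES, MACRO_LABELS, NREM_STAGES, is_a_phase,
                     macro_label)
from .staging import CHARACTERISTIC_NAMES

GROUPS = ("healthy", "insomnia", "narcolepsy")
_CRI_BLOCK = ("crq", "crr", "crb", "cra")


def summary_feature_names() -> list[str]:
    names = []
    for stage in MACRO_LABELS:
        for c in CHARACTERISTIC_NAMES:
            names.append(f"{stage}.{c}.mean")
            names.append(f"{stage}.{c}.var")
    names += [f"deep.{c}" for c in _CRI_BLOCK]
    names += [f"{s}.a_na_cra_contrast" for s in NREM_STAGES]
    return names


SUMMARY_NAMES = summary_feature_names()


@dataclass
class SubjectSummary:
    """Order-free per-subject aggregate of a staged recording."""

    values: np.ndarray
    subject_id: str = ""
    n_epochs: int = 0
    names: tuple = field(default_factory=lambda: tuple(SUMMARY_NAMES))

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names),
                         name=self.subject_id)


def summarize_subject(features: pd.DataFrame, predicted_labels,
                      subject_id: str = "",
                      min_epochs: int = 10) -> SubjectSummary:
    """Aggregate epoch features + predicted labels into a SubjectSummary.

    Blocks for stages absent from the recording are NaN (the diagnoser
    imputes with training medians); the summary is invariant to epoch
    order within stages.
    """
    labels = np.asarray([str(l) for l in predicted_labels])
    if len(features) != labels.size:
        raise ValueError("features and labels must align")
    if len(features) < min_epochs:
        raise ValueError(f"need at least {min_epochs} scored epochs")
    cols = [c for c in CHARACTERISTIC_NAMES if c in features.columns]
    X = features[cols].to_numpy(dtype=float)
    col_pos = {c: i for i, c in enumerate(CHARACTERISTIC_NAMES)}
    macro = np.array([macro_label(l) for l in labels])
    vals: list[float] = []
    for stage in MACRO_LABELS:
        rows = macro == stage
        block_mean = np.full(len(CHARACTERISTIC_NAMES), np.nan)
        block_var = np.full(len(CHARACTERISTIC_NAMES), np.nan)
        if rows.any():
            sub = X[rows]
            for k, c in enumerate(cols):
                v = sub[:, k]
                v = v[np.isfinite(v)]
                if v.size:
                    block_mean[col_pos[c]] = np.mean(v)
                    block_var[col_pos[c]] = np.var(v)
        for j in range(len(CHARACTERISTIC_NAMES)):
            vals.append(block_mean[j])
            vals.append(block_var[j])
    deep = np.isin(macro, DEEP_STAGES)
    for c in _CRI_BLOCK:
        if deep.any() and c in features.columns:
            v = features.loc[deep, c].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            # median: epochs bordering CAP activations dilute the mean
            vals.append(float(np.median(v)) if v.size else np.nan)
        else:
            vals.append(np.nan)
    a_mask = np.array([is_a_phase(l) for l in labels])
    for stage in NREM_STAGES:
        rows = macro == stage
        if "cra" in features.columns and rows.any():
            cra = features["cra"].to_numpy(dtype=float)
            a_v = cra[rows & a_mask]
            na_v = cra[rows & ~a_mask]
            a_v, na_v = a_v[np.isfinite(a_v)], na_v[np.isfinite(na_v)]
            if a_v.size and na_v.size:
                vals.append(float(np.median(a_v) - np.median(na_v)))
            else:
                vals.append(np.nan)
        else:
            vals.append(np.nan)
    return SubjectSummary(np.asarray(vals, dtype=float), subject_id,
                          n_epochs=len(features))


class SubjectDiagnoser(BaseEstimator, ClassifierMixin):
    """Three-group (healthy / insomnia / narcolepsy) SVM over summaries.

    Median imputation -> standardization -> RBF SVC; C and gamma chosen
    by an inner stratified 3-fold grid search.  Deterministic given
    ``random_state``.
    """

    def __init__(self, random_state: int = 0, inner_folds: int = 3,
                 c_grid=(1.0, 10.0, 100.0), gamma_grid=("scale", 0.1, 0.01)):
        self.random_state = random_state
        self.inner_folds = inner_folds
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid

    @staticmethod
    def _matrix(summaries) -> np.ndarray:
        if isinstance(summaries, np.ndarray):
            return np.asarray(summaries, dtype=float)
        if isinstance(summaries, pd.DataFrame):
            return summaries.to_numpy(dtype=float)
        return np.vstack([s.values for s in summaries])

    def fit(self, summaries, groups):
        y = np.asarray([str(g) for g in groups])
        X = self._matrix(summaries)
        if np.unique(y).size < 2:
            raise ValueError("training requires at least two groups")
        counts = pd.Series(y).value_counts()
        folds = int(min(self.inner_folds, counts.min()))
        pipe = Pipeline([
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", class_weight="balanced",
                        decision_function_shape="ovr",
                        random_state=self.random_state)),
        ])
        with warnings.catch_warnings():
            # blocks absent for every training subject (e.g. a stage no
            # one reached) carry no information; the imputer drops them
            warnings.filterwarnings("ignore", message="Skipping features")
            if folds >= 2:
                cv = StratifiedKFold(n_splits=folds, shuffle=True,
                                     random_state=self.random_state)
                grid = GridSearchCV(
                    pipe, {"svc__C": list(self.c_grid),
                           "svc__gamma": list(self.gamma_grid)},
                    cv=cv, n_jobs=1)
                grid.fit(X, y)
                self.model_ = grid.best_estimator_
                self.best_params_ = grid.best_params_
            else:
                self.model_ = pipe.fit(X, y)
                self.best_params_ = {}
        self.classes_ = self.model_.named_steps["svc"].classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, summaries) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(self._matrix(summaries))

    def decision_function(self, summaries) -> np.ndarray:
        """Per-group margin scores (one-vs-rest)."""
        check_is_fitted(self, "model_")
        return self.model_.decision_function(self._matrix(summaries))

    def diagnose(self, summary: SubjectSummary) -> dict:
        """Group call plus margin scores for a single subject."""
        X = summary.values[None, :]
        group = str(self.predict(X)[0])
        scores = np.atleast_2d(self.decision_function(X))[0]
        if scores.ndim == 0 or scores.size == 1:     # binary: single margin
            margins = {str(self.classes_[1]): float(np.ravel(scores)[0])}
        else:
            margins = {str(c): float(s) for c, s in zip(self.classes_, scores)}
        return {"subject_id": summary.subject_id, "group": group,
                "margins": margins}


@dataclass
class TrainingLibrary:
    """Versioned store of subject summaries with confirmed diagnoses.

    Appending recomputes nothing implicitly: the caller passes the
    recomputed summary, the version counter increments, and retraining
    happens only when explicitly requested.
    """

    summaries: list = field(default_factory=list)
    groups: list = field(default_factory=list)
    version: int = 0

    def __len__(self) -> int:
        return len(self.summaries)

    def update(self, summary: SubjectSummary, confirmed_group: str) -> "TrainingLibrary":
        if confirmed_group not in GROUPS:
            raise ValueError(f"unknown group {confirmed_group!r}")
        if summary.subject_id and summary.subject_id in {
                s.subject_id for s in self.summaries}:
            raise ValueError(f"duplicate subject id {summary.subject_id!r}")
        if self.summaries and summary.values.size != self.summaries[0].values.size:
            raise ValueError("summary feature dimension mismatch")
        self.summaries.append(summary)
        self.groups.append(str(confirmed_group))
        self.version += 1
        return self

    def train(self, random_state: int = 0) -> SubjectDiagnoser:
        """Explicit retraining on the current library contents."""
        return SubjectDiagnoser(random_state=random_state).fit(
            self.summaries, self.groups)

    # -- serialization -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "groups": list(self.groups),
            "subjects": [
                {"subject_id": s.subject_id, "n_epochs": int(s.n_epochs),
                 "values": [None if not np.isfinite(v) else float(v)
                            for v in s.values]}
                for s in self.summaries],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TrainingLibrary":
        with open(path) as fh:
            payload = json.load(fh)
        lib = cls(version=int(payload["version"]))
        for rec, grp in zip(payload["subjects"], payload["groups"]):
            vals = np.array([np.nan if v is None else float(v)
                             for v in rec["values"]])
            lib.summaries.append(SubjectSummary(
                vals, rec["subject_id"], int(rec["n_epochs"])))
            lib.groups.append(str(grp))
        return lib
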