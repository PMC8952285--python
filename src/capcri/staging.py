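"""Two-layer random-forest sleep/CAP staging.

Layer 1 assigns each 30-s epoch one of the six macro stages (W, REM,
S1-S4) from the 23-element characteristic vector (21 features + 2 HMM
stability features).  Epochs assigned an NREM stage are passed to that
stage's layer-2 forest, which scores the CAP phase (A1/A2/A3/NA).  Wake
and REM epochs carry no CAP phase, so the composed output covers the full
18-class label set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, STABILITY_NAMES
from .labels import (CAP_PHASES, NREM_STAGES, REM, WAKE, join_label,
                     macro_group, macro_label, split_label, validate_labels)

CHARACTERISTIC_NAMES = FEATURE_NAMES + STABILITY_NAMES   # the 23 characteristics


def select_training_epochs(labels, min_run: int = 20) -> np.ndarray:
    """Indices of epochs usable for layer-1 training.

    For the WAKE / LIGHT (S1,S2) / DEEP (S3,S4) macro-classes only epochs
    inside runs of at least ``min_run`` identical macro-labels (10 min at
    30 s) are kept, so the stage context is unambiguous.  REM epochs are
    all kept.  (CAP-phase training in layer 2 uses all labelled epochs.)
    """
    labels = [str(l) for l in labels]
    validate_labels(labels)
    groups = [macro_group(l) for l in labels]
    keep = np.zeros(len(labels), dtype=bool)
    i = 0
    while i < len(groups):
        j = i
        while j < len(groups) and groups[j] == groups[i]:
            j += 1
        if groups[i] == "R" or (j - i) >= min_run:
            keep[i:j] = True
        i = j
    if not keep.any():
        warnings.warn("no epochs satisfy the training-selection rule",
                      stacklevel=2)
    return np.flatnonzero(keep)


def compensate_outliers(features: pd.DataFrame,
                        stats: pd.DataFrame | None = None,
                        n_mad: float = 5.0,
                        reprocess=None) -> pd.DataFrame:
    """Bound feature outliers to median +/- n_mad * MAD.

    ``stats`` supplies per-feature training medians/MADs (columns
    ``median`` and ``mad``); by default they are computed from
    ``features`` itself.  When a ``reprocess`` callable is given it is
    invoked once with the row indices of offending fragments and may
    return a recomputed frame; values still outside the bounds afterwards
    are winsorised, so the procedure terminates in at most two passes and
    a second call is a no-op.
    """
    cols = [c for c in features.columns if c in CHARACTERISTIC_NAMES]
    out = features.copy()
    if stats is None:
        med = out[cols].median()
        mad = (out[cols] - med).abs().median()
    else:
        med, mad = stats["median"], stats["mad"]
    scale = n_mad * mad.replace(0.0, np.nan)
    lo, hi = med - scale, med + scale
    mask = (out[cols].lt(lo, axis=1) | out[cols].gt(hi, axis=1))
    if mask.any().any() and reprocess is not None:
        redone = reprocess(np.flatnonzero(mask.any(axis=1)))
        if redone is not None:
            out.loc[redone.index, cols] = redone[cols]
            mask = (out[cols].lt(lo, axis=1) | out[cols].gt(hi, axis=1))
    out[cols] = out[cols].clip(lower=lo, upper=hi, axis=1)
    return out


def outlier_stats(features: pd.DataFrame) -> pd.DataFrame:
    """Per-feature median and MAD of a training set."""
    cols = [c for c in features.columns if c in CHARACTERISTIC_NAMES]
    med = features[cols].median()
    mad = (features[cols] - med).abs().median()
    return pd.DataFrame({"median": med, "mad": mad})


class CapStager(BaseEstimator, ClassifierMixin):
    """Two-layer random-forest classifier over the 18 sleep/CAP classes.

    Parameters
    ----------
    n_estimators : int
        Trees per forest.
    random_state : int
        Seed shared by all forests; the fit is deterministic given it.
    class_weight : str or None
        Passed to the forests; the default counters class imbalance.
    feature_names : sequence of str or None
        Column subset used when a DataFrame is passed; defaults to the
        23 characteristics.

    Attributes
    ----------
    layer1_ : RandomForestClassifier
        Six-class macro-stage forest.
    layer2_ : dict
        Per-NREM-stage phase forest (or a fixed majority label where a
        stage's training data lacked class diversity).
    medians_ : ndarray
        Training medians used to impute missing feature values.
    """

    def __init__(self, n_estimators: int = 500, random_state: int = 0,
                 class_weight="balanced_subsample", feature_names=None):
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.class_weight = class_weight
        self.feature_names = feature_names

    # -- helpers -------------------------------------------------------
    def _matrix(self, X) -> np.ndarray:
        names = (list(self.feature_names) if self.feature_names is not None
                 else CHARACTERISTIC_NAMES)
        if isinstance(X, pd.DataFrame):
            X = X[[c for c in names if c in X.columns]].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-d feature matrix")
        return X

    def _impute(self, X: np.ndarray, y=None) -> np.ndarray:
        X = X.copy()
        if y is not None:
            # per-class medians where the class is known (training time)
            for cls in np.unique(y):
                rows = y == cls
                med = np.nanmedian(X[rows], axis=0)
                med = np.where(np.isfinite(med), med, self.medians_)
                X[rows] = np.where(np.isnan(X[rows]), med, X[rows])
        X = np.where(np.isnan(X), self.medians_, X)
        return X

    def _forest(self):
        return RandomForestClassifier(
            n_estimators=self.n_estimators, max_features="sqrt",
            class_weight=self.class_weight, random_state=self.random_state,
            n_jobs=1)

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y, layer1_indices=None):
        """Fit both layers from 23-feature vectors and 18-class labels.

        ``layer1_indices`` optionally restricts layer-1 training to the
        epochs chosen by :func:`select_training_epochs`; layer 2 always
        sees every labelled NREM epoch.
        """
        X = self._matrix(X)
        y = np.asarray([str(l) for l in y])
        validate_labels(y)
        if X.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.medians_ = np.nanmedian(X, axis=0)
        self.medians_ = np.where(np.isfinite(self.medians_), self.medians_, 0.0)
        Xi = self._impute(X, y)
        y_macro = np.array([macro_label(l) for l in y])
        idx1 = (np.arange(y.size) if layer1_indices is None
                else np.asarray(layer1_indices, dtype=int))
        if np.unique(y_macro[idx1]).size < 2:
            raise ValueError("layer 1 needs at least two macro classes")
        self.layer1_ = self._forest().fit(Xi[idx1], y_macro[idx1])
        self.layer2_ = {}
        for stage in NREM_STAGES:
            rows = y_macro == stage
            phases = np.array([split_label(l)[1] for l in y[rows]])
            if rows.sum() == 0 or np.unique(phases).size < 2:
                maj = ("NA" if rows.sum() == 0 else
                       pd.Series(phases).mode().iloc[0])
                warnings.warn(
                    f"stage {stage}: insufficient phase diversity; "
                    f"layer 2 degenerates to majority class {maj!r}",
                    stacklevel=2)
                self.layer2_[stage] = str(maj)
            else:
                self.layer2_[stage] = self._forest().fit(Xi[rows], phases)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Full 18-class label per epoch (W/REM epochs carry no phase)."""
        check_is_fitted(self, "layer1_")
        X = self._matrix(X)
        Xi = self._impute(X)
        macro = self.layer1_.predict(Xi)
        out = np.empty(macro.size, dtype=object)
        for stage in (WAKE, REM):
            out[macro == stage] = stage
        for stage in NREM_STAGES:
            rows = macro == stage
            if not rows.any():
                continue
            clf = self.layer2_[stage]
            if isinstance(clf, str):
                phases = np.full(rows.sum(), clf, dtype=object)
            else:
                phases = clf.predict(Xi[rows])
            out[rows] = [join_label(stage, p) for p in phases]
        return out.astype(str)

    def predict_macro(self, X) -> np.ndarray:
        """Layer-1 (6-class) prediction only."""
        check_is_fitted(self, "layer1_")
        return self.layer1_.predict(self._impute(self._matrix(X)))

    def predict_phase_proba(self, X, stage: str) -> np.ndarray:
        """Phase probabilities of one stage's layer-2 forest."""
        check_is_fitted(self, "layer2_")
        clf = self.layer2_[stage]
        Xi = self._impute(self._matrix(X))
        if isinstance(clf, str):
            proba = np.zeros((Xi.shape[0], len(CAP_PHASES)))
            proba[:, CAP_PHASES.index(clf)] = 1.0
            return proba
        return clf.predict_proba(Xi)
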