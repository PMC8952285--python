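"""End-to-end composition: signals -> CRI -> features -> staging -> diagnosis.

These helpers wire the stage-specific modules together the way the CLI
and the evaluation drivers use them; each step remains individually
accessible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .causality import cri_track
from .features import assemble_epoch_features
from .hmm import CRAStateModel, stability_features, train_hmm
from .staging import CapStager, select_training_epochs
from .synthetic import SubjectRecord


def extract_subject_features(record: SubjectRecord, order="auto",
                             with_labels: bool = True,
                             **track_kwargs) -> pd.DataFrame:
    """The 21-feature epoch table (plus CRA and labels) of one subject."""
    track = cri_track(record.rri, record.rsp, order=order, **track_kwargs)
    labels = record.annotations.labels if with_labels else None
    n_epochs = len(record.annotations)
    df = assemble_epoch_features(record.rri, record.rsp, record.accel,
                                 track, n_epochs=n_epochs, labels=labels)
    df.insert(0, "subject_id", record.subject_id)
    df["group"] = record.group
    return df


def add_stability_features(df: pd.DataFrame,
                           model: CRAStateModel) -> pd.DataFrame:
    """Append the two HMM stability features decoded from the CRA column."""
    out = df.copy()
    stab = stability_features(model, out["cra"].to_numpy(dtype=float))
    out["stab_diag"] = stab[:, 0]
    out["stab_colsum"] = stab[:, 1]
    return out


def fit_hmm_on_training(frames: list[pd.DataFrame]) -> CRAStateModel:
    """Supervised CRA state model pooled over the training subjects."""
    cra = np.concatenate([f["cra"].to_numpy(dtype=float) for f in frames])
    labels = sum((list(f["label"]) for f in frames), [])
    return train_hmm(cra, labels)


def train_stager_on_frames(frames: list[pd.DataFrame], seed: int = 0,
                           n_estimators: int = 500,
                           feature_names=None) -> tuple[CapStager, CRAStateModel]:
    """HMM + two-layer forest trained on labelled subject frames.

    Layer-1 training epochs are restricted to stable >= 10-min runs per
    subject; layer 2 uses all labelled epochs.
    """
    hmm = fit_hmm_on_training(frames)
    enriched = [add_stability_features(f, hmm) for f in frames]
    train = pd.concat(enriched, ignore_index=True)
    offsets = np.cumsum([0] + [len(f) for f in enriched[:-1]])
    idx1 = np.concatenate([
        off + select_training_epochs(f["label"])
        for off, f in zip(offsets, enriched)])
    from .labels import macro_label
    selected_macros = {macro_label(l) for l in train["label"].iloc[idx1]} \
        if idx1.size else set()
    if len(selected_macros) < 2:
        # heavily fragmented recordings leave no usable stable stretches
        # (or only the always-kept REM epochs): fall back to all epochs
        idx1 = np.arange(len(train))
    stager = CapStager(n_estimators=n_estimators, random_state=seed,
                       feature_names=feature_names)
    stager.fit(train, train["label"], layer1_indices=idx1)
    return stager, hmm


def stage_subject(df: pd.DataFrame, stager: CapStager,
                  hmm: CRAStateModel) -> np.ndarray:
    """Predicted 18-class labels for one subject's feature frame."""
    enriched = add_stability_features(df, hmm)
    return stager.predict(enriched)
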