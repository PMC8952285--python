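"""Readers and writers for the on-disk formats.

Signals travel either as EDF (optional, via :mod:`mne`) or as plain CSV;
annotations as a TSV with columns ``epoch_start_s  stage  cap_phase``;
pre-extracted tachograms as CSV ``time_ms,rr_ms``.  CRI tracks, feature
tables and hypnograms are flat CSV/TSV files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .labels import NO_PHASE, join_label, split_label
from .types import AnnotationTrack, CRIRecord, RRISeries, SignalSegment

DEFAULT_CHANNEL_PATTERNS = {
    "ecg": ("ecg", "ekg"),
    "resp": ("resp", "thor", "abdo", "breath"),
    "acc_x": ("acc_x", "accx", "x-axis"),
    "acc_y": ("acc_y", "accy", "y-axis"),
    "acc_z": ("acc_z", "accz", "z-axis"),
}


def load_edf(path, channel_patterns=None) -> dict:
    """Channels of an EDF recording as :class:`SignalSegment` objects.

    Channels are matched case-insensitively against the configured name
    patterns.  Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:                      # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package "
                          "(pip install capcri[edf])") from exc
    patterns = channel_patterns or DEFAULT_CHANNEL_PATTERNS
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    out = {}
    for role, pats in patterns.items():
        for name in raw.ch_names:
            if any(p.lower() in name.lower() for p in pats):
                data = raw.get_data(picks=[name])[0]
                out[role] = SignalSegment(data, raw.info["sfreq"], 0.0, role)
                break
    return out


def read_signal_csv(path, fs: float | None = None,
                    label: str = "") -> SignalSegment:
    """CSV with columns ``t_s,value`` (or a single value column + fs)."""
    df = pd.read_csv(path)
    if "t_s" in df.columns:
        t = df["t_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-3):
            raise ValueError("non-uniform sampling in signal CSV")
        fs = 1.0 / dt[0]
        t0 = float(t[0])
    else:
        if fs is None:
            raise ValueError("fs required when the CSV has no t_s column")
        t0 = 0.0
    value_col = [c for c in df.columns if c != "t_s"][0]
    return SignalSegment(df[value_col].to_numpy(dtype=float), fs, t0,
                         label or value_col)


def write_signal_csv(path, sig: SignalSegment) -> None:
    pd.DataFrame({"t_s": sig.times, sig.label or "value": sig.samples}
                 ).to_csv(path, index=False)


def read_tachogram_csv(path) -> RRISeries:
    """CSV dialect ``time_ms,rr_ms``: beat time of each closing beat."""
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(dtype=float) / 1000.0
    rr = df["rr_ms"].to_numpy(dtype=float)
    beats = np.concatenate([[t[0] - rr[0] / 1000.0], t])
    return RRISeries(beats)


def write_tachogram_csv(path, rri: RRISeries) -> None:
    pd.DataFrame({"time_ms": rri.interval_times * 1000.0,
                  "rr_ms": rri.intervals}).to_csv(path, index=False)


def read_annotations_tsv(path) -> AnnotationTrack:
    """TSV columns ``epoch_start_s  stage  cap_phase``.

    ``stage`` is one of W, R, S1-S4; ``cap_phase`` one of A1, A2, A3, NA
    or ``-`` for wake/REM.
    """
    # keep_default_na: the CAP phase "NA" is a real label, not a missing value
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    starts = df["epoch_start_s"].astype(float).to_numpy()
    if starts.size > 1:
        steps = np.diff(starts)
        if not np.allclose(steps, steps[0]):
            raise ValueError("annotation epochs must be on a regular grid")
        epoch_length = float(steps[0])
    else:
        epoch_length = 30.0
    labels = [join_label(s, p if p != NO_PHASE else
                         ("NA" if s.startswith("S") else NO_PHASE))
              for s, p in zip(df["stage"], df["cap_phase"])]
    return AnnotationTrack(labels, epoch_length, t0=float(starts[0]))


def write_annotations_tsv(path, track: AnnotationTrack) -> None:
    rows = []
    for t, lab in zip(track.epoch_starts, track.labels):
        stage, phase = split_label(lab)
        rows.append({"epoch_start_s": t, "stage": stage, "cap_phase": phase})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_hypnogram_tsv(path, labels, epoch_length: float = 30.0,
                        t0: float = 0.0) -> None:
    write_annotations_tsv(path, AnnotationTrack(list(labels), epoch_length, t0))


def cri_to_frame(track: list[CRIRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"t0": r.t0, "t1": r.t1, "FA": r.f_a, "CRA": r.cra, "CRB": r.crb,
         "CRQ": r.crq, "CRR": r.crr, "quality_flag": int(r.valid)}
        for r in track])


def write_cri_csv(path, track: list[CRIRecord]) -> None:
    cri_to_frame(track).to_csv(path, index=False)


def read_cri_csv(path) -> list[CRIRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(CRIRecord(
            t0=float(row["t0"]), t1=float(row["t1"]), f_a=float(row["FA"]),
            cra=float(row["CRA"]), crb=float(row["CRB"]),
            crq=float(row["CRQ"]), crr=float(row["CRR"]),
            valid=bool(row["quality_flag"])))
    return out


def convert_capslpdb_annotations(path) -> AnnotationTrack:
    """Converter stub for the CAP Sleep Database's native annotation files.

    The database ships scorer exports in a site-specific dialect; only
    the documented TSV dialect of :func:`read_annotations_tsv` is
    supported here.  Convert native files externally (one row per 30-s
    epoch with columns epoch_start_s/stage/cap_phase) and load the
    result.
    """
    raise NotImplementedError(
        "native CAP Sleep Database annotation files are out of scope; "
        "convert to the documented TSV dialect first (see read_annotations_tsv)")


def save_model(path, obj) -> None:
    """Persist a trained model bundle (joblib pickle)."""
    import joblib
    joblib.dump(obj, path)


def load_model(path):
    import joblib
    return joblib.load(Path(path))
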