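"""Per-epoch feature extraction: 3 body-movement, 12 HRV and 6 CRI features.

Features are stamped to the 30-s annotation grid.  HRV and CRI features
are computed on longer supporting windows (120 s centred on the epoch for
HRV, the CRI analysis grid for the index features) because spectral HRV
and the causality fit are unreliable on 30 s of data.  Missing values are
explicit NaN, never silent zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .causality import resample_tachogram
from .entropy import approximate_entropy, sample_entropy
from .types import CRIRecord, RRISeries, SignalSegment

HRV_NAMES = ["sdnn", "rmssd", "pnn50", "vlf", "lf", "hf", "lf_hf",
             "sd1", "sd2", "sd1_sd2", "sampen", "apen"]
BM_NAMES = ["bm_var", "bm_apen", "bm_sampen"]
CRI_NAMES = ["crr", "crb", "crq", "cra", "cra_var", "cra_entropy"]
FEATURE_NAMES = BM_NAMES + HRV_NAMES + CRI_NAMES          # 21 features
STABILITY_NAMES = ["stab_diag", "stab_colsum"]            # appended later

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


def hrv_features(rri: RRISeries, min_beats: int = 30) -> np.ndarray:
    """The 12 HRV statistics of one analysis window.

    Time domain: SDNN, RMSSD, pNN50 (%).  Frequency domain: VLF, LF, HF
    band powers (ms^2, Welch on the 4 Hz resampled tachogram) and LF/HF.
    Nonlinear: Poincare SD1, SD2, SD1/SD2, sample entropy, approximate
    entropy (m=2, r=0.2*SD).
    """
    iv = np.asarray(rri.intervals, dtype=float)
    if iv.size < min_beats:
        return np.full(len(HRV_NAMES), np.nan)
    sdnn = float(np.std(iv))
    d = np.diff(iv)
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    pnn50 = float(100.0 * np.mean(np.abs(d) > 50.0))
    vlf, lf, hf = _band_powers(rri)
    lf_hf = lf / hf if hf > 0 else np.nan
    sd1 = rmssd / np.sqrt(2.0)
    sd2_sq = 2.0 * sdnn ** 2 - sd1 ** 2
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    sd1_sd2 = sd1 / sd2 if sd2 > 0 else np.nan
    sampen = sample_entropy(iv)
    apen = approximate_entropy(iv)
    return np.array([sdnn, rmssd, pnn50, vlf, lf, hf, lf_hf,
                     sd1, sd2, sd1_sd2, sampen, apen])


def _band_powers(rri: RRISeries, fs: float = 4.0):
    """VLF/LF/HF power (ms^2) from the Welch PSD of the resampled tachogram."""
    t0, t1 = rri.beat_times[0], rri.beat_times[-1]
    try:
        x = resample_tachogram(rri, t0, t1, fs)
    except Exception:
        return np.nan, np.nan, np.nan
    x = x - x.mean()
    nperseg = min(x.size, int(64 * fs))
    f, pxx = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    out = []
    for lo, hi in (VLF_BAND, LF_BAND, HF_BAND):
        m = (f >= lo) & (f < hi)
        out.append(float(np.trapezoid(pxx[m], f[m])) if m.any() else 0.0)
    return tuple(out)


def bm_features(acc_x: SignalSegment, acc_y: SignalSegment,
                acc_z: SignalSegment) -> np.ndarray:
    """Variance, ApEn and SampEn of the acceleration magnitude signal.

    The vector magnitude is rotation invariant, so the features do not
    depend on sensor orientation.
    """
    n = acc_x.samples.size
    if acc_y.samples.size != n or acc_z.samples.size != n:
        raise ValueError("axis signals must be equally long")
    if n == 0:
        return np.full(3, np.nan)
    mag = np.sqrt(acc_x.samples ** 2 + acc_y.samples ** 2 + acc_z.samples ** 2)
    var = float(np.var(mag))
    if var == 0:
        return np.array([0.0, 0.0, 0.0])   # flat signal: entropy defined 0
    return np.array([var, approximate_entropy(mag), sample_entropy(mag)])


def cri_features(track: list[CRIRecord], epoch_start: float,
                 epoch_length: float = 30.0, context_s: float = 300.0,
                 cra_bins: np.ndarray | None = None) -> np.ndarray:
    """The 6 CRI features of one epoch.

    CRR, CRB, CRQ, CRA are means over valid records whose window centres
    fall inside the epoch (nearest valid record if none).  var(CRA) and
    the Shannon entropy of CRA (10-bin histogram, subject-level bins) are
    computed over the 5-min context centred on the epoch.
    """
    valid = [r for r in track if r.valid]
    if not valid:
        return np.full(len(CRI_NAMES), np.nan)
    centers = np.array([r.center for r in valid])
    e_mid = epoch_start + epoch_length / 2.0
    in_epoch = [r for r in valid
                if epoch_start <= r.center < epoch_start + epoch_length]
    if not in_epoch:
        in_epoch = [valid[int(np.argmin(np.abs(centers - e_mid)))]]
    crr = float(np.mean([r.crr for r in in_epoch]))
    crb = float(np.mean([r.crb for r in in_epoch]))
    crq = float(np.mean([r.crq for r in in_epoch]))
    cra = float(np.mean([r.cra for r in in_epoch]))
    half = context_s / 2.0
    ctx = np.array([r.cra for r in valid
                    if e_mid - half <= r.center <= e_mid + half])
    if ctx.size == 0:
        cra_var = cra_ent = np.nan
    else:
        cra_var = float(np.var(ctx))
        cra_ent = cra_histogram_entropy(ctx, cra_bins)
    return np.array([crr, crb, crq, cra, cra_var, cra_ent])


def cra_histogram_entropy(values: np.ndarray, bins: np.ndarray | None = None,
                          n_bins: int = 10) -> float:
    """Shannon entropy (nats) of a 10-bin CRA histogram.

    ``bins`` fixes subject-level bin edges (1st-99th percentile of the
    subject's CRA); without them the local range is used.  A degenerate
    (single-bin) distribution has entropy 0.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.nan
    if bins is None:
        lo, hi = np.min(values), np.max(values)
        if hi <= lo:
            return 0.0
        bins = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(np.clip(values, bins[0], bins[-1]), bins=bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def subject_cra_bins(track: list[CRIRecord], n_bins: int = 10) -> np.ndarray | None:
    """Subject-level CRA bin edges between the 1st and 99th percentile."""
    cra = np.array([r.cra for r in track if r.valid])
    if cra.size < 2:
        return None
    lo, hi = np.percentile(cra, [1, 99])
    if hi <= lo:
        hi = lo + 1e-9
    return np.linspace(lo, hi, n_bins + 1)


def assemble_epoch_features(rri: RRISeries, rsp: SignalSegment,
                            accel: tuple[SignalSegment, SignalSegment, SignalSegment],
                            track: list[CRIRecord],
                            n_epochs: int | None = None,
                            epoch_length: float = 30.0,
                            hrv_window_s: float = 120.0,
                            labels=None, t0: float = 0.0) -> pd.DataFrame:
    """One 21-feature row per 30-s epoch of the recording.

    HRV features use the 120-s window centred on the epoch; BM features
    the epoch itself; CRI features the analysis-grid records.  The epoch
    grid matches the annotation grid exactly.  Channels whose start times
    disagree by more than 1 s raise an error.
    """
    starts = [rri.beat_times[0], rsp.t0] + [a.t0 for a in accel]
    if max(starts) - min(starts) > 1.0:
        raise ValueError("channel misalignment exceeds 1 s")
    duration = min(rri.beat_times[-1] - t0, rsp.duration)
    if n_epochs is None:
        n_epochs = int(duration // epoch_length)
    if labels is not None and len(labels) != n_epochs:
        raise ValueError("label sequence length does not match the epoch grid")
    bins = subject_cra_bins(track)
    rows = []
    half_hrv = hrv_window_s / 2.0
    for e in range(n_epochs):
        es = t0 + e * epoch_length
        mid = es + epoch_length / 2.0
        w0 = max(mid - half_hrv, t0)
        w1 = w0 + hrv_window_s
        try:
            hrv = hrv_features(rri.slice(w0, w1))
        except ValueError:
            hrv = np.full(len(HRV_NAMES), np.nan)
        bm = bm_features(*(a.slice(es, es + epoch_length) for a in accel))
        cri = cri_features(track, es, epoch_length, cra_bins=bins)
        rows.append(np.concatenate([bm, hrv, cri]))
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    df.insert(0, "epoch", np.arange(n_epochs))
    if labels is not None:
        df["label"] = list(labels)
    return df
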