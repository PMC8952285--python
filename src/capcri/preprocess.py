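"""Signal preprocessing: quality gating, RR cleaning, beat detection, filtering.

Respiration is judged usable when the fraction of power-spectral-density
mass inside the physiological breathing band (0.03-0.5 Hz) exceeds 0.85.
RR intervals are gated by a normality rule (|RRI_i - mean| < 1.5*Std) and a
beat-to-beat continuity rule (0.7*RRI_{i-1} < RRI_i < 1.3*RRI_{i-1});
offending intervals are replaced by deterministic interpolation from their
nearest valid neighbours.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .types import RRISeries, SignalSegment

RESP_BAND = (0.03, 0.5)
ECG_BAND = (0.5, 40.0)
Q_THRESHOLD = 0.85


class InvalidInputError(ValueError):
    """Raised when a segment violates an operation's preconditions."""


class DetectionError(RuntimeError):
    """Raised when beat detection fails on degenerate input."""


def respiration_quality(res: SignalSegment, band=RESP_BAND) -> float:
    """Spectral concentration Q of a respiration segment.

    Q is the Welch power-spectral-density mass inside ``band`` divided by
    the total mass; it lies in [0, 1] and is invariant to amplitude
    scaling.  Segments with Q > 0.85 are considered to reflect stable
    breathing.
    """
    if res.samples.size < 2:
        raise InvalidInputError("respiration segment too short")
    if res.fs < 1.0:
        raise InvalidInputError("sampling rate must resolve the 0.03-0.5 Hz band")
    x = res.samples - np.mean(res.samples)
    if not np.any(x):
        return 0.0
    nperseg = min(int(60 * res.fs), x.size)
    f, pxx = sps.welch(x, fs=res.fs, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2, detrend="constant")
    total = np.trapezoid(pxx, f)
    if total <= 0:
        return 0.0
    m = (f >= band[0]) & (f <= band[1])
    if not np.any(m):
        return 0.0
    inband = np.trapezoid(pxx[m], f[m])
    return float(min(max(inband / total, 0.0), 1.0))


def _gate_stats(iv: np.ndarray) -> tuple[float, float]:
    """Robust location/scale of a segment for the normality gate."""
    mu = float(np.median(iv))
    sd = max(1.4826 * float(np.median(np.abs(iv - mu))), 2.0)
    return mu, sd


def _violations(iv: np.ndarray, k_std: float,
                stats: tuple[float, float] | None = None) -> np.ndarray:
    """Boolean mask of intervals violating either gating rule.

    The normality gate flags |RRI_i - mean| >= k_std * Std over the current
    segment; the continuity gate flags intervals outside (0.7, 1.3) times
    their predecessor.  Location and scale are estimated robustly (median
    and 1.4826 * MAD): a gate whose own statistics are dragged by the
    artifacts it is meant to catch either misses them or, re-applied
    after repair, flags progressively more of the clean signal.
    """
    # scale floored at ~beat-detection resolution: sub-millisecond
    # dispersion is measurement quantisation, not physiology to gate on
    mu, sd = _gate_stats(iv) if stats is None else stats
    bad = np.zeros(iv.size, dtype=bool)
    if sd > 0:
        bad |= np.abs(iv - mu) >= k_std * sd
    # continuity is judged against the last accepted interval, so one
    # ectopic spike does not condemn its (normal) successor
    prev = iv[0]
    for i in range(1, iv.size):
        if bad[i] or not (0.7 * prev < iv[i] < 1.3 * prev):
            bad[i] = True
        else:
            prev = iv[i]
    return bad


def clean_rr(rri: RRISeries, max_passes: int = 10,
             strict: bool = False) -> tuple[RRISeries, np.ndarray]:
    """Gate and repair RR intervals.

    Flagged intervals are replaced by monotone piecewise-cubic
    interpolation over the surviving neighbours, then the rules are
    re-checked against the repaired series until none fires (a
    deterministic fixpoint, so a second call is a no-op).  The robust
    gate statistics make the iteration stable: a non-robust Std would
    tighten after every repair and progressively flag the clean signal.
    With ``strict=True`` the normality gate tightens to 1.25*Std, used
    when a feature fragment needs re-preprocessing.

    Returns
    -------
    (cleaned, replaced_indices)
    """
    iv = np.asarray(rri.intervals, dtype=float).copy()
    if iv.size < 3:
        raise InvalidInputError("need at least 3 intervals")
    k_std = 1.25 if strict else 1.5
    replaced = np.zeros(iv.size, dtype=bool)
    for _ in range(max_passes):
        bad = _violations(iv, k_std)
        if not bad.any():
            break
        good = ~bad
        if good.sum() < 2:
            raise InvalidInputError(
                "all (or nearly all) intervals violate the gating rules")
        replaced |= bad
        idx = np.arange(iv.size)
        interp = PchipInterpolator(idx[good], iv[good], extrapolate=False)
        iv[bad] = interp(idx[bad])
        # flagged points outside the span of valid anchors take the
        # nearest valid value (extrapolation does not settle)
        first_good, last_good = idx[good][0], idx[good][-1]
        iv[:first_good] = iv[first_good]
        iv[last_good + 1:] = iv[last_good]
        iv = np.clip(iv, 1e-3, None)
    cleaned = RRISeries.from_intervals(iv, t0=rri.beat_times[0])
    return cleaned, np.flatnonzero(replaced)


def denoise(sig: SignalSegment, band: tuple[float, float],
            wavelet: str = "db4", order: int = 4) -> SignalSegment:
    """Remove baseline drift and out-of-band noise.

    Baseline is the discrete-wavelet approximation whose band lies below
    the low cut (zeroed before reconstruction); the residual is then
    band-pass filtered with a zero-phase Butterworth filter.
    """
    lo, hi = band
    nyq = sig.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise InvalidInputError(f"band {band} infeasible for fs={sig.fs}")
    x = sig.samples.astype(float)
    if not np.any(x):
        return SignalSegment(np.zeros_like(x), sig.fs, sig.t0, sig.label)
    # level such that the approximation band fs/2^(level+1) sits below lo
    level = int(np.ceil(np.log2(sig.fs / (2.0 * lo)))) - 1
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    level = min(max(level, 1), max_level)
    if level >= 1:
        coeffs = pywt.wavedec(x, wavelet, level=level)
        coeffs[0] = np.zeros_like(coeffs[0])
        x = pywt.waverec(coeffs, wavelet)[: sig.samples.size]
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=sig.fs, output="sos")
    padlen = min(3 * (order * 2 + 1), x.size - 1)
    y = sps.sosfiltfilt(sos, x, padlen=padlen)
    return SignalSegment(y, sig.fs, sig.t0, sig.label)


def detect_r_peaks(ecg: SignalSegment, refractory_s: float = 0.25) -> np.ndarray:
    """R-wave times from a single-lead ECG.

    Derivative -> squaring -> moving-window integration with an adaptive
    threshold (Pan-Tompkins style), followed by refinement of each peak on
    the band-passed signal.  Rates outside 30-200 bpm raise a warning.
    """
    if ecg.fs < 100:
        raise InvalidInputError("ECG must be sampled at >= 100 Hz")
    x = ecg.samples.astype(float)
    if x.size < int(2 * ecg.fs) or np.ptp(x) == 0:
        raise DetectionError("flat or too-short ECG")
    filt = denoise(ecg, (5.0, 35.0)).samples
    deriv = np.gradient(filt)
    sq = deriv ** 2
    win = max(int(0.15 * ecg.fs), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")
    thr = 0.25 * np.quantile(mwi, 0.99)
    if thr <= 0:
        raise DetectionError("no QRS energy found")
    min_dist = max(int(refractory_s * ecg.fs), 1)
    locs, _ = sps.find_peaks(mwi, height=thr, distance=min_dist)
    if locs.size < 2:
        raise DetectionError("fewer than two beats detected")
    # refine to the local extremum of the filtered ECG
    half = max(int(0.05 * ecg.fs), 1)
    peaks = []
    for l in locs:
        a, b = max(l - half, 0), min(l + half + 1, filt.size)
        peaks.append(a + int(np.argmax(np.abs(filt[a:b]))))
    peaks = np.unique(peaks)
    beat_times = ecg.t0 + peaks / ecg.fs
    rr = np.diff(beat_times)
    rates = 60.0 / rr
    if np.any((rates < 30) | (rates > 200)):
        warnings.warn("implausible heart rates detected (outside 30-200 bpm)",
                      stacklevel=2)
    return beat_times


def sliding_windows(duration: float, window_s: float = 120.0,
                    step_s: float = 10.0, t0: float = 0.0):
    """Start/stop times of full analysis windows over ``[t0, t0+duration]``.

    Windows start at ``t0 + k*step_s`` and have length ``window_s``;
    partial windows are dropped, so the count is
    ``floor((duration - window_s)/step_s) + 1``.
    """
    if duration < window_s:
        warnings.warn("series shorter than one window; no windows produced",
                      stacklevel=2)
        return []
    n = int(np.floor((duration - window_s) / step_s + 1e-9)) + 1
    return [(t0 + k * step_s, t0 + k * step_s + window_s) for k in range(n)]
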