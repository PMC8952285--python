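"""Bivariate autoregressive modelling, Granger causality and the CRI.

The respiratory drive on heart rate (respiratory sinus arrhythmia) is
quantified by Granger causality from respiration to the RR-interval
series.  A bivariate AR model

    RRI(t) = sum_j A11_j RRI(t-j) + sum_j A12_j RSP(t-j) + e1(t)
    RSP(t) = sum_j A21_j RRI(t-j) + sum_j A22_j RSP(t-j) + e2(t)

is fitted by least squares; the time-domain causality is the log ratio of
the restricted (own-lags-only) to unrestricted prediction-error variance,
and the frequency-domain curve G(f) is Geweke's spectral decomposition of
that ratio.  The cardiopulmonary resonance indices summarise G(f): F_A is
the in-band peak frequency, CRA the peak amplitude, CRB the full width at
half maximum, CRQ = F_A/CRB the quality factor, and (unit-capacitance
series-RLC convention) CRR = CRB/(2 pi F_A^2) the damping analogue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .preprocess import (InvalidInputError, Q_THRESHOLD, RESP_BAND,
                         clean_rr, denoise, respiration_quality,
                         sliding_windows)
from .types import CRIRecord, RRISeries, SignalSegment

DEFAULT_FS = 4.0          # resampling rate for the AR model (Hz)
DEFAULT_P_MAX = 12
DEFAULT_N_FREQ = 512
DEFAULT_F_MAX = 2.0       # Nyquist of the 4 Hz resampled series


@dataclass
class BivarARModel:
    """A fitted bivariate AR model (channel 0 = RRI, channel 1 = RSP).

    ``coeffs[j]`` is the 2x2 lag-(j+1) coefficient matrix; ``sigma`` the
    residual covariance (maximum-likelihood normalisation); ``nobs`` the
    number of regression equations (T - p).
    """

    p: int
    coeffs: np.ndarray      # (p, 2, 2)
    sigma: np.ndarray       # (2, 2)
    nobs: int
    fs: float = DEFAULT_FS

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float).reshape(self.p, 2, 2)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(2, 2)
        if self.p < 1:
            raise ValueError("order must be >= 1")
        if np.any(np.diag(self.sigma) < 0):
            raise ValueError("residual variances must be non-negative")

    def is_stable(self) -> bool:
        """True when all companion-matrix eigenvalues lie inside the unit circle."""
        comp = np.zeros((2 * self.p, 2 * self.p))
        comp[:2, :] = np.hstack([self.coeffs[j] for j in range(self.p)])
        if self.p > 1:
            comp[2:, :-2] = np.eye(2 * (self.p - 1))
        return bool(np.max(np.abs(np.linalg.eigvals(comp))) < 1.0)


def _lag_design(y: np.ndarray, p: int, start: int | None = None):
    """Stacked-lag regressor matrix and response for a VAR(p) fit.

    ``start`` (>= p) fixes the first regressed index so different orders
    can share a common sample for information criteria.
    """
    T = y.shape[0]
    s = p if start is None else start
    rows = T - s
    X = np.empty((rows, 2 * p))
    for j in range(1, p + 1):
        X[:, 2 * (j - 1):2 * j] = y[s - j:T - j]
    return X, y[s:]


def fit_bivar_ar(rri: np.ndarray, rsp: np.ndarray, p="auto",
                 p_max: int = DEFAULT_P_MAX, fs: float = DEFAULT_FS) -> BivarARModel:
    """Least-squares fit of the bivariate AR model.

    Both series must be equally long and are demeaned internally.  With
    ``p="auto"`` the order minimising the BIC over 1..p_max (computed on a
    common sample) is used.
    """
    x1 = np.asarray(rri, dtype=float)
    x2 = np.asarray(rsp, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise InvalidInputError("series must be equally long 1-d arrays")
    T = x1.size
    y = np.column_stack([x1 - x1.mean(), x2 - x2.mean()])
    if np.ptp(y[:, 0]) == 0 or np.ptp(y[:, 1]) == 0:
        raise InvalidInputError("constant input: singular regressor matrix")
    if p == "auto":
        p = select_order(y, min(p_max, T - 2))
    p = int(p)
    if not 1 <= p < T:
        raise InvalidInputError(f"model order must satisfy 1 <= p < T (p={p}, T={T})")
    X, Y = _lag_design(y, p)
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise InvalidInputError("singular regressor matrix")
    E = Y - X @ B
    n = Y.shape[0]
    sigma = (E.T @ E) / n
    coeffs = B.reshape(p, 2, 2).transpose(0, 2, 1)
    return BivarARModel(p=p, coeffs=coeffs, sigma=sigma, nobs=n, fs=fs)


def select_order(y: np.ndarray, p_max: int) -> int:
    """BIC order selection on the common sample starting at ``p_max``."""
    best_p, best_bic = 1, np.inf
    n = y.shape[0] - p_max
    if n < 8:
        return 1
    for p in range(1, p_max + 1):
        X, Y = _lag_design(y, p, start=p_max)
        B, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        E = Y - X @ B
        sigma = (E.T @ E) / n
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        bic = logdet + (np.log(n) / n) * (4 * p)
        if bic < best_bic:
            best_p, best_bic = p, bic
    return best_p


def gc_time(rri: np.ndarray, rsp: np.ndarray, p, p_max: int = DEFAULT_P_MAX) -> float:
    """Time-domain Granger causality respiration -> RRI.

    ``ln(var(e1 restricted) / var(e1 unrestricted))`` where the restricted
    model omits the respiration lags from the RRI equation.  Both models
    are fitted on the same sample, so the value is >= 0 by construction.
    """
    x1 = np.asarray(rri, dtype=float)
    x2 = np.asarray(rsp, dtype=float)
    model = fit_bivar_ar(x1, x2, p=p, p_max=p_max)
    p = model.p
    y = np.column_stack([x1 - x1.mean(), x2 - x2.mean()])
    X, Y = _lag_design(y, p)
    # restricted: RRI regressed on its own lags only (even design columns)
    Xr = X[:, 0::2]
    br, _, _, _ = np.linalg.lstsq(Xr, Y[:, 0], rcond=None)
    er = Y[:, 0] - Xr @ br
    var_r = float(er @ er) / Y.shape[0]
    var_u = float(model.sigma[0, 0])
    if var_u <= 0:
        raise InvalidInputError("zero unrestricted residual variance")
    return max(float(np.log(var_r / var_u)), 0.0)


def gc_spectrum(model: BivarARModel, freqs: np.ndarray | None = None) -> "GCSpectrum":
    """Geweke spectral causality respiration -> RRI on a frequency grid.

    The fitted transfer function H(f) = (I - sum_j A_j e^{-2 pi i f j/fs})^-1
    and residual covariance give the RRI spectrum S11(f); the causal part
    contributed by respiration's orthogonalised innovation is removed to
    form the intrinsic part |H~11|^2 s11, and g(f) = ln(S11/intrinsic).
    Averaged over frequencies up to Nyquist, g integrates back to the
    time-domain measure.
    """
    if not model.is_stable():
        raise InvalidInputError("AR model is unstable; spectrum undefined")
    if freqs is None:
        freqs = np.linspace(DEFAULT_F_MAX / DEFAULT_N_FREQ, DEFAULT_F_MAX,
                            DEFAULT_N_FREQ)
    freqs = np.asarray(freqs, dtype=float)
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, model.p + 1)) / model.fs)
    A = np.eye(2)[None, :, :] - np.einsum("fj,jkl->fkl", z, model.coeffs.astype(complex))
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
    H11 = A[:, 1, 1] / det
    H12 = -A[:, 0, 1] / det
    s11 = model.sigma[0, 0]
    s12 = model.sigma[0, 1]
    s22 = model.sigma[1, 1]
    s22_cond = s22 - s12 ** 2 / s11      # respiration innovation orthogonal to e1
    S11 = (np.abs(H11) ** 2 * s11 + 2 * np.real(H11 * np.conj(H12)) * s12
           + np.abs(H12) ** 2 * s22)
    Htil11 = H11 + (s12 / s11) * H12
    intrinsic = np.abs(Htil11) ** 2 * s11
    g = np.log(np.maximum(S11, 1e-300) / np.maximum(intrinsic, 1e-300))
    return GCSpectrum(freqs=freqs, g=np.maximum(g, 0.0))


@dataclass
class GCSpectrum:
    """A causality curve G(f) >= 0 on a strictly increasing Hz grid."""

    freqs: np.ndarray
    g: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.freqs.shape != self.g.shape:
            raise ValueError("freqs and g must have the same shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.g < -1e-12):
            raise ValueError("g must be non-negative")

    def band_mean(self) -> float:
        """Mean of g over the grid (approximates the Geweke integral)."""
        return float(np.mean(self.g))


def _half_crossing(freqs, g, i_peak, half, direction):
    """Frequency where g falls to ``half``, walking from the peak."""
    i = i_peak
    n = g.size
    while 0 <= i + direction < n and g[i + direction] > half:
        i += direction
    j = i + direction
    if j < 0 or j >= n:
        return freqs[i], True      # truncated at band edge
    # linear interpolation between samples i and j
    f = freqs[i] + (freqs[j] - freqs[i]) * (g[i] - half) / (g[i] - g[j])
    return f, False


def extract_cri(spec: GCSpectrum, band=RESP_BAND, t0: float = 0.0,
                t1: float = 0.0, quality: float = np.nan) -> CRIRecord:
    """Resonance indices from a causality curve.

    The peak is searched inside the respiratory band.  A flat curve (no
    strictly positive in-band maximum) yields a degenerate record with
    ``valid=False`` and missing indices.
    """
    m = (spec.freqs > band[0]) & (spec.freqs < band[1])
    if not np.any(m):
        return CRIRecord(t0=t0, t1=t1, quality=quality, valid=False,
                         flags=("no_band",))
    f_band, g_band = spec.freqs[m], spec.g[m]
    i_peak = int(np.argmax(g_band))
    cra = float(g_band[i_peak])
    if cra <= 0:
        return CRIRecord(t0=t0, t1=t1, quality=quality, valid=False,
                         flags=("flat_spectrum",))
    f_a = float(f_band[i_peak])
    half = cra / 2.0
    f_lo, trunc_lo = _half_crossing(f_band, g_band, i_peak, half, -1)
    f_hi, trunc_hi = _half_crossing(f_band, g_band, i_peak, half, +1)
    crb = float(f_hi - f_lo)
    flags = ("band_edge",) if (trunc_lo or trunc_hi) else ()
    if crb <= 0:
        return CRIRecord(t0=t0, t1=t1, quality=quality, valid=False,
                         flags=flags + ("zero_bandwidth",))
    crq = f_a / crb
    crr = crb / (2.0 * np.pi * f_a ** 2)
    return CRIRecord(t0=t0, t1=t1, f_a=f_a, cra=cra, crb=crb, crq=crq,
                     crr=crr, quality=quality, valid=True, flags=flags)


def resample_tachogram(rri: RRISeries, t_start: float, t_stop: float,
                       fs: float = DEFAULT_FS) -> np.ndarray:
    """Evenly sampled instantaneous-RR series (ms) by cubic interpolation.

    Each interval is stamped at its midpoint (less time-warp distortion
    than closing-beat stamps); the spline is evaluated on the
    ``[t_start, t_stop)`` grid at ``fs``.
    """
    t = 0.5 * (rri.beat_times[:-1] + rri.beat_times[1:])
    if t.size < 4:
        raise InvalidInputError("too few beats to resample")
    if t[0] > t_start + 10.0 or t[-1] < t_stop - 10.0:
        raise InvalidInputError("tachogram does not cover the window")
    grid = t_start + np.arange(int(round((t_stop - t_start) * fs))) / fs
    spline = CubicSpline(t, rri.intervals, extrapolate=True)
    return spline(grid)


def resample_signal(sig: SignalSegment, t_start: float, t_stop: float,
                    fs: float = DEFAULT_FS) -> np.ndarray:
    """Narrow-band signal brought onto the AR analysis grid.

    Cubic interpolation is adequate because respiration lives in
    0.03-0.5 Hz, far below the target Nyquist.
    """
    grid = t_start + np.arange(int(round((t_stop - t_start) * fs))) / fs
    return np.interp(grid, sig.times, sig.samples)


def cri_track(rri: RRISeries, rsp: SignalSegment, window_s: float = 120.0,
              step_s: float = 10.0, fs: float = DEFAULT_FS, order="auto",
              p_max: int = DEFAULT_P_MAX, q_threshold: float = Q_THRESHOLD,
              band=RESP_BAND, n_freq: int = DEFAULT_N_FREQ,
              clean: bool = True, denoise_resp: bool = True) -> list[CRIRecord]:
    """CRI records on the regular 120-s / 10-s analysis grid.

    The respiration channel is band-passed to the respiratory band first
    (out-of-band measurement noise otherwise caps the causality of
    strongly coupled windows).  Windows failing the respiration quality
    gate, with insufficient beat coverage, or with degenerate spectra are
    marked missing (``valid=False``) but kept, so the grid stays regular.
    """
    if denoise_resp:
        rsp = denoise(rsp, band)
    t_lo = max(rri.beat_times[0], rsp.t0)
    t_hi = min(rri.beat_times[-1], rsp.t0 + rsp.duration)
    wins = sliding_windows(t_hi - t_lo, window_s, step_s, t0=t_lo)
    if not wins:
        raise InvalidInputError("no full analysis window fits the recording")
    freqs = np.linspace(DEFAULT_F_MAX / n_freq, DEFAULT_F_MAX, n_freq)
    records: list[CRIRecord] = []
    n_valid = 0
    for (w0, w1) in wins:
        rec = _window_record(rri, rsp, w0, w1, fs, order, p_max, q_threshold,
                             band, freqs, clean)
        records.append(rec)
        n_valid += rec.valid
    if n_valid == 0 and all("low_quality" not in r.flags for r in records):
        raise InvalidInputError("no valid CRI window in the recording")
    return records


def _window_record(rri, rsp, w0, w1, fs, order, p_max, q_threshold, band,
                   freqs, clean) -> CRIRecord:
    try:
        q = respiration_quality(rsp.slice(w0, w1))
    except InvalidInputError:
        return CRIRecord(t0=w0, t1=w1, valid=False, flags=("no_respiration",))
    if not q > q_threshold:
        return CRIRecord(t0=w0, t1=w1, quality=q, valid=False,
                         flags=("low_quality",))
    try:
        sub = rri.slice(w0 - 5.0, w1 + 5.0)
        if clean:
            sub, _ = clean_rr(sub)
        x1 = resample_tachogram(sub, w0, w1, fs)
        x2 = resample_signal(rsp, w0, w1, fs)
        model = fit_bivar_ar(x1, x2, p=order, p_max=p_max, fs=fs)
        spec = gc_spectrum(model, freqs)
    except (InvalidInputError, np.linalg.LinAlgError) as exc:
        return CRIRecord(t0=w0, t1=w1, quality=q, valid=False,
                         flags=(type(exc).__name__,))
    return extract_cri(spec, band=band, t0=w0, t1=w1, quality=q)
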