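"""Surrogate overnight recordings with state-dependent cardiorespiratory coupling.

The generator emulates the statistical structure the CRI method assumes:

* an 18-state (stage x CAP-phase) Markov chain on the 30-s epoch grid,
  loosely shaped like adult sleep architecture (long NA runs, short
  A-phases recurring on the CAP time scale, stage runs long enough to
  contain 10-min stable stretches);
* narrow-band, flat-topped respiration (~0.25 Hz with slow drift and
  breath-to-breath jitter);
* an instantaneous-RR series whose respiratory-band oscillation follows
  the delayed respiratory phase through a noisy neural pathway: the
  per-state gain sets the *phase fidelity* (and mildly the depth) of the
  modulation, so spectral Granger causality sees a coherent fraction of
  the respiratory line that grades smoothly with the gain; beats are
  placed by an integrate-and-fire (IPFM) rule plus a small R-peak timing
  jitter, so the intervals truly carry the modulating signal;
* chest-acceleration bursts whose per-epoch probability grades with the
  somatomotor impact of the state (wake and A3 highest);
* optionally a template ECG with an R wave at each beat.

Group profiles encode the qualitative contrasts the indices respond to:
insomnia couples strongly in non-A deep sleep and weakly during A phases
(large A/NA swing), narcolepsy couples weakly everywhere (high damping),
the non-pathological profile sits between, deepening with sleep depth.
The oscillation runs at near-constant amplitude with a bounded
flat-topped waveform, keeping the RR marginal distribution inside the
artifact gate's 1.5*Std margin, so the gate (plus beat-to-beat
continuity) fires on well under 1% of clean simulated beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import (NREM_STAGES, REM, STAGE_LABELS, WAKE, join_label,
                     macro_label, split_label)
from .types import AnnotationTrack, RRISeries, SignalSegment

EPOCH_S = 30.0
RATE_FS = 4.0        # grid for the instantaneous-RR signal (Hz)
RESP_FS = 10.0
ACC_FS = 10.0

#: baseline RR (ms) per macro stage: mild bradycardia with sleep depth.
#: The spread is kept small so stage-boundary windows (which mix two
#: baselines) stay inside the artifact gate's 1.5*Std margin.
RR_BASE = {"W": 868.0, "R": 874.0, "S1": 882.0, "S2": 890.0,
           "S3": 898.0, "S4": 905.0}

#: respiratory-modulation amplitude for unit gain (ms)
RSA_AMP_MS = 40.0

#: stationary SD of the state-independent AR(1) RR noise (ms).  Constant
#: across states so the causality signal-to-noise ratio -- hence CRA --
#: grades with the per-state coupling gain.
NOISE_SD_MS = 1.0

#: tanh squash factor of the respiratory waveform.  Real airflow and
#: volume traces are flatter-topped than a sinusoid; the squash bounds
#: the displayed channel's peak-to-RMS ratio while keeping its harmonic
#: leakage small enough for the spectral-concentration gate.
#: RSA_SHAPE is the (harder) squash of the waveform the heart actually
#: follows: vagal gating saturates, and the near-square shape survives
#: the per-beat averaging of the tachogram with its peak-to-RMS ratio
#: intact, which is what keeps the RR artifact gate (1.5 * Std) quiet.
WAVE_SHAPE = 2.0
RSA_SHAPE = 5.0

#: per-epoch movement-burst probability and burst amplitude by CAP
#: phase / stage.  CAP activations carry somatomotor bursts whose
#: *amplitude* grades with the subtype's impact (A1 subtle, A3 heavy),
#: which is what lets 30-s-resolution movement features mark A phases.
BURST_PROB = {"W": 0.70, "R": 0.06, "NA": 0.03,
              "A1": 0.05, "A2": 0.80, "A3": 0.95}
BURST_AMP = {"W": 0.25, "R": 0.10, "NA": 0.06,
             "A1": 0.06, "A2": 0.14, "A3": 0.25}

#: breathing-regularity multiplier on the breath-to-breath frequency
#: jitter: wake and REM breathing is erratic, deep sleep very regular.
#: Feeds the resonance bandwidth/quality (CRB, CRQ) a real stage cue.
JITTER_SCALE = {"W": 2.3, "R": 3.6, "S1": 1.7, "S2": 1.0,
                "S3": 0.50, "S4": 0.30}

#: stage-dependent shift of the respiratory rate (Hz): breathing slows
#: and deepens with sleep depth, quickens in wake/REM
FREQ_SHIFT = {"W": 0.030, "R": 0.012, "S1": 0.005, "S2": -0.005,
              "S3": -0.020, "S4": -0.030}

#: Mayer-wave (LF band) activity amplitude (ms RMS): sympathetic LF
#: oscillations are prominent in wake/REM and suppressed in slow-wave
#: sleep, giving the LF and LF/HF features their stage dependence
LF_AMP = {"W": 6.0, "R": 4.5, "S1": 3.5, "S2": 3.0, "S3": 2.2, "S4": 1.8}

#: transient heart-rate acceleration (ms of RR shortening) during CAP
#: activation phases, increasing with the subtype's autonomic impact
PHASE_HR_DIP = {"NA": 0.0, "A1": 0.0, "A2": 10.0, "A3": 14.0, "-": 0.0}


def _gain_table(w, r, na, a1, a2, a3):
    """Expand per-stage tuples into the 18-label gain dict."""
    g = {WAKE: w, REM: r}
    for k, stage in enumerate(NREM_STAGES):
        g[join_label(stage, "NA")] = na[k]
        g[join_label(stage, "A1")] = a1[k]
        g[join_label(stage, "A2")] = a2[k]
        g[join_label(stage, "A3")] = a3[k]
    return g


@dataclass
class GroupProfile:
    """Per-state respiratory-coupling gains and group-level parameters."""

    name: str
    gain: dict
    rr_base: dict = field(default_factory=lambda: dict(RR_BASE))
    resp_freq_mean: float = 0.25
    resp_freq_sd: float = 0.015
    rsa_amp_ms: float = RSA_AMP_MS
    burst_prob: dict = field(default_factory=lambda: dict(BURST_PROB))

    def __post_init__(self):
        missing = set(STAGE_LABELS) - set(self.gain)
        if missing:
            raise ValueError(f"profile {self.name}: gains missing for {missing}")
        if any(g < 0 for g in self.gain.values()):
            raise ValueError("gains must be non-negative")


HEALTHY = GroupProfile(
    "healthy",
    _gain_table(w=0.26, r=0.42,
                na=(0.60, 0.80, 1.05, 1.25),
                a1=(0.26, 0.28, 0.29, 0.30),
                a2=(0.31, 0.35, 0.38, 0.42),
                a3=(0.26, 0.28, 0.29, 0.30)))

INSOMNIA = GroupProfile(
    "insomnia",
    _gain_table(w=0.30, r=0.44,
                na=(0.80, 1.05, 1.90, 2.20),
                a1=(0.34, 0.36, 0.36, 0.38),
                a2=(0.30, 0.32, 0.30, 0.32),
                a3=(0.26, 0.28, 0.26, 0.27)))

NARCOLEPSY = GroupProfile(
    "narcolepsy",
    _gain_table(w=0.20, r=0.22,
                na=(0.24, 0.29, 0.36, 0.41),
                a1=(0.18, 0.20, 0.22, 0.24),
                a2=(0.19, 0.21, 0.21, 0.24),
                a3=(0.17, 0.18, 0.18, 0.20)))

PROFILES = {p.name: p for p in (HEALTHY, INSOMNIA, NARCOLEPSY)}


def default_transition_matrix() -> np.ndarray:
    """A plausible 18x18 epoch-level transition matrix.

    Macro-stage dynamics give long stage runs (so 10-min stable stretches
    exist); within an NREM stage the phase alternates between long NA
    runs and mostly single-epoch A phases, mirroring CAP cycling.
    """
    macro = {"W": WAKE, "R": REM}
    M = {s: {} for s in ["W", "R", "S1", "S2", "S3", "S4"]}
    M["W"].update({"W": 0.94, "S1": 0.05, "R": 0.01})
    M["S1"].update({"S1": 0.86, "S2": 0.08, "W": 0.03, "R": 0.03})
    M["S2"].update({"S2": 0.92, "S3": 0.04, "S1": 0.01, "R": 0.02, "W": 0.01})
    M["S3"].update({"S3": 0.93, "S4": 0.04, "S2": 0.03})
    M["S4"].update({"S4": 0.94, "S3": 0.06})
    M["R"].update({"R": 0.92, "S1": 0.04, "W": 0.04})
    # CAP phase dynamics within a stage (rows NA, A1, A2, A3)
    phase = {
        "S1": {"NA": {"NA": 0.80, "A1": 0.04, "A2": 0.09, "A3": 0.07},
               "A1": {"NA": 0.85, "A1": 0.10, "A2": 0.03, "A3": 0.02},
               "A2": {"NA": 0.85, "A2": 0.10, "A1": 0.03, "A3": 0.02},
               "A3": {"NA": 0.85, "A3": 0.10, "A1": 0.02, "A2": 0.03}},
        "S2": {"NA": {"NA": 0.80, "A1": 0.05, "A2": 0.10, "A3": 0.05},
               "A1": {"NA": 0.85, "A1": 0.10, "A2": 0.03, "A3": 0.02},
               "A2": {"NA": 0.85, "A2": 0.10, "A1": 0.03, "A3": 0.02},
               "A3": {"NA": 0.85, "A3": 0.10, "A1": 0.02, "A2": 0.03}},
        "S3": {"NA": {"NA": 0.92, "A1": 0.03, "A2": 0.03, "A3": 0.02},
               "A1": {"NA": 0.84, "A1": 0.12, "A2": 0.03, "A3": 0.01},
               "A2": {"NA": 0.85, "A2": 0.10, "A1": 0.04, "A3": 0.01},
               "A3": {"NA": 0.86, "A3": 0.08, "A1": 0.03, "A2": 0.03}},
        "S4": {"NA": {"NA": 0.92, "A1": 0.03, "A2": 0.03, "A3": 0.02},
               "A1": {"NA": 0.84, "A1": 0.12, "A2": 0.03, "A3": 0.01},
               "A2": {"NA": 0.85, "A2": 0.10, "A1": 0.04, "A3": 0.01},
               "A3": {"NA": 0.86, "A3": 0.08, "A1": 0.03, "A2": 0.03}},
    }
    A = np.zeros((len(STAGE_LABELS), len(STAGE_LABELS)))
    index = {lab: i for i, lab in enumerate(STAGE_LABELS)}

    def targets(stage_to, phase_from_label):
        """Distribute a macro move over the destination's sub-states."""
        if stage_to in ("W", "R"):
            return {macro[stage_to]: 1.0}
        return {join_label(stage_to, "NA"): 1.0}

    for lab in STAGE_LABELS:
        stage, ph = split_label(lab)
        i = index[lab]
        for stage_to, pm in M[stage].items():
            if stage_to == stage and stage in NREM_STAGES:
                for ph_to, pp in phase[stage][ph].items():
                    A[i, index[join_label(stage, ph_to)]] += pm * pp
            else:
                for lab_to, w in targets(stage_to, lab).items():
                    A[i, index[lab_to]] += pm * w
    A /= A.sum(axis=1, keepdims=True)
    return A


@dataclass
class SimConfig:
    """Reproducible simulation settings; the seed is mandatory."""

    duration_s: float = 4 * 3600.0
    seed: int = 0
    transitions: np.ndarray = None  # type: ignore[assignment]
    resp_fs: float = RESP_FS
    acc_fs: float = ACC_FS
    rate_fs: float = RATE_FS
    resp_noise_sd: float = 0.01
    acc_noise_sd: float = 0.01
    rsa_delay_s: float = 0.5
    lf_amp_ms: float = 1.0       # scale on the per-stage Mayer-band
                                 # activity (0 disables it)
    lf_band: tuple = (0.04, 0.18)  # Hz, band of the Mayer activity
    trend_sd_ms: float = 0.0     # slow baseline wander (off by default:
    trend_cutoff: float = 0.008  # a local ramp erodes the gate margin)
    rr_noise_sd_ms: float = NOISE_SD_MS
    beat_jitter_ms: float = 0.6      # R-peak timing error SD
    phase_diffusion: float = 0.0    # respiratory phase diffusion (rad/sqrt(s))
    resp_jitter_sd: float = 0.02     # smooth breath-to-breath jitter (Hz)
    resp_jitter_cutoff: float = 0.08  # Hz
    phase_coupling_scale: float = 0.30  # sigma_theta = scale / gain (rad)
    phase_noise_cutoff: float = 0.04    # Hz, bandwidth of the phase noise
    make_ecg: bool = False
    ecg_fs: float = 128.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.transitions is None:
            self.transitions = default_transition_matrix()
        self.transitions = np.asarray(self.transitions, dtype=float)
        n = len(STAGE_LABELS)
        if self.transitions.shape != (n, n):
            raise ValueError(f"transition matrix must be {n}x{n}")
        if np.any(self.transitions < 0) or not np.allclose(
                self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix must be row-stochastic")


def simulate_stage_sequence(config: SimConfig,
                            rng: np.random.Generator | None = None,
                            start_label: str = WAKE) -> list[str]:
    """A Markov realisation of the 18-state chain on the epoch grid."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_epochs = int(config.duration_s // EPOCH_S)
    idx = {lab: i for i, lab in enumerate(STAGE_LABELS)}
    seq = [start_label]
    cur = idx[start_label]
    for _ in range(n_epochs - 1):
        cur = int(rng.choice(len(STAGE_LABELS), p=config.transitions[cur]))
        seq.append(STAGE_LABELS[cur])
    return seq


def _epoch_signal(values_per_epoch: np.ndarray, fs: float, n: int) -> np.ndarray:
    """Zero-order-hold expansion of per-epoch values onto a sample grid."""
    samples_per_epoch = int(EPOCH_S * fs)
    x = np.repeat(values_per_epoch, samples_per_epoch)
    if x.size < n:
        x = np.concatenate([x, np.full(n - x.size, values_per_epoch[-1])])
    return x[:n]


def simulate_cardioresp(labels, profile: GroupProfile, config: SimConfig,
                        rng: np.random.Generator | None = None,
                        gain_scale: float = 1.0, rr_offset: float = 0.0,
                        resp_freq: float | None = None):
    """Respiration, RR series and 3-axis acceleration for a label sequence.

    Returns
    -------
    dict with keys ``rri`` (RRISeries), ``rsp`` (SignalSegment),
    ``accel`` (3-tuple of SignalSegment), ``beat_times`` (ground truth),
    and optionally ``ecg``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = [str(l) for l in labels]
    n_epochs = len(labels)
    duration = n_epochs * EPOCH_S

    # ---- respiration: phase-diffusing narrow-band oscillation ----
    # Constant amplitude keeps the RR marginal inside the artifact gate's
    # 1.5*Std margin (a flat-topped oscillation peaks near 1.2*Std);
    # Brownian phase gives each sample genuine innovation, which is what
    # the causality measure keys on: the RR series' own past can only
    # extrapolate the respiratory phase, while respiration's past at the
    # RSA delay resolves it exactly.
    n_resp = int(duration * config.resp_fs)
    t_resp = np.arange(n_resp) / config.resp_fs
    f0 = resp_freq if resp_freq is not None else profile.resp_freq_mean
    jitter_scale_t = _epoch_signal(
        np.array([JITTER_SCALE[macro_label(l)] for l in labels]),
        config.resp_fs, n_resp)
    freq_shift_t = _epoch_signal(
        np.array([FREQ_SHIFT[macro_label(l)] for l in labels]),
        config.resp_fs, n_resp)
    drift = (_smooth_noise(rng, n_resp, config.resp_fs, cutoff=0.005, sd=0.012)
             + jitter_scale_t
             * _smooth_noise(rng, n_resp, config.resp_fs,
                             cutoff=config.resp_jitter_cutoff,
                             sd=config.resp_jitter_sd))
    freq = np.clip(f0 + freq_shift_t + drift, 0.13, 0.42)
    dt = 1.0 / config.resp_fs
    brownian = np.cumsum(rng.normal(0.0, config.phase_diffusion * np.sqrt(dt),
                                    n_resp))
    phase = 2 * np.pi * np.cumsum(freq) * dt + brownian
    amp = 1.0 + _smooth_noise(rng, n_resp, config.resp_fs, cutoff=0.02, sd=0.02)
    wave = amp * np.tanh(WAVE_SHAPE * np.sin(phase)) / np.tanh(WAVE_SHAPE)
    rsp = wave + config.resp_noise_sd * rng.standard_normal(n_resp)

    # ---- instantaneous RR on the rate grid ----
    # Coupling is encoded as *phase fidelity*: the heart-rate oscillation
    # in the respiratory band runs at near-constant amplitude (a single
    # flat-topped component, which is what keeps the RR artifact gate
    # quiet), but its phase follows the delayed respiratory phase through
    # a noisy pathway whose phase-noise SD shrinks as the per-state gain
    # grows.  The causality measure then sees a coherent fraction
    # ~exp(-sigma_theta^2) of the respiratory-band line -- a wide,
    # smoothly graded dynamic range.  The modulation depth itself also
    # grows mildly with gain (so HRV band powers retain a state cue).
    n_rate = int(duration * config.rate_fs)
    t_rate = np.arange(n_rate) / config.rate_fs
    gains = np.array([profile.gain[l] * gain_scale for l in labels])
    # modulation depth follows the *stage* (its NA gain): a CAP
    # activation perturbs the coherence of the vagal drive, not the
    # tidal volume, so phases change the phase fidelity but not the
    # respiratory modulation depth
    stage_gains = np.array([
        profile.gain[l if split_label(l)[1] == "-"
                     else join_label(split_label(l)[0], "NA")] * gain_scale
        for l in labels])
    bases = np.array([profile.rr_base[macro_label(l)] + rr_offset
                      - PHASE_HR_DIP[split_label(l)[1]] for l in labels])
    gain_t = _epoch_signal(gains, config.rate_fs, n_rate)
    base_t = _epoch_signal(bases, config.rate_fs, n_rate)
    # heart-rate baseline moves smoothly (~20 s) across stage boundaries
    from scipy import signal as sps
    b_lp, a_lp = sps.butter(1, 0.03 / (config.rate_fs / 2), btype="low")
    base_t = sps.filtfilt(b_lp, a_lp, base_t)
    sigma_theta_t = np.clip(
        config.phase_coupling_scale / np.maximum(gain_t, 1e-3) ** 1.7,
        0.05, 2.5)
    theta_unit = _smooth_noise(rng, n_rate, config.rate_fs,
                               cutoff=config.phase_noise_cutoff, sd=1.0)
    phase_on_rate = np.interp(t_rate - config.rsa_delay_s, t_resp, phase)
    amp_on_rate = np.interp(t_rate - config.rsa_delay_s, t_resp, amp)
    rsa_wave = amp_on_rate * (
        np.tanh(RSA_SHAPE * np.sin(phase_on_rate
                                   + sigma_theta_t * theta_unit))
        / np.tanh(RSA_SHAPE))
    stage_gain_t = _epoch_signal(stage_gains, config.rate_fs, n_rate)
    depth_t = profile.rsa_amp_ms * (
        0.50 + 0.50 * np.minimum(stage_gain_t / 1.5, 1.0))
    trend = _smooth_noise(rng, n_rate, config.rate_fs,
                          cutoff=config.trend_cutoff, sd=config.trend_sd_ms)
    lf_amp_t = (config.lf_amp_ms if config.lf_amp_ms > 0 else 1.0) \
        * _epoch_signal(np.array([LF_AMP[macro_label(l)] for l in labels]),
                        config.rate_fs, n_rate)
    mayer = _lowband_bounded_noise(rng, n_rate, config.rate_fs,
                                   config.lf_band)
    ar = _ar1_noise(rng, n_rate, phi=0.4)
    rr_inst = (base_t + trend + lf_amp_t * mayer
               + depth_t * rsa_wave + config.rr_noise_sd_ms * ar)
    rr_inst = np.clip(rr_inst, 320.0, 1900.0)

    # ---- IPFM beat placement ----
    beat_times = _ipfm(rr_inst, config.rate_fs)
    if config.beat_jitter_ms > 0:
        # R-peak timing error: the one source of high-frequency interval
        # noise that survives resampling, giving the causality measure an
        # amplitude-independent innovation floor (as real detectors do)
        beat_times = beat_times + rng.normal(
            0.0, config.beat_jitter_ms / 1000.0, beat_times.size)
        beat_times = np.sort(beat_times)
    rri = RRISeries(beat_times)

    # ---- acceleration with state-graded movement bursts ----
    accel = _accel_channels(labels, profile, config, rng)

    out = {
        "rri": rri,
        "rsp": SignalSegment(rsp, config.resp_fs, 0.0, "resp"),
        "accel": accel,
        "beat_times": beat_times,
    }
    if config.make_ecg:
        out["ecg"] = synth_ecg(beat_times, config.ecg_fs, duration, rng)
    return out


def _lowband_bounded_noise(rng, n, fs, band):
    """Unit-amplitude band-limited noise, tanh-bounded to about +/-1.3 rms."""
    from scipy import signal as sps
    w = rng.standard_normal(n)
    lo = min(band[0] / (fs / 2), 0.98)
    hi = min(band[1] / (fs / 2), 0.99)
    b, a = sps.butter(2, [lo, hi], btype="bandpass")
    x = sps.lfilter(b, a, w)
    s = np.std(x)
    if s > 0:
        x = np.tanh(1.2 * x / s) / np.tanh(1.2)
        x /= max(np.std(x), 1e-12)
    return x


def _smooth_noise(rng, n, fs, cutoff, sd):
    """Low-pass filtered Gaussian noise with stationary SD ``sd``."""
    from scipy import signal as sps
    w = rng.standard_normal(n)
    b, a = sps.butter(2, min(cutoff / (fs / 2), 0.99), btype="low")
    x = sps.lfilter(b, a, w)
    s = np.std(x)
    return x * (sd / s) if s > 0 else x


def _ar1_noise(rng, n, phi=0.9):
    """Unit-variance AR(1) noise."""
    e = rng.standard_normal(n) * np.sqrt(1 - phi ** 2)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


def _ipfm(rr_inst_ms: np.ndarray, fs: float) -> np.ndarray:
    """Integrate-and-fire beat placement from an instantaneous-RR signal."""
    rate = 1000.0 / rr_inst_ms          # beats per second
    dt = 1.0 / fs
    integral = np.concatenate([[0.0], np.cumsum(rate) * dt])
    t_grid = np.arange(integral.size) * dt
    n_beats = int(np.floor(integral[-1]))
    thresholds = np.arange(n_beats + 1, dtype=float)
    return np.interp(thresholds, integral, t_grid)


def _accel_channels(labels, profile, config, rng):
    n_epochs = len(labels)
    n = int(n_epochs * EPOCH_S * config.acc_fs)
    channels = [config.acc_noise_sd * rng.standard_normal(n) for _ in range(3)]
    spe = int(EPOCH_S * config.acc_fs)
    for e, lab in enumerate(labels):
        _, ph = split_label(lab)
        key = ph if ph != "-" else lab
        if rng.random() < profile.burst_prob[key]:
            dur = int(rng.uniform(3.0, 12.0) * config.acc_fs)
            start = e * spe + int(rng.uniform(0, max(spe - dur, 1)))
            burst = BURST_AMP[key] * rng.standard_normal(dur)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            for c, d in zip(channels, direction):
                c[start:start + dur] += d * burst
    names = ("acc_x", "acc_y", "acc_z")
    return tuple(SignalSegment(c, config.acc_fs, 0.0, nm)
                 for c, nm in zip(channels, names))


def synth_ecg(beat_times, fs, duration, rng=None,
              noise_sd: float = 0.02) -> SignalSegment:
    """Template ECG: a narrow R wave (plus small T wave) at each beat."""
    n = int(duration * fs)
    x = np.zeros(n)
    t = np.arange(n) / fs
    for bt in beat_times:
        x += 1.0 * np.exp(-0.5 * ((t - bt) / 0.012) ** 2)
        x += 0.15 * np.exp(-0.5 * ((t - bt - 0.25) / 0.05) ** 2)
    if rng is not None:
        x += noise_sd * rng.standard_normal(n)
    return SignalSegment(x, fs, 0.0, "ecg")


@dataclass
class SubjectRecord:
    """One simulated subject: signals, annotations and ground truth."""

    subject_id: str
    group: str
    annotations: AnnotationTrack
    rri: RRISeries
    rsp: SignalSegment
    accel: tuple
    beat_times: np.ndarray


def simulate_subject(profile: GroupProfile, config: SimConfig,
                     rng: np.random.Generator,
                     subject_id: str = "s0") -> SubjectRecord:
    """One subject with per-subject random effects (seeded)."""
    gain_scale = float(np.exp(rng.normal(0.0, 0.08)))
    rr_offset = float(rng.normal(0.0, 20.0))
    resp_freq = float(np.clip(rng.normal(profile.resp_freq_mean,
                                         profile.resp_freq_sd), 0.15, 0.38))
    labels = simulate_stage_sequence(config, rng)
    sim = simulate_cardioresp(labels, profile, config, rng,
                              gain_scale=gain_scale, rr_offset=rr_offset,
                              resp_freq=resp_freq)
    return SubjectRecord(subject_id, profile.name,
                         AnnotationTrack(labels), sim["rri"], sim["rsp"],
                         sim["accel"], sim["beat_times"])


def simulate_cohort(n_per_group: int, config: SimConfig,
                    profiles=None) -> list[SubjectRecord]:
    """``n_per_group`` subjects for each group profile, seeded."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if profiles is None:
        profiles = (HEALTHY, INSOMNIA, NARCOLEPSY)
    seeds = np.random.SeedSequence(config.seed).spawn(
        len(profiles) * n_per_group)
    records = []
    k = 0
    for profile in profiles:
        for i in range(n_per_group):
            rng = np.random.default_rng(seeds[k])
            records.append(simulate_subject(
                profile, config, rng, subject_id=f"{profile.name}-{i:02d}"))
            k += 1
    return records
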