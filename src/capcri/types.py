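"""Core containers: signal segments, tachograms, annotations, CRI records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import STAGE_LABELS, validate_labels


@dataclass
class SignalSegment:
    """A uniformly sampled channel segment.

    Parameters
    ----------
    samples : ndarray
        Finite sample values.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Start time in seconds.
    label : str
        Channel name (e.g. ``"resp"``, ``"ecg"``, ``"acc_x"``).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def slice(self, t_start: float, t_stop: float) -> "SignalSegment":
        """Return the sub-segment covering ``[t_start, t_stop)``."""
        i0 = int(np.ceil((t_start - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((t_stop - self.t0) * self.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.samples.size)
        return SignalSegment(self.samples[i0:i1], self.fs,
                             self.t0 + i0 / self.fs, self.label)


@dataclass
class RRISeries:
    """A cardiac tachogram: beat times (s) and RR intervals (ms).

    ``intervals[i]`` is the interval between ``beat_times[i]`` and
    ``beat_times[i+1]``; there is one fewer interval than beats.
    """

    beat_times: np.ndarray
    intervals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.ndim != 1 or self.beat_times.size < 2:
            raise ValueError("need at least two beat times")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        derived = np.diff(self.beat_times) * 1000.0
        if self.intervals is None:
            self.intervals = derived
        else:
            self.intervals = np.asarray(self.intervals, dtype=float)
            if self.intervals.shape != derived.shape:
                raise ValueError("intervals inconsistent with beat_times")
            if not np.allclose(self.intervals, derived, atol=1e-6):
                raise ValueError("intervals inconsistent with beat_times")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")

    @classmethod
    def from_intervals(cls, intervals_ms, t0: float = 0.0) -> "RRISeries":
        """Build a series from intervals alone, beats placed from ``t0``."""
        iv = np.asarray(intervals_ms, dtype=float)
        beats = t0 + np.concatenate([[0.0], np.cumsum(iv) / 1000.0])
        # keep the provided intervals exactly (cumsum-diff roundoff would
        # otherwise leak into interval statistics)
        return cls(beats, iv)

    @property
    def interval_times(self) -> np.ndarray:
        """Time stamp of each interval (the time of its closing beat)."""
        return self.beat_times[1:]

    def slice(self, t_start: float, t_stop: float) -> "RRISeries":
        """Sub-series of beats within ``[t_start, t_stop]``."""
        m = (self.beat_times >= t_start) & (self.beat_times <= t_stop)
        return RRISeries(self.beat_times[m])


@dataclass
class AnnotationTrack:
    """Per-epoch stage/CAP labels on a fixed 30-s grid."""

    labels: list
    epoch_length: float = 30.0
    t0: float = 0.0

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        validate_labels(self.labels)
        if not self.epoch_length > 0:
            raise ValueError("epoch_length must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def epoch_starts(self) -> np.ndarray:
        return self.t0 + self.epoch_length * np.arange(len(self.labels))


@dataclass
class CRIRecord:
    """Cardiopulmonary resonance indices for one analysis window.

    F_A is the resonance frequency (Hz, the argmax of the causality curve
    in the respiratory band), CRA its peak amplitude, CRB the full width
    at half maximum (Hz), CRQ = F_A / CRB the quality factor and
    CRR = CRB / (2*pi*F_A^2) the resonance resistance under the
    unit-capacitance convention, so CRQ * CRR * 2*pi*F_A = 1.
    """

    t0: float
    t1: float
    f_a: float = np.nan
    cra: float = np.nan
    crb: float = np.nan
    crq: float = np.nan
    crr: float = np.nan
    quality: float = np.nan
    valid: bool = False
    flags: tuple = ()

    @property
    def center(self) -> float:
        return 0.5 * (self.t0 + self.t1)


# re-export the label set for convenience
__all__ = [
    "SignalSegment",
    "RRISeries",
    "AnnotationTrack",
    "CRIRecord",
    "STAGE_LABELS",
]
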