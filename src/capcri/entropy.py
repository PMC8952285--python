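"""Approximate and sample entropy for short physiological series.

Both use Chebyshev distances between delay vectors of length m with
tolerance r; defaults m=2, r=0.2*SD follow common HRV practice.  A flat
series has no dispersion to measure and both entropies are defined as 0.
"""

from __future__ import annotations

import numpy as np


def _count_matches(x: np.ndarray, m: int, r: float) -> np.ndarray:
    """For each template of length m, the number of templates within r
    (Chebyshev), self-matches included."""
    n = x.size - m + 1
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
    return (d <= r).sum(axis=1)


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r): regularity statistic with self-matches included."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        return np.nan
    sd = np.std(x)
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd
    def phi(mm):
        c = _count_matches(x, mm, r) / (x.size - mm + 1)
        return np.mean(np.log(c))
    return float(phi(m) - phi(m + 1))


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -ln(A/B), self-matches excluded.

    Returns NaN when no template pair matches at length m (undefined).
    """
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        return np.nan
    sd = np.std(x)
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd
    b = int(np.sum(_count_matches(x[:-1], m, r) - 1))
    a = int(np.sum(_count_matches(x, m + 1, r) - 1))
    if b == 0:
        return np.nan
    if a == 0:
        # no matches at m+1: maximal irregularity at this length; cap at
        # the largest resolvable value instead of +inf
        return float(np.log(b) + np.log(2.0))
    return float(-np.log(a / b))
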