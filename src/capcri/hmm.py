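"""Hidden-Markov modelling of CRA over the 18 sleep/CAP states.

The state sequence is the expert 18-class label sequence and the
observation is the per-epoch CRA, so training is supervised: the
transition matrix is the bigram estimate

    a_ij = count(s_t = i, s_{t+1} = j) / count(s_t = i with successor)

and emissions are per-state Gaussians over CRA.  At inference the state
sequence is Viterbi-decoded from CRA alone, and each epoch contributes
two stability features read from the transition matrix at the decoded
state: the diagonal element a_ss (persistence) and the column sum
sum_i a_is (attractiveness of the state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import LABEL_INDEX, STAGE_LABELS

N_STATES = len(STAGE_LABELS)


@dataclass
class TransitionMatrix:
    """A row-stochastic 18x18 matrix in the canonical state order."""

    a: np.ndarray
    unvisited: tuple = ()

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (N_STATES, N_STATES):
            raise ValueError(f"matrix must be {N_STATES}x{N_STATES}")
        if np.any(self.a < 0) or np.any(self.a > 1):
            raise ValueError("entries must lie in [0, 1]")
        if not np.allclose(self.a.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")

    def diagonal(self) -> np.ndarray:
        return np.diag(self.a)

    def column_sums(self) -> np.ndarray:
        return self.a.sum(axis=0)


@dataclass
class CRAStateModel:
    """Supervised HMM over CRA: transitions + Gaussian emissions."""

    transitions: TransitionMatrix
    means: np.ndarray                 # (18,)
    variances: np.ndarray             # (18,)
    start_prob: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.start_prob is None:
            self.start_prob = np.full(N_STATES, 1.0 / N_STATES)


def train_hmm(cra_sequence, label_sequence,
              min_var: float = 1e-8) -> CRAStateModel:
    """Estimate transitions and CRA emissions from a labelled recording.

    Rows of states never seen (or seen only as the final epoch) are set
    to the uniform distribution and reported in
    ``model.transitions.unvisited``.  Missing CRA values (NaN) are
    ignored for the emission estimates.
    """
    labels = [str(l) for l in label_sequence]
    cra = np.asarray(cra_sequence, dtype=float)
    if len(labels) != cra.size:
        raise ValueError("label and CRA sequences must be equally long")
    if len(labels) < 2:
        raise ValueError("need at least two epochs to estimate transitions")
    idx = np.array([LABEL_INDEX[l] for l in labels])
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (idx[:-1], idx[1:]), 1.0)
    row_tot = counts.sum(axis=1)
    a = np.empty_like(counts)
    unvisited = []
    for i in range(N_STATES):
        if row_tot[i] > 0:
            a[i] = counts[i] / row_tot[i]
        else:
            a[i] = 1.0 / N_STATES
            unvisited.append(STAGE_LABELS[i])
    finite = np.isfinite(cra)
    g_mean = float(np.mean(cra[finite])) if finite.any() else 0.0
    g_var = float(np.var(cra[finite])) if finite.any() else 1.0
    g_var = max(g_var, min_var)
    means = np.full(N_STATES, g_mean)
    variances = np.full(N_STATES, g_var)
    for i in range(N_STATES):
        m = (idx == i) & finite
        if m.sum() >= 1:
            means[i] = float(np.mean(cra[m]))
        if m.sum() >= 2:
            variances[i] = max(float(np.var(cra[m])), min_var)
    start = np.bincount(idx, minlength=N_STATES).astype(float)
    start /= start.sum()
    return CRAStateModel(TransitionMatrix(a, tuple(unvisited)),
                         means, variances, start)


def _emission_loglik(model: CRAStateModel, cra: np.ndarray) -> np.ndarray:
    """(T, 18) log-likelihood table; missing observations are uninformative."""
    T = cra.size
    ll = np.zeros((T, N_STATES))
    finite = np.isfinite(cra)
    v = model.variances
    ll[finite] = (-0.5 * np.log(2 * np.pi * v)
                  - 0.5 * (cra[finite, None] - model.means) ** 2 / v)
    return ll


def viterbi_decode(model: CRAStateModel, cra_sequence) -> np.ndarray:
    """Most probable state-index path given the CRA observations."""
    cra = np.asarray(cra_sequence, dtype=float)
    if cra.size == 0:
        raise ValueError("empty observation sequence")
    if not np.any(np.isfinite(cra)):
        raise ValueError("all observations missing; path undecodable")
    ll = _emission_loglik(model, cra)
    with np.errstate(divide="ignore"):
        log_a = np.log(model.transitions.a)
        log_start = np.log(model.start_prob)
    T = cra.size
    delta = log_start + ll[0]
    back = np.zeros((T, N_STATES), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_a
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(N_STATES)] + ll[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_log_prob(model: CRAStateModel, cra_sequence, path) -> float:
    """Joint log probability of a given state path and the observations."""
    cra = np.asarray(cra_sequence, dtype=float)
    path = np.asarray(path, dtype=int)
    ll = _emission_loglik(model, cra)
    with np.errstate(divide="ignore"):
        log_a = np.log(model.transitions.a)
        log_start = np.log(model.start_prob)
    lp = log_start[path[0]] + ll[0, path[0]]
    for t in range(1, path.size):
        lp += log_a[path[t - 1], path[t]] + ll[t, path[t]]
    return float(lp)


def stability_features(model: CRAStateModel, cra_sequence) -> np.ndarray:
    """(T, 2) array of HMM stability features per epoch.

    Column 0 is the diagonal entry a_ss of the decoded state s, column 1
    the column sum sum_i a_is.  All-missing CRA yields NaN features.
    """
    cra = np.asarray(cra_sequence, dtype=float)
    try:
        path = viterbi_decode(model, cra)
    except ValueError:
        return np.full((cra.size, 2), np.nan)
    diag = model.transitions.diagonal()
    colsum = model.transitions.column_sums()
    return np.column_stack([diag[path], colsum[path]])
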