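"""Three-state sweep-scan HMM along a chromosome.

Hidden states (Neutral, Intermediate, Selection) form a linear Markov chain:
per site, Neutral and Selection switch to Intermediate with probability ``q``
and Intermediate moves either way with probability ``q`` each; direct
Neutral <-> Selection jumps are disallowed, so decoded sweeps are flanked by
Intermediate stretches.  The emission at a site is the read likelihood vector
averaged under the state's spectrum.  Positions missing from the input
(uncovered or filtered) are bridged by raising the transition matrix to the
gap length, keeping ``q`` a strictly per-site quantity.

Decoding is by Viterbi (most probable state path, reported in ``.pred`` and
summarized as sweep windows in ``.stat``) and by the forward-backward
algorithm (per-site posterior of Selection, ``.post``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .likelihood import LikelihoodVector
from .spectrum import Spectrum

__all__ = [
    "STATE_NAMES",
    "HmmModel",
    "DecodedPath",
    "SweepWindow",
    "build_hmm",
    "state_emission",
    "emission_matrix",
    "viterbi",
    "forward_backward",
    "decode",
    "call_sweep_windows",
]

STATE_NAMES = ("N", "I", "S")
MAX_GAP_POWER = 10**6  # beyond this T**d is numerically stationary


@dataclass
class HmmModel:
    spectra: tuple[Spectrum, Spectrum, Spectrum]  # (Neutral, Intermediate, Selection)
    q: float
    transition: np.ndarray
    initial: np.ndarray


@dataclass
class DecodedPath:
    chrom: str
    positions: np.ndarray
    states: np.ndarray  # Viterbi path, indices into STATE_NAMES
    log_posterior_selection: np.ndarray
    loglik: float


@dataclass
class SweepWindow:
    chrom: str
    start: int
    end: int
    peak_log_posterior: float


def build_hmm(spectra: tuple[Spectrum, Spectrum, Spectrum], q: float) -> HmmModel:
    """Assemble the chain; initial distribution is its stationary one.

    The transition matrix is symmetric and doubly stochastic, so the
    stationary distribution is uniform over the three states.
    """
    if not 0.0 < q < 0.5:
        raise ValueError(f"per-site switch probability q must lie in (0, 1/2), got {q}")
    if len(spectra) != 3:
        raise ValueError("need exactly three state spectra (Neutral, Intermediate, Selection)")
    transition = np.array(
        [
            [1.0 - q, q, 0.0],
            [q, 1.0 - 2.0 * q, q],
            [0.0, q, 1.0 - q],
        ]
    )
    initial = np.full(3, 1.0 / 3.0)
    return HmmModel(tuple(spectra), q, transition, initial)


def state_emission(lik: LikelihoodVector, spectrum: Spectrum) -> float:
    """log P(reads | state) = log sum_j spectrum[j] * P(reads | j)."""
    if lik.log_lik.size != spectrum.n_classes:
        raise ValueError("likelihood vector and spectrum disagree on class count")
    with np.errstate(divide="ignore"):
        return float(logsumexp(lik.log_lik + np.log(spectrum.probs)))


def emission_matrix(
    liks: Sequence[LikelihoodVector], model: HmmModel
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-site emissions for all three states; returns (positions, L x 3)."""
    positions = np.array([lv.pos for lv in liks])
    log_liks = np.vstack([lv.log_lik for lv in liks])
    with np.errstate(divide="ignore"):
        log_specs = np.log(np.vstack([s.probs for s in model.spectra]))  # 3 x K
    emissions = logsumexp(log_liks[:, None, :] + log_specs[None, :, :], axis=2)
    return positions, emissions


class _GapCache:
    """log(T**d) per distinct gap length d (capped at MAX_GAP_POWER)."""

    def __init__(self, transition: np.ndarray):
        self.transition = transition
        self._cache: dict[int, np.ndarray] = {}

    def log_power(self, d: int) -> np.ndarray:
        d = min(int(d), MAX_GAP_POWER)
        if d not in self._cache:
            with np.errstate(divide="ignore"):
                self._cache[d] = np.log(np.linalg.matrix_power(self.transition, d))
        return self._cache[d]


def _check_positions(positions: np.ndarray) -> None:
    if positions.size > 1 and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing within a chromosome")


def viterbi(model: HmmModel, positions: np.ndarray, emissions: np.ndarray) -> np.ndarray:
    """Most probable state path in log space; ties break toward earlier states."""
    positions = np.asarray(positions)
    _check_positions(positions)
    L = positions.size
    if L == 0:
        return np.zeros(0, dtype=int)
    gaps = _GapCache(model.transition)
    with np.errstate(divide="ignore"):
        log_init = np.log(model.initial)
    delta = log_init + emissions[0]
    backptr = np.zeros((L, 3), dtype=int)
    for t in range(1, L):
        log_t = gaps.log_power(positions[t] - positions[t - 1])
        scores = delta[:, None] + log_t
        backptr[t] = np.argmax(scores, axis=0)  # first max -> earlier state
        delta = scores[backptr[t], np.arange(3)] + emissions[t]
    path = np.zeros(L, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(L - 1, 0, -1):
        path[t - 1] = backptr[t, path[t]]
    return path


def forward_backward(
    model: HmmModel, positions: np.ndarray, emissions: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Per-site log posteriors (L x 3) plus the total log-likelihood.

    Returns ``(log_posteriors, loglik_forward, loglik_backward)``; the two
    totals agree to numerical precision and the per-site posteriors normalize.
    """
    positions = np.asarray(positions)
    _check_positions(positions)
    L = positions.size
    if L == 0:
        return np.zeros((0, 3)), 0.0, 0.0
    gaps = _GapCache(model.transition)
    with np.errstate(divide="ignore"):
        log_init = np.log(model.initial)
    alpha = np.zeros((L, 3))
    beta = np.zeros((L, 3))
    alpha[0] = log_init + emissions[0]
    for t in range(1, L):
        log_t = gaps.log_power(positions[t] - positions[t - 1])
        alpha[t] = logsumexp(alpha[t - 1][:, None] + log_t, axis=0) + emissions[t]
    for t in range(L - 2, -1, -1):
        log_t = gaps.log_power(positions[t + 1] - positions[t])
        beta[t] = logsumexp(log_t + (emissions[t + 1] + beta[t + 1])[None, :], axis=1)
    loglik_fwd = float(logsumexp(alpha[-1]))
    loglik_bwd = float(logsumexp(log_init + emissions[0] + beta[0]))
    log_post = alpha + beta - loglik_fwd
    # renormalize away residual rounding so each site sums exactly to one
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    return log_post, loglik_fwd, loglik_bwd


def decode(
    model: HmmModel, liks: Sequence[LikelihoodVector], chrom: str | None = None
) -> DecodedPath:
    """Viterbi + forward-backward over one chromosome's likelihood vectors."""
    if chrom is None:
        chrom = liks[0].chrom if liks else ""
    positions, emissions = emission_matrix(liks, model)
    states = viterbi(model, positions, emissions)
    log_post, loglik, _ = forward_backward(model, positions, emissions)
    return DecodedPath(chrom, positions, states, log_post[:, 2], loglik)


def call_sweep_windows(decoded: DecodedPath) -> list[SweepWindow]:
    """Maximal runs of Viterbi state 'Selection' with their peak log posterior."""
    windows: list[SweepWindow] = []
    sel = decoded.states == 2
    i = 0
    L = sel.size
    while i < L:
        if not sel[i]:
            i += 1
            continue
        j = i
        while j + 1 < L and sel[j + 1]:
            j += 1
        peak = float(np.max(decoded.log_posterior_selection[i : j + 1]))
        windows.append(
            SweepWindow(
                decoded.chrom,
                int(decoded.positions[i]),
                int(decoded.positions[j]),
                peak,
            )
        )
        i = j + 1
    return windows
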