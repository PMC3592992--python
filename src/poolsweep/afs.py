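"""Allele frequency spectrum estimation by EM, and per-site MAP frequencies.

The region-wide AFS is treated as a mixture over latent per-site allele counts
``j``: each site's likelihood vector ``P(reads | j)`` comes from
:mod:`poolsweep.likelihood` and the mixture weights are the spectrum being
estimated.  EM starts from the standard-neutral expectation with scaled
mutation rate ``theta = 4*N*mu`` (default 0.005) and iterates E (per-site
responsibilities over counts) and M (average the responsibilities) until the
total log-likelihood stabilizes.  Monomorphic sites are included: class-0 mass
calibrates the density of segregating sites, which the sweep model relies on.

Per-site frequencies use the estimated (or user-supplied) spectrum as a prior:
posterior[j] is proportional to prior[j] * P(reads | j) and the reported count
is the posterior mode, so low-coverage sites shrink toward the prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .likelihood import LikelihoodVector
from .spectrum import Spectrum

__all__ = [
    "EmResult",
    "SiteEstimate",
    "neutral_start_spectrum",
    "em_estimate",
    "posterior_site_estimate",
]


@dataclass
class EmResult:
    spectrum: Spectrum
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class SiteEstimate:
    chrom: str
    pos: int
    map_count: int
    posterior: np.ndarray


def neutral_start_spectrum(n: int, theta: float = 0.005, folded: bool = False) -> Spectrum:
    """Expected AFS under constant population size with scaled mutation rate theta.

    Unfolded: ``p[j] = theta/j`` for ``1 <= j <= n-1``, ``p[n] = theta/n`` (the
    fixed-derived class keeps starting mass so EM can populate it, e.g. under
    ancestral misspecification), and ``p[0]`` the remainder.  Folded:
    ``p[m] = theta*(1/m + 1/(n-m))`` for ``1 <= m < n/2`` and ``theta*2/n`` for
    the self-paired middle class when n is even.
    """
    if n < 2:
        raise ValueError(f"pool size n must be >= 2, got {n}")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if folded:
        k = n // 2
        probs = np.zeros(k + 1)
        for m in range(1, k + 1):
            if m != n - m:
                probs[m] = theta * (1.0 / m + 1.0 / (n - m))
            else:
                probs[m] = theta * 2.0 / n
    else:
        probs = np.zeros(n + 1)
        probs[1:n] = theta / np.arange(1, n)
        probs[n] = theta / n
    rest = 1.0 - probs.sum()
    if rest <= 0:
        raise ValueError(
            f"theta={theta} leaves no mass for the monomorphic class at n={n}"
        )
    probs[0] = rest
    return Spectrum(probs, n, folded=folded)


def _stack(liks: Sequence[LikelihoodVector] | np.ndarray) -> np.ndarray:
    if isinstance(liks, np.ndarray):
        return liks
    return np.vstack([lv.log_lik for lv in liks])


def em_estimate(
    liks: Sequence[LikelihoodVector] | np.ndarray,
    start: Spectrum,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> EmResult:
    """EM for the spectrum given per-site log-likelihood vectors.

    Iterates until the relative change in total log-likelihood drops below
    ``tol`` or ``max_iter`` is reached.  The trace is nondecreasing (standard
    EM monotonicity) up to floating-point slack.
    """
    M = _stack(liks)
    if M.size == 0:
        raise ValueError("em_estimate needs at least one site")
    if M.shape[1] != start.n_classes:
        raise ValueError("likelihood vectors and start spectrum disagree on class count")
    bad = np.where(~np.isfinite(M).all(axis=1) & np.isneginf(M).any(axis=1))[0]
    if np.any(np.all(np.isneginf(M), axis=1)):
        s = int(np.where(np.all(np.isneginf(M), axis=1))[0][0])
        raise ValueError(f"site index {s} has an all-impossible likelihood vector")
    probs = start.probs.copy()
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            joint = M + np.log(probs)
        site_ll = logsumexp(joint, axis=1)
        if np.any(np.isneginf(site_ll)):
            s = int(np.where(np.isneginf(site_ll))[0][0])
            raise ValueError(
                f"site index {s}: prior has zero mass everywhere the likelihood is finite"
            )
        total = float(site_ll.sum())
        trace.append(total)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
            break
        gamma = np.exp(joint - site_ll[:, None])
        probs = gamma.mean(axis=0)
        probs /= probs.sum()
    return EmResult(
        spectrum=Spectrum(probs, start.n, start.folded),
        loglik_trace=np.asarray(trace),
        n_iter=len(trace),
        converged=converged,
    )


def posterior_site_estimate(lik: LikelihoodVector, prior: Spectrum) -> SiteEstimate:
    """Posterior over allele counts at one site; MAP ties go to the smaller class."""
    if lik.log_lik.size != prior.n_classes:
        raise ValueError("likelihood vector and prior disagree on class count")
    with np.errstate(divide="ignore"):
        joint = lik.log_lik + np.log(prior.probs)
    norm = logsumexp(joint)
    if np.isneginf(norm):
        raise ValueError(
            f"site {lik.chrom}:{lik.pos}: prior has zero mass wherever the likelihood is finite"
        )
    posterior = np.exp(joint - norm)
    return SiteEstimate(lik.chrom, lik.pos, int(np.argmax(posterior)), posterior)
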