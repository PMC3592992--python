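"""Per-site read likelihoods conditional on the pool allele count.

Reads at a position sample the ``n`` pooled chromosomes independently with
replacement, so if ``j`` of them carry the derived allele each read is derived
with probability ``j/n`` before sequencing error.  A base call ``b`` given a
true allele ``a`` has probability ``1 - eps`` when ``b == a`` and ``eps / 3``
otherwise (miscalls uniform over the three alternatives).  The site likelihood
of all reads given ``j`` is the product over reads of the two-allele mixture,
kept in natural-log space throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pileup import NUCLEOTIDES, UNKNOWN, AncestralMode, PileupSite

__all__ = ["LikelihoodVector", "choose_alleles", "site_loglik_vector", "fold_loglik", "MAX_ERROR"]

# Error probabilities are capped at the no-information point of the uniform
# miscall model: at eps = 3/4 every base has probability 1/4 regardless of the
# true allele, so a Q0 call contributes a j-independent constant instead of a
# spurious (and possibly -inf) signal.
MAX_ERROR = 0.75

_LOG2 = np.log(2.0)


@dataclass
class LikelihoodVector:
    """log P(reads | j) for j = 0..n (unfolded) or 0..n//2 (folded).

    ``allele_a`` is the ancestral (or major, when folded) allele of the
    biallelic reduction at this site and ``allele_b`` the derived (or minor)
    one; ``log_lik[j]`` conditions on ``j`` copies of ``allele_b`` in the pool.
    """

    chrom: str
    pos: int
    n: int
    log_lik: np.ndarray
    allele_a: str
    allele_b: str
    folded: bool = False


def choose_alleles(site: PileupSite, mode: AncestralMode) -> tuple[str, str]:
    """Pick the biallelic (allele_A, allele_B) reduction of a site.

    Unfolded modes: allele_A is the ancestral base; allele_B the most frequent
    observed base different from it.  Folded mode: the two most frequent
    observed bases.  Ties break by fixed base order A < C < G < T; when no
    second allele is observed a placeholder (first base in order not equal to
    allele_A) marks the site as a monomorphic candidate.
    """
    counts = {b: site.bases.count(b) for b in NUCLEOTIDES}
    ranked = sorted(NUCLEOTIDES, key=lambda b: (-counts[b], b))
    if mode is AncestralMode.UNKNOWN:
        if site.coverage == 0:
            return "A", "C"
        return ranked[0], ranked[1]
    ancestral = site.ancestral
    if ancestral == UNKNOWN or ancestral not in NUCLEOTIDES:
        raise ValueError(f"site {site.chrom}:{site.pos} has no usable ancestral base")
    allele_b = next(b for b in ranked if b != ancestral)
    return ancestral, allele_b


def site_loglik_vector(
    site: PileupSite, n: int, alleles: tuple[str, str]
) -> LikelihoodVector:
    """Compute log P(reads | j derived in the pool) for j = 0..n.

    Zero-coverage sites get an identically-zero vector (likelihood 1 for every
    j: no reads, no information).
    """
    if n < 2:
        raise ValueError(f"pool size n must be >= 2, got {n}")
    allele_a, allele_b = alleles
    if site.coverage == 0:
        return LikelihoodVector(site.chrom, site.pos, n, np.zeros(n + 1), allele_a, allele_b)
    eps = np.minimum(site.error_probs, MAX_ERROR)
    base_arr = np.frombuffer(site.bases.encode(), dtype="S1")
    p_a = np.where(base_arr == allele_a.encode(), 1.0 - eps, eps / 3.0)
    p_b = np.where(base_arr == allele_b.encode(), 1.0 - eps, eps / 3.0)
    f = np.arange(n + 1) / n
    # per-read mixture across allele frequencies j/n, summed in log space
    per_read = np.outer(1.0 - f, p_a) + np.outer(f, p_b)
    log_lik = np.log(per_read).sum(axis=1)
    return LikelihoodVector(site.chrom, site.pos, n, log_lik, allele_a, allele_b)


def fold_loglik(vec: LikelihoodVector) -> LikelihoodVector:
    """Fold an unfolded vector onto minor-allele classes 0..n//2.

    Class m averages the two orientations: logaddexp(L[m], L[n-m]) - log 2,
    except the self-paired middle class when n is even.
    """
    if vec.folded:
        return vec
    n = vec.n
    k = n // 2
    out = np.empty(k + 1)
    for m in range(k + 1):
        if m != n - m:
            out[m] = np.logaddexp(vec.log_lik[m], vec.log_lik[n - m]) - _LOG2
        else:
            out[m] = vec.log_lik[m]
    return LikelihoodVector(
        vec.chrom, vec.pos, n, out, vec.allele_a, vec.allele_b, folded=True
    )
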