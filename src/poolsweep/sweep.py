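"""Hitchhiking transform: state spectra for the sweep scan.

A hard sweep distorts the local allele frequency spectrum.  In the
lineage-escape picture, each of the ``n`` sampled chromosomes escapes the
sweep (recombines onto a non-swept background) independently with probability
``p_escape``; all non-escapees coalesce onto the single swept haplotype.  The
pre-sweep sample therefore has ``m = E + 1{E < n}`` distinct lineages (the
``E`` escapees plus, if anyone was swept, one ancestral lineage), whose
derived count follows the neutral spectrum projected down to ``m`` by
hypergeometric sampling.  Escapees keep their own allele; every non-escapee
copies the ancestral lineage.  Summing exactly over the escape count, the
projected count, and which pre-sweep lineages are derived gives the post-sweep
spectrum — skewed toward monomorphic, very low, and very high frequencies, the
classic sweep signature.

The scan uses two transformed spectra: 'Selection' (small ``p_escape``,
strong distortion, sites close to the swept site) and 'Intermediate' (larger
``p_escape``, mild distortion, sites in between), both derived from the same
'Neutral' background spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom, hypergeom

from .spectrum import Spectrum, fold_spectrum

__all__ = [
    "SweepTransformParams",
    "downsample_spectrum",
    "sweep_transform",
    "build_state_spectra",
]


@dataclass(frozen=True)
class SweepTransformParams:
    """Escape probability of a sampled lineage, plus the pool size."""

    p_escape: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_escape <= 1.0:
            raise ValueError(f"p_escape must lie in [0, 1], got {self.p_escape}")
        if self.n < 2:
            raise ValueError(f"pool size n must be >= 2, got {self.n}")


def downsample_spectrum(spec: Spectrum, m: int) -> Spectrum:
    """Project an unfolded spectrum from n chromosomes down to m.

    Standard SFS projection: ``p'[k] = sum_j p[j] * Hypergeom(k; m, j, n)``.
    """
    if spec.folded:
        raise ValueError("downsampling is defined on unfolded spectra")
    if not 1 <= m <= spec.n:
        raise ValueError(f"m must lie in [1, {spec.n}], got {m}")
    if m == spec.n:
        return spec
    n = spec.n
    k = np.arange(m + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    pmf = hypergeom.pmf(k, n, j, m)  # k successes drawing m from n with j marked
    return Spectrum(pmf @ spec.probs, n=m, folded=False)


def sweep_transform(neutral: Spectrum, params: SweepTransformParams) -> Spectrum:
    """Exact post-sweep spectrum under the lineage-escape construction.

    Enumerates the escape count ``E ~ Binomial(n, p_escape)`` and the derived
    count ``k`` of the ``m``-lineage pre-sweep sample.  The ``k`` derived
    labels land uniformly on the ``m`` lineages, so the ancestral lineage is
    derived with probability ``k/m``; if it is, its allele is copied to all
    ``n - E`` non-escapees.  No Monte Carlo is involved.
    """
    if neutral.folded:
        raise ValueError(
            "sweep transform is defined on derived spectra; fold after transforming"
        )
    if params.n != neutral.n:
        raise ValueError("params.n and spectrum n disagree")
    n = neutral.n
    p = params.p_escape
    out = np.zeros(n + 1)
    w_e = binom.pmf(np.arange(n + 1), n, p)
    for e in range(n + 1):
        if w_e[e] == 0.0:
            continue
        if e == n:
            out += w_e[e] * neutral.probs
            continue
        m = e + 1
        down = downsample_spectrum(neutral, m).probs
        for k in range(m + 1):
            w = w_e[e] * down[k]
            if w == 0.0:
                continue
            # ancestral lineage derived (prob k/m): its allele floods the
            # n - e swept chromosomes; otherwise all k derived are escapees.
            if k > 0:
                out[k + n - e - 1] += w * (k / m)
            out[k] += w * (1.0 - k / m)
    return Spectrum(out, n, folded=False)


def build_state_spectra(
    neutral: Spectrum, p_sel: float = 0.1, p_int: float = 0.6, folded: bool = False
) -> tuple[Spectrum, Spectrum, Spectrum]:
    """(Neutral, Intermediate, Selection) spectra for the three hidden states.

    ``p_sel < p_int``: the closer to the swept site, the fewer lineages
    escape.  With ``folded=True`` each spectrum is folded after the transform.
    """
    if not 0.0 <= p_sel < p_int <= 1.0:
        raise ValueError(
            f"need 0 <= p_sel < p_int <= 1, got p_sel={p_sel}, p_int={p_int}"
        )
    if neutral.folded:
        raise ValueError("build_state_spectra needs an unfolded neutral spectrum")
    inter = sweep_transform(neutral, SweepTransformParams(p_int, neutral.n))
    sel = sweep_transform(neutral, SweepTransformParams(p_sel, neutral.n))
    if folded:
        return fold_spectrum(neutral), fold_spectrum(inter), fold_spectrum(sel)
    return neutral, inter, sel
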