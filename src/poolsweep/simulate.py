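"""Synthetic Pool-Seq pileups with known ground truth.

The generator mirrors the likelihood model exactly: per site a true derived
count ``j`` is drawn from a governing spectrum (the neutral background, or a
sweep-transformed spectrum inside declared sweep blocks), coverage is Poisson,
each read samples a pooled chromosome with replacement (derived with
probability ``j/n``), and each base is miscalled to a uniformly chosen other
base with its phred-implied probability.  Because the sampling scheme matches
the model, parameter-recovery tests isolate estimator error from model
mismatch.  Not emulated: read fragments, mapping artifacts, indels, coverage
autocorrelation, or unequal DNA amounts across pooled individuals.

Defaults describe a pool of n = 20 chromosomes sequenced at 20x with Q30
bases.  The default neutral spectrum is the standard-neutral shape with
theta = 0.028, which puts ~10% of sites in segregating classes — the density
observed in a diverse wild avian pool of this size — while the EM *start*
value elsewhere stays at the conservative theta = 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .afs import neutral_start_spectrum
from .spectrum import Spectrum
from .sweep import SweepTransformParams, sweep_transform

__all__ = ["SimConfig", "simulate_pileup", "make_quality_string", "DEFAULT_TRUTH_THETA"]

DEFAULT_TRUTH_THETA = 0.028
_NUC = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """World description for one simulated chromosome.

    sweep_blocks are ``(start, end, p_escape)`` triples (1-based inclusive,
    non-overlapping, within ``[1, length]``); their sites draw ``j`` from the
    sweep-transformed neutral spectrum.  ``ancestral_misspec_rate`` flips the
    recorded ancestral (reference-column) allele to the derived one at that
    fraction of sites, reproducing the spurious high-derived-class mass seen
    with an imperfect outgroup.
    """

    n: int = 20
    length: int = 2000
    truth_spectrum: Spectrum | None = None
    coverage_mean: float = 20.0
    quality_dist: Sequence[tuple[int, float]] = ((30, 1.0),)
    sweep_blocks: Sequence[tuple[int, int, float]] = ()
    ancestral_misspec_rate: float = 0.0
    seed: int = 0
    chrom: str = "sim1"
    quality_offset: int = 33
    ancestral_column: bool = False

    def resolved_truth(self) -> Spectrum:
        if self.truth_spectrum is not None:
            if self.truth_spectrum.folded or self.truth_spectrum.n != self.n:
                raise ValueError("truth_spectrum must be unfolded with matching n")
            return self.truth_spectrum
        return neutral_start_spectrum(self.n, DEFAULT_TRUTH_THETA, folded=False)

    def validate(self) -> None:
        last_end = 0
        for start, end, p in sorted(self.sweep_blocks):
            if not (1 <= start <= end <= self.length):
                raise ValueError(f"sweep block ({start}, {end}) outside [1, {self.length}]")
            if start <= last_end:
                raise ValueError("sweep blocks must not overlap")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sweep block p_escape {p} outside [0, 1]")
            last_end = end


def make_quality_string(qs: Sequence[int], offset: int = 33) -> str:
    """ASCII-encode phred scores; exact inverse of the pileup parser's decode."""
    out = []
    for q in qs:
        if not 0 <= q <= 93:
            raise ValueError(f"phred score {q} outside [0, 93]")
        out.append(chr(int(q) + offset))
    return "".join(out)


def simulate_pileup(cfg: SimConfig) -> tuple[list[str], list[tuple[int, int, str]]]:
    """Generate pileup lines and a matching truth table.

    Returns ``(pileup_lines, truth)`` where each truth entry is
    ``(pos, true_derived_count, governing_state)`` with state ``"neutral"`` or
    ``"sweep"``.  Every position in ``[1, length]`` appears in both outputs;
    zero-coverage positions get the samtools-style ``0 * *`` placeholder line.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, length = cfg.n, cfg.length
    neutral = cfg.resolved_truth()

    state = np.zeros(length, dtype=int)  # 0 = neutral, 1 = sweep
    spectra = [neutral.probs]
    for start, end, p in cfg.sweep_blocks:
        spectra.append(sweep_transform(neutral, SweepTransformParams(p, n)).probs)
        state[start - 1 : end] = len(spectra) - 1

    # per-site truth: derived count, ancestral/derived base identities
    j = np.empty(length, dtype=int)
    u = rng.random(length)
    for s_idx, probs in enumerate(spectra):
        mask = state == s_idx
        if not mask.any():
            continue
        cdf = np.cumsum(probs)
        j[mask] = np.searchsorted(cdf, u[mask], side="right").clip(0, n)
    anc = rng.integers(0, 4, size=length)
    der = (anc + rng.integers(1, 4, size=length)) % 4
    misspec = rng.random(length) < cfg.ancestral_misspec_rate
    recorded_anc = np.where(misspec, der, anc)

    coverage = rng.poisson(cfg.coverage_mean, size=length)
    total = int(coverage.sum())
    site_of_read = np.repeat(np.arange(length), coverage)

    # reads: pick a chromosome (derived w.p. j/n), then sequencing error
    is_derived = rng.random(total) < j[site_of_read] / n
    true_base = np.where(is_derived, der[site_of_read], anc[site_of_read])
    phreds = np.array([q for q, _ in cfg.quality_dist])
    weights = np.array([w for _, w in cfg.quality_dist], dtype=float)
    weights /= weights.sum()
    read_q = rng.choice(phreds, size=total, p=weights)
    eps = 10.0 ** (-read_q / 10.0)
    flip = rng.random(total) < eps
    called = np.where(flip, (true_base + rng.integers(1, 4, size=total)) % 4, true_base)

    ref_char = _NUC[recorded_anc].astype("U1")
    called_char = _NUC[called].astype("U1")
    qual_char = np.array([chr(int(q) + cfg.quality_offset) for q in read_q])

    lines: list[str] = []
    truth: list[tuple[int, int, str]] = []
    bounds = np.concatenate([[0], np.cumsum(coverage)])
    state_name = np.where(state == 0, "neutral", "sweep")
    for i in range(length):
        pos = i + 1
        lo, hi = bounds[i], bounds[i + 1]
        if hi == lo:
            base_s, qual_s, cov = "*", "*", 0
        else:
            site_calls = called_char[lo:hi]
            base_s = "".join(
                np.where(site_calls == ref_char[i], ".", site_calls)
            )
            qual_s = "".join(qual_char[lo:hi])
            cov = hi - lo
        fields = [cfg.chrom, str(pos), ref_char[i], str(cov), base_s, qual_s]
        if cfg.ancestral_column:
            fields.append(ref_char[i])
        lines.append("\t".join(fields))
        truth.append((pos, int(j[i]), str(state_name[i])))
    return lines, truth


def write_simulation(cfg: SimConfig, pileup_path, truth_path=None) -> None:
    """Write a simulated pileup (and optional truth table) to disk."""
    lines, truth = simulate_pileup(cfg)
    with open(pileup_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("pos\tderived_count\tstate\n")
            for pos, count, st in truth:
                fh.write(f"{pos}\t{count}\t{st}\n")
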