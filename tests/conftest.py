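"""Shared fixtures and small independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from poolsweep.likelihood import MAX_ERROR, choose_alleles, site_loglik_vector
from poolsweep.pileup import AncestralMode, PileupSite, parse_pileup_line


@pytest.fixture
def gtf_file(tmp_path):
    """Tiny annotation with two overlapping exons and one separate exon."""
    path = tmp_path / "anno.gtf"
    rows = [
        ("chr1", 10, 20, "g1"),
        ("chr1", 15, 30, "g1"),
        ("chr1", 50, 60, "g2"),
    ]
    with open(path, "w") as fh:
        for chrom, start, end, gene in rows:
            fh.write(
                f'{chrom}\ttest\texon\t{start}\t{end}\t.\t+\t.\t'
                f'gene_id "{gene}"; transcript_id "{gene}t";\n'
            )
    return path


def make_site(bases: str, quals: list[int], ancestral: str = "A", pos: int = 1) -> PileupSite:
    eps = 10.0 ** (-np.asarray(quals, dtype=float) / 10.0)
    return PileupSite("chr1", pos, ancestral, ancestral, bases, eps)


def enumerate_site_likelihood(site: PileupSite, n: int, alleles: tuple[str, str]) -> np.ndarray:
    """Oracle: exhaustive sum over which pooled chromosome each read sampled.

    Chromosomes 1..j carry allele_B, the rest allele_A; each read picks a
    chromosome uniformly and is then miscalled with its own error probability
    (uniform over the three other bases).  Completely independent of the
    mixture-form implementation.
    """
    allele_a, allele_b = alleles
    eps = np.minimum(site.error_probs, MAX_ERROR)
    reads = list(zip(site.bases, eps))
    out = np.zeros(n + 1)
    for j in range(n + 1):
        total = 0.0
        for origins in itertools.product(range(n), repeat=len(reads)):
            p = (1.0 / n) ** len(reads)
            for (b, e), chrom_idx in zip(reads, origins):
                true_allele = allele_b if chrom_idx < j else allele_a
                p *= (1.0 - e) if b == true_allele else e / 3.0
            total += p
        out[j] = total
    with np.errstate(divide="ignore"):
        return np.log(out)


def enumerate_hmm(model, positions, emissions):
    """Oracle: score all 3^L state paths explicitly.

    Returns (best_path, log posteriors L x 3, total log-likelihood), with
    inter-site gaps bridged by explicit matrix powers like the implementation
    claims to do -- but evaluated path by path, no dynamic programming.
    """
    L = len(positions)
    trans_pow = {}
    for d in np.diff(positions):
        d = int(d)
        trans_pow[d] = np.linalg.matrix_power(model.transition, d)
    best_path, best_score = None, -np.inf
    post = np.zeros((L, 3))
    total = 0.0
    for path in itertools.product(range(3), repeat=L):
        p = model.initial[path[0]] * np.exp(emissions[0, path[0]])
        for t in range(1, L):
            d = int(positions[t] - positions[t - 1])
            p *= trans_pow[d][path[t - 1], path[t]] * np.exp(emissions[t, path[t]])
        total += p
        score = np.log(p) if p > 0 else -np.inf
        if score > best_score:
            best_score, best_path = score, path
        for t, s in enumerate(path):
            post[t, s] += p
    return np.array(best_path), np.log(post / total), np.log(total)


def vectors_from_lines(lines, n, mode=AncestralMode.REFERENCE, quality_offset=33):
    """Parse simulated pileup lines into likelihood vectors."""
    out = []
    for i, line in enumerate(lines, start=1):
        site = parse_pileup_line(line, mode, quality_offset, line_number=i)
        out.append(site_loglik_vector(site, n, choose_alleles(site, mode)))
    return out
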