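"""Run orchestration: configuration, block queue, workers, caching, outputs.

The per-site likelihood vectors dominate runtime, and they are independent
across positions, so the engine partitions each chromosome into fixed
coordinate blocks (10 kb by default), computes blocks in parallel, and merges
results in genomic order.  Every randomized step (ratio subsampling) is seeded
from ``(seed, block ordinal)``, never from worker identity, so output files
are byte-identical for any worker count.  Likelihood vectors can be cached to
a plain-text emission file and reused by later scans with a different switch
probability ``k``, which only re-runs the (cheap) HMM.
"""

from __future__ import annotations

import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, fields
from functools import partial
from typing import Iterable, Sequence

import numpy as np

from .afs import em_estimate, neutral_start_spectrum, posterior_site_estimate
from .hmm import STATE_NAMES, build_hmm, call_sweep_windows, decode
from .likelihood import LikelihoodVector, choose_alleles, fold_loglik, site_loglik_vector
from .pileup import (
    AncestralMode,
    PileupSite,
    filter_pileup_by_gtf,
    read_pileup,
)
from .spectrum import Spectrum, read_spectrum_file, unfold_spectrum, write_spectrum_file
from .sweep import build_state_spectra

__all__ = [
    "RunConfig",
    "Block",
    "plan_blocks",
    "run_parallel",
    "run",
    "read_emission_cache",
    "write_emission_cache",
]

CACHE_MAGIC = "poolsweep-emissions"


@dataclass
class RunConfig:
    """Everything one run needs; mirrored into output-file headers."""

    input_file: str
    n: int
    ancestral: str = "unknown"
    theta: float = 0.005
    ratio: int = 1
    k: float = 1e-10
    p_sel: float = 0.1
    p_int: float = 0.6
    spectrum_file: str | None = None
    only_spectrum: bool = False
    pred: bool = False
    estim: bool = False
    emit_file: bool = False
    workers: int = 1
    seed: int = 1
    quality_offset: int = 33
    block_size: int = 10_000
    region: str | None = None
    gtf: str | None = None
    feature: str | None = None
    min_quality: int = 0
    prefix: str | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("pool size -n must be >= 2")
        if self.ratio < 1:
            raise ValueError("--ratio must be >= 1")
        if self.workers < 1:
            raise ValueError("--workers must be >= 1")
        self.ancestral = AncestralMode(self.ancestral).value

    @property
    def mode(self) -> AncestralMode:
        return AncestralMode(self.ancestral)

    @property
    def folded(self) -> bool:
        return self.mode is AncestralMode.UNKNOWN

    @property
    def out_prefix(self) -> str:
        if self.prefix:
            return self.prefix
        base = self.input_file
        if base.endswith(".pileup"):
            base = base[: -len(".pileup")]
        return base

    def header(self) -> str:
        # worker count and output prefix omitted: outputs are worker-invariant
        # and the prefix is evident from the file's own location
        skip = {"workers", "prefix"}
        parts = [
            f"{f.name}={getattr(self, f.name)}"
            for f in fields(self)
            if f.name not in skip and getattr(self, f.name) is not None
        ]
        return "poolsweep " + " ".join(parts)


@dataclass
class Block:
    ordinal: int
    chrom: str
    bin_index: int  # coordinate bin, [bin*size+1, (bin+1)*size]
    sites: list


def plan_blocks(sites: Iterable[PileupSite], block_size: int) -> list[Block]:
    """Partition the stream into fixed coordinate bins per chromosome.

    Bin ``b`` covers positions ``[b*block_size + 1, (b+1)*block_size]``; every
    site lands in exactly one block and block order is genomic order.
    """
    if block_size < 1:
        raise ValueError("block size must be >= 1")
    blocks: list[Block] = []
    key = None
    for site in sites:
        b = (site.pos - 1) // block_size
        if key != (site.chrom, b):
            key = (site.chrom, b)
            blocks.append(Block(len(blocks), site.chrom, b, []))
        blocks[-1].sites.append(site)
    return blocks


def _compute_block(
    block: Block, n: int, mode_value: str, folded: bool
) -> list[LikelihoodVector]:
    mode = AncestralMode(mode_value)
    try:
        out = []
        for site in block.sites:
            vec = site_loglik_vector(site, n, choose_alleles(site, mode))
            out.append(fold_loglik(vec) if folded else vec)
        return out
    except Exception as exc:  # annotate with the failing block for the abort message
        raise RuntimeError(
            f"block {block.ordinal} ({block.chrom} bin {block.bin_index}) failed: {exc}"
        ) from exc


def run_parallel(blocks: Sequence[Block], workers: int, fn) -> list:
    """Map ``fn`` over blocks, merging results in block (genomic) order."""
    if workers <= 1:
        return [fn(b) for b in blocks]
    with ProcessPoolExecutor(max_workers=workers) as ex:
        return list(ex.map(fn, blocks, chunksize=max(1, len(blocks) // (4 * workers))))


# ---------------------------------------------------------------- emission cache

def write_emission_cache(path, vectors: Sequence[LikelihoodVector], config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# {CACHE_MAGIC} n={config.n} folded={int(config.folded)} "
            f"quality_offset={config.quality_offset}\n"
        )
        for v in vectors:
            vals = "\t".join(repr(float(x)) for x in v.log_lik)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.allele_a}\t{v.allele_b}\t{vals}\n")


def read_emission_cache(path, config: RunConfig) -> list[LikelihoodVector]:
    vectors: list[LikelihoodVector] = []
    with open(path) as fh:
        header = fh.readline().strip()
        expected = (
            f"# {CACHE_MAGIC} n={config.n} folded={int(config.folded)} "
            f"quality_offset={config.quality_offset}"
        )
        if header != expected:
            raise ValueError(
                f"emission cache {path} header does not match the current run "
                f"(found {header!r}, need {expected!r}); delete it or rerun with "
                "--emit-file to regenerate"
            )
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            chrom, pos, a_a, a_b = parts[0], int(parts[1]), parts[2], parts[3]
            log_lik = np.array([float(x) for x in parts[4:]])
            vectors.append(
                LikelihoodVector(chrom, pos, config.n, log_lik, a_a, a_b, config.folded)
            )
    return vectors


# ------------------------------------------------------------------------- run

def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    start_s, end_s = span.split("-", 1)
    return chrom, int(start_s), int(end_s)


def _subsample_mask(blocks: Sequence[Block], ratio: int, seed: int) -> np.ndarray:
    """Per-site keep mask drawn per block from (seed, block ordinal)."""
    masks = []
    for block in blocks:
        size = len(block.sites)
        if ratio == 1:
            masks.append(np.ones(size, dtype=bool))
        else:
            rng = np.random.default_rng([seed, block.ordinal])
            masks.append(rng.random(size) < 1.0 / ratio)
    return np.concatenate(masks) if masks else np.zeros(0, dtype=bool)


def _load_vectors(config: RunConfig) -> tuple[list[LikelihoodVector], np.ndarray]:
    """Likelihood vectors (from cache or fresh) plus the ratio keep-mask."""
    cache_path = config.out_prefix + ".emit"
    if config.emit_file and os.path.exists(cache_path):
        vectors = read_emission_cache(cache_path, config)
        pseudo = [
            PileupSite(v.chrom, v.pos, "N", "N", "", np.empty(0)) for v in vectors
        ]
        blocks = plan_blocks(pseudo, config.block_size)
    else:
        sites = read_pileup(
            config.input_file,
            mode=config.mode,
            quality_offset=config.quality_offset,
            min_quality=config.min_quality,
        )
        if config.region:
            chrom, start, end = _parse_region(config.region)
            sites = (
                s
                for s in sites
                if s.chrom == chrom
                and (start is None or start <= s.pos <= end)
            )
        if config.gtf:
            if not config.feature:
                raise ValueError("--gtf requires --feature")
            sites = filter_pileup_by_gtf(sites, config.gtf, config.feature)
        blocks = plan_blocks(sites, config.block_size)
        fn = partial(
            _compute_block, n=config.n, mode_value=config.ancestral, folded=config.folded
        )
        per_block = run_parallel(blocks, config.workers, fn)
        vectors = [v for chunk in per_block for v in chunk]
        if config.emit_file:
            write_emission_cache(cache_path, vectors, config)
    keep = _subsample_mask(blocks, config.ratio, config.seed)
    return vectors, keep


def _neutral_spectrum(
    config: RunConfig, vectors: list[LikelihoodVector], keep: np.ndarray, outputs: dict
) -> Spectrum:
    if config.spectrum_file:
        return read_spectrum_file(config.spectrum_file, n=config.n, folded=config.folded)
    kept = [v for v, k in zip(vectors, keep) if k]
    if not kept:
        raise ValueError("no sites left for spectrum estimation (ratio too high?)")
    start = neutral_start_spectrum(config.n, config.theta, config.folded)
    result = em_estimate(kept, start)
    path = config.out_prefix + ".spectrum"
    write_spectrum_file(result.spectrum, path, extra_header=config.header())
    outputs["spectrum"] = path
    return result.spectrum


def run(config: RunConfig) -> dict[str, str]:
    """Execute the configured tasks; returns a map of task -> output path."""
    if not (config.only_spectrum or config.pred or config.estim):
        raise ValueError("no task requested: use --only-spectrum, --pred and/or --estim")
    vectors, keep = _load_vectors(config)
    outputs: dict[str, str] = {}
    prefix = config.out_prefix
    header = config.header()

    neutral: Spectrum | None = None
    if config.only_spectrum or config.pred or config.estim:
        neutral = _neutral_spectrum(config, vectors, keep, outputs)

    if config.pred:
        base = unfold_spectrum(neutral) if neutral.folded else neutral
        spectra = build_state_spectra(base, config.p_sel, config.p_int, config.folded)
        model = build_hmm(spectra, config.k)
        pred_path, post_path, stat_path = (
            prefix + ".pred",
            prefix + ".post",
            prefix + ".stat",
        )
        with open(pred_path, "w") as fp, open(post_path, "w") as fo, open(
            stat_path, "w"
        ) as fs:
            fp.write(f"# {header}\n")
            fo.write(f"# {header}\n# log posterior of state S, natural log\n")
            fs.write(f"# {header}\n# chrom\tstart\tend\tpeak log posterior of S (natural log)\n")
            for chrom, chrom_vecs in _by_chrom(vectors):
                decoded = decode(model, chrom_vecs, chrom)
                for pos, s, lp in zip(
                    decoded.positions, decoded.states, decoded.log_posterior_selection
                ):
                    fp.write(f"{chrom}\t{pos}\t{STATE_NAMES[s]}\n")
                    fo.write(f"{chrom}\t{pos}\t{float(lp):.10g}\n")
                for w in call_sweep_windows(decoded):
                    fs.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.peak_log_posterior:.10g}\n")
        outputs.update(pred=pred_path, post=post_path, stat=stat_path)

    if config.estim:
        estim_path = prefix + ".estim"
        with open(estim_path, "w") as fh:
            fh.write(f"# {header}\n")
            for v in vectors:
                est = posterior_site_estimate(v, neutral)
                fh.write(f"{v.chrom}\t{v.pos}\t{est.map_count}\n")
        outputs["estim"] = estim_path

    return outputs


def _by_chrom(vectors: Sequence[LikelihoodVector]):
    current: list[LikelihoodVector] = []
    chrom = None
    for v in vectors:
        if chrom is not None and v.chrom != chrom:
            yield chrom, current
            current = []
        chrom = v.chrom
        current.append(v)
    if current:
        yield chrom, current
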