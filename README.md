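# poolsweep

Allele frequency spectra, per-site allele frequencies, and selective-sweep
scans from pooled sequencing (Pool-Seq) pileup data.

## The problem

Sequencing a single pool of many individuals is a cheap way to measure
population allele frequencies, but the reads at a position are a *random,
possibly redundant* sample of the pooled chromosomes and carry sequencing
errors. Naive frequency estimates (allele-count ratios, quality thresholds)
ignore both. `poolsweep` instead computes, at every genomic position, the full
likelihood of the observed bases and qualities conditional on the unknown
allele count *j* among the *n* pooled chromosomes,

    P(reads | j) = prod_over_reads [ (j/n) e(b | B) + (1 - j/n) e(b | A) ],

with `e(b|a) = 1 - eps` when the called base matches allele `a` and `eps/3`
otherwise (`eps = 10^(-Q/10)` from the phred score). Everything downstream
works on these likelihood vectors, so low-coverage and low-quality sites are
weighted continuously instead of being discarded:

- **AFS estimation** — the sample allele frequency spectrum (probabilities of
  counts 0..n, or folded 0..n/2 when the ancestral allele is unknown) is
  fitted by EM, starting from the standard-neutral expectation with
  `theta = 4*N*mu = 0.005`.
- **Per-site frequencies** — the AFS acts as a prior; the reported count is
  the posterior mode, so uncovered sites fall back to the prior's mode.
- **Sweep detection** — a three-state HMM (Neutral / Intermediate / Selection)
  runs along the chromosome. The Selection and Intermediate spectra are
  derived from the neutral AFS by the hitchhiking transform: each sampled
  lineage escapes the sweep with probability `p_escape` (defaults 0.1 and 0.6
  for the two states), non-escapees coalesce onto the swept haplotype, and the
  resulting spectrum is computed by exact enumeration. States switch with
  per-site probability `q` (flag `-k`); Viterbi decoding yields sweep windows,
  the forward-backward algorithm yields per-site posteriors.

Intended users: population geneticists with `samtools mpileup` output from a
pooled sample who want model-based frequencies or a genome scan for hard
sweeps.

## Worked example

Simulate 5,000 positions of a pool of 20 chromosomes at 20x with a hard sweep
(no escaping lineages) at positions 2,000-2,500, then estimate the spectrum
from 1/5 of the positions and scan for sweeps:

```sh
python -c "from poolsweep.simulate import SimConfig, write_simulation; \
  write_simulation(SimConfig(length=5000, seed=4, sweep_blocks=[(2000, 2500, 0.0)]), 'demo.pileup')"
poolsweep --input-file demo.pileup -n 20 -a reference \
  --only-spectrum --theta 0.005 --ratio 5 --seed 2 --prefix demo
poolsweep --input-file demo.pileup -n 20 -a reference \
  --pred --estim --spectrum-file demo.spectrum -k 0.001 --p-sel 0.0 \
  --emit-file --prefix demo
```

`demo.stat` then contains one detected sweep window:

```
sim1	2011	2501	-6.170809256e-06
```

i.e. a run of Viterbi state `S` spanning positions 2,011-2,501 (the true sweep
is 2,000-2,500) whose peak posterior probability of Selection is
`exp(-6.2e-06) ~ 1.0` (third column is the natural-log posterior). `demo.pred`
holds the per-site state path (here 491 `S` sites flanked by `I` sites inside
~4,500 `N` sites), `demo.post` the per-site log posterior of Selection, and
`demo.estim` the MAP allele count per position. Re-running with a different
`-k` reuses the cached `demo.emit` likelihood vectors and takes a fraction of
the original time; outputs are byte-identical for any `--workers` count.

File formats are plain text: pileup in, and tab-separated
`.spectrum/.pred/.post/.stat/.estim` out, each with a `#` header recording the
configuration. See `docs/methods.md` for the model details and the
simulator's scope.

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch on a freshly
simulated 20 kb chromosome (spectrum EM with `--ratio 10`, cached sweep scan
at `k = 1e-4`, per-site estimation) and writes its JSON summary:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
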