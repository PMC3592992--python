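# Methods

## Model

### Read likelihoods

A Pool-Seq experiment sequences one DNA pool of `n` chromosomes. Reads at a
position are modeled as sampling chromosomes independently *with replacement*
(appropriate while read counts are far below the number of pooled DNA
fragments), so with `j` derived chromosomes a read is derived with probability
`j/n` before error. Base calls follow the uniform-miscall model: a call `b`
given true allele `a` has probability `1 - eps` if `b == a`, else `eps/3`,
with `eps = 10^(-Q/10)` from the per-base phred score. The per-site likelihood
vector `log P(reads | j)`, `j = 0..n`, is the product over reads of the
two-allele mixture, computed and stored in natural-log space (coverage times
sites would underflow linear probabilities). Sites with no reads get the
all-zero vector (likelihood 1 for every `j`): they carry no information but
stay in the stream for gap bookkeeping.

Each site is reduced to two alleles before the likelihood: the ancestral
allele (reference base, or a provided column) plus the most frequent other
observed base; with unknown ancestry the two most frequent bases, and the
subsequent analysis is folded (minor-allele classes `0..n/2`, obtained by
log-mean-exp of the two orientations). Ties break in the fixed order
A < C < G < T. Reads of a third base contribute the factor `eps/3` under both
alleles — pure error mass that down-weights rather than biases the site.

Numerical guard: error probabilities are capped at `3/4` inside the
likelihood. `eps = 3/4` is the no-information point of the uniform-miscall
model (every base then has probability 1/4 regardless of the true allele);
without the cap a Q0 base matching one allele would contribute a spurious
frequency signal, and `-inf` terms at the boundary classes. Parsed
`error_probs` still record the exact phred value (Q0 = 1.0).

### AFS estimation

The region AFS is the mixture weight vector over latent per-site counts,
fitted by EM: responsibilities `gamma_s(j) ∝ p[j] * P(reads_s | j)` (E-step),
then `p[j] = mean_s gamma_s(j)` (M-step). Start: the standard-neutral
expectation `p[j] ∝ theta/j` with `theta = 0.005` by default; the
fixed-derived class `n` starts at `theta/n` so ancestral misspecification can
populate it (an EM zero is absorbing). Convergence: relative change of the
total log-likelihood below `1e-6`, at most 500 iterations — unstated in the
method's sources, so standard cheap defaults. Monomorphic sites are included:
class-0 mass calibrates the density of segregating sites, which the sweep
model uses as signal.

Per-site estimates combine a prior spectrum (the EM fit, or a user file) with
the site's likelihood vector; the reported count is the posterior mode, ties
toward the smaller count (conservative and deterministic). Uncovered sites
return the prior's mode.

**Known limitation (measured).** The biallelic reduction maximizes over the
unobserved identity of the second allele. At a monomorphic site a single
error read therefore defines `allele_B` and its likelihood mildly favors
`j = 1`, inflating singleton mass; the ML deconvolution is also spiky at
finite coverage (NPMLE behavior). On simulations with a diverse background
(10% segregating sites, n = 20, 20x, Q30) the EM spectrum carries a
systematic total-variation bias of ~0.04 from the generating truth that does
not vanish with more sites; at `theta = 0.005` backgrounds the recovery error
is ~0.02-0.035 at 2,000 sites.

### Sweep spectra

The Selection and Intermediate spectra derive from the neutral AFS by the
lineage-escape construction: each of the `n` sampled lineages escapes the
sweep independently with probability `p_escape`; the `E` escapees plus (if
`E < n`) one ancestral lineage form a pre-sweep sample of size
`m = E + 1{E<n}` whose derived count `k` follows the neutral spectrum
projected to `m` chromosomes (hypergeometric downsampling); the `k` derived
labels fall uniformly on the `m` lineages, and the ancestral lineage's allele
is copied to all `n - E` swept chromosomes. The output distribution is an
exact `O(n^2)` sum over `(E, k, ancestral-derived)` — no Monte Carlo, so
emissions are noise-free. Limits: `p_escape = 1` returns the neutral
spectrum; `p_escape = 0` leaves only classes 0 and `n`. Monomorphic classes
pass through the construction like any other, preserving the
segregating-site-density signal. Defaults `p_sel = 0.1`, `p_int = 0.6` are
free parameters (exposed on the CLI): strong versus mild distortion; the
sources state no values.

For folded runs the transform needs a derived spectrum, so a folded neutral
estimate is first unfolded by splitting each minor-class mass equally between
`j` and `n - j` (the maximum-entropy inverse of folding), transformed, then
folded again.

### The scan

States (Neutral, Intermediate, Selection) form a linear chain: N and S switch
to I with per-site probability `q`, I moves either way with probability `q`;
no direct N-S jumps, so decoded sweeps are flanked by Intermediate. The
matrix is symmetric and doubly stochastic, hence the stationary distribution
is uniform (1/3 each) and is used as the initial distribution — results then
do not depend on where the scan starts. Positions absent from the input
(uncovered or filtered) are bridged by `T^d` for gap length `d` (capped at
1e6, beyond which the chain is numerically stationary), keeping `q` strictly
per-site. Viterbi ties break toward Neutral (conservative calling). Sweep
windows are maximal Viterbi-Selection runs `[first pos, last pos]`; each
window's score is the maximum per-site posterior of Selection within it, in
natural log (stated in the `.stat` header, since base could be ambiguous).

## Engine

Per-site likelihood vectors are the expensive part; they are computed over a
queue of 10 kb coordinate blocks (configurable) mapped across worker
processes and merged in genomic order. Ratio subsampling for AFS estimation
draws its randomness from `(seed, block ordinal)`, never from worker
identity, so all outputs are byte-identical for any `--workers` value — the
testable core of the parallelization design. The `--emit-file` cache stores
one tab-separated line per site (chromosome, position, alleles, log
likelihoods) under a header recording `n`, foldedness, and the quality
offset; a mismatching header is an error suggesting regeneration. Output-file
headers record the run configuration except the worker count and output
prefix (both irrelevant to the numbers).

The current implementation holds one chromosome's parsed sites in memory;
at ~200 bytes/site this is fine up to tens of millions of positions per
chromosome, which is the intended per-run scale (split by chromosome for
whole genomes).

## Synthetic data

`poolsweep.simulate` emits pileups whose generative process *is* the
likelihood model: true count `j` per site from a governing spectrum
(neutral, or sweep-transformed inside declared blocks), Poisson coverage,
reads derived with probability `j/n`, phred-governed uniform miscalls, and an
optional probability of recording the derived allele as the reference
(ancestral misspecification). Defaults state the world the package targets: a
pool of `n = 20` chromosomes at 20x with Q30 bases, neutral background with
`theta = 0.028` — the Watterson value implied by ~10% of sites segregating in
a diverse wild pool of this size. Because the simulator matches the model,
green recovery tests establish estimator correctness, *not* robustness to
real-data violations: no mapping artifacts, indels, read fragments, coverage
autocorrelation, base-quality miscalibration, or unequal DNA amounts among
pooled individuals (the last is deliberately outside the model).

## Numerical and design choices

- All coordinates 1-based inclusive (pileup and GTF native conventions).
- Quality encoding defaults to offset 33, overridable to 64; never inferred.
- The mapping-quality character after `^` is discarded; the model uses base
  qualities only. An optional `--min-quality` floor exists but defaults to
  off — the method's point is continuous weighting, not thresholding.
- GTF feature filtering merges overlapping intervals of the requested type
  before testing membership; an unknown feature type errors with the list of
  types present.
- Spectrum files: whitespace-separated probabilities, `#` comments; vectors
  must sum to 1 within 1e-6 and are renormalized exactly on read.
- Folding averages the two orientations (`- log 2`) instead of summing: the
  constant cancels in posteriors and EM, but keeping likelihood scales
  comparable between folded and unfolded runs aids debugging; fixed for
  reproducibility.
- EM ties, Viterbi ties, and allele ties all have fixed deterministic rules
  (smaller class / earlier state / base order) so repeated runs agree bitwise.

## Known limitations

- The EM spectrum bias under diverse backgrounds described above.
- With very small per-site switch probabilities (e.g. `k = 1e-10`, the scale
  used for real whole-chromosome scans), entering the Selection state costs
  `4|ln q|` nats of emission evidence; short or weak sweep windows below that
  evidence threshold are invisible to the Viterbi path even when the
  forward-backward posterior rises locally. This is inherent to the model's
  sensitivity/specificity dial, not an implementation artifact: the brute
  force path-enumeration oracle tests confirm the decoding is exact.
- Indels, structural variation, and more than two alleles per site are
  outside the model; third-allele reads are treated as errors.
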