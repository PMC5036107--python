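# Methods

## The model

Pooled somatic SNVs from many cancer genomes are reduced to per-site hit
counts. Within one genomic fraction and one trinucleotide context holding
`l` sites and `m` SNVs, the null of no site-to-site rate variation makes
the number of sites hit `x` times Poisson:

    P(x) = l * exp(-mu) * mu^x / x!,   mu = m / l.

Contexts are the 32 classes obtained by collapsing the 64 possible 3-mers
under reverse complementation to a pyrimidine (C/T) centre; this absorbs
the dominant, flanking-base component of mutation-rate variation (most
visibly CpG hypermutation) before any inference about *cryptic* variation
is attempted. The genome-wide expectation is the sum of the per-context
expectations, and the observed spectrum is compared to it with a chi-square
goodness-of-fit statistic. Sites hit 3 or more times are called *excess
sites*.

Two families of alternatives quantify residual variation:

* **Gamma-Poisson** (1a, 1b): the per-site rate is `mu * alpha`,
  `alpha ~ Gamma(mean 1, shape k)`; marginally the count is negative
  binomial with mean `mu` and size `k`, zero class `(k/(k+mu))^k`.
* **Two-process** (2a, 2b): rate `mu * (eps + (1-eps) * alpha)` — a
  constant process carrying a fraction `eps` of the SNVs plus a
  gamma-variable process carrying the rest. Marginally the count is the
  convolution of Poisson(`mu*eps`) with the negative binomial of mean
  `mu*(1-eps)` and size `k`. `eps = 1` recovers Poisson, `eps = 0` the
  gamma-Poisson family. The scientific reading: the constant process is
  mutation, the variable one sequencing/processing error concentrated on a
  tiny set of sites.

The 'a' variants share one parameter set across contexts (2 resp. 3
parameters); the 'b' variants estimate per-context parameters (64 resp. 96
over 32 contexts). The likelihood of a spectrum treats each cell count
`n_x` as Poisson around the model expectation `l * pmf(x)` and multiplies
across cells and contexts; nested models are compared by likelihood-ratio
tests with df equal to the parameter-count difference.

## Numerical choices

* Both mixture pmfs are evaluated through closed forms in log space
  (negative binomial via `gammaln`; the two-process pmf as a log-space
  convolution). Adaptive quadrature of the defining integrals is retained
  only as a test oracle, using the substitution `u = alpha^k`, which
  removes the `alpha^(k-1)` endpoint singularity exactly — direct
  quadrature of a gamma with shape ~1e-4 is hopeless, the closed forms are
  not.
* Optimisation is Nelder–Mead in transformed space (`log mu`, `log k`,
  `logit eps`), from 5 (configurable) jittered starts around moment-based
  initial values (`mu0 = m/l`; `k0` from the method-of-moments
  overdispersion, clipped to [1e-6, 1e4]; `eps0 = 0.95`), convergence
  tolerance 1e-8 on the log-likelihood. Per-context models are fitted
  context-by-context, which is exact because the likelihood factorises.
* Expected counts are floored at 1e-300 inside the log-likelihood so that
  underflow does not masquerade as impossibility; an exactly-zero
  expectation with a positive observation still returns -inf.
* Chi-square pooling: all upper-tail cells with individual expectation
  below 5 (configurable) are pooled into a single tail cell. The pooled
  tail may retain a small expectation — deliberately, since that cell is
  what carries the extreme-recurrence signal; df = cells - 1 with no
  deduction for the plug-in means.
* LRT boundary caveat: `eps` on [0,1] and `k > 0` put several null
  hypotheses on the parameter boundary, where the chi-square reference is
  conservative. p-values are reported as computed; the calibration tests
  bound the realised type-I error empirically (~alpha/2 for the 1a-vs-2a
  test) instead of pretending the nominal level is exact.
* Fisher heterogeneity test: exact enumeration of fixed-margin 2×C tables
  up to a work bound (2e6 table cells visited), otherwise seeded Monte
  Carlo via sequential hypergeometric column filling (the `r2dtable`
  construction), with the table's conditional probability as extremity
  statistic and an add-one p estimator. Margins are the raw per-lab SNV
  totals, not cohort sizes; this is surfaced in the report.
* Mappability counts k-mer occurrences exactly (dictionary over all valid
  start positions), by default matching either strand, with palindromes
  counted once. The default site rule scores the k-mer *starting* at the
  base; an "any covering k-mer" rule is available behind a flag because the
  two conventions change counts.
* Coordinates: interval files are BED (0-based half-open), SNV positions
  VCF-style 1-based; conversions are confined to `genome_context`.
  Fraction precedence when masks overlap: SSR excludes first, then exon,
  then TE, remainder NTE — so "TE" is non-exonic by construction.
  Positions at contig edges or with N in the 3-mer are skipped and
  reported, never imputed.

## The synthetic generator

`synthetic_data` draws a random genome (i.i.d. bases, GC 0.41) with a tiled
mask layout approximating the human proportions (48% TE, 4% exon, 3% SSR),
then per censusable site draws constant-process hits ~ Poisson(`mu_i*eps`)
and variable-process hits ~ Poisson(`mu_i*(1-eps)*alpha`) with one
`alpha ~ Gamma(mean 1, k)` per site — the variable rate is a *site*
property, matching the model. Defaults are the study-scale conditions:
`mu = 1.2e-3` (3.3M SNVs over 2.8 Gb of interrogable genome), `eps = 0.96`,
`k = 3e-4`, 507 samples split 3:1 across two labs, with a CpG-context rate
boost of 8 as the dominant context effect. Hits at a site go to distinct
samples (a genome carries one call per site); demanded hits beyond the
sample count are truncated and reported.

Optional artefact structure: planted duplicated segments (exact copies give
mappability 1/2; diverged copies seed collapsed-duplication pseudo-SNVs at
the source locus, Poisson intensity 4 per divergence position, emulating
reads from the copy mis-assigned to the original), and lab-private error
sites whose SNVs all come from one lab's samples (default 4 hits each).

What the generator does *not* emulate: read-level errors and chemistry
profiles, alignment with mismatches, large-scale (Mb) mutation-rate waves,
multi-nucleotide mutations, driver selection. Passing recovery tests
therefore demonstrates that the inference machinery is correct under its
own assumptions at realistic parameter values — not that those assumptions
hold in any particular real call set.

`simulate_spectra` additionally draws per-context recurrence spectra
directly at the site level (no genome), which is how the parameter-recovery
and calibration studies reach 32 × 10^7 sites in seconds.

## Problem sizes and tolerances used in the checks

Bookkeeping identities (SNV totals, excess counts, fold ratios, reduction
percentages) are exact integer/rounding arithmetic on the bundled published
tallies. Oracle equivalence of the closed forms against quadrature is
asserted at 1e-8 absolute over ~160 parameter points. Parameter recovery
simulates model 2a at 32 contexts × 10^7 sites (one fixed seed) and
requires `eps` within ±0.02 and `k` within a factor of 3; repeat simulation
at 10^6 sites per context shows seed-to-seed spread in `eps` of about the
tolerance itself, so the tenfold larger size keeps the check meaningful
rather than marginal. Null calibration uses 200 replicates each for
the excess test (Poisson truth, l = 1e5, mu = 0.1) and the 1a-vs-2a LRT
(gamma-Poisson truth, interior shape k = 1, l = 3e4), requiring the
rejection rate within 3 binomial SE of alpha = 0.05; both tests sit
slightly below nominal (plug-in means; boundary null), inside the band.
Mappability tracks are checked position-by-position against independent
find-scan counting on 3 kb random genomes for k in {4, 20, 100}. The
truncated pmf-normalisation checks account for the exact negative-binomial
tail mass, which at shape 1e-5 is ~3e-5 beyond x = 200 and cannot be pushed
below 1e-6 by any truncation.

## Known limitations

* Exact Fisher enumeration is exponential in the number of columns; real
  2×30 excess-site tables go through the Monte-Carlo path (1e6 draws by
  default, SE reported).
* Mappability counting is exact-match only; mismatch-tolerant alignability
  (the regime of real read mappers) is out of scope, and the start-position
  scoring convention means a base inside a non-unique k-mer can still score
  1 — both conventions are documented and the alternative rule is provided.
* Model-comparison preference walks the nesting lattice (1a → {1b, 2a} →
  2b) with pairwise LRTs at alpha = 0.05; 1b and 2a are not nested in each
  other and are never compared directly.
* The shared-parameter models assume one (mu, k, eps) across contexts; with
  strong context effects (CpG) the shared-mu assumption is knowingly wrong
  and model 2b exists precisely to relax it.
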