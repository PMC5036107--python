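# recurrency

Some genomic positions are hit by somatic single-nucleotide variants (SNVs)
again and again across independent cancer genomes. A recurrently hit site may
be a positively selected driver, a cryptically hypermutable position, or a
systematic sequencing/mapping artefact. `recurrency` implements a complete,
testable pipeline for telling these apart in a pooled pan-cancer SNV call
set:

1. **Context-aware Poisson expectation.** After excluding simple sequence
   repeats, the genome is split into non-exonic transposable-element (TE),
   non-exonic non-TE (NTE) and exonic (EX) fractions, and every position is
   assigned one of 32 pyrimidine-centred trinucleotide contexts. With
   *l<sub>i</sub>* sites of context *i* carrying *m<sub>i</sub>* SNVs, the
   expected number of sites hit *x* times is
   *P<sub>i</sub>(x) = l<sub>i</sub> e<sup>−μ<sub>i</sub></sup> μ<sub>i</sub><sup>x</sup>/x!*
   with *μ<sub>i</sub> = m<sub>i</sub>/l<sub>i</sub>*, summed over contexts.
   Departures are tested with a chi-square goodness-of-fit statistic; sites
   hit ≥ 3 times are *excess sites*.

2. **Mixture models of rate variation.** Four nested models are fitted to
   the recurrence spectra by maximum likelihood (Nelder–Mead, multi-start):
   a gamma-Poisson model in which the per-site rate is *μα* with
   *α* ~ Gamma(mean 1, shape *k*) (models 1a/1b), and a two-process model in
   which a constant process carries a fraction *ε* of the rate and a
   gamma-variable process the rest, rate *μ(ε + (1−ε)α)* (models 2a/2b).
   The 'b' variants give every context its own parameters (N = 64 / 96
   parameters over 32 contexts); the spectrum likelihood treats each cell
   count as Poisson-distributed around the model expectation, and nested
   fits are compared by likelihood-ratio tests.

3. **Mappability stratification.** Exact k-mer occurrence counting assigns
   every position the score 1/occurrences (1 = uniquely mappable at length
   k, with k = 100 and 20 by default). Re-censusing on the uniquely
   mappable subset shows how much of the recurrence excess lives in
   duplicated sequence.

4. **Privacy (lab-heterogeneity) testing.** For a cancer type sequenced by
   two laboratories, SNVs at excess sites form a 2 × C lab-by-site table;
   Fisher's exact test (exact enumeration, or seeded fixed-margin Monte
   Carlo for large tables) asks whether recurrent calls cluster within one
   lab — the signature of a pipeline artefact rather than hypermutation.

A synthetic-data module generates genomes, masks, duplicated segments and
SNV tables with exactly this generative structure (including lab-private
error sites and collapsed-duplication pseudo-SNVs), providing ground truth
for every stage.

## Worked example

Simulate a 60 kb toy study and run the full pipeline:

```bash
recurrency simulate --seed 77 --genome-length 60000 --out sim/
recurrency run --fasta sim/genome.fa --snvs sim/snvs.tsv \
  --ssr sim/ssr.bed --te sim/te.bed --exon sim/exon.bed \
  --out analysis/ --seed 5
```

or, from Python, fit the two-process model to spectra simulated at study
scale (32 contexts × 10⁷ sites, μ = 1.2×10⁻³, ε = 0.96, shape 3×10⁻⁴):

```python
from recurrency import simulate_spectra, fit_model

spectra = simulate_spectra(10_000_000, 1.2e-3, 3e-4, 0.96, n_contexts=32, seed=5)
fit = fit_model(spectra, "2a", n_starts=5, seed=1)
print(f"eps = {fit.median_eps:.3f}  shape = {fit.median_shape:.2e}  "
      f"logL = {fit.log_likelihood:.1f}  N = {fit.n_params}")
```

This prints

```
eps = 0.958  shape = 3.44e-04  logL = -668.6  N = 3
```

i.e. the refit recovers the constant-process share ε (0.958 vs the true
0.96) and the gamma shape within ~15%, with the model's 3 parameters — the
parameter-recovery behaviour the analysis relies on. With shape this small
the gamma law is extremely skewed: over 99.99% of sites draw an effectively
zero variable-process rate, while a few sites have rates thousands of folds
above average — which is why a small error share (1 − ε ≈ 4% of SNVs) can
generate sites hit 5–7 times.

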