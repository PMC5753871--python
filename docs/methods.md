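# Methods

## Model

An ancient panel of `m` diploids is modeled as a sample from a
population that split from the modern population's lineage and then
evolved in isolation under pure genetic drift (no mutation or selection
on the timescales considered).  Time is measured in diffusion units per
branch: `t1 = tau1 / (2 Ne1)` for the modern branch and
`t2 = tau2 / (2 Ne2)` for the ancient branch, where `tau` are branch
lengths in generations and `Ne` diploid effective sizes.  `t2 = 0` is
population continuity: the sampled population sits directly on the
modern lineage.

All inference conditions on the modern derived-allele frequency
`x in (0,1)` of each SNP, treated as known.  This conditioning is what
makes the likelihood insensitive to how the SNPs were ascertained, at
the price of discarding sites fixed in the modern population (they are
filtered out, with counts logged).

### Moments instead of densities

The likelihood needs, for each site, the distribution of the derived
count `k` among `n = 2m` sampled ancient chromosomes given `x`.  This is
fully determined by the binomial moments
`p_{n,k} = E[Y^k (1-Y)^{n-k} | X=x]` of the unobserved ancient frequency
`Y`.  The moment vector solves linear ODEs with tridiagonal generators,
so it is computed as

    p(t1, t2) = expm(Q t2) @ expm(Q_down t1) @ h_n(x)

with `h_n(x)_k = x^k (1-x)^{n-k}`.  Row `i` of the forward generator `Q`
is `(i(i-1)/2, -i(n-i), (n-i)(n-i-1)/2)` on the three central diagonals
— the coefficients the Wright-Fisher diffusion generator produces on the
monomial basis — and the backward generator `Q_down` has diagonal
`-i(n-i+1)` and super-diagonal `(n-i+1)(n-i)/2`.  Vector entries are
indexed by the derived count `k` (stated explicitly because the
convention is easy to get backwards).  Probabilistically, `Q_down`
propagates the *posterior* of the ancestral frequency given `x` under a
neutral derived-allele prior with density proportional to `1/z`; we
verified this interpretation against a discrete Wright-Fisher grid
computation before adopting it for the simulation engine (posterior
means match `x e^{-t1}` and order-2 moments match the exponentials to
numerical precision at moderate `x`).

The exponentials use dense scaling-and-squaring (`scipy.linalg.expm`) on
the small `(n+1)^2` matrices rather than eigendecomposition: `Q_down` is
non-normal and eigenvector-based routes are fragile.  Round-off can
leave tiny negative entries; these are clamped to zero and the vector is
renormalized only when the binomial-weighted sum is within 1e-6 of 1 —
otherwise a `NumericalError` is raised, so a silently broken
exponentiation can never pass downstream.  Both exponentials are cached
per distinct order and invalidated whenever `(t1, t2)` changes, making
the cached and uncached paths bit-identical.

### Read model

Given genotype `g in {0,1,2}`, the read counts `(a, d)` of an individual
at a site are binomial with derived-read probability `eps`, `1/2`, or
`1 - eps`; the symmetric error rate `eps` absorbs sequencing error and
postmortem damage jointly (a separate damage parameter is deliberately
out of scope — it is known not to improve this class of inference).  A
panel collapses to count weights

    W_k = sum over genotype vectors with sum g_i = k of
          prod_i C(2, g_i) P(R_i | g_i)

computed by convolving the per-individual triplets
`(P(R|0), 2 P(R|1), P(R|2))` in O(m^2) — never by enumerating 3^m
configurations, which the tests use only as an oracle.  No additional
`C(2m, k)` appears in the site likelihood `sum_k W_k p_{2m,k}`: by the
Vandermonde identity, the `C(2, g_i)` products summed over
configurations with total `k` already equal `C(2m, k)`, which is exactly
the factor the sampling probability requires on top of the raw moments.

Two numerical choices matter at high coverage: the per-individual
triplet maximum is factored out before the convolution (the shared
binomial coefficient cancels entirely and only shifts the log scale), so
deep sites cannot underflow; and individuals with zero reads at a site
are dropped with the moment order reduced, which is exact — an uncovered
diploid convolves `(1, 2, 1)` into the weights, and that contraction
composed with the order-`2m+2` moments reproduces the order-`2m` value
(tested to 1e-10).  Error rates can be shared across the panel (default;
lowest variance at low coverage) or per-individual.

### Consequences worth knowing

* A site covered by a single read contributes
  `log(eps + (1 - 2 eps) x e^{-t1})`: no `t2` anywhere.  Heterozygosity
  — hence multiple reads per individual, or several individuals — is the
  only source of information about drift in the ancient population.
  Two individuals with one read each *do* carry `t2` information (their
  two chromosomes jointly probe the second moment).
* `t1` and `t2` estimates are negatively correlated across replicates:
  the data pin their sum more tightly than the split.
* Relabeling ancestral/derived alleles (swapping `(a,d)` and mirroring
  `x`) is a symmetry of the forward stage only; the backward stage's
  `1/z` prior distinguishes the derived allele, so the full likelihood
  is intentionally polarization-aware.

## Fitting and testing

The full model maximizes the likelihood over `t1, t2 in [0, 10]` (beyond
10 diffusion units the moments are numerically at fixation) and
`eps in [1e-6, 0.5 - 1e-6]`; the null pins `t2 = 0`.  Optimization runs
a deterministic multi-start bounded Nelder-Mead — default starts are the
grid {0.005, 0.05, 0.5} for each free drift time and {0.001, 0.01} for
`eps` — with a coarse per-start tolerance (1e-3 in lnL), then polishes
the incumbent with L-BFGS-B to 1e-6 in lnL.  Simplex-first is robust to
the flat ridge the likelihood develops along `t2 = 0`; the count of
starts agreeing within 1e-4 is reported, and ties are broken toward the
smallest `t1 + t2`, then the smallest `eps` (parsimony).  Refitting the
same data with the same options is bit-identical.

The continuity LRT is `2 (lnL_full - lnL_null)`, clamped at zero.
Because `t2 = 0` lies on the boundary of the parameter space, the
default p-value uses the 50:50 mixture of a point mass at zero and
chi-square(1); the conventional chi-square(1) p-value is reported
alongside (it is conservative here).  Decision threshold in all
calibration checks: 0.05 on the mixture p-value.

Bootstrap confidence intervals resample sites with replacement (the
likelihood assumes unlinked sites; a block option over consecutive sites
exists for linked data, default block 1), refit the full model per
replicate starting from the full-data MLE (the standard warm start), and
report 2.5/97.5 percentiles.  Failed replicates are dropped and counted;
more than 10% failures aborts.

## Synthetic data

Two generators with very different logic protect against circular
validation:

* **model-exact** — draws `k ~ P_{2m,k}(x)` from the same moments the
  likelihood uses, distributes the `k` derived alleles uniformly over
  chromosome slots, and pairs them into diploids.  Modern frequencies
  come from a truncated neutral `1/x` spectrum by default (uniform
  available), bounded away from 0 and 1 as a finite modern panel of 100
  diploids would enforce.
* **wright_fisher** — a discrete forward simulation: standing variation
  with a `1/z` spectrum at the oldest epoch plus new mutations injected
  every generation (rate proportional to each branch's `Ne`, entering at
  frequency `1/(2 Ne)`), so the frequency spectrum stays at neutral
  mutation-drift equilibrium at every epoch — the regime the model's
  backward stage assumes, and the one a coalescent simulator with
  mutation provides implicitly.  Binomial resampling per generation;
  sites are emitted conditional on segregating in the modern population.

Reads are Poisson in depth with mean the nominal coverage; each read is
a contaminant with probability `c` (then derived with probability the
modern frequency `x`), otherwise it samples one of its individual's
chromosomes, and the observed allele flips with probability `eps`
(default simulated `eps` 0.01, a typical post-filtering aDNA error
scale).  Admixture scenarios run on the Wright-Fisher engine only:
secondary contact pulses a fraction `f` from the ancient lineage into
the modern population 200 generations before present (after the default
sample's death), ghost admixture splits an outgroup 800 generations ago
(0.04 units) and pulses it into the modern population 200 generations
ago; pulses are one-generation binomial mixing of allele frequencies.

What the simulations do *not* emulate: linkage (sites are independent by
construction, so bootstrap calibration on simulated data says nothing
about linked real data), fragment-length and damage-pattern structure
(error is symmetric and site-independent), finite-panel noise in the
modern frequencies (x is the true population frequency), and
non-equilibrium modern demography.  Passing tests therefore demonstrate
correctness of the inference machinery under the model's own sampling
assumptions plus the stated violations, not robustness to everything
real data can do.

## Validation design and problem sizes

The test suite checks, at desk scale:

* exact drift-time conversions (400 gen at Ne 10,000 -> 0.02; 100 gen at
  Ne 1,000 -> 0.05);
* parameter recovery under the benchmark design — 20 replicates of 5
  diploids at 4x over ~20,000 segregating sites recover both mean drift
  times within 10%;
* the sampling-design ordering: RMSE of `t2_hat` for two diploids at
  0.5x beats one diploid at 2x (20 replicates each);
* LRT calibration: rejection rate at or below 0.05 (plus binomial CI)
  over 200 continuity replicates (one diploid at 2x, 5,000 sites), and
  rejection in at least 95% of 20 replicates for 5 diploids at 0.5x with
  the benchmark sample age;
* secondary-contact linearity: mean `t2_hat` within 15% of
  `(1 - f) 0.05` for `f in {0.1, 0.25, 0.5}` (6 replicates per `f`,
  10,000 sites, 5 diploids at 1x), and mean estimates non-increasing in
  contamination over `c in {0, 0.05, 0.1, 0.2}`;
* computational oracles: the convolution against 3^m enumeration, moment
  normalization, forward-stage moments against a discrete Wright-Fisher
  Monte Carlo (Ne 1,000, 200,000 replicates, 3 SE), single-read
  invariance in `t2`, and exact marginalization of uncovered
  individuals.

Replicate-loop fits thin the optimizer start grid to {0.01, 0.1} per
drift time (one `eps` start) through the public options — well-identified
simulated data do not need the full exploration grid — while the
acceptance script uses the package defaults.  The two generators are
cross-validated by fitting datasets from each at the same demography and
requiring the mean estimates to agree within Monte-Carlo error.

## Preparing inputs from alignments

The package deliberately takes ancestral/derived *read counts*, not
BAMs: polarization and allele matching live upstream, keeping the tool
format-agnostic and desk-testable.  A typical route from an indexed BAM
and a site list:

    samtools mpileup -B -q 30 -Q 30 -l sites.bed sample.bam

then, per site, count pileup bases matching the ancestral and the
derived allele from the frequency table (third alleles can be counted as
errors or the site dropped — either is consistent with the symmetric
error model, and the filter counts make the choice auditable).  One row
per site and individual goes into the read-count table
(`chrom pos ind n_anc n_der`, 1-based positions).  Modern frequencies
come from any source that reports derived-allele frequencies for the
same polarization, e.g. `bcftools +fill-tags` output via the VCF route.

## Known limitations

* One ancient panel at a time; no joint admixture-graph inference.
* Modern frequencies are treated as exact; very small modern reference
  panels would add noise the model ignores.
* The error model is symmetric and shared across read positions; heavily
  damaged, unfiltered data may want damage-aware preprocessing upstream.
* Under strong model violations (large contamination, large admixture)
  the estimates shift smoothly rather than failing loudly — by design,
  since those shifts are themselves the quantities of interest in the
  misspecification studies — so contamination should be controlled or
  estimated upstream.
* At `f = 1` secondary contact (complete replacement), `t2_hat`
  collapses toward zero but retains a small positive residual in the
  Wright-Fisher validation engine: a population-size change along the
  lineage keeps the site-frequency spectrum slightly off equilibrium,
  which the model reads as a little extra drift.
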