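# Methods

## Model

Two non-recombining loci, A and B, sit on one chromosome with
population-scaled recombination rate ρ = 4Nₑr between them (r the
per-generation recombination probability, Nₑ the diploid effective size).
Each locus mutates under the infinite-sites model at rate θ/2 per lineage per
coalescent time unit, θ = 4NₑμL for a locus of L basepairs.  Time is measured
in units of 2Nₑ generations unless a demography is supplied, in which case
everything runs in generations.  One haplotype is sampled at the present and
one at age tₐ (the panel simulator allows arbitrary per-haplotype ages).

Looking backwards from the present, the process has two phases.  Before tₐ
only the modern haplotype's ancestry evolves; its material at the two loci is
either *coupled* (one ancestral chromosome) or *uncoupled*, a two-state
continuous-time chain with split rate ρ/2 and re-join rate 1.  The closed
forms in `stratld.theory` marginalise over the phase-1 state at tₐ and reuse
classical contemporaneous two-locus moments for phase 2.  Key identities used
(and verified in the test suite):

* the uncoupling probability equals entry (0, 1) of exp(Q·tₐ) with
  Q = [[−ρ/2, ρ/2], [1, −1]] — a matrix-exponential implementation serves as
  the in-package oracle at 1e−10 relative tolerance;
* Corr(L_A, L_B) at tₐ = 0 equals (ρ+18)/(ρ²+13ρ+18), and the
  tₐ → ∞ limit is the algebraic limit (8ρ+36)/(ρ³+15ρ²+44ρ+36) of the exact
  form;
* σₜ² at t = 0 reduces exactly to σ_d² = (ρ+10)/(ρ²+13ρ+22), because
  ρ³+15ρ²+48ρ+44 = (ρ+2)(ρ²+13ρ+22).  The denominator grouping of the σₜ²
  expression was fixed by requiring this reduction to hold identically; it is
  asserted to 1e−12 over ρ ∈ [0, 1000].

The time argument of σₜ² is interpreted on the same 2Nₑ-generation scale as
every other time in the package.

A caveat on quoted asymptotics: the large-ρ form 1 − e^{−tₐ/2} of the
uncoupling probability approaches the exact expression only where both are
near 1 (large tₐ); the true ρ → ∞ limit at fixed tₐ is ρ/(ρ+2) → 1.  The
small-argument form tₐρ/2 is first-order accurate in tₐ(ρ/2+1), so its
validity requires that product — not merely tₐρ — to be small.  Tests check
both limits inside their actual domains of validity.

## Simulators

Both engines are exact Gillespie simulations — exponential waiting times and
categorical event draws, no time discretisation — so oracle comparisons are
meaningful at Monte-Carlo precision.

**Pair engine.**  For two haplotypes the lineage configurations form a small
state machine: {2 coupled}, {1 coupled + 2 uncoupled}, {4 uncoupled},
and the two one-locus-open states after a marginal MRCA.  Coalescence events
occur at rate 1 per unordered lineage pair (all admissible merges equally
likely; an A-only with a B-only lineage merges into a coupled lineage) and
each coupled lineage splits at rate ρ/2.  The engine is vectorised across
replicates with a masked event loop; one seeded numpy Generator drives an
entire call, so identical `(seed, n_reps)` reproduce bit-for-bit.  Per-
replicate derived streams were considered and rejected: the package has no
parallel execution path, and a single stream keeps the vectorised loop
simple and ~1000× faster than per-replicate Python.

In demography mode the same machine runs in generations with pair-coalescence
hazard 1/(2Nₑ(t)) and per-coupled-lineage recombination hazard r.  Epoch
boundaries are handled exactly by the memoryless property: a waiting time
crossing a boundary moves the replicate to the boundary and redraws under the
new rates, which is an exact inverse-CDF rescaling, not an Euler step.

**Panel engine.**  For n haplotypes, each lineage carries bitmasks of
descendant haplotypes at both loci.  Ancient lineages activate at their
sampling times.  On each event the affected lineages emit "segments"
(birth time, death time, descendant sets); after a locus reaches its marginal
MRCA, material at that locus is stripped from all live lineages (it can no
longer affect the other locus's genealogy — this preserves the other locus's
marginal law and bounds the state).  Infinite-sites mutations are dropped
afterwards as Poisson(θ/2 × segment length) per locus, assigning the derived
allele to the segment's descendant set; basepair positions are uniform
within a locus (distinct, so the infinite-sites assumption is visible in the
output), map positions are flat within a locus and separated by ρ/(4Nₑ_ref)
Morgans between loci (Nₑ_ref defaults to 10,000, also used to express sample
ages in generations).  A test verifies the panel engine's two-sample
marginal distribution against the pair engine by Kolmogorov–Smirnov, and an
independent coalescent simulator (msprime) cross-checks the branch-length
correlation as a dual route.

## Estimators

**Windowed pairwise differences.**  Windows are 0-based half-open basepair
intervals.  Haploid–haploid comparisons count mismatches; a haploid against
an unphased diploid adds the probability a randomly drawn haplotype differs
(0.5 at heterozygous sites, 1 at opposing homozygotes).  Missing sites
contribute nothing and are excluded from the per-window callable-site count,
which is emitted so users can normalise for coverage themselves; no
mappability machinery is bundled.

**Paired-window correlation.**  For a target distance r, anchors are drawn
uniformly; a direction is drawn at random, falling back to the other
direction if the target leaves the anchor's chromosome span; the partner is
the window on the same chromosome whose midpoint map position is closest to
the target, never the anchor itself.  The per-chromosome rule matters for the
two-locus layout (each simulated replicate is its own two-window chromosome):
it is what makes the direction fallback well defined.  The reported SE is the
asymptotic Pearson form √((1−r²)/(n−2)) — written with the square root,
which some renderings of the formula omit typographically.

**Joint LD (σ̂ₜ²).**  Within each timepoint's sample, D(t) = p_AB − p_A p_B;
for every site pair passing the pooled-MAF filter (minor fraction strictly
above 0.05 by default, pooled over both timepoints) the numerator D(0)D(t)
and denominator p_A(0)(1−p_A(t)) p_B(0)(1−p_B(t)) are accumulated into
log-spaced genetic-distance bins (default 30 bins over (1e−5, 1e−3)
Morgans), and each bin reports the ratio of sums — the convention σ_d²
estimation uses.  Ratio-of-expectations statistics are biased upwards
relative to the closed form under frequency ascertainment; with 200+200
haplotypes and θ = 4 per locus the bias is ~5–17% at t = 0 (largest at large
ρ) and shrinks with t.  The relabeling symmetry of the statistic is exact
for the numerator only; the denominator is symmetric in expectation, so only
the equal-frequency case is exactly invariant under REF/ALT flips.

**Curve comparison.**  Two per-bin curves are compared by an exact two-sided
binomial sign test on the proportion of non-tied bins where one exceeds the
other.

## Copying model

The hidden state is the panel haplotype being copied.  Between sites at map
distance g the chain stays with probability e^{−λg} + (1−e^{−λg})/K and moves
to each other state with probability (1−e^{−λg})/K; emissions match the
copied allele with probability 1−ε.  The initial distribution is uniform —
the exchangeable choice consistent with the transition kernel's stationary
distribution (nothing in the model fixes it otherwise).  Missing query sites
emit 1 (marginalised), which is how sparse pseudohaploid data enter; sites
missing from the panel are dropped before analysis, and inter-site distances
are re-differenced after any filtering so they remain non-negative.

The forward pass is scaled (per-site normalisation, log accumulated), exact
for ε ∈ (0, 0.5) and S up to ~1e5; impossible configurations return −inf
rather than raising.  A brute-force sum over all K^S paths (K·S ≤ 12) pins
the likelihood to 1e−10 relative error in tests.

Estimation maximises the forward log-likelihood in (log λ, logit ε)
coordinates — the nominal box λ ∈ [0, 1e6], ε ∈ [1e−6, 0.5−1e−6] spans nine
decades and is poorly conditioned in natural scale; λ has a floor of 1e−3
per Morgan standing in for the 0 bound.  The joint fit uses L-BFGS-B from a
small deterministic multistart (λ₀ ∈ {10, 100, 1000}); the profile fit holds
ε fixed (default 0.01) and uses bounded Brent-style search in log λ.
Standard errors come from a central finite-difference Hessian (relative step
1e−4 in the transformed coordinates), inverted and delta-method mapped back;
estimates on a bound or a non-positive-definite curvature yield missing SEs
with a flag, never an exception.  Calibration is checked by generative
recovery at the study scale (K = 100, S = 2000 common sites over 0.4
Morgans, λ = 100/Morgan, ε = 0.01): 2-SE coverage of the truth in ≥ 90% of
50 seeded replicates, and joint/profile agreement within 2 SE.

## Synthetic data

The fixture generator emulates the *shape* of real inputs — VCF panels with
phased/haploid/unphased-diploid samples, HapMap-format maps, sampling-age
sidecars — with two content models: (i) copying fixtures draw site
frequencies from a 1/x-weighted density with a strict panel-MAF > 5% filter
(mirroring common-variant ascertainment) and sample the query from the
copying model itself; (ii) two-locus fixtures wrap the panel simulator, so
their statistical content is genuinely coalescent.  The copying fixture's
sites are exchangeable given their frequencies: no LD among panel
haplotypes, no frequency–age structure, no sequencing error or contamination.
Passing recovery tests on it therefore demonstrates correctness of the
likelihood and optimiser, not robustness to real aDNA artifacts; the
age-dependence experiments instead use an external coalescent simulator to
generate panels with genuine genealogical correlation.  All fixtures are
byte-reproducible from (spec, seed) and carry a versioned truth JSON.

Two-locus fixture maps encode the inter-locus distance as globally
cumulative map values across the two artificial contigs (with a large
per-replicate offset); `attach_map(..., cumulative=True)` restores them,
while the default mode treats per-chromosome maps as restarting and inserts
10-Morgan gaps between chromosomes.

## Problem sizes and numerical choices

* Oracle grids: 100,000 replicates per (ρ, tₐ) cell; agreement within 3
  asymptotic SEs in ≥ 15/16 cells (the asymptotic Pearson SE slightly
  understates the sampling SD of correlations for these skewed variables,
  hence the 1-cell allowance).
* Age–decay regression: correlations at 11 ages spanning 0–500 generations;
  50,000 replicates per age in the test suite, 1–16 million per age
  (scaling with Nₑ) in `scripts/acceptance.py` so the fitted slope's SE
  stays near 0.02 — the regression's x-range in coalescent units shrinks as
  1/Nₑ, so unscaled replicate counts leave the largest-Nₑ slope with an SE
  of ~0.2.  The analytic small-age slope −(ρ/2)(ρ+12)/(ρ²+13ρ+18) is
  reported beside every fitted slope; over a finite age range the fitted
  slope is slightly shallower (factor ≈ 1 − (ρ/2+1)T/2 for maximum age T).
* σ̂ₜ² panels: 800 replicates per (ρ, tₐ) cell with common random numbers
  across ages (coupling stabilises the monotone-decay comparison without
  biasing levels).
* σₜ² overflow guard: exponents above 700 return exactly 0 (double
  precision).
* Degenerate inputs: ρ = 0 short-circuits the branch-length correlation to
  (1, 0) — the loci share one genealogy and Pearson SE is undefined at
  r = 1; an all-missing query yields a flat likelihood and an unconverged
  fit rather than an arbitrary estimate.

## Limitations

* Closed forms cover a single panmictic population with at most two sampling
  times for the pair statistics; a two-population divergence scenario is not
  implemented (no closed form is exposed for it, and the simulator does not
  model migration or population splits).
* No more than two loci: there is no ancestral recombination graph, gene
  conversion, or multi-locus LD.
* The copying model is haploid-query only — no diploid Li & Stephens, no
  posterior decoding or imputation output — and genotyping error and
  coverage are not modelled anywhere; the 0.5/1 diploid weighting and the
  missing-site marginalisation are the only concessions to aDNA data quality.
* σ̂ₜ² inherits the known low-frequency fragility of ratio-of-expectations
  LD statistics; the pooled-MAF filter is a mitigation, not a fix.
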