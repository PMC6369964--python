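# Methods

## Polarization and the βDAF profile

Each GWAS record carries an effect allele, the other allele, an ancestral
allele, an effect size β, and an effect-allele frequency. If the ancestral
allele equals the non-effect allele the record is already derived-oriented;
if it equals the effect allele, the derived effect is −β at frequency 1−f.
Records whose ancestral state matches neither allele, or whose frequency is
not strictly inside (0, 1), are excluded with counted reasons — the
statistic is undefined for them. Indels and strand-ambiguous (A/T, C/G)
sites are kept by default; an option drops strand-ambiguous sites. No MAF
or imputation-quality filters are imposed at ingest.

Derived alleles are grouped into DAF bins of width y<sub>w</sub> (default
0.01; any exact divisor of 1 is accepted). Bin membership is half-open
(lower, upper], so a DAF exactly on an edge belongs to the lower bin and
every DAF in (0, 1) maps to exactly one bin. Empty bins record β̄ = 0 and
are flagged; they contribute zero to Sβ, which keeps the statistic defined
for sparse data without silently changing the bin count between datasets.
Sβ(fi, fj) sums β̄ over bins inside [fi, fj]; endpoints must lie on bin
edges (an informative error names the nearest valid edges otherwise). The
MAF-restricted variants Sβ(0.01, 0.99) and Sβ(0.05, 0.95) are the same
operation with different endpoints.

## Permutation null

Coordinates follow the two dominant dialects: linkage blocks are 0-based
half-open BED intervals, GWAS positions are 1-based. Variants outside every
block receive singleton blocks (allocated in genomic order, so assignment is
order-independent); a one-variant block is its own exchangeable unit, which
is conservative — it never merges unrelated signals.

The null draws one fair ±1 sign per block (in ascending block-id order, so
results do not depend on file order) and multiplies all effect sizes in the
block by it. This preserves the frequency spectrum and the marginal |β|
distribution exactly. The two-sided empirical p-value is the fraction of
permutations with |statistic| ≥ |observed|, ties counted as extreme (a
small relative tolerance absorbs float jitter between summation orders so
exact sign-flip ties are never undercounted). The default 2000 permutations
give a resolution floor of 1/2000 = 0.0005; a zero count is reported as the
upper bound "<1/n_perm" rather than zero. A (count+1)/(n+1) estimator is
available for downstream consumers that need strictly positive p-values.
Because Sβ is linear in per-block signed sums, its null distribution is
computed as one sign-matrix product; arbitrary statistics take a generic
per-permutation path that consumes the identical sign stream.

## Trait simulator

Individual-based diploid Wright–Fisher dynamics with additive effects and
free recombination between causal sites (each site transmits independently,
Bernoulli(g/2) per gamete). Free recombination matches the downstream
assumption of independent linkage blocks and keeps per-generation cost
linear in sites. Per generation: (1) Poisson(2Nu) new mutations on fresh
sites in random individuals, |β| exponential with scale `effect_scale`
(trait units) and sign positive with probability δ; (2) genetic value = sum
of allelic effects plus the fixed background; phenotype adds
N(0, V_E) noise with V_E = V_G(1−h²)/h² recomputed each generation so h²
stays interpretable across demographic epochs (a flag-free alternative was
rejected because fixed V_E silently changes h² through bottlenecks; if
V_G = 0 a configurable floor of 1e−8 is used and a warning logged);
(3) parents are sampled with probability ∝ exp(−(φ−φo)²/2w²); selection and
environmental noise act on the phenotype, not the genetic value;
(4) fixed sites fold into a constant background (which matters: a fixed
allele moves the whole population relative to the optimum), lost sites are
dropped. `fitness_width=None` disables selection entirely.

The optimum shift Δφ is specified in SDs of the phenotype distribution one
generation before the shift and applied either instantaneously (default) or
as a linear ramp over `shift_duration` generations. Shift time t_s is in
generations before the present; meaningful shifts sit at a modest fraction
of the 2N drift timescale — much older shifts have largely decayed, much
newer ones have not yet moved frequencies.

Mutation rate u is per gamete (haploid genome) per generation, so
θ = 4Nu and the constant-N neutral spectrum E[#sites at derived count i]
= θ/i is the simulator's closed-form oracle.

Demography is a list of epochs (duration, size, optional exponential
growth) preceded by a burn-in of 10N generations at the initial size. A
rescaled European-style history (ancestral expansion, out-of-Africa
bottleneck, European founding with growth) is provided as a preset with
scaling factor Q (default 100): sizes and durations divide by Q, growth
rates multiply by Q, preserving the products N·t and N·r that control
drift. Selection intensity is set directly through w in trait units rather
than rescaled automatically.

An alternative effect rule (Eyre-Walker-style coupling) draws a deleterious
selection coefficient s per mutation (gamma with mean `ew_s_mean`, shape
`ew_s_shape`); the trait effect is sign·|s|^τ·(1+e), e ~ N(0, noise_sd²),
and selection acts multiplicatively through s (log-fitness −s/2 per derived
copy) rather than through the trait.

Two post-processing layers model data imperfections: GWAS estimation noise
β̂ = β + N(0, σ²/(2n·x(1−x))) — the OLS per-variant sampling variance,
largest for rare variants and vanishing with sample size — and ancestral
misorientation, an independent Bernoulli(ε) flip per variant
(β → −β, x → 1−x).

## Inference

The observed data are reduced to Sβ(0.01, x) on a grid (deciles plus 0.99)
after dropping variants with DAF < 0.01 (the variants most exposed to
stratification and ancestral error), scaled by |Sβ(0.01, 0.99)|. The
scaling uses the *magnitude* of the normalizer deliberately: the trait
model is exactly symmetric under jointly flipping δ → 1−δ and Δφ → −Δφ,
which negates every β̄, and a summary scaled by the signed normalizer is
invariant under that mirror map — no amount of data could then identify the
directions of bias and shift, only their relative pairing. Preserving the
curve's overall sign breaks the degeneracy and is what gives the method its
direction-finding power. (The general-purpose
`normalized_sbeta_vector` defaults to signed scaling, whose final element is
exactly 1; inference passes `signed=True`.)

Two numerical safeguards shape the distance. Summary elements are
winsorized at ±5: when a positive shift nearly cancels Sβ(0.01, 0.99) the
normalized curve explodes, and it is the blow-up's presence — not its exact
magnitude, which is pure noise — that carries information. And each
coordinate is scaled by its median absolute deviation across the simulated
pool before the Euclidean distance, so the high-variance low-frequency
coordinates do not drown the informative end of the curve. Both are
switchable off (`summary_clip=None`, `standardize_distance=False`); with
them in place, replicated recovery experiments find the true directions of
δ and Δφ in a clear majority of replicates.

Rejection sampling draws parameters from independent priors — δ ~ U(0.1,
0.9); Δφ ~ U(−2, 2) SD; t_s uniform over a recent-generation window; h² ~
U(0.2, 0.9); mutation rate log-uniform (0.1, 0.5) per gamete (θ between 16
and 80 at the default desk-scale population, playing the polygenicity
role); effect scale log-uniform (0.1, 1.0) — simulates each draw with a
deterministic child seed, summarizes identically, and accepts the fraction
(default 5%) with the smallest distance. Top-fraction
acceptance guarantees a non-empty posterior at any budget; draws whose
simulation yields no usable summary (no variants above the frequency floor,
or |Sβ(0.01, 0.99)| below 1e−12 times the count-weighted mean |β̄|) get
infinite distance and are never accepted. Reruns with the same master seed
reproduce the accepted set exactly.

Diagnostics: `sign_power` measures the fraction of replicate inferences
whose posterior-median signs of δ − 0.5 and Δφ match the truth (magnitudes
are known to be noisy; directions are the robust read-out), and
`posterior_predictive` re-simulates resampled accepted parameters
out-of-sample and reports per-grid-point quantile envelopes.

## Synthetic fixtures

Calibration data emulate the permutation's null: DAFs i.i.d. from the
neutral 1/x density truncated to (0.001, 0.999) (uniform available), and
zero-mean Gaussian effect noise with equicorrelation ρ (default 0.5) within
contiguous blocks — the simplest surrogate for LD-induced correlation of
effect estimates. Generation is a pure function of the configuration. A
fixed 12-variant, 3-block toy dataset with hand-computed bin means backs
worked examples and exhaustive-enumeration tests.

## Problem sizes and what the tests show

Validation experiments run at desk scale: constant populations of 40–150
diploids with 10N burn-in, θ in the tens, effect sizes a few tenths of a
trait SD, 50–200 replicates or fixtures, 400–2000 permutations or
simulation draws. At these sizes the qualitative model signatures (neutral
flatness, θ/i spectrum, negative/decreasing Sβ under bias plus stabilizing
selection, the high-frequency rise after a recent +2 SD shift, direction
recovery by ABC) are resolvable above Monte-Carlo noise in minutes on one
CPU. The fixtures do not emulate genome-scale LD, realistic coordinates,
ascertainment, or stratification, and the simulator omits linkage,
dominance, epistasis, and multi-population history — so passing tests
demonstrate correctness of the statistics and machinery and qualitative
faithfulness of the evolutionary model, not calibration on real GWAS
cohorts.

## Known limitations

- DAF resolution at tiny populations quantizes the profile; bins narrower
  than 1/2N are structurally empty.
- The magnitude posteriors of δ and Δφ shrink toward the prior at small
  simulation budgets; only directions should be interpreted.
- The permutation p-value is conservative at its resolution floor; raise
  n_perm for smaller p.
- Ancestral misorientation is modeled as frequency-independent, whereas
  real misidentification rates rise with allele age.
- At small populations, mutational bias displaces the mean phenotype below
  the optimum enough that the resulting weak directional selection on
  trait-increasing alleles can cancel the bias composition in the highest
  frequency bins; the stabilizing-selection signatures are therefore
  validated in the wide-fitness-function (weak per-allele selection)
  regime, where the bias composition dominates at all frequencies as it
  does for highly polygenic traits.
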