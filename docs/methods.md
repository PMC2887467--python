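# Methods

## The model

A single ~1.5-kb locus in one or more panmictic diploid Wright–Fisher
demes of constant size N with non-overlapping generations.  Three sites
within the locus can carry a resistance mutation; a haplotype's adaptive
state is the 3-bit configuration a₁a₂a₃.  Fitness is multiplicative with
heterozygote fitness 1 + s(h), where s(h) depends only on the number of
resistant alleles: before the environmental shift every resistant
haplotype has s = −s₁ₘ (strong purifying selection); after it, haplotypes
with 1, 2, 3 resistant alleles have s₁ₘ, s₂ₘ, s₃ₘ (default 0.05, 0.1,
0.2 — moderate, semi-additive resistance benefits).

Only one of the three possible nucleotide changes at a resistance site is
resistant, so the adaptive mutation rate per site is μᵤ = μ/3 and
Θᵤ = Θ/3; a mutation hitting an already-resistant site always reverts it.

### Infinite-alleles bookkeeping

Haplotype classes are distinguished exactly as far as the summary
statistics can see.  Every event that changes the adaptive configuration
creates a *new haplotype class* with a unique ID, and so does every event
— even configuration-preserving — on a single-mutation (1m) background,
because the haplotype diversity of 1m alleles is what the soft-sweep
signature measures (a neutral mutation or a recombination on a sweeping
1m haplotype makes a second, distinguishable 1m haplotype).
Configuration-preserving events on other backgrounds merge into their
source class: all fully sensitive haplotypes form one canonical class,
and 2m/3m classes are distinguished only by independent origin.  No
reported statistic (P_1m, P_3m, P_ss, P_c, configuration frequencies,
origin attribution) distinguishes the merged classes, so the ensemble
distributions are unchanged while the class count stays proportional to
the rate of events that matter.

Treating every event as detectable overstates haplotype distinguishability
at most by the locus homozygosity, which the coalescent module estimates
at ~10–12% for Θ_π = 0.5%/site over 1.5 kb — a conservative bias for the
soft-sweep statistics (it can only inflate them in the low-Θ regime where
the claim is that they are absent).

### One generation

Within each deme, in order:

1. **Mutation** — K ~ Poisson(μ·L·2N) events; each picks a count-weighted
   copy (multivariate hypergeometric, i.e. without replacement) and a
   uniform position in [1, L].
2. **Recombination** — K ~ Poisson(ρ·10⁻⁸·L·2N) events; each draws two
   copies and a uniform breakpoint; the single recombinant product takes
   parent A's bits at sites ≤ breakpoint and parent B's above it, and
   replaces one parent-A copy.  Emitting one product rather than two
   reciprocal ones only rescales the effective ρ by ≤2×, which the
   scenario grid sweeps anyway.
3. **Migration** — for every ordered deme pair, Poisson(M) migrant
   individuals contribute two count-weighted source copies each, *added*
   to the destination (the source is unchanged; deme size is restored at
   resampling).  Class identity is global: a migrant copy belongs to the
   same class as its source haplotype.
4. **Resampling** — multinomial(2N, p) with pₕ ∝ xₕ·(1 + s(h)); classes
   that drop to zero copies are pruned, and IDs are never reused.

Runs start from the sensitive class at 100%, burn in for 1000 generations
(ample: the purifying timescale is 1/s₁ₘ = 20 generations), switch
selection schemes, and run a 1500-generation adaptive epoch (~50 years of
pesticide use).  A run may stop early once all three detection flags
below are set, as they are monotone in time.

### Detection flags (per run, on global pooled frequencies)

* **1m** — any of configurations 100/010/001 ever *exceeds* 10%.
* **3m** — configuration 111 ever reaches *at least* 10% (the two
  thresholds deliberately differ in strictness, matching their
  definitions; both are configurable).
* **ss** (soft-sweep signature) — at some generation, two independently
  drawn alleles have > 10% probability of carrying the same 1m
  configuration on *different* classes:
  Σ_c [(Σₕ xₕ)² − Σₕ xₕ²] > 0.1, summed over the three 1m
  configurations (draws with replacement, ordered distinct pairs).
* **c** — conjunction of 3m and ss within the same run (never a product
  of marginals).

Soft-sweep runs are additionally attributed by the origin of the
runner-up class at the first flagging generation: if any event in its
primary-parent origin chain is a recombination, the run counts as
recombination-origin, otherwise as independent-mutation origin.  This is
a bookkeeping-level approximation (the chain does not trace the adaptive
allele itself through recombinant ancestries), adequate for the
qualitative mutation-vs-recombination split; with ρ = 0 it is exact.

## Closed-form theory

With x₀ = 1/(4·N_e·s) the establishment frequency:

* mutation–selection balance density
  g(x) = C·x^(Θᵤ−1)·(1−x)^(Θ−1)·e^(4·N_e·s_d·x), normalized numerically
  over (0, 1) on a log-frequency grid (the mass concentrates at the
  boundary); presence probability = ∫ over [1/(2N_e), 1], absolute
  quadrature tolerance 1e-10.  The back-mutation exponent uses Θ because
  all three changes away from the resistant nucleotide restore
  sensitivity.
* P_sgv = 1 − (1 + s/|s_d|)^(−Θᵤ) — probability that standing resistant
  variation rescues the population after the shift.
* T_e ≈ 1/(Θᵤ·s); logistic trajectory x(t) = x₀/(x₀ + (1−x₀)e^(−st));
  T_f ≈ ln(4·N_e·s)/s; T_w = T_e + T_f.
* Minimal s meeting a deadline: bracketing + Brent on T_w(s) − deadline
  to relative tolerance 1e-6; non-bracketable cases return an explicit
  invalid-result flag, not an exception, so grid sweeps never abort.
* Hard-sweep haplotype diversity: R = L·μ + L·ρ·10⁻⁸;
  T_d ≈ ln((1−d)/d)/s; P_d = 1 − exp(−(R/s)·(1−d)/d), independent of Θ.
  The Box-style asymptotics assume N_e·s·d ≫ 1; results carry an
  `asymptotics_ok` flag (threshold N_e·s·d ≥ 10).  The establishment rate
  behind P_d uses the plain 2s escape probability, a slight overestimate
  when the first haplotype is already common; the refined 2s(1−x₁)
  variant is deliberately not implemented, keeping the printed
  (conservative) form.

**Accuracy.**  The 2s establishment probability and the purely
deterministic sweep phase are O(s) approximations.  Against a single-site
forward oracle at s = 0.2, T_w underestimates the simulated mean time to
50% by ~10–30% (exact Poisson-branching survival is 0.313 vs 2s = 0.4);
the tests therefore hold the theory/simulation ratio inside [0.6, 1.05]
rather than within Monte-Carlo error, and the frozen standing-variation
oracle (10⁴ forward replicates at N = 10⁴, s = 0.1) agrees with P_sgv
within two standard errors.  The diffusion presence probability
overestimates the discrete-copy occupancy at 2N = 2·10⁴ by roughly 2×
(continuum mass near the 1/(2N) boundary); that comparison is held to an
order-of-magnitude band.

## Neutral coalescent

Standard Kingman n-coalescent with piecewise-constant diploid sizes
(exponential waiting times re-drawn at epoch boundaries) and Poisson
mutations on branches; no intra-locus recombination.  For the ~10%
homozygosity figure the no-recombination value 1/(1 + Θ_π·L) differs
negligibly from the with-recombination estimate at this locus scale, and
the claim is order-of-magnitude.  The island-model variant competes
within-deme coalescence against per-lineage migration at rate M/N per
source deme (matching the forward model's Poisson(M) migrant individuals)
and is used for the structured-scenario Θ_π axis only.  msprime serves as
an independent cross-check in the test suite, never as the
implementation.

## Synthetic data

Neutral panels drop coalescent mutations (uniform positions, random
derived states) onto a uniform-random ancestral sequence.  Resistance
panels plant a fixed sensitive state 'A' and resistant state 'G' at each
resistance site on a configurable number of distinct coalescent
backgrounds — the knob that creates or withholds the
one-mutation-on-several-haplotypes structure; a truth table accompanies
every panel and round-trips through the genotyper.  What these panels do
*not* emulate: sequencing error, heterozygous base calls, gaps/alignment
artifacts, and within-codon constraint — so tests passing on them show
estimator correctness, not robustness to real-data noise.

## Desk-scale choices

The forward ensembles keep the study conditions exactly — scheme
(0.05, 0.1, 0.2), μ = 2.5·10⁻⁹, ρ = 0.15 cM/Mbp, burn-in 1000, epoch
1500, Θ → N via 4Nμ (Θ = 0.01 → N = 10⁶, Θ = 1 → N = 10⁸) — because the
sparse class representation makes run-time scale with the event rate
(Θ·L), not with N.  Only ensemble sizes are reduced: 200 replicates per
scenario (~1.6 s/replicate at Θ = 1) instead of 10⁵, so regime contrasts
are asserted as one-sided proportion tests at α = 0.05 rather than as
precise probabilities.  The coalescent homozygosity estimate uses 10⁵
two-lineage replicates; diversity estimates use 2,000–10,000 genealogies.

## Known limitations

* Selection coefficients are constant within an epoch; no dominance
  beyond the multiplicative heterozygote model.
* The structured coalescent is matched to the forward island model only
  through the backward migration rate M/N; for very small deme counts and
  strong structure the two diverge at order 1/N.
* Origin attribution is qualitative (see above).
* Synonymous-divergence estimation would require an outgroup panel and an
  annotated reading frame; only the in-panel estimators are provided.
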