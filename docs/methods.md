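# Methods

## Scope and intent

`foundersim` simulates the first ~10³–10⁴ sexual generations of two
zooplankton populations founded simultaneously from one source, to measure
how founder effects, migration, drift, diapausing egg banks and local
adaptation shape neutral (FST) and selected-locus (FSTQ) differentiation.
It is an individual-frequency (not agent-based) forward simulator: each
population is a vector of real-valued densities or integer egg counts over
the full multilocus genotype space.

## Genetic state

Individuals carry `n` locus pairs; a pair couples a neutral biallelic
marker to a biallelic selected locus at recombination fraction `c`
(`0 ≤ c ≤ 0.5`).  Pairs assort independently; there is no mutation,
dominance or epistasis.  Within a pair, phase matters (cis and trans double
heterozygotes produce different gametes), so a pair has 10 unordered
diplotype states; phase across pairs never affects gamete output under
independent assortment and is not stored.  The genotype space therefore has
`10^n` states with selection and `3^n` without (`s = 0` drops the selected
loci entirely).  All engine operations are table-driven numpy array work
over this space; the same per-pair gamete probabilities back both the
object API (`genetics`) and the vectorized path (`_state`), and a test
pins them together.

Selection is locality-reversed and additive on the clonal growth rate:
allele 1 is favored in locality 1 and allele 0 in locality 2 (a fixed,
documented convention), each allele copy contributing ±δ (days⁻¹), so
`θ_g,l ∈ [−2sδ, +2sδ]` and `θ_g,1 = −θ_g,2`.  Growth rates `r − 2sδ ≤ 0`
are permitted; such genotypes simply decay under the logistic.

## Demography

One sexual generation = hatch → grow → reproduce → bank survival →
migration.  Defaults (changeable per run) describe a rotifer-like
colonizer:

| parameter | meaning | default |
|---|---|---|
| τ | growth season (days) | 60 |
| r | basal clonal growth rate (d⁻¹) | 0.3 |
| K | carrying capacity (individuals) | 2×10⁷ |
| m | sexual proportion | 0.7 |
| sr | sex ratio | 0.5 |
| e | diapausing eggs per sexual female | 3 |
| γ | annual egg survival in sediment | 0.763 |
| λ | annual hatching fraction | 0.046 |
| F | founding eggs per locality | 1 |
| M | migrant eggs per generation each way | 2 |
| n | neutral loci | 5 |
| s | selected loci (0 or n) | 0 |
| δ | additive effect on r (d⁻¹) | 0 |
| c | within-pair recombination | 0.5 |

`K = 2×10⁷` in the reference 200 m² × 1 m pond is 100 individuals/L.

**Growth.**  The coupled logistic `dN_g/dt = N_g r_g (1 − ΣN/K)` shares its
density regulation across genotypes, so every lineage satisfies
`N_g(t) = N_g(0) exp(r_g Φ(t))` with one growth integral
`Φ(t) = ∫₀ᵗ (1 − ΣN/K) dt`.  The engine solves the scalar ODE for Φ
(adaptive Cash–Karp RK45, relative tolerance 10⁻⁸; genotypes grouped by
their ≤ 2s+1 distinct rates), which is exact up to integration tolerance
and independent of the size of the genotype space.  Tests integrate the
full coupled system directly with scipy's RK45 at tight tolerance as an
independent oracle and require 10⁻⁶ relative agreement.  Instances with no
finite attractor (start above K with negative-rate lineages dominating)
raise `GrowthIntegrationError`; the engine never produces them, since
seasons start from hatchling densities far below K.

**Reproduction.**  The new cohort totals `round(ΣN(τ)·m·sr·e)` eggs.  Its
genotype composition is always stochastic: pooled gametic frequencies are
computed over all `4^n` haplotypes (a weight-averaged mixture of per-parent
gamete distributions — gametes from one parent share that parent's
multilocus genotype, so the pool does not factorize across pairs), eggs are
random unions of two pool gametes, and the cohort is one multinomial draw.

**Egg bank.**  Survival γ is age-independent when a bank is modeled; the
no-bank scenario keeps only the current cohort (survivors that fail to
hatch are discarded).  The within-year order is: cohort joins the bank →
survival γ → migration of M eggs each way (drawn multinomially from the
donor's post-survival bank, donor not depleted) → hatching λ of the whole
post-migration bank.  Migrants therefore share the residents' hatching
schedule, and the generation-1 record already includes migrant hatchlings.
Founding eggs bypass λ: foundation is treated as successful establishment,
otherwise a single-egg foundation would almost always fail.

**Stochastic regime.**  When a bank holds ≥ 1,000 eggs, survival and
hatching are deterministic real-valued fractions; below that, each egg is a
binomial trial (counts are integers; if a shrinking bank carries fractional
deterministic-regime counts they are rounded to the nearest egg first).
Egg composition and migrant selection are random at any size.

## Statistics

`FST = (H̄_T − H̄_S)/H̄_T`, computed just after hatching: `H̄_S` averages
`2p(1−p)` over loci within each population and then over the two
populations; `H̄_T` averages over loci the heterozygosity of the pooled
frequency, weighted by census ("total number of alleles"); the ratio is
formed once, after averaging heterozygosities over loci.  In the
deterministic regime frequencies are density-weighted.  The statistic is
NaN (flagged, not zero) when `H̄_T = 0`.  FSTQ is the same functional on the
selected loci.  Rank associations between replicate-level FST and FSTQ use
Kendall's τ and Spearman's ρ.

`time_to_plateau` summarizes a mean trajectory as the first generation
reaching 95% of its plateau, with the plateau estimated as the mean over
the final tenth of the trajectory.

## Experiments and scale

Each replicate draws fresh source allele frequencies uniformly on (0, 1)
per locus (the source is infinite, at Hardy–Weinberg and linkage
equilibrium, with no preadaptation), founds both localities with F
independent HWE draws, and runs Y generations.  Replicates get independent
integer seeds spawned from a master seed, so every run is reproducible and
order-independent.  A locality that loses both plankton and bank ends the
replicate (flagged; excluded from trajectory averages).

Preset grids mirror the published result panels; desk-scale defaults use
10 replicates and 1,000 generations (the original experiments used 50–100
replicates and up to 4,000 generations), with `--full` restoring full
scale.  The migration ladder of the `fig2` preset (0–10⁵) is a
reconstruction: the source panel does not enumerate its ticks.  The
fixation-timing experiments use M = 2 and unlinked pairs (`c = 0.5`); the
recombination rate for those runs was not pinned down by the source
description, and FSTQ timing is insensitive to it.

## Known behaviors and limitations

- **Persistent founder effects** dominate large banked populations: with
  `K = 2×10⁷` the mean FST after 1,000 generations stays at its
  post-foundation level (≈ 1/3 for F = 1) even with 100 migrant eggs per
  generation.
- **Founder-number sampling theory.**  The expected post-foundation value
  of this Nei-style ratio is ≈ `1/(4F−1)` (measured 0.331, 0.138, 0.054,
  0.005 for F = 1, 2, 5, 50), so doubling founders from 1 to 2 divides the
  initial FST by 7/3 ≈ 2.33 — "half" is the large-F approximation
  `1/(4F)`.
- **Adaptive introgression tails.**  Under locality-reversed selection
  with uniform starting frequencies, about one third of population×locus
  pairs fix the locally disfavored allele during founding.  Migrant eggs
  later reintroduce the favored allele; above the 1,000-egg threshold its
  hatching trickle is deterministic, so establishment is near-certain and
  a rescue sweep follows (slower at larger K: the sweep starts from one
  copy in a larger census).  Mean FSTQ trajectories therefore show
  transient dips after the main sweep and approach a plateau of ≈ 1 only
  once all rescues complete, which makes strict plateau-crossing times
  substantially later (and noisier at 10 replicates) than the visually
  flat shoulder of the main sweep.
- The model has no mutation, no inbreeding depression, no environmental
  fluctuation, no metapopulation turnover, exactly two focal localities,
  and no continued input from the source after foundation.  The synthetic
  scenarios are the study conditions themselves; conclusions about real
  populations inherit the model's assumptions (notably deterministic
  within-season growth and the sharp 1,000-egg stochasticity threshold).
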