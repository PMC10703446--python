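# Methods

## Model structure

The simulator tracks a diploid, panmictic, constant-size population of N
individuals described solely by their PRDM9 genotypes. Each segregating
PRDM9 allele carries two site classes: a hotspot class (initial count
n₁ ∈ [1, 5000], dissociation constant k₁) and a weak backdrop
(n₂ = 200,000, k₂ = 8030). Every allele's sites are disjoint from every
other allele's, so a heterozygote runs two independent binding systems
coupled only through the shared DSB pool. Site counts are real-valued,
population-level quantities per allele: erosion is deterministic, and
fixations of cold site alleles are treated as instantaneous. There are no
per-individual site genotypes, no linkage among sites, and no
back-mutation from cold to hot.

### Binding equilibrium

Per binding system, the free-molecule count P_F solves
P_F + Σᵢ 4nᵢ·P_F/(P_F + kᵢ) = dose. The left side is strictly increasing
and concave in P_F, so the root in [0, dose] is unique and Newton
iteration started at zero converges to it monotonically from below; we
iterate to a relative residual of 1e-13 (with a floating-point-noise
stall guard). The chromatid multiplicity (factor 4nᵢ) is applied inside
the solver and nowhere else. For one or two site classes the balance is a
quadratic or cubic, solved algebraically
(`closed_form_free_prdm9`) as an independent oracle; the test suite
cross-validates solver and closed form to 1e-8 relative error on 1000
random instances. A dose of zero returns P_F = 0 and all heats zero (the
continuous limit).

The PRDM9 dose convention: P_T is the total per diploid individual.
Homozygotes run a single system at dose P_T; each allele of a heterozygote
gets P_T/2. This reproduces the required ordering — every heat and P_F is
strictly higher in homozygotes than in heterozygotes for the same allele.
An alternative convention would pool both alleles' molecules into one
competitive system; we solve per-allele systems because the two alleles'
binding sites are disjoint, and molecules of one allele do not occupy the
other's sites.

### DSBs, symmetry and fitness

D DSBs per meiosis are spread uniformly over all bound sites:
c = D/P_B, with P_B summed over the genotype's binding systems. When an
eroded state transiently has P_B < D, c is capped at one and the event is
counted (`cap_generations`) rather than treated as an error; the cap never
engages under the baseline parameters. The symmetric-DSB probability per
site is the model's defining closed form
α = 1 − (1 − cH²(2−H)(2−cH))². This is an approximation: exact enumeration
over the 2⁴ binding configurations of four chromatids (each bound with
probability H, each bound chromatid broken with probability c, success =
both homologs bound and at least one break) gives a smaller value at
interior heats — 0.464844 versus the formula's 0.548584 at H = c = 0.5.
The enumeration (`exact_symmetric_dsb_prob`) is kept as an oracle; the
tests verify that the formula upper-bounds it everywhere with equality at
H ∈ {0, 1} and c = 0. Fitness is the per-meiosis probability of at least
one symmetric DSB on the smallest chromosome, W = 1 − Πᵢ(1−αᵢ)^{r·nᵢ}
(both alleles' classes in heterozygotes), computed in log space so that
large r·n cannot underflow.

### Erosion

Per-meiosis conversion rate g = B·c·H per site; population rates combine
genotype rates at Hardy–Weinberg frequencies built from *post-selection*
allele frequencies (g_i^j = 2f_j Σ_k f_k g_i^{j,k} − f_j² g_i^{j,j});
counts update as n ← n·max(0, 1 − 4Nμg), clipped at zero, for every class
of every segregating allele including the weak backdrop (whose loss is
negligible by construction). Because c·P_B = D when the cap is off, the
total loss per generation is exactly NμBD; the state records the applied
loss (`last_site_loss`) each generation so this identity can be checked
without the catastrophic cancellation of differencing ~2×10⁵-site counts.

### Generation loop

Order of operations: fitness matrix and marginal fitnesses → expected
post-selection frequencies (Eq. f′_j = f_j W_j/W̄) → erosion using f′ →
multinomial sampling of 2N copies → PRDM9 mutation → recording. Erosion
must use post-selection frequencies; mutation comes last so each new
allele enters at exactly 1/(2N). New alleles replace a uniformly chosen
pre-existing gene copy (victims drawn proportional to current counts,
sequentially within a generation); a victim at a single copy exits.
Per generation the record is (mean hotspot count Σf·n₁, population mean
fitness W̄, heterozygosity π = 1 − Σf²). Fitness is computed once per
allele pair per generation from per-allele binding solutions (hom and het
doses); since erosion changes all site counts every generation, no state
is cached across generations.

The initial condition is a single fixed founder allele with n₁ drawn from
the mutational distribution (or `founder_n1`). Summary helpers accept a
`burn_in` argument and exclude the founder, removing initial-condition
dependence; analyses here use a burn-in of roughly one turnover.

## Parameters

| symbol | meaning | default |
|---|---|---|
| N | diploid population size | 10³ (explored 10³–10⁶) |
| μ | hot→cold mutation rate per site per generation | 1.25×10⁻⁷ |
| ν | PRDM9 mutation rate per gamete per generation | 10⁻⁵ |
| D | DSBs per meiosis | 300 |
| P_T | PRDM9 molecules per meiosis (homozygote total) | 5000 |
| B | probability a conversion tract spans the motif | 0.7 |
| r | genome fraction on the smallest chromosome | 1/40 |
| k₁ | hotspot dissociation constant | 50 (strong: 5) |
| k₂, n₂ | weak backdrop | 8030, 200,000 |
| n₁ range | new-allele hotspot count, uniform | 1–5000 |

The backdrop pair (n₂, k₂) makes the weak sites bind 99% of the dose in
the absence of hotspots while contributing almost nothing to symmetric
binding. k₂ is recoverable from the package's own calibration
(`calibrate_dissociation(200000, 5000, 0.99)` → 8030.8). Lower-expression
variants (P_T ∈ {500, 1000, 2500}) are available as presets, as is a
tight unimodal alternative for the new-allele hotspot distribution
(rounded normal, default center 1000 and SD 100, truncated to the n₁
range — the center and spread are this package's choice of a "tight"
distribution dictated by zinc-finger specificity).

`neutral` is a diagnostic switch that forces all genotype fitnesses to 1;
it exists to validate the Wright–Fisher machinery against neutral-drift
expectations (fixation probability 1/2N) and is not a model variant.

## One-heat variants

The single-heat comparisons use the expected-symmetric-DSB formulation
W = 1 − exp(−r·D_eff·H(2−H)): each of the D_eff DSBs lands on a bound
chromatid and is symmetric when the other homolog carries at least one
bound chromatid (probability 1 − (1−H)² = H(2−H)). Under
`fixed_dsb_noncompetitive` (H pinned, D_eff = D) fitness is exactly
constant along the erosion grid, which is the defining property of that
variant; `proportional_dsb` (H pinned, D_eff ∝ n) falls, and
`fixed_dsb_competitive` (H re-solved per n, D_eff = D) rises as sites are
lost. We use this formulation rather than pushing c = D/P_B through the
per-site α formula because the latter leaves a residual dependence of
order (2 − cH) on the site count — a fraction of a percent — that would
blur the exact constancy of the non-competitive variant; the comparison is
qualitative and only the monotonicity/constancy contrasts are meaningful.
The companion symmetric-binding curves report (H(2−H))², the probability
that both homologs carry a bound chromatid, with the dose calibrated so
that 5000 molecules are bound when 20,000 sites are present.

## Landscapes and optima

Two-heat landscapes evaluate homozygote and same-count-heterozygote
fitness on a hotspot grid (default step 10), then refine each argmax by
bounded golden-section search inside the bracketing interval; ties break
toward smaller counts. Invasion susceptibility compares each resident
homozygote against the best achievable challenger heterozygote (maximum
over the challenger's hotspot count, evaluated on the full resident ×
challenger grid). Landscape values are deterministic; at k₁ = 50 the
susceptible region is a single low-n₁ interval, and at k₁ = 5 a second
region appears at high n₁ where saturated binding penalizes homozygotes.

## Summary statistics

Allele-level distributions weight each exited allele by sojourn time ×
mean frequency — the probability of sampling that allele by drawing a
random gene copy from a random generation. Mean turnover time is the
same weighted mean of sojourn times. Right-censored alleles (alive at run
end) are excluded from the final-count distribution and the turnover
estimate; with runs of several turnovers the censoring bias of that
exclusion is small compared to the regime differences of interest.
Initial-count distributions are binned at width 100, final counts at
width 50. Percentiles (interquartile ranges of π and W) use linear
interpolation between order statistics.

## Problem sizes used in the checks

The automated checks run the dynamics at the parameter sets above with
run lengths sized to contain at least five dominant-allele turnovers at
each N (about 4×10⁶ generations at N = 10³ down to 6×10⁴ at N = 10⁶ for
k₁ = 50), and 6000-generation runs at N = 10⁶ for the regime contrasts.
At N = 10⁶, 2Nν = 20 new PRDM9 alleles arise per generation, so exact
monomorphism is unreachable; "fixation" there means an allele's frequency
reaching 0.99. Turnover times measured this way scale as N^(−0.96±0.05)
across N = 10³–10⁵; the small-N/large-N ratio falls short of the ideal
10³ (≈ 400) because the invasion-and-sweep phase of a cycle, unlike the
erosion phase, does not stretch as 1/N.

## What the simulations do and do not show

The generator *is* the study system — there is no external data — so the
tests demonstrate the internal consistency of the model and the
qualitative regime structure (cycling with weak hotspots, balanced
polymorphism with strong hotspots at large N, intermittent chaotic cycles
with strong hotspots at small N). They do not show that real PRDM9
populations occupy any particular regime: the two-heat site distribution
is a caricature of a continuous affinity distribution, every new allele
is assumed to bind a completely novel site set (real alleles overlap),
fitness equals a single-meiosis probability rather than integrating over
gamete pools, and population structure, crossover interference and
chromatin state are all absent. Quantities tied to those simplifications
— absolute turnover times, load, diversity levels — should be read as
order-of-magnitude behavior of the model, not predictions for any
species.
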