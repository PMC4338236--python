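# Methods

## Statistics and windowing

All haplotype statistics are computed in windows containing a fixed number
of SNPs (default 400, stepped by 50), not a fixed physical length: fixed-SNP
windows hold the neutral haplotype-spectrum distribution constant across the
genome, at the cost of a variable physical span. Within a window haplotypes
are grouped by exact identity; a haplotype with missing calls joins a group
whose representative matches it at every site genotyped in both (the
representative is the first member assigned to the group; missing positions
in either sequence act as wildcards), and ties between several matching
groups are broken uniformly at random. This makes the spectrum of a window
with missing data a random variable; every clustering call therefore takes
an explicit seeded generator, and identical (input, seed) pairs reproduce
identical spectra. With the group frequencies p₁ ≥ p₂ ≥ …:

H1 = Σ pᵢ², H12 = H1 + 2p₁p₂, H123 = H12 + 2p₃(p₁+p₂), H2 = H1 − p₁²,
and the softness ratio H2/H1 ∈ [0, 1).

H12 is the detection statistic (responds to both one and several frequent
haplotypes); H2/H1 is the classification statistic and is only meaningful
where H12 is already high, because removing the top haplotype from a
near-neutral spectrum leaves it almost unchanged.

## Significance calibration

The critical value H12ₒ is the 10th-highest H12 among 10 × W neutral
simulations, where W is the number of analysis windows in the scanned
genome — the level at which about one neutral window per genome is expected
to exceed the threshold (a 1-per-genome FDR). Neutral replicates are drawn
from the coalescent (msprime) under the chosen demography, with H12 computed
on the central 400 SNPs of each simulated locus and replicates with fewer
than 400 SNPs discarded.

The production null uses 10⁵-bp loci. Because the statistic depends only on
the genealogy at the scale of the 400-SNP window (~18 kb here), the null is
insensitive to locus length; the test suite checks this directly
(Kolmogorov–Smirnov between nulls from 10⁵-bp and 3×10⁴-bp loci) and its
calibration check therefore simulates 3×10⁴-bp loci, cutting the cost about
five-fold. The suite's 2×10⁴-replicate calibration under the constant
N_e = 10⁶ demography at ρ = 5×10⁻⁷ cM/bp, μ = 10⁻⁹, n = 145 brackets the
extreme (99.992th-percentile) quantile around 0.017.

## Peak calling

Windows with H12 > H12ₒ and local recombination rate ρ ≥ 5×10⁻⁷ cM/bp are
grouped into peaks: a peak is a maximal run of consecutive (adjacent in the
50-SNP-step sequence) unmasked above-threshold windows, represented by its
highest-H12 member. A masked window terminates a run. Positions not covered
by the recombination map return a NaN sentinel that fails every rate
comparison, so unmapped regions are masked by construction.

## Sweep simulator

Sweeps are generated forward in time in a Wright–Fisher population of
N′ = N_e/Q diploids (default N′ = 500), founded from an exact stationary
msprime coalescent sample of all 2N′ haplotypes — this replaces a long
forward burn-in with an exact draw. Per-generation rates are inflated by Q
so that θ = 4N_e μL, ρ_pop = 4N_e r, θ_A = 4N_e μ_A and 2N_e s are
preserved. Meiosis draws a Poisson number of crossovers per transmission;
the adaptive site sits at the locus midpoint and travels with whichever
parental haplotype contributes that point.

Two regimes required care:

* **Strong rescaled selection.** For s′ = sQ ≫ 1 a discrete generation
  cannot represent the corresponding amount of real time, so a naive
  rescaled sweep lasts too many generations and accumulates excess
  recombination and mutation, erasing the hitchhiking signature. The
  simulator caps the per-generation selection coefficient at s_eff =
  min(s′, 1) and multiplies within-sweep recombination and neutral-mutation
  rates by s_eff/s′, preserving events per unit of allele-frequency change —
  the quantity that shapes swept haplotypes. Adaptive mutation follows a
  different invariant: establishing origins per unit frequency change
  (θ_A/x in the target process, where establishment probability 2s cancels
  the sweep speed s), which fixes the within-sweep adaptive rate at
  μ_A · 2 s_eff / p_est(s_eff), with p_est the Poisson-branching
  establishment probability. For s′ ≤ 1 both corrections reduce to the
  identity, and simulations at different Q agree in distribution (checked by
  KS on segregating sites). Residual distortion at s′ ≫ 1 enters only
  through log(N s) terms (e.g. footprint widths biased wide by
  ln(2N_e s)/ln(2N′ s_eff), about 1.3× at s = 0.01); trends in θ_A, s, PF
  and T_E are unaffected.
* **Conditioning.** De novo sweeps are conditioned on success by seeding the
  first origin immediately (the pre-origin waiting time only shuffles a
  stationary neutral population) and restarting from the onset state if all
  adaptive copies are lost. Standing-variant (SGV) sweeps drift a single
  copy neutrally until it first reaches frequency f0 (rejection sampling on
  trajectories, preserving the identity-by-descent structure among
  carriers); each carrier present at selection onset then receives a
  distinct origin label, so origin counts measure distinct haplotype
  backgrounds. Frequencies below 1/(2N′) are represented as a single copy.

Selection is co-dominant (fitnesses 1 : 1+s : 1+2s) and switches off the
first time the adaptive count reaches ⌈PF·2N′⌉. Because a strong rescaled
generation can overshoot PF, the crossing generation is conditioned to land
exactly on the target count by regenerating excess adaptive children from
fitness-weighted non-adaptive transmissions — the forward analogue of
stopping the allele-frequency trajectory at PF. The population then evolves
neutrally for T_E·4N′ generations before n haplotypes are sampled without
replacement.

Validation at the default study conditions (N_e = 10⁶, μ = 10⁻⁹,
ρ = 5×10⁻⁷ cM/bp, n = 145, s = 0.01, PF = 0.5): hard sweeps (θ_A ≤ 0.5)
give mean window H12 ≈ 0.19–0.24 with H2/H1 ≈ 0.04–0.2, softening
monotonically through θ_A = 10 to θ_A = 100; θ_A = 10 sweeps carry ≈ 20–25
distinct origins in a sample of 145, matching the Ewens-formula expectation.
Neutral mode reproduces Watterson's E[S] and pairwise diversity θπ.

The forward machinery supports the constant-size demography; bottleneck and
admixture histories are available for neutral simulation (the admixture
template merges its two source populations into a common ancestor at a
configurable split time — without that merge the model has no stationary
coalescent).

## ABC inference of θ_A

A candidate sweep is summarized by (H12, H2/H1) in its peak window.
Parameters (θ_A, s, PF, T_E) are drawn from uniform priors — θ_A on
[0, 100], s on [0, 1], PF on [0, 1], T_E on [0, 0.001]·4N_e — the local
recombination rate is drawn uniformly within the peak's rate bin, and each
draw is simulated and summarized on the central 400-SNP window; draws
yielding fewer than 400 SNPs are discarded and redrawn. Acceptance uses the
variance-normalized distance

d = √[(H12_obs−H12ᵢ)²/Var(H12) + (H2/H1_obs−H2/H1ᵢ)²/Var(H2/H1)] < 0.1,

with variances estimated from all simulations of the run (a per-component
relative-10% rule is available behind a flag). The MAP is the mode of a
Gaussian KDE (Silverman bandwidth, 512-point grid on the prior support) over
accepted θ_A draws; the credible interval is the empirical 2.5–97.5
percentile range. The fixed-radius rule needs large reference tables when
the observation falls where prior-predictive density is low (e.g. soft,
weakly selected sweeps: P(θ_A ≈ 5, s ≈ 0.01) is ~10⁻³ under these priors);
`posterior_nearest` provides the standard quantile-based variant (accept the
k nearest draws), which the reduced-budget tests use with a shared
1200-simulation table and k = 30.

Bayes factors compare point hypotheses θ_A = 0.01 (hard) against θ_A of 5,
10, 50 or the inferred MAP (soft): BF = (#soft within d < 0.1)/(#hard
within d < 0.1), with variances pooled over both simulation sets. A zero
hard count is reported as a flagged lower bound (BF ≥ #soft) rather than
infinity; zero counts in both sets are flagged undefined.

## LD and iHS comparisons

R² is computed on haplotypes non-missing at both sites, requiring at least
4 complete haplotypes and both sites polymorphic in that subset; decay
profiles pair each 10-kb window's first MAF-passing SNP (frequency within
[0.05, 0.95], bounds inclusive, computed on non-missing calls) with every
other passing SNP in the window, de-duplicating pairs repeated by the 50-bp
window step, and bin by distance (20-bp bins to 300 bp, 150-bp bins
beyond).

iHS is unpolarized: alleles are oriented major/minor, EHH is integrated
trapezoidally over physical distance in both directions and truncated where
it falls below 0.05, and ln(iHH_major/iHH_minor) is standardized to mean 0,
sd 1 within MAF bins of width 0.1. SNPs are dropped, with a recorded
reason, when the MAF filter fails, an allele has fewer than two carriers,
EHH reaches a chromosome end before decaying ("edge"), or the MAF bin is too
small to standardize. Haplotypes with missing data are removed from the
carrier set as the extension reaches them. Enrichment windows tile the
chromosome with non-overlapping 100-kb windows counting |iHS| > 2 SNPs; the
top decile by count is flagged, ties resolved leftmost.

## Problem sizes used by the test suite

Simulation-based tests scale the study down to keep the default suite
desk-scale: sweep-based checks use 5×10⁴-bp loci (3×10⁴ bp where only
origin counts matter) instead of the 10⁵-bp production default, 25–40
replicates per condition, a 1200-simulation shared ABC reference table with
k = 30 nearest-draw acceptance, 150-simulation Bayes-factor reference sets
with 20 test observations, and a 2×10⁴-replicate neutral calibration on
3×10⁴-bp loci. The rescaling-invariance check compares Q = 2500 vs Q = 5000
at s′ ≤ 0.125, inside the regime where generation-wise rescaling is
faithful.

## Known limitations

* Rescaled sweeps with s′ ≫ 1 compress the establishment phase; footprint
  widths are biased wide by a log-ratio factor and very strong selection
  (s ≳ 0.1 at Q = 2000) is represented coarsely.
* Sampling n haplotypes from a rescaled population of 2N′ = 1000 slightly
  distorts low-frequency haplotype counts relative to sampling from 2×10⁶.
* The forward simulator does not implement selection under the bottleneck
  or admixture demographies; neutral simulation supports all three.
* SGV sweeps with f0 ≲ 1/(2N′) collapse to single-copy starts.
* The synthetic data contain no missing calls, sequencing error, or
  inversion structure; tests of the missing-data clustering rules use
  constructed fixtures, so passing simulations say nothing about robustness
  to real-data artifacts like residual heterozygosity beyond the N-handling
  contract itself.
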