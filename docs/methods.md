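# Methods

## The process being modeled

All machinery rests on one stochastic process: the multispecies coalescent
with introgression (MSci) on the species tree ((A,B)T, C)R with a distant
outgroup O and a single introgression edge. Backwards in time, populations
are absorbed into parents on a fixed schedule (A,B → T at τ_T; T,C → R at
τ_R; everything → the ancestral-root population at τ_O; for the ghost
scenario an extra ghost population joins the R-ancestral lineage at τ_G),
and at the introgression time τ_H every lineage present in the recipient
population independently moves to the donor-side population with
probability γ — the lineage-level (ms `-es`-style) semantics, not a
per-locus coin. Two lineages sharing a population coalesce at rate 2/θ per
unit of time, with times in expected substitutions per site and θ = 4Nμ.

The three scenarios differ only in the jump: ghost moves *a*'s lineages
into the ghost population (which rejoins above the sampled root), inflow
moves *b* into C's population, outflow moves *c* into B's population. The
recipient/donor branch must exist at τ_H, so τ_H < τ_T in every scenario.

Everything downstream — the event-driven simulator, the pairwise
coalescent-time densities, and the joint gene-tree density — is generated
from the same population-itinerary tables (`ghostintro.process`), so the
analytic objects are forced by the process rather than transcribed, and the
simulator and densities cross-validate each other (KS tests and exact
topology-probability comparisons in the suite).

## Internal branches and the grid parameterization

The identifiability results depend on the scenario only through the
internal branch of the speciation history, l_T = τ_R − τ_T, and of the
introgressed history l_S:

* ghost: l_S = τ_G − τ_R (b and c may coalesce without a between the
  sampled root and the ghost join);
* inflow: l_S = τ_R − τ_H (b sits in C's population until the root);
* outflow: l_S = τ_T − τ_H. The window closes at τ_T, not τ_R: once A
  joins, all three lineages share population T and exchangeability makes
  each first pair equally likely. This choice is not free — it is the only
  one under which P(ac|b) = [(1−γ)e^{−C_T} + γe^{−C_S}]/3 holds for the
  outflow geometry, and the suite verifies the closed form against exact
  integrals of the joint density and against simulation for all three
  scenarios.

Simulation grids are parameterized in coalescent units (1 CU = θ/2 mutation
units): the sister divergence is anchored 1.5 CU before the present, C2
sets the speciation branch above it, C1 is the introgression time measured
from the present, the ghost join sits 1.5 CU above the sampled root, and
the outgroup 5 CU above the root. Under this construction C_S equals 1.5
(ghost), 1.5 + C2 − C1 (inflow) and 1.5 − C1 (outflow), which reproduces
the qualitative bias pattern of the pattern-ratio γ estimator across the
grid (over-, well- and under-estimation as C_T/C_S crosses 1).

Defaults are the study conditions throughout: θ = 0.036 in every
population, 1000 loci of 1000 bp, one sequence per species, HKY with κ = 1
and equal base frequencies (a transition/transversion ratio of 0.5; κ and
the frequencies are configurable and recorded in the dataset manifest).

## What the generator emulates, and what it does not

The simulator reproduces the two-stage pipeline of coalescent gene trees
followed by i.i.d. HKY sites: no recombination within loci, free
recombination between them, no rate heterogeneity across sites or lineages
(strict clock), no indels or missing data. Gene trees carry *exact* node
ages, so the likelihood fitter sees branch lengths free of estimation
error; passing its tests therefore demonstrates the information content of
topologies-plus-branch-lengths, not robustness to gene-tree estimation
noise — on real data the corresponding step is a sequence-level likelihood
that integrates over gene trees. Two independent simulation paths exist
(an event-driven per-locus simulator and a vectorized trio path used for
large frequency checks); they are tested against each other and against an
external coalescent simulator on matched demographies.

## Site-pattern test

Sites are classified for taxon order (A, B, C, O) with the outgroup state
ancestral: BBAA, ABBA and BABA are the only counted (parsimony-informative
biallelic) patterns; everything else is excluded by construction. Under
every one of the three scenarios f(BABA) is the strictly smallest expected
frequency, and the MSC null equates the two smallest. The test statistic is
therefore the fixed contrast z = (N_ABBA − N_BABA)/SE, one-sided. Fixing
the contrast a priori (rather than selecting the two smallest counts from
the data) is what gives the test its nominal size; a data-selected
orientation doubles the false-positive rate. SE comes from a delete-one
block jackknife with **block = locus**, since sites within a locus share a
genealogy and site-level variances are far too small; with L blocks,
SE² = (L−1)/L · Σ(d_l − d̄)² for per-locus differences d_l. Significant
results are interpreted under the hybrid-speciation reading: the pair
sharing the derived state in the rarest pattern are the parents, the
remaining ingroup taxon the hybrid — hence the invariable "B is the hybrid"
call whatever the true scenario. γ is estimated by the pattern ratio
(N_ABBA − N_BABA)/(N_ABBA + N_BBAA − 2 N_BABA). Multiple tests are combined
with Benjamini–Hochberg (statsmodels) at 5% FDR.

The closed-form pattern frequencies assume infinite sites. At θ = 0.036
multiple hits deflate the γ estimate by ~0.01–0.02 relative to the closed
form (visible only because replicate SEs are tiny); quantitative
theory-versus-sequence comparisons in the suite therefore run at θ = 0.0036
with the same coalescent-unit geometry, where the assumption holds. Power,
misdirection and null-calibration checks stay at θ = 0.036.

## Topology-count fit

Rooted triples are counted after outgroup removal; because the trees are
clock-rooted, rerooting on the outgroup and pruning is implemented as
restriction to the ingroup tips, with the cherry of smallest MRCA age
deciding the topology and the structural topology breaking exact ties. The
multinomial likelihood is profiled over a γ grid, maximizing over
(C_T, C_S) ∈ [0, 50]² (50 CU stands in for infinity; the closed-form
saturated optimum is used where attainable, Nelder–Mead on (e^{−C_T},
e^{−C_S}) otherwise). The flat region is reported as the plug-in interval
(p̂₂ − p̂₃, 1 − (p̂₁ − p̂₃)) when the observed frequencies are attainable,
and is read off the profile grid otherwise (degenerate counts with
p̂₃ > p̂₂ pin C_S = 0 and still produce a boundary ridge). Because the MLE
is set-valued, a "point estimate" is a uniform draw from the flat region —
deliberately emulating the arbitrary output of pseudo-likelihood network
searches. The scenario label never enters this likelihood; the per-label
maximizations exist only to exhibit that fact.

## Gene-tree likelihood fit

The per-locus likelihood is the exact joint density of (topology, first and
second coalescence ages) for one sequence per species: a two-component
mixture over the recipient lineage's path, each component a product of
piecewise-constant hazards determined by the population itineraries.
Evaluation is vectorized over loci and done in log space with half-open
[start, end) interval conventions.

Maximization uses Nelder–Mead on log-gap/log-θ/logit-γ transformed
parameters — divergence times are support boundaries, so the likelihood is
only piecewise-smooth and derivative-based optimizers mis-terminate. Starts
combine moment-based initial values (support minima of the observed pair
ages; θ from the mean inter-coalescence gap; γ from the plug-in topology
interval midpoint) with Latin-hypercube restarts (8 by default), and the
incumbent is polished by repeated simplex restarts until the objective
stops improving (single NM runs demonstrably stall on the ghost γ–τ_G
valley). τ_H is profiled on a coarse grid of fractions of the smallest
observed b–c age for inflow/outflow — it only positions a support boundary
and is weakly identified, and the fit flags it as such; for ghost it drops
out of the likelihood entirely (the ghost population never holds two
sampled lineages) and is not a parameter. Fits of the three scenarios have
equal parameter counts, so model selection compares maximized
log-likelihoods directly. The default fit shares one θ across populations
(matching the generator); a free-θ mode estimates the ancestral θs that are
actually identifiable from trio gene trees (T, R, and the donor-side
population for inflow/outflow) — tip populations and the ghost never
contain two sampled lineages, so their θs are structurally unidentifiable
and are not pretended to be estimated.

## Numerical choices and problem sizes

* Piecewise-exponential densities integrate to 1 to 1e−8 (checked by
  quadrature); joint-density topology marginals match the closed form to
  1e−12 via exact per-interval integration.
* Random streams: one `SeedSequence` per dataset with per-locus spawned
  substreams, so locus i is reproducible in isolation and shorter runs are
  prefixes of longer ones.
* Desk-scale test sizes: 10⁵ loci for frequency agreement, 20 replicates ×
  1000 loci for the estimator studies, 100 replicates for null calibration;
  grid experiments default to 20 replicates per cell with the full design
  available through `GridSpec`.
* Acceptance-style checks use 3 binomial/replicate SEs for stochastic
  comparisons and machine tolerance for algebraic identities.

## Known limitations

Single introgression edge, three ingroup species, strict clock, exact gene
trees for the likelihood stage, and one sequence per species in the
estimators (the simulator supports more; with multiple sequences per
species τ_H would become identifiable, which the fitter does not attempt).
Sequence-level (Felsenstein) likelihoods, Bayesian posteriors and
credibility intervals are out of scope: selection is by maximized
log-likelihood difference, not Bayes factors.
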