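# ghostintro

Identifiability of **ghost introgression** in species trios under the
multispecies coalescent with introgression (MSci).

When a genome shows the classic excess of one discordant site pattern
(ABBA > BABA), three very different histories on the species tree *AB|C*
(plus a distant outgroup *O*) can be responsible:

* **ghost** — an unsampled lineage that diverged *above* the sampled root
  donated genes into *A*;
* **inflow** — *C* donated into *B* (into the sister pair);
* **outflow** — *B* donated into *C* (out of the sister pair).

`ghostintro` implements the theory, simulation machinery and estimators
needed to show that summary-statistic methods cannot tell these apart while
branch-length-aware likelihoods can, and is aimed at phylogeneticists who
want to probe what their introgression tests can and cannot conclude.

## The model

Times τ are measured backwards from the present in expected substitutions
per site; population sizes θ = 4Nμ share those units, so two lineages in one
population coalesce at rate 2/θ. A lineage of the recipient species takes
the introgressed path at the hybridization time τ_H with probability γ.
Writing C_T = 2 l_T/θ and C_S = 2 l_S/θ for the internal branches of the
speciation (*AB|C*) and introgressed (*A|BC*) histories in coalescent units,
the rooted-triple gene-tree probabilities are, for **all three scenarios**,

    P(ac|b) = [(1−γ) e^{−C_T} + γ e^{−C_S}] / 3
    P(ab|c) = (1−γ)(1 − e^{−C_T}) + P(ac|b)
    P(a|bc) = γ (1 − e^{−C_S}) + P(ac|b)

so topology counts (and, analogously, pooled biallelic site-pattern
frequencies BBAA/ABBA/BABA) determine only two contrasts of three unknowns:
the likelihood has a flat ridge over γ ∈ (P₂−P₃, 1−(P₁−P₃)), the
pattern-ratio estimator of γ is biased by the factor C_T/C_S, and the
scenario label drops out entirely. The joint density of (topology, both
coalescence ages), by contrast, differs across scenarios in its support
minima and mixture structure — that density is implemented exactly and
drives a maximum-likelihood scenario selector.

The package provides:

| module | contents |
| --- | --- |
| `ghostintro.model` | `MSciModel` parameterization, coalescent-unit grid construction, config I/O |
| `ghostintro.simulate` | coalescent gene trees (ms-style γ-coin at τ_H) + HKY sequence evolution |
| `ghostintro.theory` | the closed forms above, γ bounds, pattern frequencies, bias law, detectability |
| `ghostintro.density` | pairwise and joint coalescent-time densities (piecewise-exponential mixtures) |
| `ghostintro.hyde` | site-pattern counting, block-jackknife test, B–H correction (`HydeDetector`) |
| `ghostintro.topology` | rooted-triple counting and the multinomial ridge fit (`TopologyRidgeEstimator`) |
| `ghostintro.fit` | gene-tree likelihood fitting and scenario selection (`ScenarioMLE`, `ScenarioSelector`) |
| `ghostintro.experiments` | config-driven simulation grids, density figures, TSV reports |

## Worked example

Simulate a ghost-introgression dataset (introgression at 0.3 coalescent
units, speciation branch C₂ = 0.5, γ = 0.3, θ = 0.036; 1000 loci × 1000 bp)
and analyze it three ways:

```python
import ghostintro as gi

model = gi.from_coalescent_grid("ghost", 0.3, 0.5, 0.3, theta=0.036)
config = gi.SimConfig(n_loci=1000, sites_per_locus=1000, seed=7)
trees = gi.simulate_gene_trees(model, config)
alignments = gi.simulate_alignments(trees, config)

det = gi.HydeDetector().fit(alignments)
ridge = gi.TopologyRidgeEstimator(gamma_grid_size=41, random_state=0).fit(trees)
sel = gi.ScenarioSelector(n_restarts=4, random_state=0).fit(trees)
```

which prints, for this seed:

```
hyde:  z=11.68  p=8.0e-32  hybrid=b  gamma_hat=0.586
ridge: flat region = (0.269, 0.707), arbitrary point draw = 0.548
selected: ghost   log-likelihood deficits {ghost: 0.0, inflow: 252.6, outflow: 252.6}
estimates: tau_T=0.0270  tau_R=0.0360  tau_G=0.0631  theta=0.0354  gamma=0.321
```

Read: the site-pattern test is loudly significant but **misreads the ghost
as inflow** (hybrid *b*) and roughly doubles γ (0.586 vs 0.3 — exactly the
C_T/C_S = 1/3 bias law, which predicts 0.5625); the topology-count fit
cannot choose a γ (any value in the flat region fits equally well, matching
the theoretical interval (0.233, 0.725)); the gene-tree likelihood selector
identifies the ghost scenario by ~250 log-likelihood units and recovers the
divergence times, θ and γ ≈ 0.3.

The same machinery is scriptable from the shell:

```bash
ghostintro simulate --scenario ghost --c1 0.3 --c2 0.5 --gamma 0.3 --seed 7 --out ds/
ghostintro hyde --data ds/
ghostintro topofit --trees ds/trees.nwk
ghostintro gtfit --trees ds/trees.nwk --mode select
ghostintro theory --gamma 0.3 --ct 1.5 --cs 1.5 --theta 0.036
ghostintro experiment fig1 --out figs/
```

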