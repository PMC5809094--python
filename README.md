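# phylocomp

Competition-aware models of continuous trait evolution on time-calibrated
phylogenies.

## The problem

Interspecific competition is expected to leave a signature in how traits
diverge among coexisting species, but only species that overlap in space
and in resource use can actually interact.  `phylocomp` implements a
process-based workflow for measuring that signature across a radiation:

1. **Who could interact, and when.**  Biogeographic histories (which
   regions each lineage occupied through time) and guild histories (diet,
   habitat, or territorial class, evolving under an Mk model and sampled as
   stochastic character maps) are combined into a time-resolved binary
   interaction matrix **A**(t): `A_ij(t) = 1` when lineages *i* and *j* are
   both alive, share a region, and belong to the same focal guild.
2. **Trait models with and without competition.**  Five models of a
   continuous trait *z* on the tree are fit by maximum likelihood:
   - **BM**: dz = σ dW
   - **OU**: dz = α(θ − z) dt + σ dW
   - **MC** (matching competition):
     dz_i = S(μ_i − z_i) dt + σ dW_i, with S ≤ 0 and μ_i the mean trait of
     the lineages currently interacting with *i* — sympatric competitors
     repel each other's traits
   - **DD_lin** / **DD_exp** (diversity dependence): the instantaneous
     rate is σ₀² + b·n_i(t) or σ₀²·exp(r·n_i(t)), where n_i(t) counts the
     lineages sympatric with *i* (including itself) — rates rise (positive
     DD) or fall (negative DD) with the number of coexisting competitors
3. **Model comparison.**  Models are compared per trait × subgroup ×
   stochastic map by AICc and Akaike weights *w*; the relative support for
   competition is
   RS = max(w_MC, w_DDlin, w_DDexp) / (max(w_BM, w_OU) + max(w_MC, w_DDlin, w_DDexp)),
   summarized as mean ± SD over the stochastic-map bank.

Supporting analyses included: disparity-through-time curves and the
morphological disparity index (MDI) against Brownian nulls; evolutionary
tempo indices (BM σ² on z-scored traits, felsens, BM with measurement
error) with trait-class ANOVAs; a pairwise sympatric-convergence test with
phylogenetic simulation nulls (Szymkiewicz–Simpson range overlap at 5 / 20 /
50 / 80 % thresholds, Bonferroni α = 0.0125); and time-varying birth–death
diversification fits with likelihood-ratio tests.

A synthetic-data generator (`phylocomp.synth`) builds complete studies —
trees, region/guild histories, 27 traits in four classes with known
generating models, measurement replicates, range overlaps — so every stage
is testable end to end.

## Worked example

```python
from phylocomp import make_fixture_bank, fit_over_maps

study = make_fixture_bank("tiny", seed=0)       # 16-tip synthetic study
focal = study.modal_guild("diet2")              # largest diet class
timelines = [study.timeline("diet2", focal, m) for m in range(3)]

trait = "trait_04"                               # generated under MC
comps, summary = fit_over_maps(study.tree, timelines,
                               study.traits.values[trait])
print(summary["best_family"], summary["mean_rs"])
```

prints (for this seed):

```
trait trait_04: focal guild = 'invertivore'
  generating model: MC, params {'S': -0.3, 'sigma2': 1.0, 'z0': 0.0}
  best family (majority over maps): MC
  relative support for competition: 1.000 +/- 0.000
  map 0 best-fit params: S = -0.296, sigma2 = 0.343, AICc = 99.89
```

The trait was generated with repulsion strength S = −0.3 among sympatric
members of the focal diet guild; the fit recovers Ŝ = −0.296, the
matching-competition model wins on every stochastic map, and the relative
support for competition is 1.0.

There is also a thin CLI over the library
(`phylocomp synth|timeline|fit|dtt|tempo|converge|diversify|report
--config cfg.yaml`), each subcommand writing TSV/JSON outputs plus a run
manifest.

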