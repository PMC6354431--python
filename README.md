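# osteophylo

Cross-sectional long-bone geometry meets phylogenetic comparative methods.

Limb bones resist two principal loads: axial compression, governed by the
cross-sectional area (CSA), and bending, governed by the second moment of
area (SMA) and section modulus (MOD) about an anatomical axis.  How these
traits vary along a bone, and whether that variation tracks a species'
locomotor habit — digging (fossorial), swimming (natatorial), climbing
(scansorial), or a generalist lifestyle — is a question about both
biomechanics and evolutionary history.  `osteophylo` implements the full
analysis chain for a clade of species (designed around a mustelid-sized
study: ~28 species, four habits) whose bones have been CT-scanned:

1. **Slice geometry.**  From calibrated greyscale cross-sections, bone
   pixels (intensity ≥ threshold) are point areas `A` at their centres:
   `CSA = Σ A`, `SMA = Σ A·d²` about the medio-lateral and cranio-caudal
   centroidal axes, `MOD = SMA / c` with `c` the extreme-fibre distance.
   Stacks are downsampled to 21 slices at 5% increments of bone length, and
   traits are made dimensionless (`CSA½/L`, `SMA¼/L`, `MOD⅓/L`, and the
   resistance ratio `R = (SMA¼/L) / (CSA½/L)`) so species two orders of
   magnitude apart in mass are comparable.
2. **Increment-wise statistics.**  One-way ANOVA of each trait on habit at
   each of the 19 interior increments with Tukey–Kramer pairwise tests,
   gated by a Bonferroni omnibus threshold (0.05/19 ≈ 0.0026); a
   phylogenetic ANOVA by residual randomization (RRPP) after whitening by
   C^(−1/2), C the Brownian-motion covariance of the tree; and a two-block
   PLS statistic for how strongly habit clusters on the phylogeny.
3. **Trait-evolution model selection.**  Exact likelihoods and ML fits for
   BM1, multi-rate BM (BM3/BM4), single- and multi-optimum
   Ornstein–Uhlenbeck (OU1/OU3/OU4, shared α and σ²), and Early Burst
   (rate σ₀²·e^{rt}, r ≤ 0).  Habit histories on internal branches are
   unknown, so an equal-rates Mk model is fitted to the tip habits and
   regime histories are drawn by stochastic character mapping (500 maps by
   default); AICc is averaged over maps, Akaike weights are computed from
   the mean AICc, and OU support is screened by whether the 95% Wald
   interval for α excludes zero.

Because raw CT data for such studies are rarely deposited, the package
ships a first-class synthetic-data module: elliptical-annulus bone stacks
with closed-form geometry, pure-birth trees, Mk habit histories, and traits
simulated exactly (per-branch transition sampling) under every candidate
model.

## Worked example

```python
import numpy as np
from osteophylo import (StackParams, make_annulus_stack, extract_profile,
                        simulate_tree, simulate_discrete_history,
                        simulate_traits, TraitModel, fit_mk_er,
                        sample_histories, fit_across_maps)

# geometry: a 21-slice annular bone, 0.05 mm pixels
stack, oracle = make_annulus_stack(StackParams())
profile = extract_profile(stack)
print(f"CSA at mid-shaft: {profile.raw[10].csa:.2f} mm^2 "
      f"(closed form {oracle['csa_mm2'][10]:.2f})")
print(f"dimensionless R_ML at mid-shaft: {profile.traits[10].r_ml:.3f}")

# evolution: 28 species, OU with one optimum per habit
tree = simulate_tree(28, seed=3)
habits, history = simulate_discrete_history(tree, 0.5, seed=4)
theta = {s: 1.0 * i for i, s in enumerate(sorted(set(habits.values())))}
x = simulate_traits(tree, TraitModel("OU4", sigma2=1.0, alpha=8.0,
                                     theta=theta), seed=5, regime_map=history)
mk = fit_mk_er(tree, habits)
maps = sample_histories(tree, habits, mk, n_maps=50, seed=6)
comp = fit_across_maps(tree, maps, x)
print(comp.table[["mean_aicc", "weight"]].round(3))
print("best model:", comp.best_model)
```

Output:

```
CSA at mid-shaft: 23.54 mm^2 (closed form 23.56)
dimensionless R_ML at mid-shaft: 0.603
       mean_aicc  weight
model
BM1       63.671   0.001
BM3       64.591   0.001
BM4       67.137   0.000
OU1       66.191   0.000
OU3       51.246   0.438
OU4       50.759   0.559
EB        65.424   0.000
best model: OU4
```

The rasterized annulus reproduces its closed-form area to 0.1%.  In the
model competition, averaged over 50 stochastic habit maps, the
multi-optimum OU models absorb essentially all Akaike weight, with the
four-optimum generating model narrowly ahead of its three-optimum
reduction — the expected picture at only 28 species.

A `click` CLI mirrors the library: `osteophylo simulate | geometry | stats
| phylo-stats | fitmodels | run-all | summarize` (see `osteophylo --help`);
`run-all` drives the whole pipeline from a YAML config and writes TSV
tables plus a reproducibility manifest.

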