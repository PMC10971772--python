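# cyclemur

Comparative analysis of tropical-cyclone exposure and species traits, built
around the lemurs of Madagascar but applicable to any taxa with range
polygons and a phylogeny. The package provides, as one tested pipeline:

1. **A gridded Cyclone Impact index.** Historical storm tracks (IBTrACS-style
   point records with Saffir–Simpson class 0–5) are filtered to tropical-storm
   strength (≥ 34 kt) within 500 km of the study area, weighted as
   *class + 1*, and accumulated on a 50 × 50 km grid: each storm whose track
   passes within a buffer radius of a cell adds the weight of its strongest
   in-buffer point. Three buffer scales (impact diameters 87.5, 175 and
   350 km) capture uncertainty in storm size. Per-species summaries (sum,
   mean, mode, median, range, sd, count, min, max) are aggregated over all
   grid cells intersecting each range polygon.
2. **A six-trait cyclone-resilience score.** Binary indicators for energy
   conservation (torpor/hibernation), terrestrial habitat use, small groups
   (< 5), low frugivory (< 50 % of diet), home range > 10 ha, and small body
   mass (< 898 g) are summed to a 0–6 score. The published 26-species
   indicator table is packaged as a fixture.
3. **Spatial diagnostics.** Global Moran's I (inverse-distance,
   row-standardised weights, randomization-assumption variance) and Anselin's
   Local Moran's I with conditional-permutation p-values and HH/LL/HL/LH
   cluster classes.
4. **A joint phylogenetic–spatial GLS.** Regression with error correlation
   R = λP + φS + (1 − λ − φ)I, where P is the Brownian-motion correlation
   from the maximum clade credibility tree of a posterior sample and
   S_ij = (1 − δ)^{D_ij} is a distance-decay correlation on range-centroid
   distances normalised to the study extent. (λ, φ, δ) are estimated by
   maximum likelihood (multi-start Nelder–Mead on a logistic
   reparameterisation, β and σ² profiled out analytically); models are
   compared by AICc with Akaike weights and relative likelihoods, and nested
   models by likelihood-ratio tests. Reported structure: total
   autocorrelation AC = λ + φ, phylogenetic share λ/AC, and decay δ.
5. **A synthetic-data generator** producing storm tracks (random walks with
   class-consistent winds), range polygons (buffered random ellipses),
   ultrametric Yule phylogenies, and traits drawn from the exact GLS
   generative model — so every stage is testable without external data.

## Worked example

```python
import numpy as np
from cyclemur import (SimConfig, fit_ml, gen_ranges, gen_traits, gen_tree,
                      model_table, phylo_correlation, spatial_structure)

cfg = SimConfig(n_species=40, seed=8, lambda_p=0.5, phi_s=0.2, delta=0.3,
                beta=(1.0, -0.3, 0.15), sigma2=0.25)
ranges, tree = gen_ranges(cfg), gen_tree(cfg)
P, _ = phylo_correlation(tree, [r.species_id for r in ranges])
D = spatial_structure(np.array([r.centroid for r in ranges]))
rng = np.random.default_rng(9)
X = np.column_stack([np.ones(40), rng.normal(2.0, 0.8, 40), rng.normal(8.0, 1.2, 40)])
y = gen_traits(tree, ranges, X, cfg)
full = fit_ml(y, X, P, D, formula="~ impact + range")
null = fit_ml(y, X[:, :1], P, D, formula="~ 1")
print(model_table([full, null]).round(3).to_string(index=False))
```

prints

```
           model   AICc  delta     w   rLL    AC  phylo  decay
~ impact + range 37.856  0.000 0.999 1.000 0.668    1.0    0.0
             ~ 1 52.073 14.216 0.001 0.001 0.521    1.0    0.0
```

The full model carries essentially all the Akaike weight (`w`), its
estimated total autocorrelation is 0.67 with an entirely phylogenetic share
here, and `delta` is the fractional loss of spatial correlation across the
study extent. `examples/` holds one narrative script per capability
(impact grid, resilience scoring, Moran's I, the GLS, and the full
pipeline); `cyclemur run-all --out-dir out/` runs the synthetic analysis
end to end from the shell.

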