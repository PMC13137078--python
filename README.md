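# tetherdyn

Seasonal predation-risk analysis for tethering assays in structured habitats.

Field ecologists measure relative predation risk by tethering live prey and
scoring, per site × deployment date × species, the proportion of recovered
tethers with the prey missing. A recurring question is how *among-species*
differences in the seasonal timing of predation relate to the stability of
*community-level* predation: a community can have stable aggregate risk
either because every species has a flat risk profile, or because species'
seasonal peaks are staggered and compensate for each other. `tetherdyn`
implements the analysis chain that separates these regimes:

1. **Risk tables.** Species-level predation risk r = consumed / recovered
   per site, deployment and species (lost tethers carry no information).
2. **Predation schedules.** Each species × site risk series is normalized to
   unit mass over the deployment calendar, giving a temporal distribution of
   predation; interior gaps are linearly interpolated (and flagged).
3. **KS distance matrix.** Pairwise Kolmogorov–Smirnov statistics
   D(a, b) = sup_t |F_a(t) − F_b(t)| between cumulative schedules, with an
   exhaustive triangle-inequality audit.
4. **PCoA + dispersion.** Principal coordinates analysis of the KS matrix
   (Gower double-centering, signed eigenvalues; non-Euclidean input yields
   negative eigenvalues, accounted for explicitly), then per-site
   multivariate dispersion — the mean distance of a site's species points to
   their centroid, with the real² − imaginary² correction on negative axes.
   Site dispersion is the "among-species variation in predation risk".
5. **Variability and correlations.** Community-level risk per deployment is
   the pooled proportion Σconsumed / Σrecovered; its sample SD over the year
   is the site's community-level variability. A Pearson/Spearman correlation
   battery relates dispersion, community SD, per-species SDs and habitat
   means (eelgrass cover, shoot density, bare ground, macroalgae), with
   exact-permutation Spearman p-values at small n.

A synthetic-study simulator generates binomial tethering outcomes from
Gaussian seasonal risk curves, with a per-site parameter γ that interpolates
from a shared seasonal peak (γ = 0) to evenly staggered, compensatory peaks
(γ = 1), alongside a habitat gradient whose eelgrass cover increases with γ.
This makes every downstream stage testable without field data.

## Worked example

```python
import tetherdyn as td

design = td.default_design(seed=1)        # 6 sites, 16 deployments, 21 series
tethers, habitat = td.simulate_study(design)
res = td.analyze_tables(tethers, habitat)

print(len(tethers))                       # 336 site x date x species records
print(res["eigen"].negative_share)        # 7.8  (% eigenvalue mass negative)
print(res["dispersion"].group_means)
#  group  dispersion  n_members
#     BL    0.273978          4
#     CC    0.263552          3
#     MM    0.103551          3
#     MP    0.201198          4
#     NC    0.051065          4
#     WP    0.289420          3
corr = res["report"].correlations.set_index(["x", "y"])
print(corr.loc[("dispersion", "community_sd")])
# estimate -0.894, df 4, p 0.016
```

Sites are ordered NC → BL along the habitat/γ gradient: the nearly bare,
shared-peak site NC has the lowest among-species dispersion (0.05) and the
densest, staggered-peak site BL among the highest (0.27), and across the six
sites dispersion correlates negatively with community-level SD
(r = −0.89, df = 4) — more among-species complementarity, more stable
aggregate predation.

The same pipeline runs from the shell against a YAML config (either a
`simulation:` block or `inputs:` paths to tether/habitat CSVs, with a column
mapping for externally deposited files):

```sh
tetherdyn run --config config.yaml --seed 1 --out-dir out/
```

writing every intermediate artifact (risk table, schedules, KS matrix,
metric report, PCoA coordinates and eigenvalue accounting, dispersion,
variability tables, correlation battery) plus a run manifest; identical
config and seed give byte-identical artifacts.

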