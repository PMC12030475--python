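# traitpart

Community trait analysis for factorial vegetation experiments: given a plot
design crossing a climate gradient with a large-herbivore treatment, a
plot × species percent-cover matrix, and species trait measurements,
`traitpart` computes

* **community-weighted means** (CWM = Σᵢ wᵢ tᵢ, relative-cover weights)
  under three conventions — *specific* (plot-measured trait values, total
  variation), *fixed* (species averages pooled across plots, species
  turnover only) and *ITV* (specific − fixed, the intraspecific component);
* the **turnover / ITV / covariation decomposition** of CWM variation: the
  same two-way ANOVA (`response ~ climate × treatment`, sequential SS) run
  on all three responses, with per-term covariation
  `SS_cov = SS_specific − SS_fixed − SS_itv` and relative contributions in
  percent of the specific ANOVA's total SS;
* **functional diversity** — FRic (convex-hull volume), FEve
  (minimum-spanning-tree evenness), FDiv (divergence from the hull
  centroid), FDis (abundance-weighted dispersion) — on a Gower +
  corrected-PCoA or z-scored Euclidean trait space;
* **community dissimilarity tests** — Jaccard on the species making up 90%
  of each plot's cover, with rank-based ANOSIM permutation tests (exact
  enumeration for small designs) grouping plots by climate and, within each
  climate, by herbivore treatment;
* **mixed-model selection and contrasts** — five marginality-respecting
  fixed-effect structures with a site random intercept, ML fits compared by
  AICc (`AICc = AIC + 2k(k+1)/(n−k−1)`, ties within 2 units going to the
  fewest parameters), then estimated marginal means with Tukey-adjusted
  pairwise contrasts;
* a **synthetic-community generator** with tunable species-pool overlap,
  Dirichlet abundances, lognormal traits and known intraspecific shift
  structure, so every stage can be verified against ground truth.

It is aimed at plant community ecologists working with grazing-exclosure or
climate-gradient designs who want the full pipeline as tested, scriptable
Python instead of a patchwork of R snippets. See `docs/methods.md` for the
statistical details and design choices.

## Worked example

Simulate an experiment in which intraspecific shifts oppose the
between-climate trait gradient, then decompose leaf-area CWM variation:

```python
import traitpart as tp

design, abundance, traits, truth = tp.generate(tp.regime("mixed_negative", seed=42))
filt = tp.CommonSpeciesFilter(0.90)

cwms = tp.cwm_table(design, abundance, traits, species_filter=filt)
print(tp.decompose(cwms, design, "LA").contributions.round(2))
```

```
                   turnover_pct  itv_pct  cov_pct  total_pct
climate                   74.49     0.42    -8.98      65.93
treatment                  4.20     3.72     7.87      15.79
climate:treatment          3.10     1.08    -2.05       2.12
residuals                 15.36     0.35     0.45      16.16
total                     97.15     5.56    -2.71     100.00
```

Species turnover carries almost all leaf-area variation (97% of the total),
the climate term dominates (66%), and the climate-term covariation is
negative (−8.98): the simulated intraspecific shifts pull against the trait
differences between the climate species pools, exactly as this regime's
ground truth dictates. Rows satisfy turnover + ITV + covariation = total,
and the total row is pinned at 100%.

The community-composition tests on the same data:

```python
d = tp.jaccard_matrix(abundance, filt)
for name, r in tp.run_study_anosims(d, design, seed=0).items():
    print(f"{name:13s} R = {r.r:+.3f}  p = {r.p_value:.3f}  ({r.method})")
```

```
climate       R = +0.991  p = 0.001  (sampled)
arid          R = +0.222  p = 0.182  (exact)
intermediate  R = +0.066  p = 0.386  (exact)
mesic         R = +0.247  p = 0.125  (exact)
```

Climates host nearly disjoint communities (R ≈ 1, the permutation floor
p = 0.001), while herbivore treatments within a climate share one species
pool, so their R values sit near zero. And model selection for the
leaf-area CWM (log scale by default):

```python
data = design.table.copy()
data["CWM_LA"] = cwms.wide("specific")["LA"]
sel, emmeans, contrasts = tp.analyse_response("CWM_LA", data.reset_index())
print(sel.table[["model", "k", "AICc", "dAICc", "chosen"]].round(2))
```

```
                       model  k   AICc  dAICc  chosen
                  CWM_LA ~ 1  3  -6.35  26.49   False
            CWM_LA ~ climate  5 -21.91  10.93   False
          CWM_LA ~ treatment  5 -15.71  17.13   False
CWM_LA ~ climate + treatment  7 -32.84   0.00    True
CWM_LA ~ climate * treatment 11 -16.26  16.58   False
```

Both simulated main effects are recovered; `contrasts` then holds the
Tukey-adjusted pairwise differences of the marginal means.

The same pipeline runs from the shell:

```sh
traitpart simulate --regime mixed_negative --seed 42 --out data/
traitpart run-all --config config.yaml --out results/
```

`run-all` writes every stage's CSV/JSON output plus a manifest with content
hashes, seeds and timings; rerunning the same configuration reproduces the
hashes byte for byte.

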