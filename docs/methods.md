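# Methods

`traitpart` implements the quantitative pipeline of a factorial
grazing-exclosure experiment replicated along a topo-climate gradient: plant
communities are surveyed in plots crossing a climate factor (arid /
intermediate / mesic) with a large-herbivore treatment (all herbivores /
wildlife only / no herbivores) in blocks, and five leaf and seed traits (LA,
SLA, LDMC, LNC, seed mass) are measured on the common species. This note
describes the statistical machinery, the choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Community-weighted means and the three conventions

For a plot with species covers `a_i` and trait values `t_i`, the
community-weighted mean is

    CWM = Σ_i w_i t_i,     w_i = a_i / Σ_j a_j

over the species that carry a trait value. Using *relative*-abundance
weights makes the CWM invariant to rescaling a plot's covers (so quadrat
count conventions are irrelevant); an unnormalised raw-cover sum is
available via `normalize=False` as a sensitivity check.

Three conventions are computed per plot × trait:

* **specific** — trait values measured in that plot; carries the total
  community trait variation;
* **fixed** — each species enters with its pooled average over every plot
  where it was measured; only species turnover can move this quantity;
* **itv** — specific − fixed, computed by subtraction and never refitted, so
  the identity holds to the last bit.

Species without a trait value under a convention are dropped from numerator
and weights alike, and the cover fraction lost is recorded; a warning fires
above 20% loss. Traits known only from pooled records (seed mass and LNC in
the emulated study, whose site-specific values come from trait databases)
yield fixed CWMs only and are automatically excluded from the ITV
decomposition.

## The common-species filter

Surveys of this kind measure traits for the species jointly making up at
least 90% of each plot's cover. `CommonSpeciesFilter` ranks a plot's species
by cover (descending, lexicographic tie-break for determinism) and retains
the minimal prefix whose cumulative share of the plot's own total reaches
the threshold (≥, so a species tying the boundary is included). The
threshold is relative to the *input* row, which makes the filter a run-once
preprocessing step: re-applying it to its own output can only shrink the
retained sets (covers {1,1,1} at threshold 0.5 keep two species on a first
pass, one on a second). A second pass is a no-op exactly when the smallest
retained species carries more than (1 − threshold) of the retained cover,
which is the typical situation for right-skewed cover distributions at the
0.90 default.

## Turnover / ITV / covariation decomposition

Each of the three CWM responses is analysed with the same two-way ANOVA,
`response ~ climate × treatment`, using sequential (Type I) sums of squares
entered climate → treatment → interaction. With the balanced full-factorial
design the SS type is immaterial; sequential SS is used because it matches
the reference decomposition's additivity,

    SS_total = SS_climate + SS_treatment + SS_climate:treatment + SS_error.

For every term,

    SS_cov = SS_specific − SS_fixed − SS_itv,

positive when turnover and intraspecific shifts select the same trait
values and negative when they oppose. Relative contributions are expressed
as percentages of the **specific ANOVA's total SS** — the only
normalisation under which the rows (turnover + ITV + covariation = total)
and columns (terms sum to the total row) of the contribution table are
simultaneously coherent, with the grand total pinned at 100%.

`decompose` requires at least two plots per climate × treatment cell;
with a single observation per cell the interaction is confounded with the
residual and an error is raised rather than silently refitting.

An optional permutation mode attaches one-sided p-values per term by freely
permuting each response across plots (999 permutations by default, seeded)
and comparing per-term F statistics; the free-permutation scheme is the
simplest exchangeability assumption for a balanced fixed design.

## Functional diversity

Species are first placed in a trait space. The default geometry computes
range-normalised Gower dissimilarities (for one trait this reduces to the
normalised absolute difference), takes their square root — which makes a
Gower matrix Euclidean-embeddable, removing negative eigenvalues up to
numerical noise — and embeds by classical principal coordinates, retaining
min(S − 1, number of traits) axes. A z-scored Euclidean geometry is
available as an alternative, with standardisation optional so that
already-commensurate coordinates pass through untouched. On that space:

* **FRic** — convex-hull volume of the species cloud (range in one
  dimension). Abundance-free. Undefined (flagged, not fabricated) when
  fewer than axes + 1 species remain or the points are affinely dependent;
  a true point community has volume 0.
* **FEve** — minimum-spanning-tree evenness: each branch of length `d`
  joining species i, j gets weight `EW = d / (w_i + w_j)`; with
  `PEW = EW / ΣEW` and S species,
  `FEve = (Σ min(PEW, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1))` ∈ [0, 1].
  MST edge selection uses distances shifted by a constant so zero-length
  edges between coincident species stay in the graph (every spanning tree
  has S − 1 edges, so a uniform shift cannot change the minimiser).
  Undefined for S < 3 or a fully coincident community.
* **FDiv** — with G the centroid of the hull vertices, dG_i the species
  distances to G and d̄ their unweighted mean:
  `FDiv = (Δd + d̄) / (Δ|d| + d̄)` where `Δd = Σ w_i (dG_i − d̄)` and
  `Δ|d| = Σ w_i |dG_i − d̄|`; equals 1 when all species are equidistant
  from G.
* **FDis** — abundance-weighted mean distance to the abundance-weighted
  centroid; zero iff all abundance-bearing species coincide.

All four are invariant to rigid motions of the coordinates, which also makes
the arbitrary axis orientation of the eigendecomposition harmless.

## Community dissimilarity and ANOSIM

Jaccard dissimilarity `d = 1 − |A ∩ B| / |A ∪ B|` is computed on
presence/absence after the 90% filter (binarising after filtering, so rare
species do not blur the comparison). ANOSIM ranks all pairwise
dissimilarities with mid-ranks for ties and forms

    R = (mean between-group rank − mean within-group rank) / (M/2),

M = n(n−1)/2. The one-sided p-value permutes group labels: exhaustively
when the number of distinct labelings (a multinomial coefficient) is at
most 10,000 — e.g. the 9-plot within-climate tests enumerate all 1,680 —
and by seeded sampling (999 draws by default) otherwise. R depends on the
dissimilarities only through their ranks, so any monotone transform leaves
it unchanged. The study design yields four tests: climate across all plots,
and treatment within each climate.

## Mixed models, AICc, marginal means

Each per-plot response (a CWM or an FD metric) is fitted with five
fixed-effect structures respecting marginality — intercept, climate,
treatment, climate + treatment, climate × treatment — each with a random
intercept for the physical site (block letter; sites sit inside climates
and contain one plot per treatment). Fits use maximum likelihood rather
than REML because REML likelihoods are not comparable across differing
fixed effects. With k counting fixed-effect coefficients plus the two
variances,

    AICc = AIC + 2k(k+1)/(n − k − 1),

and the chosen model minimises AICc except that any candidate within two
units of the best with fewer parameters supersedes it (fewest parameters
first, AICc as tie-break). A random-intercept variance estimated at the
zero boundary is flagged singular but the model is retained. Right-skewed,
strictly positive responses — the leaf-area and seed-mass CWMs — are
modelled on the log scale, with back-transformed means and ratio contrasts
reported.

Estimated marginal means average model predictions over the levels of the
other factor with equal weights (equal to raw level means under the
balanced design). Pairwise contrasts use residual degrees of freedom
(n − p; simple and deterministic, at the cost of small p-value differences
versus approximations such as Kenward–Roger) and a Tukey studentized-range
adjustment within each contrast family; when the interaction is in the
model, simple contrasts within each level of the other factor are added as
separate families.

## The synthetic-community generator

The generator exists so every stage can be tested against a known answer.
It emulates, with defaults chosen once on ecological grounds:

* the 3 × 3 × 3 design: 27 plots, block letters A–I nested in climate;
* climate-specific species pools of 14 species, adjacent pools sharing
  `round(overlap × pool size)` species via overlapping windows on a global
  species list (overlap 0.4 by default, giving the high between-climate
  dissimilarity such gradients show);
* percent-cover abundances from a symmetric Dirichlet (concentration 1.0;
  smaller values give dominance-skewed communities) scaled to 100;
* lognormal species base traits (e.g. LA around 300 mm², SLA around
  20 mm²/mg, LDMC around 250 mg/g, log-sd 0.4) with a per-climate log-mean
  gradient for species by home pool (LA and SLA decreasing, LDMC increasing
  from arid to mesic, mirroring drought-strategy turnover);
* additive plot-level intraspecific shifts from climate, treatment and
  their interaction (for LA: 30/20/10 units per centred factor step) plus
  Gaussian noise (LA: sd 15), floored at 5% of the base value to keep trait
  values positive;
* seed mass and LNC emitted as pooled-only records, emulating
  database-sourced traits without site-specific measurements.

`covariation_mode` aligns (`reinforcing`) or anti-aligns (`opposing`) the
intraspecific climate shifts with the between-pool base-trait gradient,
producing positive or negative turnover–ITV covariation in expectation; the
recorded `GroundTruth` carries pools, base traits, per-plot shifts and the
expected covariation sign. Four presets exercise the decomposition regimes:
`turnover_only` (no intraspecific effects or noise → the ITV response is
identically zero), `itv_only` (one shared pool and one shared abundance
vector → turnover exactly zero), `mixed_positive`, `mixed_negative`. Sign
recovery of the covariation term is strongest for leaf area, whose default
shift magnitudes are largest relative to its noise; LDMC's weaker
configured signal recovers the sign less reliably.

What the generator does **not** emulate: spatial structure within plots,
species' abundance–trait correlations, demographic or ontogenetic trait
variation, survey measurement error, and missing-data patterns beyond the
pooled-only traits. Passing tests therefore demonstrate correctness of the
estimators and their identities under the assumed sampling model, not
robustness to every feature of field data.

## Numerical choices and limitations

* Sums-of-squares identities are asserted at 1e-10; the covariation term is
  defined by subtraction so its identity is exact by construction.
* CSV writers use shortest round-trip float formatting and readers parse
  with `float_precision="round_trip"`, so a write/read cycle is bit-exact.
* PCoA axes with eigenvalues below 1e-10 (relative guard 1e-8·max) are
  dropped; a space whose species all coincide is flagged degenerate.
* Exact ANOSIM p-values include the observed labelling in the reference
  set; sampled p-values use (1 + exceedances) / (n_permutations + 1) and are
  therefore never smaller than 1/(n_permutations + 1).
* Problem sizes in the test-suite ensembles (200 random datasets for the
  decomposition identities, 50 seeds for covariation signs, 500 null
  simulations for ANOSIM and contrast calibration, 20 seeds for selection
  consistency) were sized to estimate the checked fractions to a few
  percent.
* Reproducing the p-values of any particular published analysis is out of
  scope: degrees-of-freedom conventions and optimiser details differ across
  mixed-model implementations. The machinery here is deterministic given a
  seed and documented above.
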