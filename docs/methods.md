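# Methods

This note documents the models, estimators, numerical choices and known
limitations of `divelev`, module by module, and states what the synthetic
data generator does and does not emulate.

## Chronogram handling (`divelev.phylo`)

A chronogram is a rooted tree with strictly positive branch lengths in Myr.
Node *depth* is the maximum path time from the node down to any descendant
tip (Ma before present). The **stem age** of a genus tip is the depth of its
parent node — the divergence from its sister lineage — which is the standard
quantity the stem-lineage rate estimator consumes. Where a pipeline prunes
the tree to the study taxa, stem ages are still taken from the *full* input
tree, so removing a genus's sister from the dataset does not inflate its
age.

Ultrametricity is checked with a relative tolerance of 1e-6 × root depth
(dated ML trees carry rounding error); failing trees are flagged
(`is_ultrametric = False`) but remain usable. Taxon matching is exact after
whitespace/case normalization and an explicit synonym substitution map;
fuzzy matching is deliberately excluded so the match report stays auditable.
Pruning suppresses the degree-2 nodes it creates and sums their branch
lengths, leaving all retained divergence times unchanged.

## Net diversification rates (`divelev.rates`)

The Magallón–Sanderson ML stem estimator with relative extinction ε = μ/λ:

    r̂ = ln(n(1−ε) + ε) / t ,   n ≥ 1, t > 0, 0 ≤ ε < 1.

"log" is the natural logarithm — only that base is consistent with rates of
the reported order of magnitude given genus-level stem ages — but the base
is exposed as a parameter for audit. ε defaults to 0 (r̂ = ln(n)/t), the
implicit choice in genus-level applications, and can be raised to probe
extinction sensitivity. r̂ = 0 exactly iff n = 1 at ε = 0.

The distribution summary uses fixed bins [0, 0.1), [0.1, 0.2], (0.2, ∞)
with zeros counted separately. Because verbal descriptions of the middle
bin are ambiguous at its boundaries, the half-open convention [0.1, 0.2) /
[0.2, ∞) is reported alongside whenever the two differ.

## Band statistics (`divelev.gradients`)

Bands are taken as given in the input records (the source transects' own
belts); the package never re-bins raw elevations. DivElev and AgeElev
average over the *distinct* genera present in a band by default, matching
the one-record-per-genus-per-band reduction; `distinct_genera=False` keeps
the raw-record weighting so both variants of the analysis are available.
AgeElev uses the same stem ages as the rate estimator. relElev is a band's
elevation as a percentage of the highest *occupied* band on its gradient;
relRich the band richness as a percentage of the gradient's maximum.
Records whose genus has no profile are dropped with a logged reason code,
never silently.

The one-way ANOVA is the classical between/within mean-square ratio with
fixed degenerate conventions (all values identical → F = 0, p = 1; zero
within-group variance with differing means → F = ∞, p = 0). The HSD test is
Tukey–Kramer (scipy's studentized-range implementation), which honors the
unequal group sizes that arise when the all/epiphyte/non-epiphyte datasets
cover different numbers of bands.

## Climate calibration (`divelev.climate`)

Per gradient and Bioclim variable, a polynomial in elevation is fitted by
least squares; elevations are internally rescaled to [0, 1] before building
the Vandermonde matrix (metre-scale cubes are numerically ill-conditioned)
and the coefficients back-transformed exactly. Temperature variables are
restricted to degree 1 and always accepted — a lapse line is the physically
sensible model and the acceptance rule is meant for precipitation surfaces.
Precipitation variables try degrees 1–3 (where the point count allows,
n ≥ degree + 2) and keep the highest adjusted R², with AICc selection
available as an option; they are accepted only if adjusted R² exceeds the
threshold (default 0.5). Predictions from rejected models are refused
rather than returned with a warning, which forces the exclusion rule at the
call site. Direct (station/raster) values always override model predictions
when climate is attached to band statistics; bands covered by neither stay
missing.

## Regressions (`divelev.regress`)

**Beta regression.** DivElev is a mean of small rates and lives in [0, 1);
bands holding only monospecific genera give exactly 0, so the response
vector is compressed by the standard (y(n−1) + 0.5)/n transformation
whenever any value touches a boundary. The model is the mean–precision
parameterization (shape parameters μφ and (1−μ)φ), logit mean link,
constant φ, fitted by ML (statsmodels' beta model). Initialization is
deterministic: least squares on logit(y) for the mean coefficients and a
method-of-moments φ. Newton, L-BFGS and BFGS are all run from that start
and the best converged solution kept, because Newton can stall on a
spurious stationary point; an ascent check rejects any "solution" below the
initializer. If the mean model fits the logit response exactly (constant y,
or y generated noiselessly from the model) the ML precision diverges and
the analytic limit is returned (exact coefficients, φ = ∞) instead of
chasing it. Goodness of fit is the Ferrari–Cribari-Neto pseudo-R²: the
squared Pearson correlation between the linear predictor and logit(y),
reported as missing when either vector is constant.

**Identity-link Poisson-family GLM.** AgeElev is a continuous mean age, so
the fit is quasi-likelihood IRLS with Poisson variance and identity link
(the deviance 2Σ[y ln(y/μ̂) − (y − μ̂)] extends continuously to non-integer
y); `round_response=True` gives a strict Poisson likelihood on rounded
responses. The identity link is the only response scale on which
intercepts of tens of Ma and slopes of a few Ma/°C are meaningful — a log
link would put ages on e^{tens}. Starting values come from OLS, shifted
into the positive-mean domain when necessary; fits whose means are driven
to ≤ 0 raise. Fit quality is the Kullback–Leibler (deviance-ratio) R² =
1 − D/D₀, clamped to [0, 1] and defined as 0 for intercept-only fits. It is
reported unadjusted, and flagged as such by name.

**Model comparison.** Likelihood-ratio tests require term-subset nesting
and use χ² with df = Δk; ΔAICc (small − large) is reported alongside, with
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1). Quadratic fits additionally report the
stationary point −β₁/(2β₂), labeled maximum (β₂ < 0) or minimum.

## Phylogenetic signal and ancestral states (`divelev.comparative`)

Thermal preference per genus is the unweighted mean of band-level climate
values over *all* the genus's occurrence records, pooled across gradients —
a genus recorded in many bands is averaged over all of them; genera with no
climate-bearing record are excluded and logged.

Pagel's λ multiplies the off-diagonal entries of the BM tip covariance
(shared path length from the root), leaving the diagonal unchanged. The
profile likelihood over λ — root state and σ² profiled out analytically by
GLS — is maximized on [0, 1] by bounded Brent search (tolerance 1e-6), with
both endpoints evaluated explicitly so boundary optima are exact. λ > 1 is
not supported: its admissible range is tree-dependent and rarely
interpretable. The reported p value is the LR test of λ̂ against λ = 0 on
χ²₁. A singular covariance (e.g. effectively zero-length structure) raises
with a pointer to the cause rather than returning garbage.

Ancestral states are the BM maximum-likelihood (GLS) values. Implementation
is a linear-time two-pass message-passing scheme: a tip-to-root pass
combines each node's descendant information into a (mean, variance)
message, and a root-to-tip pass supplies the information from the rest of
the tree; a node's estimate pools the messages from all adjacent subtrees
by precision weighting, which equals the GLS root estimate of the tree
re-rooted at that node. The variance is σ̂² (the ML rate from the original
rooting) times the pooled message variance — equivalently σ̂²/(1ᵀC′⁻¹1) on
the re-rooted covariance — and the 95% CI is ±1.96 sd. The test suite
verifies numerical equality (1e-8) against an independent dense-matrix
oracle that literally re-roots the tree and inverts the covariance.
Reconstruction is on the untransformed tree by default (the convention of
the standard tools), with an optional λ argument that rescales internal
branch shares while preserving tip depths.

## Synthetic data (`divelev.synth`)

The generator emulates the statistical *structure* the analysis assumes, at
desk scale, with full determinism under one seed:

* **Tree** — a birth–death tree conditioned on the tip count via the
  general sampling approach (dendropy; GSA avoids the zero-length terminal
  edges of naive stopping), rescaled to a fixed crown age. Defaults: 180
  tips, pure birth, 400 Ma crown age.
* **Trait** — one multivariate-normal draw from the λ-transformed BM
  covariance. Defaults: root 11 °C, σ² = 0.06 °C²/Myr (tip sd ≈ 5 °C at
  400 Ma), λ = 1.
* **Richness** — n = round(exp(r(T)·t)) with r(T) = max(0, a + bT),
  defaults a = 0.005, b = 0.004: warm-adapted genera diversify faster, the
  regime the regression stage should recover. r·t is capped at ln 10⁶.
* **Gradients** — 6 mountains with sea-level temperatures evenly spaced
  over 20–26 °C, a 5.5 °C/km lapse, 250 m bands (midpoints) up to 4000 m.
  A genus occupies a band iff the band temperature is within ±5 °C (niche
  breadth) of its preference — deterministic occupancy keeps the test
  oracles exhaustive; an optional dropout probability stress-tests the band
  statistics. Life form is a deterministic threshold (preference ≥ 13 °C →
  epiphyte), mirroring the warm-epiphyte association.
* **Climate points** — the exact lapse line for Bio1 and a hump-shaped
  quadratic surface for Bio12, with optional Gaussian noise.

What it does **not** emulate: observation-effort differences between source
studies, species-level (as opposed to genus-level) sampling, precipitation
seasonality structure beyond a single polynomial surface, spatial
autocorrelation among gradients, and taxonomy errors beyond the synonym
mechanism. Tests passing on these data therefore demonstrate correctness of
the estimators and plumbing under the stated generating model, not
robustness to the messiness of real transect compilations.

## Problem sizes and tolerances used in the test suite

Simulation-based checks run at sizes chosen to make their pass criteria
statistically comfortable while keeping the suite quick: beta-regression
Wald coverage at n = 500 × 200 replicates (≥ 90% per coefficient),
LR-test size at 500 null simulations (0.05 ± 0.02), λ recovery/null
behavior at 200 tips × 100 replicates, the end-to-end slope-sign check at
100 replicate worlds (≥ 95% positive), and dense-oracle equality for the
ASR at 8 tips to 1e-8. Round-trip Newick IO is exact to 1e-9 relative.

## Known limitations

* The stem estimator conditions on clade survival only through the
  Magallón–Sanderson form; no rate-shift or lineage-through-time inference.
* Beta regression uses constant precision; variable-φ models are out of
  scope.
* The identity-link Poisson GLM can be untenable when a linear predictor
  crosses zero inside the data range; it raises rather than silently
  switching link.
* No multiple-testing correction is applied across the many reported
  regressions, matching the analysis design this package reproduces.
* Climate models are per-gradient 1-D polynomials; no spatial
  interpolation or raster sampling.
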