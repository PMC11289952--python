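# Methods

This note records the models implemented in `chromascape`, their
assumptions, the numerical choices made where the design was open, and
what the synthetic-data tests do and do not demonstrate.

## Observer model

The modeled observer is a trichromatic reef fish with a double cone:
channels (sw, mw, lw, dbl), relative photoreceptor abundances
η = 1:2:2:2 and receptor noise ν = 0.05. Channel Weber fractions are

    ω_i = ν · sqrt(η_max / η_i),

so the most abundant channels carry the nominal noise and the rare sw
channel is noisier (0.0707…, reported as 0.07). This is the standard
receptor-noise-limited (RNL) scaling in which discriminability of a
log-contrast Δf_i is set by channel noise; the chromatic distance ΔS
is the trichromatic RNL form on Δf = ln(q^a/q^b), and is verified in
the tests to equal, to 1e−9, an independently coded Mahalanobis
distance with covariance diag(ω²) projected onto the plane orthogonal
to uniform intensity changes. Consequences used throughout: ΔS is a
pseudometric (symmetry, triangle inequality hold in Δf space), is zero
for proportional catches, and is invariant to overall intensity.
Achromatic contrast is ΔL = |Δf_dbl|/ω_dbl.

Assumptions: catches are linear, strictly positive quantum catches
already integrated over receptor sensitivities (no spectral
integration, no chromatic adaptation); noise is independent across
channels; the double cone alone carries luminance.

## Viewing distance and acuity

A scene detail of physical size s at distance d subtends
θ = atan(s/d). With acuity a (cycles/degree, default 3) the minimum
resolvable angle is 1/a degrees. The acuity operator is a channel-wise
Gaussian low-pass whose σ is chosen so the modulation transfer at the
acuity frequency — a·(degrees per pixel), in cycles/pixel — equals
10%:

    MTF(f) = exp(−2π²σ²f²),  σ = sqrt(ln 10) / (√2 · π · f_cutoff).

The 10% point treats the acuity limit as near-extinction of contrast,
which matches how behavioral acuity is measured; the operator is
linear, positive, and attenuates a grating 6× finer than the limit by
many orders of magnitude (asserted spectrally in tests). A scene whose
blur extent exceeds the image is rejected rather than silently
returning a constant.

At the default scale (4 px/mm) the 2 cm view is nearly unblurred
(cutoff above Nyquist) and the 30 cm view blurs with σ ≈ 1.7 px — the
2 cm / 30 cm contrast in the statistics is driven by this difference.

## RNL ranked filter

Acuity blur creates shallow gradients that would segment into spurious
thin classes. The ranked filter removes them while preserving genuine
edges: for each pixel, neighbors within `radius` (5) are ranked by
combined distance √(ΔS² + ΔL²) to the center, weighted
(1 − rank/N)^falloff (falloff 3, center weight 1), averaged, and the
pass repeated (5×). Perceptually close neighbors dominate, so a pixel
near an edge averages with its own side. The parameter names and
values follow the published toolbox settings; the ranking metric and
weight law are this package's reconstruction, and the tests assert the
behavioral contract directly: ≥99% class recovery on noisy two-phase
mosaics with the mean edge position unmoved, exact invariance on
uniform images, identity at repetition 0.

## RNL clustering

Segmentation merges image regions that the observer cannot tell apart.
Pixels are first assigned to perceptual prototypes found by
deterministic farthest-point seeding in (ΔS, ΔL) space (brightest
pixel first; up to 10 seeds by default), split into 4-connected
regions, and then merged agglomeratively: an adjacent pair merges when
its means are below **both** thresholds (t_color = 2 ΔS,
t_lum = 4 ΔS), smallest combined distance first, ties broken by lower
region index, means recomputed after every merge. A final global pass
applies the same rule to non-adjacent classes so that the class table
satisfies pairwise discriminability: every pair of classes differs by
≥ t_color chromatically OR ≥ t_lum achromatically.

The merge-on-below-both rule encodes that a pair differing strongly in
luminance alone is still discriminable; the alternative (merge unless
both exceed) would fuse luminance-only boundaries. The merge order and
tie-break make the fixed point deterministic. Under heavy pixel noise
a vanishing extra class (abundance < 1%) can survive filtering; the
segmentation contract in the acceptance tests is therefore pixel
agreement with ground truth (≥99%), with exact two-class recovery
asserted in the noiseless case.

## Pattern statistics

All statistics are computed over the background mask only. Transition
matrices count class pairs of adjacent samples along every horizontal
and vertical transect (spacing 1 px by default); "synonymous" =
diagonal. The implemented catalogue (33 outputs) covers the named
statistics of the four families plus horizontal/vertical variants,
behind a registry in fixed order so downstream column filtering is
reproducible:

* CAA: mean 4-connected patch size in mm² (PT), Shannon evenness of
  class abundances (Qc, = 1 for a single class) and of off-diagonal
  transition types (Qt, = 1 when only one type exists, NaN with no
  boundaries), and the horizontal/vertical nonsynonymous-rate aspect
  ratio (Inf when one direction has no boundary, NaN when neither
  does).
* VCA: abundance-product-weighted mean and SD of pairwise ΔL (ML,
  MSL), abundance-weighted CoV of class saturation (CVS), plus mean
  class luminance and saturation. Saturation is the chromatic ΔS of a
  class mean from the equal-catch (achromatic) locus.
* BSA: the same contrasts weighted by realized boundary frequencies
  (off-diagonal transition counts): BML, BMS, BCVL, BCVSsat.
* LEIA: ΔS and ΔL between each in-mask pixel and its right/lower
  neighbor, summarized by mean, CoV and excess kurtosis, pooled and
  per direction.

Degenerate inputs produce NaN (single class → pairwise statistics;
zero variance → kurtosis and CoV; zero mean → CoV), which is load-
bearing: the complete-case filter downstream uses exactly these NaNs
to exclude uniform backgrounds. Excess kurtosis uses the normal ⇒ 0
convention. Every family is tested against hand counts and brute-force
recomputation on checkerboards, stripes and uniform images, and for
invariance to class relabeling.

## Defense scoring

Per-extract indices are 1 − normalized ED50 (unpalatability) and
1 − normalized LD50 (toxicity), both on [0, 1] with 1 = most defended;
normalization of raw doses happens upstream. Species indices average
whole-body extracts only; a species with no usable extract is reported
missing, never zero. Classification: 0 → palatable; (0, 0.25] →
weakly; (0.25, 0.74) → medium; ≥ 0.74 → highly unpalatable. The 0.25
boundary is read inclusive-low and 0.74 inclusive-high (0.74 being the
median unpalatability among defended species in the motivating data);
both cut-offs are arguments. Analysis groups combine class with
toxicity presence: undefended (palatable, no toxicity),
toxic-moderate, toxic-high; an unpalatable-but-nontoxic combination
has no defined group and raises for manual assignment.

## Factor reduction

Rows with any NaN/Inf statistic are dropped with per-distance counts
reported (more drop at 30 cm, where blur merges patches). Columns then
pass a greedy filter in registry order: keep a column iff |Pearson r|
< 0.6 against all kept columns. The survivor set depends on the scan
order; the registry order is fixed and logged precisely because
alternative orders give different (equally valid) survivor sets.

The factor count comes from parallel analysis: observed correlation
eigenvalues vs the position-wise median over simulated iid standard-
normal datasets of identical shape (10,000 by default; the retained
count is the leading run of observed values strictly above their
medians). The leading-run convention matters: on pure noise roughly
half of all positions beat their median by chance, but the leading run
is short, and on factored data the run ends exactly where the signal
eigenvalues stop.

Extraction is unweighted least squares (minres): uniquenesses ψ are
optimized (L-BFGS-B, bounded [0.005, 1], Heywood cases clipped with a
warning) to minimize the residual sum of squares of the reduced
correlation matrix beyond the top-k eigencomponent, whose scaled
eigenvectors are the loadings. Varimax rotation (with Kaiser
normalization) matches R's `stats::varimax` to 1e−7 on a frozen
reference case. Factors are ordered by explained variance and
sign-fixed so the dominant loading is positive; scores use the
regression (Thurstone) method. Bootstrap loading intervals resample
rows, refit, and align each replicate to the point estimate by the
signed column permutation maximizing Tucker congruence — without
alignment, factor switching would make percentile intervals
meaningless.

## Distributional group model

For one factor's scores y_i (species s(i), group g, distance d):

    y_i ~ Student-t(ν, μ_i, σ_i)
    μ_i = x_i'β + u_{s(i)} + v_{s(i)}·d_i + p_{s(i)}
    log σ_i = x_i'γ

x is the full 3×2 group-by-distance interaction (treatment coding,
6 columns, identical for mean and scale). (u_s, v_s) are correlated
species intercepts and distance slopes; p_s is a phylogenetic
intercept with correlation matrix C from the tree — for Brownian
evolution on an ultrametric tree, C_ij = shared root-to-split path /
tree depth (identity for a star tree, 0.5 for sisters splitting at
half depth). Species and phylogenetic intercepts are deliberately two
separate terms with their own SDs: one absorbs species-specific
ecology, the other the heritable signal; with 12 species they are only
weakly separable, which the sampler must handle (below).

Priors: β_j, γ_j ~ N(0, 5); sd_u, sd_v, sd_p ~ Exponential(1);
intercept–slope correlation ~ LKJ(2); ν − 1 ~ Gamma(2, 0.1). All
random effects are non-centered. The likelihood and priors are written
as one explicit vectorized log posterior.

**Sampling.** Affine-invariant ensemble MCMC (emcee) with
differential-evolution moves, ~160 walkers for the 53-dimensional
posterior, run as 4 independent ensembles from jittered least-squares
initializations. The species/phylogeny variance ridge gives integrated
autocorrelation times of ~200–300 steps, so the desk schedule uses
6,000 warmup steps and a retained span of 3,200 steps thinned by 40;
each ensemble contributes ≥500 post-warmup draws (walkers × kept
steps) and the four ensembles serve as chains for split R-hat, bulk
ESS and MCSE (via arviz). The `full` profile lengthens warmup and
returns 2,000 draws per chain (8,000 total); `fast` is a short
schedule for simulation studies where per-fit convergence
certification is not needed. The convergence contract — max R-hat
≤ 1.01, bulk ESS > 10% of draws, MCSE < 5% of the posterior SD for
every sampled parameter — is checked after every fit and raises by
default.

**Summaries.** Population-average cell values marginalize random
effects at zero: cell means x_c'β and cell residual SDs exp(x_c'γ)
(back-transformed from the log scale), summarized by posterior medians
and 95% quantile intervals; all C(6,2) = 15 pairwise contrasts are
computed draw-wise (hence exactly linear: contrast(a,b) +
contrast(b,c) = contrast(a,c) per draw).

## Synthetic data

Scenes are Voronoi mosaics: seeds Poisson-sampled at density
(image area)/(diameter²), each cell colored by its class mean,
lognormal multiplicative pixel noise (catches stay positive; RNL math
is log-ratio based). Class means are placed by drawing random
log-catch directions and rescaling them so the mean pairwise ΔS and ΔL
across classes equal the requested chromatic and luminance spreads
exactly (verified to 5% against realized class means in tests). A
study couples species to defense levels through multiplicative effects
on spread and patch size; assay indices are drawn uniformly inside
each level's classification interval so scoring round-trips exactly;
the tree is a pure-birth (Yule) simulation scaled to unit height.
Factor-score simulation draws directly from the distributional model
itself (known cell means/SDs, species, slope and Brownian phylogenetic
effects, Student-t noise).

What the generator does **not** emulate: real coral-reef backgrounds
have spatial spectra, illumination gradients, shadows, and non-Voronoi
patch geometry; species occupy overlapping habitat distributions
rather than parameter-shifted copies of one process. Passing tests
therefore demonstrate that the pipeline recovers structure it is
pointed at under controlled conditions — correctness of the machinery,
not ecological realism of any particular effect size.

## Problem sizes and simulation scale

Defaults chosen for desk-scale validation: 12 species (5/4/3 per
group), 15 images × 2 distances for score-level studies (360
observations per fit), 64×64 px scenes at 4 px/mm for image-level
runs, parallel analysis with 1,000 simulated datasets in the
validation suite (10,000 remains the pipeline default), bootstrap
intervals at 1,000 iterations in the pipeline. The calibration studies
(null coverage, effect recovery) run 20 replicate fits each at the
`fast` schedule.

**Null-coverage design.** The null study mirrors the generator's
equal-multiplier design: with no group effects, species share a single
background-generating process, so the score-level null sets the
species, slope and phylogenetic SDs to zero. Coverage is assessed per
interval (pooled over 20 replicates × 15 contrasts ≥ 90%): the model
issues unadjusted 95% intervals, and the probability that 15
correlated intervals *simultaneously* cover zero is ~0.75–0.8 by
construction (~6–9 quasi-independent contrasts at 95% each) — a joint
criterion would measure multiplicity, not calibration. Measured pooled
coverage is ~97%; the corresponding effect-recovery study (a planted
1.5-score group shift, the magnitude of the largest group contrast the
method is expected to detect) recovers the shift with a
zero-excluding, truth-covering interval in 19/20 replicates.

## Known limitations

* The ranked filter and clustering internals are behavioral
  reconstructions of published toolbox settings; statistic-by-
  statistic numerical parity with that toolbox is not claimed, and the
  registry is deliberately swappable.
* The statistic catalogue is the documented subset (33 outputs), not
  the full inventory of the original 157-dimensional space; factor
  structure over a different catalogue will differ.
* The ensemble sampler certifies convergence through the stated
  diagnostics but remains slower per effective sample than a
  gradient-based sampler would be on this posterior; the desk profile
  trades wall-clock time for certification.
* Exact zero catches are rejected rather than imputed; real calibrated
  images with clipped pixels need upstream cleaning.
* `apply_acuity` models optical resolution only — no contrast
  sensitivity function, no photon noise at distance.
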