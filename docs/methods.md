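# Methods

## The forward model

`leafoptics` simulates leaf directional-hemispherical reflectance and
transmittance with the generalized plate model (the PROSPECT-D
formulation). A leaf is `N` identical absorbing plates separated by air
gaps, `N ≥ 1` real-valued. Per wavelength λ:

1. **Absorption.** k(λ) = Σ_c C_c·K_c(λ) / N over the five absorbing
   constituents c ∈ {CHL, CAR, ANT, EWT, LMA}; K_c are the specific
   absorption coefficients of the optical-constants table, in units
   reciprocal to the trait so C_c·K_c is dimensionless. Brown pigment is
   excluded throughout (absent outside late senescence); the constants
   reader rejects tables carrying a sixth absorber rather than silently
   ignoring it.
2. **Elementary layer.** τ(k) = (1−k)e^{−k} + k²E₁(k) — the exact
   transmission of an isotropically illuminated slab, equal to
   2∫₀¹ µe^{−k/µ}dµ. E₁ is `scipy.special.exp1`.
3. **Interfaces.** tav(α, n): the Fresnel transmittance of unpolarized
   light averaged over incidence angles 0..α, evaluated with the closed
   form of Stern used throughout the plate-model lineage. The top surface
   uses α = 40° (near-normal illumination cone, the lineage's convention,
   exposed as an argument); interior faces use α = 90° (diffuse flux). The
   interior exit transmissivity is tav(90, n)/n².
4. **Single plate and stack.** The one-plate reflectance/transmittance
   follow from the geometric series over internal bounces; the remaining
   N−1 identical interior plates are composed with the Stokes solution
   (b^{N−1} evaluated as exp((N−1)·log b), so non-integer N is smooth),
   and the two systems are coupled with the standard two-stream adding
   formulas using the asymmetric pair (top-plate transmittance down,
   interior-plate transmittance up) — the convention of the reference
   implementations of this model family.

Degenerate branches: layers with r + t = 1 (no absorption) use the
conservative limit T = t/(t + (1−t)m); r → 0 uses the purely transmitting
limit; t = 0 returns (r, 0). Energy (R, T ≥ 0, R + T ≤ 1) is asserted by
the `LeafSpectra` container and property-tested over random trait draws.

The engine is grid-agnostic: every operation runs on whatever wavelength
grid the optical-constants table defines. Two grids are bundled: the full
1-nm grid (400–2450 nm, 2051 points) and a 41-nm "desk" grid (51 points)
that preserves the band geometry at a fraction of the cost. All
simulation-based tests and the acceptance script use the desk grid; the
full grid is the documented production default for real coefficient
tables, which load through the same CSV layout.

## Inversion

Reflectance-only inversion (transmittance is commonly unmeasured) minimises
the RMSE over wavelengths between simulated and target reflectance. The
optimizer is bounded trust-region least squares on the per-wavelength
residual vector (`scipy.optimize.least_squares`, `method="dogbox"`), in
unit-box-scaled parameter space, with three starts: the fixed
mid-physiological init (N=1.5, CHL=40, CAR=10, ANT=1, EWT=0.01, LMA=0.005)
plus two seeded perturbations around mid-bounds. `dogbox` rather than `trf`
because traits pinned at a bound (CAR or ANT at 0 is common on noisy
spectra) are exactly where `trf`'s interior-point gradient scaling vanishes
and triggers premature convergence; `dogbox` drives the residual to
~machine precision on the same cases. Default bounds span the ranges of
the plate-model literature (N ∈ [1,4], CHL ∈ [0,120] µg/cm², CAR ∈ [0,30],
ANT ∈ [0,40], EWT ∈ [0,0.1] cm, LMA ∈ [0,0.05] g/cm²); stopping at merit
1e−10 or 5000 evaluations per start. Per-row random substreams are keyed
by `sample_id` (CRC32), so permuting dataset rows permutes results
identically, and a fixed seed makes whole cycles bit-reproducible.

The regeneration cycle chains inversion and simulation twice
(measured → P_inv → HSR_sim → P_re → HSR_re). Because HSR_sim lies on the
model manifold by construction, the sim→re leg isolates pure inversion
error — measured zero to ~1e−11 relative — so any measured-vs-simulated
discrepancy is attributable to the forward model, not the optimizer.

## Error statistics and band flagging

Per wavelength, across paired samples: mean relative error
δ̄(λ) = (1/n)Σ|b−a|/|a| (asymmetric; `a` is the measured/denominator
role), Pearson correlation (NaN marker when a column is constant — treated
as sub-threshold by band flagging, since constant near-zero columns are
exactly the failure mode of interest), and RMSE. `flag_low_accuracy_bands`
returns maximal contiguous runs with r below a threshold (default 0.8),
dropping runs narrower than 10 nm; the defaults reproduce four distinct
bands on the bundled synthetic phenomenology without fragmenting into
single-wavelength islands. Paired datasets are matched by row position and
a `sample_id` ordering mismatch raises rather than reorders.

## Transferability and sensitivity

PLSR models (scikit-learn, 30 latent variables, mean-centering only — no
unit-variance scaling) map reflectance to one trait. The transfer protocol
fits on one *full* dataset and scores on every *full* dataset — no internal
split; the diagonal is training-set performance and labelled as such.
Scores: Pearson r and the coefficient of determination
R² = 1 − SS_res/SS_tot on the test set, with a copy clamped at −1 so failed
transfers share a display scale. Requested component counts above
min(n_samples−1, n_wavelengths) are capped with a logged warning.

Sensitivity profiles vary one trait at a time: each sample keeps its own
value of the probed trait, the other five sit at dataset means, and the
per-wavelength CV = σ/µ of the simulated ensemble (NaN where µ = 0,
excluded from summaries) measures where and how strongly that trait moves
the spectrum.

## Neural surrogate

A feed-forward ReLU network with four hidden layers (512-256-128-64)
predicts one trait from a reflectance spectrum. Training: mean-squared
error, Adam (β = 0.9/0.999) with decoupled L2 weight decay, batch size 128,
500 epochs (desk-scale tests use 200), and a step scheduler multiplying the
learning rate by 0.95 every 10 *epochs* — with batch 128 a per-batch decay
would annihilate the rate within one epoch. Per-trait defaults from the
fixed hyperparameter grid: learning rate 5e−4 (N, CHL, EWT, LMA) or 1e−3
(CAR, ANT); weight decay 1e−3 (N, CHL, EWT), 5e−3 (LMA), 5e−5 (CAR),
1e−5 (ANT). Inputs are raw reflectance in [0,1] (users of radiance-scaled
data must convert first) and single-target models train on raw trait units.
Multi-target models standardize each head's target inside the loss and
de-standardize predictions: trait units differ by three orders of magnitude
and the largest-unit head otherwise owns the shared layers. Hidden layers
use He initialisation; the output layer is zero-initialised, which makes
multi-target head order exactly symmetric.

The network, its optimizer and its input gradients are implemented directly
on numpy: the training recipe (epoch-step scheduler, decoupled decay) and
the exact input gradients needed for attribution live in one small,
seedable implementation. Ensembles train members at seeds s, s+1, …;
a diverging member is reported and the ensemble continues if at least half
survive.

Integrated gradients use the all-zeros spectrum as the default baseline —
the origin of the reflectance input space, which makes the attribution of
an exactly linear model equal w_λ·x_λ in closed form. The path integral is
a right-endpoint Riemann sum (s = 1..steps, default 64); the completeness
residual |Σ_λ IG_λ − (F(x) − F(baseline))| is recorded per sample and
shrinks as steps grow.

## Heritability

Each wavelength of a measured dataset is an individual trait. Repeats
(multiple technical measurements within a replicate) are averaged first:
the variance model has no repeat term. The random-effects model
y = µ + genotype + environment + genotype×environment + residual is fitted
by REML (statsmodels MixedLM: genotype random intercept, a
genotype-by-environment variance component, environment main effect fixed —
it does not enter the entry-mean variance). Components are truncated at
zero. H² = σ²_g/σ²_p with σ²_p = σ²_g + σ²_ge/n_e + σ²_ε/(n_e·n_r); for
unbalanced trials n_e and n_r are harmonic means of per-genotype counts
(standard entry-mean practice), reported alongside the components.
Degenerate designs are handled explicitly: a single unreplicated
environment confounds genotype and residual, and by convention all
between-genotype variance is then genotypic; a noiseless dataset makes the
REML surface singular, and a method-of-moments ANOVA estimator (exact for
balanced data) takes over there and on any MixedLM convergence failure.

## Synthetic data: what it emulates, and what it does not

The synthetic module makes every pipeline testable offline; its defaults
are fixed study conditions, not tuning knobs.

**Optical constants.** Gaussian absorption bands with compact support
(centre ± 3 widths) per constituent. CAR (490 nm) and ANT (555 nm) are
nested wholly inside the CHL support — the chlorophyll masking that makes
the two pigments weakly identifiable; EWT and LMA occupy broad bands in the
1100–2450 nm half. Peak magnitudes are calibrated so a typical green leaf
is saturated-dark (reflectance pinned near the surface-reflection floor)
inside the four classic low-reflectance wavebands — 400–500, 600–725,
1860–2025, 2325–2450 nm — while the green window, NIR plateau and
1500–1850 nm shoulder stay bright and trait-responsive. The refractive
index declines smoothly from ~1.49 to ~1.41.

**Populations.** Three archetypes. *Wide*: broad truncated-normal coverage
of all six traits with long-tailed lognormal CAR and ANT and a CHL–CAR rank
correlation of 0.8 (Gaussian copula). *Crop*: the same shapes, narrow and
unimodal, contained inside the wide coverage. *Tropical*: bimodal mixtures
for N, CHL, EWT and LMA whose components are cohort-linked — all mixture
traits share one per-sample latent (correlation 0.988), so samples lie
almost on a one-dimensional developmental axis (young vs mature leaves of a
single species). This gives the tropical set large marginal variances (so
models tested *on* it can score well) but nearly collinear traits (so
models trained *on* it confound traits and extrapolate poorly) — the
mechanism behind the asymmetric transfer the framework studies.
`archetype_suite` bundles the three at n = 400 with mild
wavelength-uniform noise (sd 0.003), which regularizes the 30-component
PLSR the way instrument noise does; on noiseless low-rank synthetic data
the trailing latent variables are numerical junk with explosive
extrapolation.

**Measurement noise.** Band-localized: inside the four wavebands above,
multiplicative jitter (relative sd 0.6) plus additive noise (sd 0.02);
elsewhere additive sd 5e−4. Output clipped to [1e−4, 1] — a measured
reflectance of exactly zero is unphysical and would poison the relative
error's denominator. Magnitudes were chosen once so that the regeneration
cycle on corrupted data reproduces the qualitative band phenomenology
(correlation depressed inside, intact outside, the four bands recovered by
flagging at the default threshold).

**Trials.** Genotype effects (σ²_g), genotype×environment effects (σ²_ge)
and plot residuals (σ²_ε) act additively on one trait axis (default CHL)
around a baseline leaf, with fixed environment shifts, 1–2 replicates and
1–3 repeats drawn per cell, and small repeat-level technical noise;
spectra follow by forward simulation.

What passing tests do **not** show about real data: the synthetic optical
constants are not the calibrated coefficients of the real model family
(those load through the same CSV interface but are not bundled); real
measured spectra carry instrument response functions, smoothly correlated
noise and species-specific structure absent here. The synthetic suite
demonstrates that the machinery — inversion, error statistics, transfer
scoring, surrogate training, heritability estimation — behaves correctly
under known ground truth, not that any particular real dataset will show
the same numbers.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script run on the 51-point desk
grid with: 50 leaves for the regeneration round trip; 100 uniform draws
over the interior of the default bounds (5% margin per trait, keeping
relative recovery error well-defined away from zero) for inversion
recovery; 400 samples per archetype for transfer; n = 2000 training /
500 test samples, 200 epochs for surrogate recovery; 200 genotypes × 2
environments × 2 replicates × 20 seeds for heritability recovery. Inversion
tolerances: xtol/ftol 2.5e−16, gtol 1e−15, 5000 evaluations per start.
CSV output uses 9 significant digits. Pearson and CV undefined cases are
NaN markers, never silent zeros.

## Known limitations

* The NN surrogate runs on CPU numpy; it is fast at desk scale
  (~10 s/model) but not GPU-accelerated for the full 2051-input production
  configuration at large n.
* The heritability model fits wavelengths independently; no spatial field
  trend correction, no narrow-sense or marker-based heritability.
* Inversion is point-estimate only (no posterior), reflectance-only by
  design, and the merit applies no wavelength weighting.
* The sensitivity analysis is one-at-a-time; it does not capture
  interaction effects between traits.
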