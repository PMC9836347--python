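# Methods

## The model

Plot-level temporal phenotypes (vegetation indices and the 99th-percentile
canopy height, CHM) from repeated drone flights over a replicated hybrid
trial are decomposed with a flight-nested random-effects model

    y_ijg = μ + β_i + R_j(i) + Ω_g(i) + ε_ijg ,

where i indexes flights (time points, in days after planting), j
replicates and g genotypes. All terms are random and the intercept fixed.
Nesting replicate and genotype within flight treats the season-long series
of one index as a single phenotype whose dominant source of variation is
temporal plasticity (the flight term), with a small genotype-within-flight
term carrying the genetic signal at each time point. Two estimators are
implemented:

* **Balanced ANOVA / method of moments** — closed form from the expected
  mean squares of the nested design. With I flights, J reps, G genotypes:
  σ̂²_ε = MS_res, σ̂²_Ω = (MS_geno − MS_res)/J, σ̂²_R = (MS_rep − MS_res)/G,
  σ̂²_β = (MS_flight − MS_rep − MS_geno + MS_res)/(JG). Negative estimates
  are truncated to zero after estimation (the raw values are kept for
  diagnostics). This path refuses unbalanced tables.
* **EM-REML** — EM iterations on Henderson's mixed-model equations,
  handling unbalanced data (e.g. fewer genotypes in the stressed trial)
  and never leaving the parameter space. Convergence is declared when
  every component's relative change falls below 1e-8 (default), capped at
  10,000 iterations. On balanced designs the two estimators agree to
  ~1e-9 relative, which the tests assert; the restricted likelihood is
  checked to be non-decreasing across iterations on fixture-sized
  problems (an O(n²) dense evaluation used only in tests).

Temporal repeatability is the entry-mean repeatability of the
genotype-within-flight term, TR = σ²_Ω / (σ²_Ω + σ²_ε/n_rep), clamped to
[0, 1], with n_rep the (harmonic-mean) number of replicates per
genotype-flight cell. Flight-wise genotypic values are BLUPs
μ̂ + β̂_i + Ω̂_g(i) obtained from a single mixed-model solve at the
estimated components; components at numerical zero are floored at 1e-9 of
the total variance in that solve so the system stays well conditioned
while the corresponding effects shrink to ~0.

## Imaging

The VI registry ships 20 RGB-only and 20 red-edge/NIR indices under their
standard published formulas (RCC, NGRDI, MGRVI, VARI, ExG/ExR/ExGR, GLI,
chromatic coordinates, RGBVI, CIVE, ...; NDVI, GNDVI, NDRE, SAVI, OSAVI,
NLI, MNLI, EVI2, MSAVI, RDVI, SR, chlorophyll indices, ...), each with its
required bands and, where bounded, a valid output range that property
tests enforce on random reflectance. The registry is extensible; exact
formula-level parity with any particular instrument panel is not claimed.
Division-by-zero pixels become NaN (missing), never infinities.

Plot extraction uses pixel-center containment with half-open edges: a
center lying exactly on a shared plot boundary belongs to the polygon
whose interior lies toward +x/+y (implemented by nudging the sampling
point by 1e-9 px), so adjacent plots partition the raster
deterministically. Reflectance is float in [0, 1]; 8-bit rasters are
rescaled by 1/255 on read. The CHM percentile uses linear interpolation
between order statistics. Soil masking is off by default; an optional ExG
threshold mask is exposed.

## Synthetic trials

The generator reproduces the study design the analysis assumes: ~280
hybrids from inbred crosses (homozygous parents, F1 dosage = parent mean),
a two-rep RCBD under optimal (OM) and stressed (SM) managements with the
SM genotypes a subset of OM (default ratio 230:280), 15 flights between
27 and 144 days after planting, flight-dominant variance shares with
genotype-within-flight in the low-percent range, and heritable GY
(t/ha), DTA/DTS (days) and PHT terminal traits. Gaussian forms are
assumed for flight, replicate and residual effects (the distributional
form is an open modeling choice; it is configurable at the draw site).

Design choices that matter downstream:

* **Variance targeting.** Every drawn component is centered and rescaled
  to its exact configured sample variance. Recovery tests therefore
  measure estimator error rather than generator sampling noise; with few
  levels (15 flight effects, 30 rep effects) untargeted draws would
  dominate the recovery error.
* **Named substreams.** One root seed feeds independent streams for
  markers / effects / trial / raster, so stages can be re-run
  independently and the whole trial is bit-reproducible.
* **Time-varying marker effects.** Per-flight marker effect vectors share
  a configurable across-flight correlation (default 0.7), and an optional
  per-flight genetic-share profile lets individual flights carry more,
  less, or zero genetic variance — the basis of the per-timepoint genomic
  prediction checks.
* **Plasticity.** A per-genotype latent factor (default 30% of the
  genotype-within-flight variance, orthogonalized against the marker part
  so realized variances are exact) loads on the temporal phenotypes and,
  at a configurable share (default 15%), on grain yield. It models the
  repeatable genotype-specific environmental response that sensors
  integrate but a marker matrix cannot express. Temporal marker effects
  are additionally correlated with the yield architecture (default 0.5),
  since in real trials the same loci drive both reflectance trajectories
  and yield. Together these control how much a phenomic predictor can
  legitimately beat a genomic one in a tested environment.
* **SM construction.** SM genotype effects mix the OM effects with an
  independent draw at weight gxe_corr (exactly controlling the
  cross-environment genetic correlation) plus a per-trait mean shift
  (defaults: −2.5 t/ha GY, +2/+3 d flowering, −30 cm height).
* **Rendering.** Band stacks are drawn so each pixel's NGRDI equals the
  plot's simulated value plus optional Gaussian pixel noise, with G+R held
  constant so the identity is exact at zero noise; heights are the plot
  CHM plus noise. Rasters are desk-scale (8 px plots by default). Only the
  target index round-trips exactly; other indices computed from the same
  bands are not constrained to match their simulated series. Rendered
  fixtures carry none of the photogrammetric artifacts of real
  orthomosaics (seams, distortion, radiometric drift), so imaging tests
  validate extraction geometry and arithmetic, not robustness to such
  artifacts.

What passing tests on these trials do **not** show about real data: the
generator has no spatial field trend, no LD structure beyond the
inbred-cross design, no weather-driven temporal correlation between
flights, and exact variance targeting — so recovery tolerances observed
here are optimistic relative to field data, and the TPP-vs-GP margins are
set by explicit simulation knobs rather than discovered biology.

## Features

AUC is the trapezoidal integral of a genotype's temporal curve on days
after planting over the observed flight window only (no extrapolation to
planting or harvest). The canopy growth fit uses the asymptotic Weibull
H(t) = A(1 − exp(−(t/B)^C)), A in height units, B in days (time to
1 − 1/e of the asymptote), C dimensionless — standard for sigmoid,
asymptote-bounded height trajectories. Fitting is bounded least squares
(trust-region reflective) with self-start A₀ = 1.05·max(h),
B₀ = first time at half-max, C₀ = 2, and up to four perturbed restarts;
all-zero height series are rejected rather than silently fit.

Feature matrices follow the printed platform conventions — temporal
columns are exactly n_traits × n_flights (35×15 = 525 RGB,
89×12 = 1,068 multispectral), sorted by (trait, flight day), with AUC and
Weibull A/B/C appended only on request. An alternative 36-trait/16-flight
panel is representable by passing the corresponding trait and flight
lists. Standardization is deliberately *not* done at assembly time; it
happens inside model fitting with training-set statistics only.

## Prediction

Split plans hold the full list of train/test genotype partitions
(|train| = floor(0.7·n), 500 iterations by default) and are hashed;
every model consumed by a comparison must carry the same hash. CV1
resubstitutes on the training genotypes in OM — the overfitting control —
while CV2/CV3/CV4 vary the genotype/environment novelty. Predicted
values are compared to genotype-level observed trait values (not plot
values) by Pearson correlation, RMSE, MAE and R²; zero-variance inputs
raise rather than silently scoring 0.

Penalized families tune their penalty by 5-fold inner CV on training rows
over a 25-point log grid 10⁻⁴..10⁴ (elastic-net l1_ratio over 0.1..0.9),
via scikit-learn's RidgeCV/LassoCV/ElasticNetCV; random forest defaults
to 500 trees, p/3 feature subsampling and leaf size 5, seeded. The
unpenalized linear family uses the minimum-norm least-squares solution,
which interpolates when p ≥ n (making the CV1 control exact).

GBLUP uses the VanRaden method-1 relationship matrix (observed allele
frequencies, MAF filter 0.025, monomorphic markers dropped with a count),
and predicts û_test = G_test,train (G_train,train + λI)⁻¹ (y − ȳ) + ȳ.
λ = σ²_ε/σ²_g is REML-estimated per iteration on the training block by
direct maximization of the restricted likelihood on the kernel's
eigenbasis — exact and deterministic for this single-kernel model, and
equivalent to running EM on the same likelihood to convergence. A
marker-space RR-BLUP reimplementation serves as an independent oracle in
the tests (agreement to 1e-8). Singular training systems get one 1e-8
ridge jitter before failing.

## Numerical conventions and degenerate inputs

Tab-separated UTF-8 text with '.' decimals and literal `NA` everywhere;
flight identifiers are integer days after planting. GeoTIFFs are written
with tifffile, band order and flight metadata as JSON in the description
tag; layouts are GeoJSON in raster pixel coordinates (no CRS for
synthetic fixtures). Duplicate (plot, flight, trait) rows, non-biallelic
dosages, single-flight tables, empty MAF-filtered panels, constant
responses under penalized tuning, and zero-variance evaluation vectors
are all explicit errors, not warnings. Missing marker dosages are imputed
to the per-marker mean with a logged count; zero-variance temporal
columns in correlation profiles and per-timepoint GP are recorded as
missing.

## Problem sizes

The bundled tests and the acceptance script run everything at desk scale:
variance recovery at the full design size (280 genotypes × 15 flights ×
2 reps) over 10–20 seeds with the closed-form estimator; prediction
comparisons at 120–150 hybrids, 200–400 markers and 30–100 CV iterations
over 10–20 seeds. These sizes give stable means (Monte-Carlo error well
inside the stated tolerances) while keeping any single check in the
minutes range; EM-REML is exercised on small fixtures where its dense
mixed-model algebra is cheap, since it provably matches the closed form
on balanced designs.

## Known limitations

Single-trait REML only (no multi-trait or spatial models); homogeneous
residual variance across flights; no photogrammetry (orthomosaic/point
cloud generation is upstream of this package — height grids are the input
contract); no GWAS stage (AUC traits are exported for external tools);
no multi-kernel phenomic+genomic predictor.
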