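# Methods

This package couples a forward simulator of a gravimetric (lysimeter)
drought experiment with the estimation pipeline used to analyse such
experiments, and a matching RNA-seq layer (negative-binomial count
simulator, differential-expression screens, clustering and co-expression
network analysis). Everything the estimators see is what a real feedback
phenotyping platform records: system weight, soil volumetric water
content (VWC), VPD/PAR, and irrigation events.

## Whole-plant water-relations model

### The stomatal response

The midday transpiration rate normalized to atmospheric demand and plant
size,

    Tr_m,VPD  (mg H2O min^-1 kPa^-1 g^-1 FW),

responds to soil water content through a four-parameter logistic (4PL),

    Tr_m,VPD(v) = A2 + (A1 - A2) / (1 + (theta_c / v)^p),

with A1 the well-watered asymptote, A2 the severe-drought asymptote,
theta_c the critical VWC at the inflection (the point of fastest stomatal
closure) and p > 0 the steepness. The exponent convention is deliberate:
with (theta_c/v)^p and p > 0 the curve *increases* in v, so A1 is the
high-VWC asymptote, matching its physiological meaning. This is
algebraically identical to the (v/theta_c)^p form with a negative
exponent. `max_decline_rate` returns |dTr/dv| at the inflection,
(A1 - A2) p / (4 theta_c).

Two species presets anchor the generator at published values for a
conservative water user (cowpea-like: A1 = 3.747, A2 = 0.913,
theta_c = 0.350, WUE = 0.065, no midday phase shift) and a profligate one
(soybean-like: A1 = 5.247, A2 = 0.451, theta_c = 0.263, WUE = 0.054,
maximum phase advance 1.9 h). The steepness p is not published; it is
fixed once at 10 (conservative) and 6 (profligate) — the conservative
habit is the sharper stomatal regulator. These two values shape the curve
but every analysis estimates p freely.

### Simulator structure

The simulated system is pot + soil water pool + plants on a load cell.
Per 3-minute step during daylight the transpiration flow is

    tr = (g / 1000) * VPD(t + a_d) * W(t) * dt,

where g is the day's stomatal response factor, W the plant fresh weight
and a_d the day's phase advance (below). Plant growth is
dW = WUE x tr, integrated exactly (exponential within-step update), and
growth water is drawn from the soil pool, so recorded system weight obeys
exact water conservation: weight(t2) - weight(t1) = irrigation -
transpiration over any interval. VWC is water volume over soil volume
(3.9 L pot). Measurement noise is Gaussian on recorded weight (default
s.d. 1 g); probe channels are returned clean.

Three modelling choices matter and are intentional:

* **Daily stomatal state, evaluated at midday VWC.** g is constant within
  a day and equals the 4PL evaluated at that day's midday (12:00-16:00)
  mean VWC, computed self-consistently (the unique root of
  g = 4PL(v_mid(g)), found by bracketed bisection). Rationale: with
  per-timestep gating, the intra-day VWC decline of a stressed pot would
  shift the diurnal transpiration peak by *hours* — an uncontrolled,
  emergent phase advance that would swamp the planted one — and the
  (midday VWC, Tr_m,VPD) pair would not lie on the generating curve. With
  the daily gate, the diurnal course is separable
  (g x VPD(t) x W(t)) and the estimated midday response paired with the
  measured midday VWC reproduces the 4PL to <= 1e-3 relative error in
  noise-free runs (tested).
* **Phase advance as a VPD-course time warp.** For the profligate habit
  under drought, transpiration follows VPD(t + a_d) with
  a_d = a_max x clip((v_onset - v_predawn) / (v_onset - v_full), 0, 1),
  ramping from VWC 0.35 down to 0.18. Driving the ramp with *predawn*
  VWC keeps the well-watered pot unwarped regardless of its intra-day
  drawdown. The light gate is not warped, so transpiration stays inside
  daylight and the predawn/evening weight anchors remain valid.
* **Feedback irrigation.** Nightly (21:30) the treated pot receives
  f x (water drawn since the previous irrigation), default f = 0.8,
  which depletes VWC from pot capacity (0.45) to ~0.1 over the 14 drought
  days of the default 12 / 14 / 2-day schedule. Outside drought (and for
  well-watered pots throughout) irrigation refills to pot capacity, which
  is also what makes predawn-to-predawn system-weight drift a direct
  gravimetric reading of biomass gain. Under severe deficit the
  controller keeps predawn VWC at or above a floor (default 0.10) — pots
  are droughted, not killed; if the pool empties intra-day anyway,
  transpiration stops (physical supply limit) and the day is flagged.

Known limitations of the emulation: plant growth is exactly linear in
cumulative transpiration (the same law the estimation side assumes), so
whole-experiment growth is near-exponential and late-experiment plants
are unrealistically large; canopy ontogeny, self-shading, nocturnal
transpiration and soil evaporation (film-covered pots) are absent; the
environment is a stylized half-sine day (VPD peak 3 kPa at 13:00, cubed
half-sine shape; PAR 06:00-18:00) with lognormal day-to-day peak jitter.
Passing the recovery tests therefore shows estimator correctness under
the model's own assumptions, not robustness to violations of them.

### Estimation pipeline

All estimators operate on the recorded series only:

* daily transpiration = weight(05:00) - weight(19:00) (+ any irrigation
  inside the window; small negatives clamp to 0);
* daily biomass gain = predawn-to-predawn system-weight drift (valid in
  the refill-to-capacity regime; WUE is fitted only there);
* WUE = OLS slope of cumulative biomass gain on cumulative transpiration
  over a 7-day well-irrigated window (days 1-8 by default);
* plant weight W(t) = W0 + WUE x cumT(t), with cumT recovered from the
  weight balance and W0 from the pot bookkeeping (system weight minus
  tare, soil-at-capacity and drainage components);
* momentary Tr = -dW/dt on a 15-min moving-average of the weights
  (centered difference; irrigation windows masked; negatives clamped and
  counted);
* Tr_m,VPD = windowed mean of Tr x 1000 / (VPD x W) over 12:00-16:00,
  excluding VPD < 0.1 kPa, paired with the midday mean VWC. The window
  follows the wider of the two published definitions (12:00-16:00 rather
  than 12:00-14:00) and is configurable;
* the 4PL fit uses trust-region nonlinear least squares with bounds
  (A2 >= 0, theta_c inside 0.5-1.5x the observed VWC range, p in
  [0.5, 60]) and five jittered multi-starts from A1 = max y, A2 = min y,
  theta_c = median v, p = 5; near-flat inputs return a degenerate flag.
  Recovery days are excluded (rewatered stomata reopen below the drought
  curve, scaled by the preset's recovery fraction), as are days whose
  recorded VWC collapsed to ~0 (supply-limited, not stomata-limited);
* midday peak time = vertex of a quadratic fitted +-1.5 h around the
  argmax of the 45-min-smoothed, weight-normalized Tr course inside
  10:00-16:00. Weight normalization removes the within-day growth trend,
  which would otherwise bias the raw-Tr peak late by ~0.1-0.25 h; the
  phase shift is WW peak minus treated peak (positive = advance);
* daily WW-vs-treated contrasts use Welch's t-test (the unequal-variance
  choice is deliberate; only "t-test" is published).

One distortion is inherent to the warp: the estimator normalizes by the
*measured* VPD(t) while warped transpiration followed VPD(t + a_d), so on
fully-warped days the measured normalized Tr is depressed by ~25%. This
reaches only the profligate A2; A1, theta_c and the phase shift are
unaffected beyond ~1%.

## RNA-seq layer

### Count simulator

Counts are NB(mu, phi) via gamma-Poisson, with log-mean = baseline
(lognormal across genes) + planted effects + module latent factors, and
per-gene dispersion phi ~ lognormal(log 0.1, 0.5). The design is the full
4 drought stages (WW/MD/SD/RC) x 3 times of day (06/12/16) x 3
replicates. Planted truth: 100 drought genes (stage-ramped shift, max
|log2FC| 2), 60 diurnal genes (sinusoid over clock time, amplitude 1.5 in
log2), 40 interaction genes (MD-at-noon multiplier), and three disjoint
co-expression modules (60/50/40 genes, loadings ~ N(1, 0.25^2), scale 0.8
in natural log) driven by latent 12-vectors — the first factor is the
transpiration trait vector taken from the lysimeter simulation, which
anchors gene significance (GS) and module-trait analysis. Library sizes
are lognormal around 1e7; FPKM is derived from counts, lengths and
library sizes.

### Differential expression

Pairwise route (FPKM-based filters, count-based test): expression filter
FPKM >= 1 in all replicates of at least one condition; variability filter
replicate CV < 0.2 in every expressed condition; |log2FC| >= 1 on
pseudocounted (+1) mean FPKM; NB likelihood-ratio test (two-group GLM,
log link, median-of-ratios size-factor offset, moment-estimated
trend-shrunk dispersion); BH-FDR q <= 0.05 across tested genes. Note the
CV rule is strict: at phi = 0.05 and mean 100 the *true* replicate CV is
~0.24, so many genuinely expressed genes are filtered — an intentional
reproduction of the published stringency.

Factorial route: per gene an NB log-linear model over categorical stage
(K) and time of day (T) with log size-factor offset; three nested LRTs —
interaction (K*T vs K+T, df 6), drought (K+T vs T, df 3), TOD (K+T vs K,
df 2) — with BH within each factor family at FDR 0.05. Time of day is
treated as categorical (3 sampled clock times, not a continuous axis);
all four stages enter by default. Factor fold-change summaries come from
log2 size-factor-normalized cell means: max stage-vs-WW shift (drought),
max pairwise TOD shift (TOD), and the max absolute deviation from
row+column additivity (interaction). Dispersions are per-gene method of
moments pooled over the 12 cells, shrunk 50% toward a running-median
mean-dispersion trend, floored at 1e-8. Type-I error of the screen is
checked on 2000 null genes in the test suite.

### Clustering

Factor-responsive genes pass their category's |log2FC| screen (1 / 0.5 /
0.25 for drought / TOD / interaction), are z-scored over the 12 cell
means, and clustered by k-means (k-means++ seeding, 20 restarts, seeded;
ties resolved by best within-SS). k is the smallest value whose
between-SS/total-SS ratio reaches 0.75 (checked per factor category); if
none reaches it the maximum of the range is returned with a flag. The
published cluster-pair test ("different expression patterns between MD
and SD") is operationalized as a Welch t-test on the per-gene
(mean over MD cells - mean over SD cells) summary; the summary columns
are configurable.

### Co-expression network

On replicate-averaged log2(FPKM+1) profiles: unsigned adjacency
|cor|^10, TOM with the standard shared-neighbour normalization,
average-linkage clustering of 1 - TOM, static-height tree cut
(default 0.9) with minimum module size 30 — the "tree" variant of dynamic
cutting; the variant is a documented choice — followed by iterative
merging of modules whose eigengene dissimilarity is below 0.25. Module
eigengenes are first principal components of the gene-standardized module
submatrix, unit-norm, sign-oriented to positive mean kME (making
cross-dataset correlations reproducible). Module-trait association uses
Spearman rank correlation against the 12-cell transpiration trait
(significance P < 0.01); kME is the Pearson correlation of a gene with
its own module's eigengene, GS the Pearson correlation with the trait;
hub genes require kME >= 0.85 and |GS| >= 0.85 inside trait-associated
modules. Cross-dataset module links are Pearson correlations of
eigengene pairs with the t-based two-sided p at n = 12. The inter-modular
network regresses each standardized eigengene on all others with the
lasso; lambda comes from leave-one-out CV with the one-standard-error
rule (n = 12 observations leaves no room for k-fold), and nonzero
coefficients become signed directed edges.

## Problem sizes and tolerances

Default study conditions: 28-day experiments at 3-min resolution (13,440
samples per pot), 2000-gene count matrices over 36 samples. The recovery
studies in the tests and the acceptance script use ten seed replicates of
the paired-pot simulation per preset; each pair simulates and analyses in
well under a second, and the full factorial screen on 2000 genes takes
tens of seconds. Numerical tolerances: the within-day gate root is solved
to 1e-13; noise-free generator/estimator consistency holds to <= 1e-3
relative for WUE, A1, A2 and theta_c; the between/within/total SS
identity is asserted to 1e-8 on every clustering run; TOM, tree-cut and
lasso results agree with naive reimplementations to 1e-8 on small
instances.
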