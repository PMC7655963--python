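# Methods

## The analysis

`iccmap` implements a voxel-wise hub-mapping analysis of resting-state
fMRI. The central statistic is the intrinsic connectivity contrast
(ICC): for an in-mask voxel *i* with time series *x_i*,

    ICC(i) = (1 / n_i) * Σ_{j ≠ i} r(i, j)² ,

the mean squared Pearson correlation between *x_i* and the series of
the other included gray-matter voxels. It is a weighted degree-
centrality measure — voxels whose spontaneous BOLD fluctuations are
broadly coupled across the brain score high, and regions whose
connectivity spans several resting-state networks (RSNs) are connector
hubs. Three variants restrict the included voxels *j*: whole-brain
(all other mask voxels), short-range (world Euclidean distance
≤ d_thr) and long-range (distance > d_thr), with d_thr = 75 mm by
default. Each subject's map is z-scored over the mask so maps can be
averaged and regressed across subjects; z-scoring preserves each map's
topography.

Group analyses are mass-univariate: a one-sample t-test characterizes
where ICC is reliably high, and an ordinary-least-squares model

    z-ICC(v) ~ intercept + age + ACE-R + sex + mean FD

tests, with one-sided contrasts Age(±) and ACER(±), whether hub
strength changes over the adult lifespan after adjusting for sex and
residual head motion. Seed-based connectivity maps (Pearson r of a
4 mm spherical seed's mean series with every mask voxel, Fisher
transformed, one-sample tested) are scored against 14 canonical RSN
templates by the overlap ratio R = N_overlap / N_RSN, the fraction of
a template covered by the seed's corrected group map.

## Preprocessing model and assumptions

The pipeline ingests BOLD images already aligned to a common space;
realignment, slice timing, normalization and smoothing are upstream
and out of scope. Denoising is: drop the first 5 volumes (steady-state
magnetization), regress 24 motion terms [R_t, R_t², R_{t−1}, R_{t−1}²]
built from the 6 rigid-body parameters (lags zero-filled at t = 0)
plus optional CSF/WM-sphere, global-signal and derivative regressors,
then band-pass 0.01–0.1 Hz. The order regress-then-filter follows the
narrative order of the underlying protocol; a joint (filter-the-
confounds) variant is intentionally not the default. Subjects are
screened on mean frame-wise displacement FD_t = |Δx|+|Δy|+|Δz| +
50 mm·(|Δα|+|Δβ|+|Δγ|), rejected when mean FD strictly exceeds
0.2 mm. The 50 mm rotation lever arm is the conventional reference-
sphere radius. CSF/WM sphere coordinates are configuration (no
canonical coordinates exist for synthetic or arbitrary grids).

Rank-deficient confound matrices (e.g. an all-zero motion trace) are
reduced to a maximal independent column set with a logged warning
rather than raising — residualization is unchanged by dropping
dependent columns. The band-pass is an order-4 Butterworth applied
forward-backward (zero phase), so correlations are not phase-shifted;
its contract (0.05 Hz sinusoid within 5%, 0.19 Hz attenuated ≥ 90% at
TR 2.5 s) is asserted in the tests.

## Numerical choices in the ICC engine

* **Masking** — the GM mask keeps voxels whose tissue probability
  strictly exceeds 0.2.
* **Distances** — voxel-center world coordinates through the affine;
  pairs at exactly d_thr are short-range ("within" inclusive,
  "greater than" exclusive).
* **Denominator** — each variant divides by its own included-pair
  count n_i (whole: n−1), keeping all three modes on the common [0, 1]
  scale and making the decomposition Σ_short + Σ_long = Σ_whole hold
  pair-for-pair. A `denominator="global_n"` switch divides by the mask
  size n instead (the literal 1/n reading).
* **Memory bounding** — correlations accumulate over row chunks sized
  to a MB cap; the full V×V pair matrix is never materialized. Each
  voxel's correlation row is computed as one matrix–vector product, so
  results are bit-identical for every chunk size (batched GEMM is not
  shape-stable in floating point, which is why the engine deliberately
  avoids it). The count decomposition across strata is exact; the
  value decomposition holds to float round-off (~1 ulp) because the
  three row reductions are independent float sums.
* **Degenerate series** — zero-variance voxels get r = 0 (flagged, with
  a warning) rather than being dropped, preserving mask geometry; an
  empty stratum yields value 0 with count 0, flagged.
* **Standardization** — population (divide-by-N) standard deviation
  over the mask; documented so tests are exact. A constant map is an
  error.

## Group inference

Family-wise-error control is permutation-based (max-statistic), not
random-field theory: sign-flipping for one-sample tests, Freedman–Lane
residual permutation for the regression (nuisance fit retained,
reduced-model residual rows permuted, full-model contrast t
recomputed). This is exact under exchangeability and requires no
smoothness estimate. Clusters form at the analytic one-sided Student-t
quantile for the cluster-defining threshold (default p = 0.001);
corrected p = (1 + #{null max extent ≥ observed}) / (1 + n_perm).
Cluster connectivity is 26-neighbor by default (6/18 configurable).
The stringent voxel-level variant thresholds at the permutation max-t
95th percentile and applies a cluster-extent floor (≥ 25 voxels kept).
Tables report peak world coordinates, peak t, an equivalent normal
deviate (matched tail probability), extent and corrected p, sorted by
peak statistic. Degenerate voxels (zero residual or across-subject
variance) get a capped statistic or a flagged zero rather than NaN.
Permutation seeds are explicit arguments everywhere.

## Synthetic cohorts: what they emulate and what they do not

The generator plants known structure at desk scale. Gray matter is a
central box split into near-cubic blocks, one per latent network; each
non-hub GM voxel loads 1 on its block's network; hub voxels sit on the
two layers flanking each block-pair interface and load 1 on both
abutting networks; the hub quota (`hub_voxel_fraction`, default 4% of
GM) is split evenly over borders. Latent time-courses are white
Gaussian series smoothed by a 5-volume moving average (power
concentrated inside the 0.01–0.1 Hz passband at TR 2.5 s), made
exactly zero-mean and mutually orthogonal over the post-trim window
and scaled to `network_amplitude`. The orthogonalization is a
deliberate design choice: at zero noise it makes the correlation
structure exact, so hub voxels provably carry the top whole-brain ICC
values (margin = half the per-border hub count, in pair units) and hub
recovery can be asserted voxel-for-voxel rather than statistically.
Background voxels carry pure noise and exercise the GM masking.

Aging enters as a multiplicative gain on hub loadings,
`1 + age_effect·(age − mean age)`: because correlations are amplitude-
invariant, the gain acts through the signal-to-noise ratio, so a
planted negative slope lowers hub ICC with age only when `noise_sd` is
nonzero (default 1.0, equal to the network amplitude). The default
`age_effect = −0.012`/year was sized so the per-hub-voxel effect is
around Cohen's f² ≈ 0.3 at the default 40-subject cohort — there is no
literature effect size for this coupling, so the default is a package
choice documented here. ACE-R totals are drawn independently of the
BOLD model (the study conditions place cognition effects elsewhere);
`acer_effect` can plant one for power studies. Motion is a 6-parameter
random walk with rotation steps scaled by 1/50 mm⁻¹ so both channels
contribute comparably to FD.

Deliberately absent: hemodynamic response convolution, physiological
(cardiac/respiratory) noise, scanner drift, and spatial autocorrelation
beyond the block structure. Passing tests therefore demonstrate the
pipeline's correctness and statistical calibration under a clean
latent-factor model, not robustness to the full noise ecology of real
scanner data.

## Problem sizes used in the validation suite

The test suite runs cohorts of 40 subjects on a 16³ grid of 3 mm
voxels (≈ 1000 GM voxels) with 120 retained volumes — large enough for
stable correlation estimates and contiguous hub clusters, small enough
that 20-replicate recovery and 40-replicate null-calibration studies
complete in a few minutes on one core. Oracle-equivalence checks use
random instances of a few hundred mask voxels against a brute-force
all-pairs double loop at 1e-10. With 3 mm voxels a 16³ grid spans
48 mm, so distance-stratified tests use thresholds of a few voxel
lengths; the 75 mm default is meant for full-FOV images.

## Known limitations

* The distance predicate recomputes chunk-by-chunk pairwise distances
  rather than caching strata; this favors memory over speed.
* Anatomical labeling of cluster peaks (an atlas "Area" column) is not
  included; tables carry coordinates only.
* Freedman–Lane permutes subject rows, assuming exchangeable errors;
  heteroscedastic cohorts would need a different scheme.
* `overlap_ratio` resamples templates by nearest neighbor only, which
  is appropriate for binary masks but can alias very thin templates on
  coarse analysis grids.
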