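# Methods

This note documents the models, conventions, and design choices behind
`neurocoloc`, in the spirit of a statistical appendix: what each stage
assumes, which knobs matter, and what validation on synthetic data does
and does not establish.

## fALFF

`falff.compute_falff` implements the spectral ratio per voxel: demean,
discrete Fourier transform, amplitude `a_f = |F(f)|` at the positive
DFT frequencies, and

```
fALFF = sum(a_f, low <= f <= high) / sum(a_f, f > 0)
```

with inclusive band edges (default 0.01–0.08 Hz) and NaN where the
total amplitude is zero. Two conventions are supported because the
verbal definition "root mean square of the amplitude in the band
divided by the amplitude of the whole spectrum" is ambiguous:

- `ratio="amplitude_sum"` (default): the sum-of-amplitudes ratio, the
  convention of the widely used resting-state toolbox lineage. Values
  lie in [0, 1] and are invariant to rescaling and to added constants.
- `ratio="rms"`: the root-mean-square ratio
  `sqrt(mean in-band power) / sqrt(mean total power)`.

Linear detrending is available (`detrend=True`) but off by default:
least-squares removal of a line from a trend-free series injects a
small broadband amplitude into every bin, and the amplitude-sum ratio
is sensitive to it (a pure in-band sinusoid drops from 1.00 to ≈0.92
under detrending at 300 volumes). The analytic endpoint identities
(in-band sinusoid → 1, out-of-band → 0) hold for the default
convention. No windowing or tapering is applied; spectral leakage for
non-bin frequencies is tolerated and covered by test tolerances.

Nuisance regression (`nuisance_regress_timeseries`) is per-voxel OLS on
an intercept plus the supplied regressors; `build_friston24` produces
the 24-column motion expansion `[R(t), R(t−1), R(t)², R(t−1)²]` with
the lagged rows zero-filled at t = 0. Note that regressing noisy
broadband regressors out of a band-limited signal removes a random
k-dimensional subspace and therefore pulls the amplitude ratio toward
the interior by roughly `k / T`; this is a property of the estimator,
not a bug, and is illustrated in `examples/02_falff_from_bold.py`.

## Image-level confound regression

`regress_confounds_images` fits, per voxel, OLS of the subject values
on an intercept plus dummy-coded covariates (reference level =
lexicographically first; one indicator per non-reference level).
Covariate columns are mean-centered so the fitted intercept is the
grand mean, and the returned maps are residuals plus that intercept —
the operation is idempotent and preserves the mean map. Rank-deficient
designs raise an error naming the collinear columns (via pivoted QR).
Voxels missing in any subject are missing in all outputs, since the
cross-subject fit is undefined there.

## Regional extraction and eigenvariates

Regional means are arithmetic means over in-mask, non-missing voxels
per atlas label; a region with no eligible voxels is NaN ("missing"),
never zero-filled, and missing regions are excluded pairwise in every
downstream correlation. The cluster eigenvariate is the first left
singular vector of the column-centered subject × cluster-voxel matrix,
rescaled to unit sample variance, with its sign anchored so that it
correlates nonnegatively with the per-subject cluster mean. The SVD
definition with an explicit sign anchor was chosen because the concept
is usually named after its implementation in standard SPM software
without a formula; the anchor makes results deterministic.

## Group contrast with permutation cluster inference

Voxel-wise OLS on group + covariates gives a t-map for the group
contrast (pooled residual variance per voxel, df = n − rank(design)).
One-sided thresholding at the Student critical value for the voxel-level
p is applied per contrast direction, since the two directions are
evaluated as separate contrasts. Connected components use
18-connectivity by default (the face+edge convention of the SPM
lineage), switchable to 6 or 26; connectivity affects only clustering,
never the t values. The null distribution of the maximum cluster size
is built by permuting group labels only — covariate rows stay attached
to their subjects. This is the literal label-permutation scheme; it is
approximate when covariates correlate strongly with group (a
Freedman–Lane refit would be the alternative) and that limitation is
deliberate. Cluster-level p-values use the add-one convention and
therefore live in [1/(n_perm+1), 1].

FWER validation design: on a 16³ grid the null of the maximum cluster
size is an integer distribution; with unsmoothed noise and a 0.001
voxel threshold its support is so short (sizes 0–3) that no achievable
alpha is near 0.05 — the achievable rejection rates jump from ≈0.18 to
≈0.02. The FWER study therefore uses spatially smoothed noise
(Gaussian σ = 1.5 voxels) and a voxel threshold of p = 0.01, which
spread the cluster-size null over a near-continuous range; the
measured family-wise error then sits inside the binomial 95% interval
around 0.05. This choice makes the nominal level *achievable*; it does
not bias the test.

## Co-localization

Each patient's regional vector is z-scored per region against the
control group (sample SD, n−1; zero-SD regions → missing). Profiles
are Fisher-z-transformed Spearman correlations between the z-map and
each template's regional means, with correlations clipped to
|ρ| ≤ 1 − 10⁻⁶ before atanh so degenerate inputs stay finite. The
partial variant ("adjust for gray-matter probability") is the Pearson
partial correlation on average-ranked data, equivalent to correlating
the OLS residuals of the two rank vectors on the covariate ranks.

The group test statistic is the mean Fisher z over patients, per
template. The permutation null reassigns subjects uniformly at random
to patient/control roles of the original sizes and recomputes the full
z-scoring + correlation chain per draw — the plain reading of
permutation testing by random group-label reassignment. When the
number of distinct role assignments C(n, n_pat) − 1
does not exceed the requested permutation count, the test enumerates
all of them and is exact. Two-sided p-values use the add-one
convention; BH-FDR is applied across the template set of the call, and
mean r is reported as tanh(mean Fisher z). The implementation is fully
vectorized (role reassignments × patients × regions ranked in one
pass) with a per-subject pairwise-deletion fallback when any region is
missing.

ROC discrimination compares patient profiles against leave-one-out
control profiles (each control z-scored against the remaining
controls, making the two score sets comparable). The AUC is the
Mann–Whitney pair-ordering probability with ties counted ½; the
reported AUC is oriented to be ≥ 0.5 with a flag recording the
orientation, since planted (and observed) effects make patients score
*lower*.

## Structural and clinical analyses

Variance explained by structure: per patient, Spearman's ρ across
templates between the functional and volumetric profile vectors; the
reported fraction is the squared median of those correlations —
squaring deliberately discards the sign, so perfectly anti-correlated
profiles also yield 1. Clinical associations are Spearman correlations
between per-patient profiles (for the significant templates) and each
score, with pairwise-complete deletion and the reported n; the BH-FDR
family is all tests of one call. The site check is the tie-corrected
Kruskal–Wallis H with df = (#sites with data) − 1; an all-tied sample
returns H = 0, p = 1 by convention.

## mRNA association and differential stability

Per patient and per expression donor, Spearman's ρ between the regional
z-map and the gene's regional expression (pairwise deletion per donor;
at least 4 joint regions required), Fisher-z transformed. The averaging
order is fixed: over donors first, then a one-sample t-test of the
per-patient means against zero, Bonferroni-corrected over the explicit
gene list of the call (the screen-then-test flow of a real analysis is
reproduced by two calls with different lists). Gene differential
stability is the mean pairwise inter-donor Fisher-z Spearman of a
gene's regional profile — symmetric in donor order and finite by the
same clipping.

## The synthetic-study generator

The generator defines the conditions under which the pipeline is
validated:

- **Atlas** — a centered ellipsoid mask (connected, ≈half the box)
  partitioned into nearest-seed (Voronoi) cells around randomly chosen
  in-mask voxels; every label nonempty, labels exactly partition the
  mask.
- **Templates** — Gaussian-smoothed white noise shifted to be
  nonnegative inside the mask (density-like), accepted by rejection
  until all pairwise regional |Spearman ρ| are below a cap (default
  0.3) so that a planted effect is attributable. For effect-recovery
  studies the cap is tightened to 0.1 (with template smoothness 1.0 on
  the 16³ grid, where regional means decorrelate enough for rejection
  sampling to succeed): a template correlated at ρ with the planted
  map carries an induced true effect of roughly ρ·β, so only a
  near-orthogonal set makes "false flags on non-planted templates" a
  measurement of FDR control rather than of real secondary effects.
- **Cohort** — control map = smooth baseline + covariate effects +
  iid voxel noise; patient map additionally subtracts β × the
  standardized planted template. Demographics default to the reference
  study population: 52 patients (age ≈ N(61.5, 10.0²), 38 m / 14 f)
  and 22 controls (age ≈ N(63.6, 11.9²), 9 m / 13 f); TIV ≈
  N(1450, 130²) ml. Sites default to 3 levels — enough for a site
  factor with dummies to be well-conditioned at reduced cohort sizes
  (the real consortium had 9 centers; a 9-level factor over 30
  synthetic subjects produces near-empty cells).
- **Effect calibration** — `calibrate_effect_size` finds, by bisection
  with common random numbers over Monte-Carlo replicates, the β whose
  population mean patient co-localization ρ with the planted template
  equals a target (−0.2 by default, the magnitude of the strongest
  group-level co-localization the method is expected to resolve). The
  evaluation log is returned alongside β.
- **BOLD** — series synthesized in the frequency domain with
  complex-Gaussian bin coefficients whose variance is split so the
  expected spectral power fraction inside the band equals the request;
  synthetic motion (random walk) and WM/CSF signals are attached.
- **Donors** — per gene, donor profiles share a Gaussian latent
  pattern: `sqrt(ρ_p)·latent + sqrt(1−ρ_p)·noise`, with ρ_p =
  2 sin(π ρ_s / 6) so the *population Spearman* correlation between
  donors equals the requested `inter_donor_rho`. Optionally the latent
  is the normal-scores transform of a template's regional values,
  coupling that gene's expression to the template's layout.
- **Clinical scores** — Gaussian copula on the normal scores of the
  per-patient effect strengths, so the population Spearman correlation
  equals the target; ±1 reproduces the ranks exactly.

Everything is deterministic given its seed, and ground truth (planted
index, β, noise SD) is returned and serialized beside the outputs so
recovery tests never re-derive it.

What the generator does **not** emulate: hemodynamics, scanner
artifacts and site-specific intensity profiles, anatomical structure
(the "brain" is an ellipsoid), spatial autocorrelation of the noise in
the cohort maps (noise is iid per voxel; smoothness enters through the
baseline and templates), realistic regional covariance of gene
expression, or missing-data patterns of real donor atlases beyond
simple NaN handling. Passing recovery tests therefore demonstrates the
statistical machinery — calibration, error control, effect recovery,
determinism — not robustness to the physics and artifacts of real
acquisitions.

## Validation problem sizes

The heavy simulation studies run at reduced sizes chosen to estimate
each property with useful precision in minutes: null calibration of
the co-localization test at 20 patients / 10 controls / 60 regions /
500 permutations over 400–500 replicates; effect recovery at the
reference size (52/22, 74 regions, 11 templates, 1000 permutations)
over 100 replicates after a 50-replicate calibration run; cluster FWER
at 16³ / 200 permutations over 150–200 replicates; differential
stability at 169 regions × 6 donors over 30 replicates per ρ₀. The
pipeline defaults themselves (1000 cluster permutations, 10,000
co-localization permutations, voxel p 0.001, cluster p 0.05, FDR q
0.05) are the reference settings of the analysis the package
implements.

## Known limitations

- Label permutation with covariates held fixed is approximate under
  covariate–group dependence (see above).
- The amplitude-sum fALFF convention, while standard, is not the only
  reading of the verbal definition; the rms variant is provided.
- The co-localization permutation test treats patients' profiles as
  exchangeable across role reassignments; with very small control
  groups the control-SD estimate is noisy and the z-maps of different
  patients are correlated through it. The null calibration study shows
  the resulting p-values are uniform at the sizes tested.
- `variance_explained` squares a median, so it cannot distinguish
  structure-driven from anti-structure-driven profiles; the sign
  information is in the returned per-patient correlations.
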