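# neurocoloc

Cross-modal spatial co-localization of resting-state fMRI alterations
with neurotransmitter density and gene expression maps.

## The problem

In neurodegenerative disease, voxel-wise maps of local brain function
(such as the fractional amplitude of low-frequency fluctuations, fALFF)
show group-level reductions in patients, but the spatial layout of
those reductions is hard to interpret on its own. One productive
question is whether alterations *co-localize* with the non-pathological
distribution of specific neurotransmitter systems — receptor and
transporter density maps derived from nuclear imaging of healthy
volunteers — and with the regional expression of the genes encoding
them. A negative spatial correlation between a patient's alteration map
and a receptor density template means that function is lost
preferentially where that receptor is normally dense: a signature of
selective vulnerability of that neurotransmitter system.

`neurocoloc` implements this analysis chain for researchers in imaging
neuroscience, end to end and fully testable: because cohorts of this
kind cannot usually be shared, the package includes a first-class
synthetic-study generator that plants effects of known size so every
stage can be validated against ground truth.

## The method

For subject maps `Y_i` on a voxel grid with a gray-matter mask and an
atlas of regions `r = 1..R`:

1. **fALFF** — per voxel, with amplitude spectrum `a_f = |DFT(y)|`,

   `fALFF = Σ_{f ∈ [0.01, 0.08] Hz} a_f / Σ_{f > 0} a_f`

   after demeaning and nuisance regression (Friston-24 motion expansion
   + mean WM/CSF signals).
2. **Group contrast** — voxel-wise OLS of value on group + covariates
   (age, sex, site, and TIV for volumetric maps); one-sided t-maps
   thresholded at uncorrected voxel p, cluster-level significance from
   an exact permutation null of the maximum cluster size (group labels
   permuted, covariates fixed).
3. **Co-localization** — confound-regressed regional means; each
   patient z-scored per region against the control group
   (`z_r = (x_r − μ_r^ctl) / σ_r^ctl`); Spearman's ρ (optionally partial,
   adjusting for regional gray-matter probability) between the z-map and
   each template's regional means; Fisher z = atanh(ρ). The group
   statistic per template is the mean Fisher z over patients, tested by
   randomly reassigning subjects to patient/control roles
   (`p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)`), with Benjamini–Hochberg
   FDR across templates. Mean r is the back-transformed mean Fisher z.
4. **ROC** — per template, the Mann–Whitney AUC of patient profiles vs
   leave-one-out control profiles.
5. **Structure & clinic** — the median-squared per-patient correlation
   between functional and volumetric profiles (variance explained by
   atrophy); Spearman associations of profiles with clinical scores
   (FDR-corrected); a Kruskal–Wallis check of profile homogeneity across
   acquisition sites.
6. **mRNA** — per patient × expression donor, Spearman between the
   regional z-map and a gene's regional expression; Fisher z averaged
   over donors first, then one-sample t-tests over patients with
   Bonferroni correction over the gene list; gene differential stability
   as the mean pairwise inter-donor Fisher-z Spearman.

## Worked example

`examples/04_colocalization.py` generates a 24-patient / 12-control
cohort on a 14³ grid with 60 regions and five templates, where patients
lose signal in proportion to template 1's density (β = 0.1), and runs
the full co-localization test:

```
   template  mean_z  mean_r      p      q  significant
template_00  0.0415  0.0415 0.3003 0.3754        False
template_01 -0.3344 -0.3225 0.0005 0.0025         True
template_02 -0.0125 -0.0125 0.6987 0.6987        False
template_03 -0.0964 -0.0961 0.0210 0.0525        False
template_04 -0.0687 -0.0686 0.0560 0.0933        False

   template   auc  auc_raw  flipped
template_00 0.601    0.601    False
template_01 0.993    0.007     True
template_02 0.503    0.503    False
template_03 0.708    0.292     True
template_04 0.688    0.312     True
```

Only the planted template is FDR-significant, with the expected
negative mean r (−0.32: patients lost signal where its density is
high) and a permutation p at the test's resolution (1/2001 ≈ 0.0005).
Its per-patient profile almost perfectly separates patients from
controls (AUC 0.99; `flipped` records that patients score *lower*).
The other examples cover the study generator, fALFF from BOLD series,
cluster inference, and the mRNA analyses; each prints what it computes
and what the numbers mean.

There is also a thin CLI (`neurocoloc simulate|run|... --config cfg
--seed N --out DIR`) over the same pipeline; configs are plain-text
`key = value` files.

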