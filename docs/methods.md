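# Methods

`respcad` reproduces, on synthetic data, the analysis chain of a
computerized decision-support study for bladder-cancer treatment-response
assessment: a per-case CAD score built from paired pre/post-chemotherapy
lesion images, and a multi-reader multi-case (MRMC) observer study measuring
how that score changes physicians' diagnostic accuracy.  This note records
the models, the defaults and why, the numerical choices, and what the
synthetic data can and cannot show.

## The study being emulated

A cohort of 157 pre/post-treatment cancer pairs (123 patients), of which 40
are pathological complete responders (stage T0 after chemotherapy) and 117
have residual disease (>T0).  Class-mean maximum diameters: responders
30.1 mm pre / 14.3 mm post; non-responders 43.0 mm pre / 31.2 mm post.
Seventeen readers from six specialties and four institutions estimate the
likelihood of T0 (0–100) for every case, first unaided, then after seeing a
1–10 CAD score with per-class score distributions.  A per-reader random
subset (51 cases) is read a second time for intra-reader analysis, so the
repeat-read arm is not fully crossed.

## Synthetic data generator

**Images.** Each lesion is an axis-aligned ellipsoid in a 40×72×72 voxel
grid at 2.0 mm isotropic voxels (sized so the largest plausible lognormal
diameter draw fits with margin).  Maximum diameter is lognormal with the
class mean above and CV 0.25; the post-treatment diameter is the
pre-treatment diameter times a lognormal shrink ratio whose mean preserves
the class-mean post diameter (capped at 0.95 for responders so their post
lesion is always smaller).  Texture is multiplicative, spatially smoothed
Gaussian noise; responding post-treatment lesions are fainter and more
homogeneous (lesion mean 70, relative SD 0.08, correlation length 2.5 vox)
than residual tumors (mean 115, SD 0.22, length 1.5 vox).  Masks delimit
the ellipsoid exactly; segmentation itself is out of scope.

**Ratings.** A Roe–Metz-style latent binormal model: reader r's impression
of case c is `L_rc = a_r·y_c + σ_c·d_c + σ_e·e_rc` with per-case difficulty
`d_c` shared across readers, reader-by-case noise `e_rc`, and per-reader
skill `a_r = a·(1 + 0.10·z_r)`.  The unaided rating is `100·Φ(L_rc)` plus
round-specific rating noise (SD 18 on the 0–100 scale), clipped to the
scale; the impression is held fixed across rounds so test–retest
variability is rating noise alone.  The aided rating is the convex
combination `(1−w)·unaided + w·(100·(cad−1)/9)` plus small noise (SD 4),
mirroring the sequential unaided-then-aided read.  Percent response is the
true diameter shrinkage plus noise (SD 15), mapped to RECIST 1.1-style
categories at +100 / ≥30 / ≤−20 thresholds; the treatment recommendation is
a simple threshold on the likelihood.  Both are recorded but not analyzed,
matching the study design.

**Defaults as study conditions.** The default model solves its two free
parameters from the reported operating points: the separation `a` so the
expected mean unaided reader AUC is 0.73 (including rating-noise
degradation) and the aid weight `w` so the expected aided AUC is 0.77, with
the CAD score itself at AUC 0.80.  Both solves are deterministic bisections
against a fixed quasi-Monte-Carlo stream (200 000 samples per class) and are
cached.  Variance components default to σ_c = 0.6, σ_e = 0.8 (latent total
SD 1), a conventional Roe–Metz split with a substantial case effect so that
difficulty stratification has signal.

**Seeding.** One global seed is expanded into named substreams (`cases`,
`cad`, `ratings`, `repeats`) via `numpy.random.SeedSequence`, so each stage
regenerates independently and the whole study is byte-reproducible.

## Image scoring chain

**Hybrid ROIs.** One 32×16 ROI per tumor-containing axial slice whose
in-slice mask area reaches 10 pixels, centered on the slice's mask centroid
and clamped inside the slice.  A hybrid 32×32 patch places the pre-treatment
ROI in columns 0–15 and the post-treatment ROI in columns 16–31 (the
left/right order is this package's convention).  Hybrids enumerate the full
pre×post Cartesian product, optionally capped by a seeded uniform subsample
(pipeline default 8–16 per case to bound training cost).  At the pipeline
level the area minimum adapts down to the largest available slice, because a
well-responding tumor can shrink below any fixed threshold.

**CNN.** A compact numpy CNN (two 3×3 'same' convolutions with ReLU, two
2×2 max-pools, one dense logistic unit) trained with Adam on binary
cross-entropy; inputs are z-scored with the training fold's global mean/SD.
Initialization and batch order derive from the config seed, and training is
single-threaded, so scores are bit-reproducible.  Cross-validation is
case-level leave-one-case-out (a hard assertion forbids any held-out hybrid
in its training fold); a grouped class-balanced k-fold mode is provided as a
documented fast approximation.  The per-case DL score is the mean scorer
output over the case's hybrids.  The architecture is deliberately small and
fully configurable — the pipeline contract (fold purity, determinism, score
pooling), not the architecture, is what this package certifies.

**Radiomics.** 91 features per scan inside the mask: 17 first-order
intensity statistics, 24 gray-level co-occurrence features (8 statistics at
distances 1–3, 13 directions aggregated, 32-bin equal-width quantization),
13 run-length statistics (3 axis directions), 13 size-zone statistics
(26-connected zones), 5 neighborhood gray-tone difference features, 13 3-D
shape descriptors (marching-cubes surface, convex-hull maximum diameter,
PCA axes), and 6 gradient-magnitude statistics.  The registry is
configurable; the contract is the count and the presence of the run-length
and contrast families, not any specific external feature definition.  Each
case is represented by per-feature percent differences
`100·(post−pre)/|pre|`, with values clipped at ±1000 and a logged rule for
near-zero denominators (<1e−6: 0 if post is also tiny, else the signed cap).

**Two-loop cross-validation.** The outer loop holds out one case; the inner
loop, on the remaining cases only, runs greedy forward selection maximizing
inner-leave-one-out AUC and stops when no candidate improves it.  Candidate
subsets are scored with a linear discriminant by default (fast and
deterministic; a random-forest option exists but is ~100× slower for the
same selections on separable data), after a univariate-AUC prescreen to the
top 20 features and with a safety cap of 8 selected features.  The final
per-fold classifier is a 100-tree random forest (depth unlimited, seeded).
A hard assertion keeps the held-out case out of both selection and
training; if selection returns empty, the fold falls back to all features
with a warning.

**Fusion and CAD score.** The combined score is the per-case max of the DL
and radiomics scores.  CAD scores are the affine image of the combined
scores onto [1, 10], anchored at the reference cohort minimum/maximum; the
fitted map is persisted so all readers and any new case share one scale, and
out-of-range values clip.  Display densities per outcome class are Gaussian
KDEs with boundary reflection at 1 and 10 (normal fit as an alternative),
renormalized to unit area on the scale (trapezoid rule, tolerance 1e−6).

## Observer-study statistics

**AUC.** Empirical (Wilcoxon) AUC with midrank ties everywhere, equal to
exhaustive positive–negative pair counting.

**MRMC comparison.** Per-reader AUCs are computed on the cases each reader
actually rated in an arm (an arm is a modality–round pair), so
non-fully-crossed designs are first-class.  Case-induced (co)variances of
per-reader AUCs are estimated by the U-statistic category decomposition:
all pairs of success-indicator terms are grouped by equality of the
(reader, negative-case, positive-case) indices, and the product of means is
estimated from the all-indices-different category, which is exactly
independent under random sampling of readers and cases.  Inference uses the
Obuchowski–Rockette construction: a t statistic on the per-reader AUC
differences with squared standard error `s_d²/R + 2·max(Cov2 − Cov3, 0)`
(Cov2 = different readers/same arm, Cov3 = different readers/different
arms) and Hillis degrees of freedom
`(R−1)·[(MS_TR + R·max(Cov2−Cov3,0))/MS_TR]²`.  A pure z-test on the
unbiased U-statistic variance of the difference is unbiased but far too
noisy at realistic reader counts (simulated type-I error ≈ 0.14 at 8
readers × 60 cases versus 0.048 for the implemented construction; the
calibration simulation ships in the acceptance suite).  Degenerate variance
estimates are floored at 1e−12 with a warning; single-reader subgroups fall
back to case-variance-only (fixed-reader) inference and are flagged.  A
delete-one-case jackknife is kept as an independent reference and agrees
with the U-statistic variance on fully-crossed toys.

**Stratification.** Per-case difficulty is the sample SD (n−1) of the
radiologist subgroup's unaided original likelihoods; SD ≤ 25 is "easy"
(the tie at exactly 25 goes to easy — the boundary is unspecified by
convention, so it is fixed and documented here), SD > 25 "difficult".

**Agreement.** Bland–Altman per reader on (repeated − original) likelihoods
over the commonly rated cases: bias, SD (n−1), and their means over
readers.  Krippendorff's alpha from the coincidence matrix with full
missing-data support and nominal/ordinal/interval difference functions;
interval is the default for 0–100 likelihoods.  The conventional bands are
0.8 (satisfactory) and 0.667 (tentative floor).  If every pairable value is
identical, expected disagreement is zero and alpha is reported as 1 with a
degeneracy note.

**Multiplicity.** Subgroup comparisons are reported at per-comparison
p = 0.05 with no family-wise correction, matching the emulated study's
analysis.

## Problem sizes

The default test suite and the acceptance script use reduced problem sizes
chosen as the package's own trade-off between evidence and runtime: the
reader-study arm runs at full scale (157 cases × 17 readers — rating
simulation and MRMC are cheap), while the image chain runs on 24-case
cohorts with a 4-filter/8-filter CNN, grouped 4-fold cross-validation, and
a hybrid cap of 8 per case.  MRMC type-I calibration uses 500 replicates of
an 8-reader × 60-case null; parameter recovery uses 6 full-scale seeds.

## What passing tests do and do not show

The generator produces the statistical *structure* the analysis assumes —
binormal reader scores with case and reader effects, sequential aided
reads, class-dependent lesion size and texture — not realistic CT
appearance.  In particular: (i) the synthetic imaging classes are more
separable than real CTU data, so image-chain AUCs near 1 on 24-case cohorts
say nothing about clinical performance, and greedy selection usually stops
after 1–2 features where the real study averaged four; (ii) rating noise is
homoscedastic on the latent scale and clips at the 0/100 edges, which
shrinks the realized Bland–Altman SD (~21 under defaults) below the
unclipped closed form σ√2 ≈ 25.5; (iii) between-reader agreement
(inter-reader alpha ~0.35) is lower than a real cohort with shared training
would show, because reader-by-case noise dominates the case effect at the
default variance split.  What the tests *do* certify: oracle-exact AUCs,
leak-free nested cross-validation, the fusion/scaling algebra, calibrated
MRMC inference on both crossed and non-crossed designs, and byte-level
reproducibility of the whole chain.

## Known limitations

- The CNN is a minimal reference implementation without augmentation,
  early stopping or architecture search.
- Feature definitions follow common formulations but are not certified
  against any external radiomics standard.
- Patients with multiple cancers are not modeled; hold-out is per cancer
  pair, with per-patient grouping left as an extension.
- The aided-rating model (convex shrinkage toward the CAD score) is a
  stand-in for unknown reader behavior; only its two operating points
  (unaided/aided AUC) are pinned to the emulated study.
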