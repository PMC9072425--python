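# Methods

## Detection model

The detector searches skull-stripped T1-weighted volumes for MRI-visible
perivascular spaces (PVS): thin, interstitial-fluid-filled channels that
follow penetrating vessels through the deep white matter and appear as
hypointense, elongated structures of sub-3 mm caliber. Detection is purely
morphological — no training data, no vesselness filter — and proceeds in
two steps on a 0.5 mm isotropic working grid.

**Working grid.** Input volumes (native acquisition 0.488 × 0.488 × 0.9 mm)
are resliced to 0.5 mm isotropic. The output grid has
`round(n·spacing/target)` voxels per axis and is aligned to the input's
first voxel center; intensities use trilinear interpolation (exact on
constants), masks nearest-neighbor. Masks are resliced before
conditioning, so "two voxels" of dilation/erosion always means two 0.5 mm
voxels.

**White-matter conditioning.** The WM mask is dilated by two voxels,
hole-filled, and eroded by two voxels. The structuring element is the
6-connected (face-adjacent) unit ball applied iteratively; this is the
most common reading of "by N voxels" and is configurable, since other
elements (a 26-connected ball, a Euclidean ball) are defensible. Hole
filling floods from the volume border with 6-connectivity; any enclosed
background cavity is filled. The net operation is a morphological closing,
which removes partial-volume pocks at the WM boundary without shifting it.

**Candidate criteria.** For each voxel the pipeline evaluates
(a) membership in the conditioned WM mask; (b) an intensity deficit
relative to the mean of the surrounding voxels within a 4 mm sphere of
more than 15 %; (c) an intensity rank in the bottom 5th percentile of its
3 mm-sphere neighbors. Neighborhoods exclude the center voxel ("the
surrounding voxels"), are restricted to the brain mask, and truncate at
the volume border without padding. Sphere membership uses voxel-center
physical distance with an inclusive boundary, so the offset sets are
identical to an exhaustive enumeration. Two conventions the criteria do
not pin down are resolved as follows and exposed in configuration:

* the 15 % deficit is measured against the *neighborhood mean*
  (100·(μ − I)/μ), so only hypointense voxels can pass, and the criterion
  is invariant to global intensity scaling;
* the rank fraction counts neighbors *strictly darker* than the center
  (ties do not count), so a voxel in a perfectly flat region has rank 0
  but is rejected by the contrast criterion.

Both statistics are computed for the whole grid by offset shifting; the
test suite proves them equal to an independent per-voxel brute-force
evaluation on random phantoms.

**Clustering and morphology.** Candidates are grouped with 26-connectivity
("corner-to-corner"); components strictly larger than 1 mm³ (≥ 9 voxels at
0.5 mm) survive. Each cluster's voxel-center coordinates give a covariance
matrix with eigenvalues λ₁ ≥ λ₂ ≥ λ₃; linearity is λ₁/(λ₁+λ₂+λ₃)
(1 for a line, 1/3 for an isotropic blob; an alternative 1 − λ₂/λ₁ is
available behind the same interface), and length/width are the projection
extents onto the first/second principal axes plus one voxel edge, so a
single voxel has a physical size. Clusters with width < 16.41 mm (strict)
and linearity ≥ 0.8 (inclusive) are putative PVS. The 16.41 mm width
bound is inherited from prior PVS work and lives in configuration, not at
call sites. The "< 3 mm diameter" textbook definition of a PVS is *not*
applied as an extra filter; the morphological constraints are the
operative definition here, and users who want a caliber cut can lower
`max_width_mm`.

**Session outcomes.** Total PVS volume (mL), total PVS number, and the
median per-PVS volume, length and width. Totals are normalized by the
subject's average pre-flight WM volume (cm³), ventricular volume by
average baseline total intracranial volume; medians are never normalized.
Sessions with zero detections carry NaN medians, which propagate as
missing values so downstream models drop those sessions explicitly rather
than treating them as zeros. Even-count medians use the midpoint of the
two central order statistics.

## Synthetic phantoms

Phantoms are a 28 mm white-matter box (56³ voxels at 0.5 mm) of uniform
intensity 100 inside a brain box, with:

* **tubules** — straight cylinders; a voxel belongs to a tubule when its
  center is within the radius of the centerline segment; intensity is
  scaled by (1 − contrast);
* **blob distractors** — spheres of radius 1.5–2 mm at detectable
  contrast; they pass the intensity criteria but have linearity ≈ 1/3 and
  must be removed by the morphological filter;
* **faint tubules** — contrast 0.10, below the 15 % criterion; implanted
  negatives;
* additive Gaussian noise (sd 2, i.e. 2 % of WM intensity — a high-SNR
  MPRAGE regime). Gaussian rather than Rician noise is appropriate at this
  SNR and is recorded as configurable.

Default tubule parameters: contrast ~ U(0.25, 0.4), radius ~ U(0.5, 1) mm,
length ~ U(max(3, 6·radius), 10) mm. The coupling of length to radius
keeps implanted "true PVS" at the ≥ 6:1 aspect ratio characteristic of
MRI-visible white-matter PVS; an isotropic stub (e.g. radius 1 mm, length
3 mm) is by the morphological definition not a PVS and is represented by
the blob distractors instead. Structures keep a 2.5 mm margin inside the
WM box and ≥ 4 mm separation so detections are unambiguous. Scoring
matches a detected cluster to a tubule when its centroid lies within 1 mm
of the centerline; recall and precision are aggregated over a batch, and
a Pearson correlation of true vs. detected counts emulates a
counts-vs-raters validation.

What the phantoms do **not** emulate: gyral anatomy and tissue-boundary
partial voluming, bias fields, Rician noise at low SNR, curved or
branching PVS, and basal-ganglia PVS. Passing the phantom battery
therefore demonstrates algorithmic correctness and internal consistency,
not clinical accuracy on real MRI.

## Cohort simulator

The metric-level simulator reproduces the study design: 9 novice and
6 experienced astronauts with sessions L-180, L-60, R+4, R+30, R+90,
R+180, and 11 controls with four sessions. Per subject and metric, a
latent baseline ~ Normal(mean, between-subject sd); each session adds
independent Normal(0, session sd) noise; astronauts additionally receive a
group-specific shift on every post-return session. Controls never receive
session effects, so their table measures pure test–retest noise.

Defaults (mean, between-SD, session-SD) were chosen once to sit in the
range of published white-matter PVS burdens and to reproduce the
qualitative reliability ordering of the motivating study — total volume
and number highly reliable, median width unreliable (ICC < 0.5, hence
gated): normalized total volume (1.0, 0.35, 0.08) mm³/cm³; normalized
count (0.10, 0.035, 0.006) /cm³; median volume (7, 2, 2) mm³; median
length (5, 0.8, 0.95) mm; median width (2, 0.25, 0.38) mm; normalized
ventricular volume (0.020, 0.005, 0.00005) mL/mL. Default group shifts put
a positive total-volume change on novices (+0.06) and a negative one on
experienced flyers (−0.10), i.e. a novice-vs-experienced contrast of 0.16
mm³/cm³ of WM. Covariate distributions follow the cohort demographics
(novice age ≈ 44 ± 5 yr, experienced ≈ 53 ± 4 yr, ~27 % female, missions
167–226 d; experienced flyers carry 187 ± 152 prior flight days). Six
astronauts carry a SANS label, six no-SANS, three unknown.

A small image-level longitudinal mode renders each subject's fixed phantom
geometry once per session with fresh noise; it exists for end-to-end smoke
tests and reliability checks, not statistical power.

## Statistics

**ICC(3,k).** Two-way mixed effects, consistency, average measures:
ICC = (MS_R − MS_E)/MS_R from the subject × session decomposition,
complete cases only; k = 2 for the astronaut pre-flight pair, k = 4 for
controls. A metric is retained only if ICC ≥ 0.5 in *both* cohorts. The
implementation is a hand-written sums-of-squares computation; the tests
verify it against an explicit oracle and against pingouin's ICC(C,k).

**Change models.** Δ = value(R+4) − value(L-60), with L-180 as fallback
baseline when L-60 is missing; subjects lacking both baselines or R+4 are
dropped with a logged reason. The intercept-only fit is algebraically the
one-sample t test of mean Δ (asserted exactly in tests). The full model
adds sex, mean-centered age, mission duration, landing-to-scan time, and
novice/experienced status; Shapiro residual normality is reported
alongside each fit. Significance is 0.05 two-sided throughout, and no
multiple-comparison correction is applied anywhere — all raw p values and
CIs are emitted.

**Stepwise AIC.** Bidirectional search from the full model using the
Gaussian least-squares AIC = n·log(RSS/n) + 2p (additive constants
dropped; p counts mean parameters including the intercept). The intercept
is always retained; ties break toward the smaller model; the visited
trace is returned and is monotone decreasing by construction. Absolute
AIC values differ from other conventions by a constant; only within-search
comparisons are meaningful.

**Exploratory analyses.** Experienced-subgroup correlations of average
baseline metrics (mean of the two pre-flight sessions; the single
available session when one was excluded) with prior flight days: Pearson
r with df = n − 2, and an age-partial correlation via
residual-on-residual regression (verified against pingouin). Demographic
contrasts use Welch t tests (configurable to pooled) and Pearson
chi-square without continuity correction. The SANS analysis reuses the
change-model machinery with SANS status replacing experience status;
subjects with unknown SANS status are excluded.

## Problem sizes and numerical choices

Tests and the acceptance script run phantoms at 48³–56³ voxels (24–28 mm
boxes), 20-phantom scoring batches, 8-subject × 2-session reliability
tables and 500-replicate recovery studies — sizes chosen so the whole
battery completes in minutes on one core while keeping every statistical
check comfortably powered. Sphere boundary voxels exactly at the radius
are included (deterministic, matches the enumeration oracle). Rank ties
never count as darker. Degenerate cases: empty neighborhoods yield NaN and
non-candidacy; single-voxel clusters have linearity 1; zero-variance
outcomes produce SE 0 and are flagged by the NaN Shapiro statistic; an
empty WM mask warns and returns empty.

## Known limitations

Real-data effects absent from the phantoms (above) mean recall/precision
here bound algorithmic, not clinical, performance. The detector is
specific to white-matter PVS on T1; it does not separate arterial from
venular PVS and will count any elongated T1-hypointensity (e.g. a small
lesion) that satisfies the criteria. The stepwise-AIC search inherits the
usual post-selection inference caveat: reported p values for selected
terms are not corrected for the selection step, matching the analysis it
reimplements.
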