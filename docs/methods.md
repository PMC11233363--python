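# Methods

`lingtract` models how white-matter language tracts, delineated by
probabilistic tractography seeded from naming-fMRI activation peaks, relate
to naming decline after temporal lobe epilepsy surgery. Because patient
imaging of this kind is not publicly distributable, the package pairs every
analysis operator with a synthetic generator that reproduces the *structure*
the operators assume, so the whole chain can be exercised, validated and
calibrated on a desk.

## Seed construction

The tractography seed is the set of the `k` (default 100) white-matter
voxels whose centres lie nearest — in Euclidean millimetres, measured from
the activation peak's world coordinate to voxel centres — to the cortical
activation maximum. Millimetre (not index) distances make anisotropic grids
behave correctly. Ties at exactly equal distance are broken by lexicographic
voxel-index order; any deterministic rule would do, but one must be fixed
for reproducible volumes. The homotopic correlate of a peak is its
reflection across the mid-sagittal plane, estimated as the plane
`world x = centroid-x` of the brain mask; a registration-based homotopic
mapping could replace this single function without touching anything
downstream. Reflections landing outside the brain are snapped to the
nearest in-brain voxel centre (error beyond 10 mm).

## Streamline propagation

Tracking is single-orientation probabilistic propagation under
anatomically-constrained termination rules, with these parameters:

| parameter | default | meaning |
|---|---|---|
| `n_streamlines` | 1000 | attempts per seed |
| `step_mm` | 1.0 | fixed step length |
| `min_curvature_radius_mm` | 1.0 | bounds the per-step turn at `2·asin(step/2r)` = 60° |
| `min_fod_amplitude` | 0.1 | minimum fibre-orientation amplitude to enter a point |
| `dispersion_deg` | 15 | angular SD of the probabilistic direction draw |
| `max_steps` | 200 | per direction |

Each attempt starts at a uniformly sampled seed-voxel centre and runs in
both directions along the (noise-perturbed) local orientation. Both halves
take their first step exactly along that shared initial direction, so the
junction at the seed introduces no turn and the curvature bound holds along
the entire assembled polyline. At later steps the candidate direction is
the trilinearly interpolated field orientation (corner vectors sign-aligned
with the incoming direction, because fibre orientations are axial),
perturbed by a folded-normal angle about a uniform azimuth. A step is
rejected — terminating the streamline — if the turn exceeds the curvature
bound or the amplitude at the new point (interpolated, and in the containing
voxel) falls below `min_fod_amplitude`.

Termination follows five-tissue-type logic at label granularity: ends are
valid in cortical or subcortical grey matter; stopping in white matter,
CSF, or off the brain invalidates the streamline; propagation continues
only through white matter and pathological tissue. A streamline is accepted
when **both** ends are valid. The visitation-probability map divides
per-voxel visit counts (one per accepted streamline, however many of its
points fall in the voxel) by the number of *accepted* streamlines; the
binary tract mask thresholds it at 0.01 (inclusive). These two
denominator/boundary conventions are not forced by the science; they are
fixed for determinism.

## Volumetry, laterality, commonality

Binary masks are split at the mid-sagittal plane; voxels exactly on the
plane belong to neither hemisphere (avoids double counting; affects at most
one voxel slab on even-symmetric grids). Volumes are corrected for head
size as `raw / ICV × 1.5e6 mm³` — the reference constant keeps normalized
volumes in interpretable mm³ and cancels in every index and correlation.
The tract laterality index is `(Vsurg − Vcontralat)/(Vsurg + Vcontralat)`,
positive when the surgery-side tract is larger, undefined (missing) when
both volumes are zero. Commonality maps average binary masks across the
subjects of a surgery-side group; they are descriptive and feed no
statistic.

The fMRI lateralization index uses counts of suprathreshold ROI voxels over
a 20-rung threshold ladder (0 to the map maximum), bootstrap-resampling the
pooled suprathreshold voxels at each rung (100 resamples, sample size
capped at 1000) and taking the 25%-trimmed mean of all resample
`(L − R)/(L + R)` values. Rungs with no suprathreshold voxel on either side
are dropped rather than contributing 0. The two ROIs are processed in a
canonical order derived from the masks themselves, which makes the result
*exactly* antisymmetric under mask exchange. |LI| ≤ 0.2 is bilateral;
beyond that, the sign decides hemispheric dominance relative to the surgery
side.

## Outcome statistics

Naming change is analysed as decline magnitude (pre − post) so that a
positive correlation reads "larger tract volume, greater decline"; a
decline of ≥ 4 Graded Naming Test items is clinically significant. Missing
follow-up scores stay missing and are deleted pairwise. The multiple
regression is OLS of decline on the tract predictor plus preoperative
score, age, onset age, epilepsy duration, sex, education (ordinal 1–4),
surgery type and fMRI LI — nine regressors, so an n = 20 cohort yields
F(9, 10). Rank-deficient designs raise an error naming the collinear
columns (age, onset and duration are only *nearly* collinear because the
three are recorded at different rounding, as in real clinical tables).

Predicted decline for the contingency table applies the same ≥ 4-item
cutoff to the model's fitted decline after rounding it to the integer score
scale; comparing raw continuous predictions against integer observed
changes would introduce a systematic half-point bias at the cutoff.
In-sample fitted values are the default; leave-one-out prediction is
available as an option. Sensitivity and specificity are reported in whole
percent.

The mixed model is a random-intercept regression of decline on the
predictor plus a 12-month indicator, fitted by maximum likelihood (not
REML) so the likelihood-ratio chi-squared against the nested null model —
the same model without the predictor — is valid. Marginal R² is the
fixed-effects share of modelled variance,
`var(Xβ) / (var(Xβ) + σ²_subject + σ²_resid)`. Cohorts in which every
subject contributes a single row degrade to OLS with a warning. Group
correlation contrasts use the Fisher r-to-z two-sample test; the seizure
outcome association uses the two-sided Fisher exact test (p = 1 for empty
margins). No multiple-testing correction is applied; raw p-values are
reported. A `z_transform` flag standardizes decline scores before
modelling (off by default).

## Synthetic data

**Phantoms.** An ellipsoidal brain of concentric shells — CSF under the
skull (shell 0.92–1.0 of the semi-axes), a cortical grey rind (0.75–0.92),
a white-matter core, a small deep-grey nucleus — carries straight fibre
bundles: tubes (default radius 4 mm) of tangent-aligned unit orientations
at amplitude 0.8, connecting a posterobasal temporal anchor to
anterior-temporal, occipital and frontal targets in each hemisphere, echoing
the connection pattern of temporal-lobe language tracts. The default grid
is 40³ voxels at 2 mm isotropic. Tissue labels are exactly mirror-symmetric
about the mid-sagittal plane; activation peaks sit in cortical grey matter
at the posterobasal bundle terminus and are exact x-mirrors of each other
before per-subject Gaussian jitter (SD 2 mm). Bundle radii are scaled per
hemisphere to control left–right tract-volume asymmetry (volume scales with
radius²). Phantoms are geometric stand-ins, not anatomy: they exercise
label topology, orientation coherence and hemispheric asymmetry, but say
nothing about real cortical folding, crossing fibres, or partial-volume
effects — passing tests demonstrate correctness of the operators, not
real-data performance.

**Cohorts.** Per subject *i* and time point *t*, planted decline is

    decline_it = β·(v_i − ref)/1000 mm³ + δ12·[t = 12 mo] + b_i + e_it

with subject intercept `b_i ~ N(0, 1.5²)`, occasion noise
`e_it ~ N(0, 2²)`, slope β = 1.5 GNT points per 1000 mm³ of ipsilateral
normalized volume, and `ref` the cohort median volume (so a zero slope
plants exactly zero systematic decline). Post-operative scores are
`pre − decline`, rounded and clipped to the 0–30 test range; rounding adds
variance 1/12, which the closed-form correlation checks account for.
Demographics follow the published cohort's descriptive statistics: n = 20,
age ≈ N(38, 10) years, onset ≈ N(21, 13), preoperative naming
≈ N(16.2, 4.8) clipped to 8–25, 45% female, 45% left-sided surgery, 80%
anterior temporal lobe resections, education levels 35/30/25/10%, two
subjects missing 12-month scores. Where the source tables give no value
(volume scale ≈ N(5000, 1500) mm³ for directly drawn volumes, seizure
freedom 60%, fMRI LI ≈ N(0.3, 0.4) clipped to [−1, 1], per-subject
asymmetry uniform on [0.8, 1.25]) the defaults are fixed at values typical
for this surgical population and not revisited. All generators draw from a
single explicitly seeded RNG; identical spec + seed reproduces outputs
bit-exactly.

## Pipeline and problem sizes

`run_pipeline` derives every stage and per-subject seed from one master
seed via `SeedSequence`, then per subject: phantom → ipsilateral seed from
the peak → contralateral seed from its homotopic correlate → tracking from
both (1000 streamlines each) → binarize at 0.01 → union → hemispheric
volumes; the cohort generator plants decline on the *computed* volumes, and
the statistics layer emits correlations, regression and contingency tables,
mixed models and the Fisher test, plus per-side commonality maps and a
manifest with parameters, seeds and file checksums. A default run
(20 subjects, 40³ phantoms) takes a few seconds.

Validation problem sizes were chosen to make the checks sharp yet quick:
seed-builder oracle equivalence on 20 random phantoms up to 34³; tracker
contracts on a 400-streamline walled corridor plus 500 streamlines on a
full phantom; estimator calibration on 100 replicate cohorts of n = 200
(CI coverage) and 200 null replicates (likelihood-ratio type-I error);
end-to-end prediction on 20 replicate pipeline runs at the published n = 20
scale with a strong planted effect (β = 1.5, noise SD 0.25). The "strong
effect" setting keeps the planted signal an order of magnitude above the
noise so that in-sample prediction is expected to saturate sensitivity.

## Numerical and degenerate-case choices

* Binarization and the decline cutoff use ≥ (inclusive) comparisons.
* Zero accepted streamlines yields an all-zero map flagged by
  `n_accepted == 0`, not an exception.
* Laterality is missing (NaN) when no ROI voxel is suprathreshold; tract LI
  is missing when both volumes are zero; sensitivity is missing with no
  actual decliners.
* NIfTI-1 stores affines in 32-bit floats; write/read round-trips are
  bit-exact at that precision (all grids the package writes are).
* Streamline polylines round-trip bit-exactly through a plain-text format
  using 17-significant-digit floats.

## Known limitations

Single-peak orientation fields cannot represent crossing fibres; the
angular-noise draw is a stand-in for sampling a full fibre-orientation
distribution. Termination logic works at label granularity, not at the
sub-voxel tissue interfaces used by full anatomically-constrained
implementations. The midline is a plane, so strongly asymmetric brains
would need the registration-based homotopic variant. Synthetic cohorts
plant a linear volume→decline relation only; none of the analyses here can
be read as evidence about nonlinear or threshold effects in real patients.
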