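# Methods

`slmvpa` implements a whole-volume searchlight multi-voxel pattern
analysis (MVPA) for person-identity decoding from fMRI beta images,
within and across sensory modalities, together with a synthetic-data
forward model that makes every stage testable against known ground
truth. This note documents the model, the tunable parameters, the
numerical choices, and what the synthetic validation does and does not
establish.

## The experimental structure being modelled

Four familiar identities are presented in three conditions — face (F),
voice (V) and audiovisual face-voice (FV) — i.e. 12 conditions, in a
slow event-related design: inter-stimulus intervals drawn uniformly
from 10–18 s, onsets locked to the volume acquisition (TR = 3.6 s, 2 mm
isotropic voxels), each condition twice per block, with tens of blocks
per subject. One GLM regressor per condition per block (the two trials
share a regressor) yields `12 × n_blocks` beta images per subject — the
samples for decoding. With 29 blocks that is 348 betas.

## Decoding model

At every admissible sphere centre, a linear support-vector machine
(libSVM backend; one-vs-one reduction for the 4 classes, `C = 1`,
no feature scaling by default) is trained and tested on the sphere's
in-mask voxels under four schemes:

| scheme          | train on | test on  | detects                       |
|-----------------|----------|----------|-------------------------------|
| `face`          | F betas  | F betas  | visual identity code          |
| `voice`         | V betas  | V betas  | auditory identity code        |
| `face_to_voice` | F betas  | V betas  | modality-abstracted code      |
| `voice_to_face` | V betas  | F betas  | modality-abstracted code      |

FV betas are generated (their pattern is the sum of the F and V
patterns) so that sample counts match the design, but no scheme trains
or tests on them.

**Sphere geometry.** A searchlight of radius r voxels is the set of
lattice points within Euclidean distance r of the centre (257 voxels at
the standard r = 4, i.e. 8 mm at 2 mm resolution). Spheres are clipped
at grid borders; a centre is admitted only if it lies in the grey-matter
mask and *strictly more than* `min_inmask_fraction` (default 50%) of its
clipped sphere is in-mask; only in-mask voxels serve as features. The
inclusion denominator is the clipped sphere size, so cortex at volume
edges is not penalized — the border convention was an open choice and
this is the least biased one.

**Splits.** Accuracy is the mean over `n_repeats` (default 100) random
80/20 train/test splits. Splits are *identity-stratified* (80% of each
identity's samples train, the rest test). This is a deliberate design
choice: with unstratified draws at these pool sizes (~40 samples per
modality), the training class counts anti-correlate with the test
composition, and the classifier's majority-class bias then drags both
the accuracy and the shuffled-label chance level measurably below 1/4
(≈0.22–0.235 in our null measurements) — an artifact of the split
procedure, not of the data. Stratified splits restore the exchangeable
null (0.250 ± 0.002). `SplitPlan(stratify=False)` switches the literal
unstratified procedure back on. For cross-modality schemes, each repeat
trains on a stratified 80% of the training modality's samples and tests
on a stratified 20% of the *other* modality's samples, so the test count
matches the within-modality case; this interpretation of "train on one
modality, test on the other within the cross-validation paradigm" is the
natural one that keeps the binomial trial counts comparable across
schemes.

**Empirical chance.** Per sphere, the chance level c′ is the mean test
accuracy over `n_shuffles` (default 100) runs in which the *training*
labels are randomly permuted and the classifier is tested on intact
labels. By default each shuffle redraws the split ("this process is then
repeated"); a fixed-split variant is available
(`redraw_split_per_shuffle=False`). c′ guards against label structure or
data artifacts biasing the classifier away from the theoretical 1/4.

## Inference

Per centre, a two-tailed exact binomial test (doubling the smaller tail,
capped at 1) compares `k = round(accuracy × n)` successes in `n` trials
against `p0 = c′`. The p-value map over all centres of one subject ×
one scheme is thresholded by Benjamini–Hochberg FDR at q = 0.01;
surviving above-chance voxels are kept only in connected components of
*strictly more than* 20 voxels (26-connectivity by default; 6/18
available). Below-chance rejections are reported in a separate signed
layer; final maps keep above-chance voxels only.

**The binomial trial count `n` (the one genuinely open choice).**
Repeated splits reuse the same samples, so the summed held-out
predictions (e.g. 100 repeats × 8 = 800) are far from independent.
Measured under the null (400 spheres, pool 40, 20 repeats), the SD of
the mean cross-validated accuracy is 0.070 — matching a binomial with
n = 40 (the *pool size*, SD 0.069), not n = 160 (SD 0.034). Using the
summed count rejects ~22% of null spheres at α = 0.01 and floods the
FDR maps with false positives; using a single repeat's test count
(n = 8) quantizes k so coarsely that a sphere decoding at 0.6 cannot
reach significance. The default `n_mode="pool"` therefore sets n to the
number of distinct samples the test sets are drawn from — the quantity
that actually bounds the information in the mean — and is empirically
calibrated (null FDR fraction ≈ 5×10⁻⁴ at q = 0.01). `"total"` and
`"per_repeat"` remain available for comparison.

## Group level

With few subjects and many samples each, random-effects analysis would
be underpowered; instead a voxel enters the group map when it is
significant in ≥ `min_subjects` (default 4 of 5) of the individual
FDR-thresholded — but *not* cluster-filtered — subject maps. Synthetic
subjects share one grid, so the spatial-normalization step of a real
study reduces to the identity here; this is the one intentional
simplification of the group procedure. A post-hoc cluster filter on the
group map is available behind `group_cluster_filter`. Scheme-pair
conjunctions (e.g. face ∩ voice, or the two cross directions) mark
candidate multimodal/amodal regions.

## Synthetic forward model

Each subject gets:

- a **grey-matter mask**: a smoothed Gaussian random field thresholded
  at the requested fill fraction, grown/trimmed by field value from its
  largest connected component to the exact target count — irregular,
  connected borders that exercise the >50% admission rule;
- **planted regions** (balls of radius r voxels), one pattern vector per
  (region, identity) drawn once from a standard Gaussian over the
  region's voxels and scaled by `effect_amplitude`:
  - `face_only` / `voice_only`: pattern present in one modality, zero in
    the other;
  - `bimodal_overlap`: independent patterns per modality (both
    within-modality decoders succeed; nothing transfers);
  - `amodal`: one shared pattern for F and V (cross-decoding succeeds);
- **betas**: pattern + i.i.d. Gaussian voxel noise (`noise_sd`, default
  1) inside grey matter; optional Gaussian-smoothed noise via
  `smooth_noise_fwhm_mm`;
- optionally **BOLD**: the design matrix (boxcars of 0.5 s convolved
  with a canonical double-gamma HRF — peak 6 s, undershoot 16 s, unit
  dispersions, ratio 6, 32 s kernel) times the planted amplitudes, plus
  noise. Because generation and fitting share the regressor
  construction, noiseless GLM recovery is exact (relative error < 1e-6),
  which pins down the estimation path. Blocks are concatenated on one
  continuous timeline (a real study would scan them as separate runs);
  no drift or autocorrelation is simulated or modelled — plain OLS, with
  optional Legendre drift columns for external data.

**Effect amplitude.** No empirical unit exists for the pattern strength,
so it is tied down operationally: `calibrate_effect_amplitude` bisects
the amplitude until a single sphere decodes the four identities
within-modality at a target accuracy (0.6 in the validation suite).

**What the synthetic data do not contain:** spatial autocorrelation of
signal, vascular/physiological noise, motion, session effects,
between-subject anatomical variability, or registration error. Passing
the validation suite therefore establishes the *statistical machinery*
(calibration of c′, FDR control, recovery and dissociation of region
kinds) — not robustness to the full noise structure of real fMRI.

## Determinism and numerics

Every stage is a pure function of (inputs, config, master seed). Each
sphere draws its splits from a private generator seeded by (master seed,
scheme, stream, centre voxel index), so maps are independent of centre
iteration order and worker count, and accuracy/chance estimation never
share draws. The SVM path calls the libSVM bindings on a per-sphere
precomputed Gram matrix and is verified prediction-identical to
`sklearn.svm.SVC(kernel="linear")`; one-vs-one voting ties are broken
deterministically by class order. Ties in `accuracy_to_counts` follow
`round`; p-values are capped at 1; BH is applied over exactly the
admissible centres of one subject × one scheme.

## Validation problem sizes

The test suite runs the full pipeline at reduced sizes chosen for
single-CPU turnaround: chance calibration on two 20³ subjects (10
blocks, radius 3, 10 shuffles); null FDR calibration over ten 16³
subjects (10 blocks, radius 2, 20 repeats/20 shuffles); and
recovery/dissociation on one cohort of five 14³ subjects with one
radius-3 region of each kind, 20 blocks (80 samples per modality,
comparable to the emulated design's tens of blocks), a radius-2
searchlight, 10 repeats/10 shuffles, and the amplitude calibrated to
0.6 single-sphere accuracy. The searchlight radius is deliberately
smaller than the region radius there: spheres centred near a region's
edge then contain a majority of informative voxels, which is what makes
edge voxels recoverable at a calibrated test. The acceptance script
(`scripts/acceptance.py`) recomputes the headline chance-level
calibration at full scale: five region-free 24³ subjects, 10 blocks,
radius 3, 20 shuffles per sphere.

## Known limitations

- The per-sphere feature count of a radius-4/8 mm searchlight is the
  full 257-voxel Euclidean ball (minus masking); reports of ~22 voxels
  per sphere in comparable designs are not reproducible from this
  geometry and are not targeted.
- `n_mode="pool"` calibrates the *variance* of the mean CV accuracy;
  the binomial shape is still an approximation for an average of
  dependent proportions.
- The empirical chance level is itself a Monte-Carlo estimate; with few
  shuffles its noise propagates into the test (visible as mild
  anticonservativeness if `n_shuffles` is very small).
- Cross-scheme asymmetry (face→voice vs voice→face) is permitted and
  expected; no symmetry is asserted anywhere.
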