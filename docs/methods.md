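# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `oddball_fmri`.

## Paradigm and design generation

Each trial presents eight 50 ms sounds at a 700 ms inter-stimulus
interval (750 ms onset-to-onset; trial duration 5.30 s): seven
repetitions of a standard and one deviant at position 4, 5, or 6.
Because every trial contains exactly one deviant and listeners know the
allowed positions, deviant probability follows a hazard over the
remaining slots:

    P(dev at 4) = 1/3,  P(dev at 5 | not at 4) = 1/2,
    P(dev at 6 | not at 4 or 5) = 1.

Standards at the candidate positions carry the complementary
probabilities (2/3 at position 4, 1/2 at position 5); standards at
positions where no deviant can occur, or after the deviant, are fully
predictable (P = 1). The first sound of a trial is assigned P = 1/2:
either member of the standard/deviant pairing may open the trial, and
nothing before it disambiguates which.

Sounds are drawn from six ordered standard/deviant pairings of three
stimuli — pure tones (1455, 1500, 1600 Hz; frequency separations 145,
100, 45 Hz) or FM-sweeps characterised by their frequency spans (+80,
+100, −80 Hz; span separations 20, 160, 180 Hz).

A run has 60 trials in 6 blocks of 10. Deviant positions are
pseudorandomised to occur exactly 20 times each; the sequence is
rejection-sampled until no position repeats more than 3 times in a row
(an engagement constraint chosen here; the generator exposes it as a
parameter). Pairing × position cells are filled 3 times each, with the
6 per-run leftovers rotated across runs so a 3-run cycle balances every
cell exactly.

**Inter-trial intervals.** Each gap is solved so the deviant-to-deviant
interval targets a draw from N(5 s, 1 s): the within-trial offsets of
the two flanking deviants are subtracted from the drawn target and the
result is clipped to [1.5, 11.0] s. With 5.30 s trials the within-trial
offsets alone usually exceed the 5 s target, so most realised ITIs sit
at the 1.5 s floor; the target distribution acts as jitter, and the
properties the package guarantees (and tests) are the trial counts and
the ITI bounds, not the realised separation distribution. Null events —
silent gaps of one trial duration — are inserted before 10% of trial
slots (rate configurable; the package's own default) to decorrelate the
design from the volume grid.

## Amplitude models

Two candidate per-sound response profiles (all values in (0, 1]):

* **h1 — habituation.** The first standard and the deviant respond
  fully (amplitude 1). The n-th standard of the trial (counting
  standards only) responds 1/n before the deviant and 1/(n − 1) after
  it, a small post-deviant recovery on the exponential-decay trend. The
  counting rule indexes standards, not sequence positions: this is the
  only reading consistent with the tabulated post-deviant values.
* **h2 — prediction error.** Every sound responds in proportion to the
  probability of hearing it at its position (the hazard above); the
  profiles for deviant positions 5 and 6 coincide. Both models are used
  only up to affine transformations, so h2 equally represents responses
  that *decrease* with predictability.

## Synthetic BOLD generator

The generator emulates analysis-ready (motion-free, registered) runs
over a 3-D voxel grid whose labelled blocks stand in for the auditory
cortical fields Te1.0, Te1.1, Te1.2, Te3 (bilateral, 100 voxels each on
the default 20×20×10 grid).

Per voxel, each sound contributes a neural impulse of amplitude
`baseline + slope_sign · gain · a`, where `a` is the h1 or h2 model
amplitude of that sound (null voxels contribute nothing). The default
prediction-error mapping is `gain · (1 − P)` (slope_sign −1, baseline
1): BOLD increases with surprise. Impulses on a 50 ms grid are
convolved with a double-gamma HRF (response gamma peaking at 5 s,
undershoot at 15 s with weight 1/6, unit peak) and sampled at volume
times.

Defaults (the emulated study conditions):

| parameter | default | rationale |
|---|---|---|
| TR | 1.6 s (pure tones) / 1.9 s (sweeps) | acquisition protocols of the two arms |
| tSNR | 50 (7 T arm) / 30 (3 T arm) | reported temporal SNR of the two acquisitions |
| cohort | 19 participants × 4 runs | pure-tone arm sample size |
| gain | 2.0 (2% of the 100 a.u. mean signal) | typical suprathreshold auditory response at high field; consistent with the near-ceiling SSA prevalence the emulated study reports |
| AR(1) coefficient | 0.3 | standard short-TR serial correlation |
| drift | sinusoid, 60 s period, 10% of noise variance | slow scanner drift |
| white noise | 30% of noise variance | thermal noise floor |

Noise is the sum of an AR(1) process (started from stationarity), a
random-phase sinusoidal drift, and white noise, jointly scaled so a
null voxel's mean/temporal-sd equals the target tSNR.

**What the generator does not emulate:** motion, physiological cycles,
field inhomogeneity, slice timing, spatial noise correlations, and
between-voxel response heterogeneity within an ROI. Passing tests
therefore demonstrate the *statistical machinery* — error control,
sensitivity at realistic SNR, model identifiability — not robustness to
the artifacts a real preprocessing chain must remove.

## First-level GLM

Six condition regressors (std0, std1, std2, dev4, dev5, dev6) are
HRF-convolved unit impulses. std1 and std2 additionally carry linear
parametric modulators indexing each repeated standard within its trial
(1..count), z-standardised across the run's events before convolution
and mean-centred afterwards; they absorb a linear within-trial trend
that cannot be estimated sound-by-sound at 750 ms spacing. Nuisance
terms are an intercept, a linear drift, and a cosine set up to 1/120 Hz
(standing in for motion/physiological regressors, which are out of
scope). Estimation is voxel-wise OLS; downstream group tests are
nonparametric across participants, so serial correlation is left in the
residuals at this stage. Condition estimates are taken from the
unmodulated main columns.

Betas are z-standardised within each (participant, run, ROI) slice over
that slice's voxels × conditions — an order-preserving affine map that
removes participant-, run-, and region-specific scale before
group-level statistics.

## SSA detection and quantification

Adaptation (std0 vs 0.5·std1 + 0.5·std2) and deviant detection (dev4 vs
the same average) are tested per voxel with right-tailed rank-sum tests
across participants on run-averaged betas (exact null for cohorts of
≤ 8, tie-corrected normal approximation otherwise; participants are the
unpaired sampling unit). The conjunction p is the voxel-wise maximum of
the two p-values; Benjamini–Hochberg FDR at α = 0.05 runs pooled across
all ROI voxels (per-ROI pooling is available as an option). Peak-level
FWE control is Bonferroni within ROI (by voxel count) followed by Holm
across the 8 ROIs. Clusters are connected components at 26-connectivity
within each ROI; peak = minimum conjunction p, ties broken by lowest
linear voxel index.

The SSA index normalises the pooled (dev4, std1, std2) ×
(participant, run) betas per voxel to [0, 1], averages per condition,
and computes

    SSAi = (dev4 − 0.5·std1 − 0.5·std2) / (dev4 + 0.5·std1 + 0.5·std2),

bounded in [−1, 1]; voxels with a degenerate range or zero denominator
are flagged undefined and excluded.

## Predictability statistics

Within each SSA region (significant voxels of an ROI whose peak
survives FWE correction), betas are averaged over runs and voxels per
participant and six signed-rank contrasts are tested: dev4>dev5,
dev4>dev6, dev5>dev6, std0>std2, dev4>std2 (one-sided) and dev6 vs std2
(two-sided — under prediction-error coding both sounds are fully
predictable and should not differ). Zero paired differences are dropped
(the standard convention); the null is exact up to 25 non-zero pairs,
enumerated conditional on ranks up to 14 pairs when ties occur, and
normal with continuity correction above. Holm correction accepts a
configurable family size so the family can span all regions (e.g. 30
for six contrasts in five regions), treating unseen members
conservatively.

The mixed model is `beta ~ 1 + predictability` on voxel × run level
observations (the observation level is a package choice; region-level
aggregation is possible upstream), with predictability coded 1/3, 1/2,
1 for dev4/dev5/dev6. The intended random-effects structure — intercept
and slope for both participant and run — is crossed; statsmodels
MixedLM supports one grouping factor, so the fit uses random intercept
+ slope per participant plus a variance component for run-within-
participant intercepts (sessions, when present, are folded into the run
factor). Estimation is REML, intervals and p-values are Wald, and the
slope p is Bonferroni-corrected for the number of regions. Singular or
non-converged fits are flagged in the result, never dropped.

Per participant, Spearman's ρ correlates predictability with
run-averaged deviant betas over all (voxel, deviant-condition)
observations; constant inputs are flagged undefined.

## Bayesian model comparison

Each candidate model contributes one regressor: its amplitude vector
over the run's 480 sounds, z-standardised per run and convolved. A
shared sound-onset regressor (all amplitudes 1) joins the nuisance set:
z-standardisation removes the amplitude mean, so without this column
neither candidate could fit the large response common to every sound
and the comparison would be dominated by shared lack of fit. Nuisance
columns are identical across candidates; data are demeaned per run and
AR(1)-prewhitened (coefficient estimated from nuisance-only residuals,
the same filter applied to the data and to both designs).

The log marginal likelihood is available in closed form under a
Zellner g-prior, β | σ² ~ N(0, g σ² (XᵀX)⁻¹) with g = n (unit
information) and σ² ~ InvGamma(a₀, b₀) with a₀ = 1, b₀ = a₀·var(y):

    ln p(y) = lnΓ(a_n) − lnΓ(a₀) + a₀ ln b₀ − a_n ln b_n
              − (p/2) ln(1+g) − (n/2) ln 2π,

a_n = a₀ + n/2, b_n = b₀ + ½(yᵀy − g/(1+g)·yᵀP_X y). Tying b₀ to the
data variance makes evidence *differences* invariant to affine
rescaling of the data. Runs are independent given the model, so
per-run log-evidences add per subject.

Group summaries are produced both ways: a fixed-effects Bayes factor
K_{h2/h1} = exp(Σ_subjects Δln evidence) per voxel, and random-effects
Bayesian model selection — variational updates alternating subject
responsibilities with Dirichlet concentrations (prior α₀ = 1 per model)
until the concentrations change by < 1e−6 — giving expected posterior
model probabilities per voxel and, on request, exceedance probabilities
from seeded Dirichlet draws (10⁶ by default). "Best explanation" per
voxel means RFX posterior > 0.5.

## Pipeline

A single config (cohort, acquisition, per-ROI generative profiles,
thresholds, one global seed) drives simulate → fit-glm → detect-ssa →
stats → compare-models → report. Child seeds are derived by hashing the
stage tag with the global seed, so every stage is independently
reproducible and the whole run is deterministic. Cohort data are cached
under the output directory keyed by the config digest. The report
bundle contains the cluster table, the contrast and mixed-model tables,
the SSAi and posterior maps, Bayes-factor histogram data, and a summary
JSON.

Desk-scale problem sizes used by the test suite: full-grid detection at
19 participants × 4 runs × 800 voxels; model recovery at 10
participants × 4 runs × 200 signal voxels; error control from 200
simulated null cohorts (19 × 800) and 200 zero-slope mixed-model
replicates.

## Known limitations

* Under h1 generation the six-condition GLM leaks a small negative bias
  (≈ −0.15 gain units per deviant step) into the deviant-beta vs
  predictability relation: h1's post-deviant standard amplitudes depend
  on the deviant's position, which the within-trial linear modulator
  cannot absorb, and the lack of fit is shared with the temporally
  adjacent deviant regressors. This is a property of the GLM structure
  itself, visible only in noise-free simulation; the mixed-model
  zero-slope guarantees are therefore stated (and tested) at the level
  of fit_lmm's own inputs.
* Evidence values use a fixed conjugate prior; only model *comparisons*
  under matched priors are meaningful, not absolute evidences.
* Wald p-values from the mixed model with ~19 groups are mildly
  liberal (measured type-I ≈ 6% at nominal 5%).
* The realised deviant-separation distribution is floor-dominated (see
  ITIs above); analyses that depend on the separation *distribution*
  rather than its bounds should re-derive it from generated schedules.
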