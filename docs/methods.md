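# Methods

This note records the models, conventions and numerical choices behind
`speechassay`, in the order the pipeline runs them.

## Synthetic speech generation

The generators exist to plant ground truth, not to sound natural. A
sustained vowel is modeled source–filter style: a glottal impulse train
whose cycle periods are T₀ + ε_i with ε_i i.i.d. Gaussian of standard
deviation `jitter_pct`·T₀/100, truncated at ±3 s.d. (resampled, not
clipped), and whose per-cycle amplitudes are 1 + η_i with η_i similarly
drawn at `shimmer_pct`/100. Each impulse is rendered as the impulse response
of a fixed two-resonance vowel-like filter (600 Hz / 90 Hz and 1100 Hz /
130 Hz bandwidths), truncated just under the shortest admissible period with
a raised-cosine taper. The truncation is deliberate: successive cycles then
do not overlap, so the waveform peak of each cycle is an exact image of the
planted amplitude and the sidecar's per-cycle ground truth is consistent
with the signal sample-for-sample. Pulse positions are quantized to integer
samples and the *realized* (quantized) periods are what the sidecar stores,
so estimator checks are not confounded by quantization that truth and
measurement would otherwise see differently. White Gaussian noise is added
at a power ratio of exactly `hnr_db`; both additive components are stored.

Because truncation at ±3 s.d. shrinks E|ΔT|, the oracle jitter computed from
realized periods is a few percent below the nominal 2σ/√π value; all
recovery checks therefore compare against the realized-series oracle, never
the nominal parameter.

DDK recordings are trains of a 25 ms noise burst (the /t/ release) followed
by an enveloped voiced nucleus, with inter-onset intervals
Normal(1/rate, ctv) truncated positive; passage recordings alternate voiced
segments with near-silent pauses (−60 dB noise floor) at specified
durations. Sidecars store onset times and pause boundaries.

The cohort generator reproduces the published ALS cohort marginals: n = 122,
39% female, 11% bulbar onset, and median [IQR] values for six clinical
measures (FRS-total 35 [12], FRS-bulb 11 [3], FRS-resp 10 [6], SIT-R 148
[51] WPM, SIT-I 99 [5] %, %FVC 75 [30]), with the per-measure missing-value
counts of the source cohort. Continuous measures are drawn from logistic
distributions quantile-matched to median and IQR (scale s = IQR/(2 ln 3)) —
a choice the generator owns, since only median [IQR] is specified — clamped
to valid ranges, with rating-scale scores rounded to integers. The feature
table uses a single shared latent "acoustic" factor (loading 0.6) across
non-designated features plus a planted severity effect: designated columns
shift by `effect_size` standard deviations between the subgroups of one
clinical measure (default SIT-R at the < 160 WPM threshold). One nuisance
factor, not more, is used on purpose: the downstream representation is
2-dimensional, and the validation question is whether severity structure is
recovered *alongside* shared acoustic covariance, not buried under several
competing factors.

What the generator does **not** emulate: formant trajectories, voice breaks,
diplophonia, room reverberation, device/channel effects, or longitudinal
progression. Passing the recovery suites therefore shows the estimators are
correct on signals whose perturbation structure is the model's own — it does
not certify accuracy on pathological voices, where cycle marking is the
known weak point of all such pipelines.

## Preprocessing and QC

Noise reduction is magnitude spectral subtraction on a 0.025 s STFT: the
average noise-region magnitude spectrum (the region must be ≥ 0.25 s),
smoothed to 40 Hz frequency resolution, is subtracted inside the 80 Hz–10 kHz
band only, with a Berouti-style over-subtraction factor of 2.0 and a floor
of 2% of the original magnitude against musical noise. Output length equals
input length. Because suppression is band-limited, broadband improvement is
bounded by the out-of-band residual; improvement claims are evaluated on
noise within the suppression band. When no noise region is given, the
lowest-energy 0.3 s window is used.

The quality gate applies the protocol thresholds — estimated SNR > 30 dB and
clipping (samples within one LSB of full scale at the nominal bit depth) in
fewer than 1% of samples. The SNR estimator is a region-based power ratio
(signal-region power, noise-floor corrected, over noise-region power); the
gate is applied after noise reduction.

## Feature extraction

The automated extractor emits a fixed 53-name vector for every task.
Pitch is tracked by frame autocorrelation (25 ms window, 10 ms hop, unbiased
lag normalization, voicing when the peak exceeds 0.45 plus an energy gate,
octave errors guarded by preferring the shortest near-best lag). Glottal
cycles are then marked by a waveform-peak walker driven by the run-median
period, choosing within each expected-period window the peak that maximizes
amplitude weighted by proximity to the expected position (suppressing
secondary resonance lobes), with parabolic sub-sample refinement clamped to
±0.5 sample. Jitter and shimmer use the MDVP-standard formulas over the
marked series (≥ 6 cycles, ≥ 12 for APQ11, else NaN). HNR "ac" converts the
frame autocorrelation at the pitch period through 10·log₁₀(r/(1−r)), clamped
to [−20, 60] dB; "cc" uses the correlation of consecutive cycle-length
chunks. Intensity works on 25 ms frame RMS in dB full scale (silence floored
at −120 dB); sones use a fixed synthetic calibration mapping digital full
scale to 90 dB SPL-equivalent — an arbitrary offset, documented as such,
since no SPL calibration exists. ZCR is crossings per second per frame with
moments across frames (excess kurtosis).

Speech/pause segmentation marks frames within 25 dB of the maximum frame
level (with a −60 dBFS absolute floor), median-smooths, merges gaps under
0.15 s, and classes pauses short [0.15, 0.5), medium [0.5, 1.0), long
≥ 1.0 s — bounds chosen from common pause-analysis practice and exposed in
configuration, as is the count normalization (counts per minute of total
duration). Timing features need transcript metadata (words for passage,
syllables for DDK): speech rate = words/total·60, articulation rate =
words/phonated·60, average word duration = phonated/words, phonation rate =
phonated/total, pause–word ratio = pause time/phonated time. Undefined
measures are always NaN, never 0, so correlation code can use
pairwise-complete data.

The reference extractor deliberately uses different algorithms: cepstral
pitch tracking on 40 ms frames (voicing by a robust-z cepstral-peak gate
plus an f0-consistency pass; cepstral peak prominence reported with the
zero-padding-compensated scale of this implementation), a −30 dB/0.20 s
segmentation variant, and additional spectral/cepstral measures, yielding 80
features for passage, 43 for phonation and exactly {rate, CTV} for DDK. DDK
rate is (onsets − 1)/span and CTV the sample standard deviation of
inter-onset intervals, onsets being peaks of the 20 Hz-low-passed envelope.

## Analytical validation

The cross-pipeline Spearman matrix is computed per cell on pairwise-complete
data with average ranks for ties; cells with fewer than 4 complete pairs are
NaN. Strength bands follow |ρ| > 0.50 (moderate), > 0.70 (strong), > 0.90
(very strong); values exactly on a boundary go to the stronger band (the
source inequalities leave boundaries open).

Sparse CCA uses the penalized matrix decomposition: alternating
soft-thresholded power iterations on K = XᵀZ under ‖u‖₂ ≤ 1 and ‖u‖₁ ≤ c,
the threshold found by binary search, two dimensions by rank-one deflation,
convergence at 1e-6 or 500 iterations, objective asserted non-decreasing.
Views are standardized; rows with any missing value in either view are
dropped (after removing columns missing in ≥ 50% of recordings —
task-inapplicable measures). Default penalties are 0.6·√p per view — the
source gives none; this mid-range choice reproduces "groups of features"
sparsity. Canonical correlations are Pearson correlations of the variates;
loadings are feature–variate correlations; the biplot keeps features with
at least one |loading| > 0.50. Signs are fixed so each u's largest-|weight|
entry is positive. Note that PMD assumes identity within-view covariance,
so its no-sparsity limit equals classical CCA exactly when each view is
whitened — the regime the equivalence check uses.

## Clinical validation

Subgrouping uses strict thresholds: more-severe iff FRS-total < 35,
FRS-resp < 10, FRS-bulb < 11, SIT-R < 160 WPM, SIT-I < 96%, %FVC < 80%;
sex (male = 1, female = 2) and onset site enter as natural binaries, giving
eight measures. Clinical measures enter Cramér's V as these binary
subgroups (a configuration switch allows Jenks discretization instead).

**BasisVAE.** Features (standardized; columns with any missing value removed
first) are encoded to a 2-D Gaussian posterior; the decoder produces K ≤ 3
shared basis functions of the latent, each basis column normalized to zero
mean and unit variance over the batch — this pins the scale ambiguity
between basis functions and the per-feature scales λ_j, which is what keeps
the optimization well conditioned. Every feature reconstructs as
λ_j·b_k(z) + δ_j under a categorical assignment posterior φ_jk with a
sparse Dirichlet(α = 0.1) MAP update for the mixture weights. Training
alternates a reparameterized Adam step (lr 1e-3, gradient-norm clipping at
5, hidden width 32, 2000 epochs, 2 restarts selected by ELBO) with
closed-form updates for λ, δ, σ², φ and π. Assignments are initialized by
k-means on the feature-feature |correlation| profile, and during the first
20% of epochs the basis functions are regressed onto their initial
clusters' leading principal-component scores while assignments stay fixed;
φ updates are temperature-annealed (τ: 5 → 1 over the first half) once they
begin. All hyperparameters are exposed in `BasisVAEConfig`. Requesting more
clusters than the data supports usually — not always — leaves the surplus
cluster empty: for some draws a duplicated basis genuinely absorbs shared
noise and wins the ELBO, so the empty-cluster rate is reported as observed
rather than forced. Outputs are posterior-mean embeddings, φ, and decoder
reconstructions ("feature-level predictions") returned on the original
feature scale.

**Fasano–Franceschini test.** For each sample point as origin, the plane
splits into four open quadrants (boundary-tied points count for neither);
the statistic is the maximum discrepancy of empirical quadrant proportions,
averaged over the two origin-sample choices and scaled by
√(n₁n₂/(n₁+n₂)). Significance is by label permutation (default 1000
shuffles, p = (1 + #{perm ≥ obs})/(n_perm + 1)) rather than the asymptotic
approximation, matching the small subgroup sizes this is applied to. The
quadrant statistic is invariant to strictly monotone per-axis transforms of
both samples jointly; it is not rotation-invariant, and no such claim is
tested. Family-wise error uses Bonferroni: 0.05/24 = 0.0021 for eight
measures × three tasks.

**Discretization and association.** Feature-level predictions are
discretized by exact dynamic-programming Jenks natural breaks, choosing the
smallest k in [2, 4] whose goodness of fit (1 − within-group SS / total SS)
exceeds 0.90, else k = 4; all-identical input is rejected. Cramér's V is
computed per measure × feature cell (8 × 53 = 424) on pairwise-complete
labels from the uncorrected χ²; the display copy blanks cells ≤ 0.35 and
saturates at 0.50, with rows and columns ordered by average-linkage
Euclidean hierarchical clustering (NaN as 0 for clustering only).

## Workbench

One master seed fans out to per-stage seeds via `SeedSequence([master,
stage_index])`, so stages re-run in isolation reproduce exactly. The demo
pipeline synthesizes a small recording battery (default 6 per task, with a
0.5 s room-tone lead-in so QC has a noise region), a 122-participant
cohort, and runs both validations; result files are byte-deterministic
under a fixed configuration (the run log carries wall-clock timestamps and
sits outside that guarantee). The CLI (`speechassay synth|qc|extract|
validate-analytical|validate-clinical|run|report`) is a thin layer over the
library.

## Problem sizes and known limitations

The shipped verification suites use sizes chosen to exercise each property
cleanly: 1.5–2.5 s vowels on a 5×5 jitter×shimmer grid, 150-participant /
24-feature planted-cluster tables over 5 seeds, 500 null replicates for the
type-I check and 50 for power, and 122-participant cohorts for the
end-to-end association. Known limitations: cycle marking assumes a dominant
waveform peak per period and will degrade on strongly diplophonic or
creaky voices; the reference extractor is an independent re-implementation
of lab-style measure families, not a bit-compatible reproduction of any
commercial tool; the FF permutation p-value has resolution 1/(n_perm + 1);
and BasisVAE's ELBO is a non-convex objective — restarts mitigate but do
not eliminate local optima.
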