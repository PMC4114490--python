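# Methods

This note documents the models, numerical choices and known limitations of
`cbci`, in the spirit of a methods appendix.  Nothing here states an
empirical result that the test suite does not itself compute.

## Task model

A stimulus set is an ordered triple of shapes (triangle, square, pentagon),
each white or grey, giving (2·3)³ = 216 distinct sets and 216² ordered pairs.
The *degree of match* (DoM) of a pair counts positionwise shared features
(shape and shade separately), 0–6; DoM 6 means identical.  Off-position
repeats never count.

Uniformly sampled pairs over-represent intermediate DoM, so experiments are
built from blocks of 28 trials containing each DoM exactly 4 times: the first
set is drawn uniformly; the subset of the 6 feature slots that must match is
drawn uniformly among subsets of the target size; non-matching features are
resampled uniformly from the alternatives.  How the original experiment
sampled the second set among DoM-consistent configurations is not recorded
anywhere we could follow, so uniformity over matching-slot configurations is
this package's choice.  A full experiment is 8 blocks (224 trials, 32 of them
identical pairs), generated from a single seed and shared verbatim by every
observer — the property that makes offline fusion meaningful.

Stimulus timing (83 ms first set, 250 ms mask, 1 s delay, 100 ms second set)
and the shade RGB values are carried as metadata only; masking is not
modelled psychophysically.  The response-time measurement jitter budget
(8 ms USB polling + 5 ms poll loop + 1 ms EEG marker = 14 ms worst case) is
likewise exposed as a documented constant.

## EEG preprocessing

The chain assumes 2048 Hz, 64-channel input referenced to linked earlobes
(the simulator emits referenced data; reference electrodes are not
simulated).

* **Band-pass 0.15–40 Hz, 14677 taps.**  Built by convolving a 1025-tap
  Hamming-window low-pass with a 13653-tap high-pass.  The high-pass is a
  spectral inversion (δ − low-pass): at this length the window's transition
  lobe (~0.5 Hz) is wider than the 0.15 Hz cutoff itself, so a directly
  windowed high-pass would leave a substantial DC response, whereas spectral
  inversion nulls DC to machine precision.  The filter is odd-length and
  linear-phase, applied in a single pass with the integer group delay
  compensated — i.e. zero-phase, preserving ERP latencies.
* **Ocular correction.**  A surrogate EOG e(t) = mean[(Fp1−F1), (Fp2−F2)] is
  regressed out of every channel with coefficients b_c = cov(c, e)/var(e)
  estimated over the whole recording (global, not per-block — a choice; blink
  statistics are assumed stationary within a session).  If var(e) = 0 the
  step is a logged no-op.
* **Low-pass + decimation.**  An 820-tap equiripple (Remez) filter with pass
  band 0–6 Hz and stop band 8–1024 Hz, applied forward–backward, then every
  128th sample kept (2048 → 16 Hz).  With a 2 Hz transition at this rate,
  820 taps buy only ~25 dB of total ripple (Kaiser estimate), i.e. a ~7%
  equiripple; the forward–backward application squares the response, which
  costs some passband droop (|H(2 Hz)|² ≈ 0.86) but pushes the stop band to
  ≈0.005 so that under 1% of white-noise power survives above 8 Hz — the
  property the downstream feature extraction actually relies on.  Tests
  compare measured sinusoid amplitudes against the freqz response of the
  designed filter, not against an idealised brick wall.
* **Epochs.**  1500 ms, 24 samples × 64 channels: stimulus-locked from the
  onset of the second set, response-locked from 1000 ms before the response
  (the response falls on within-epoch sample 16).  Markers are rounded to the
  nearest 16 Hz sample (≤31 ms, half a sample).  Trials whose window leaves
  the recording, or without a response marker, are excluded and logged.
  Edge handling everywhere is reflect padding.  Stimulus-locked epochs are
  extracted and stored but play no role in the confidence feature.

## Confidence features

Epochs are flattened channel-major to length-1536 vectors; every (channel,
sample) pair is a separate variable ("spatio-temporal PCA").  The empirical
covariance is eigendecomposed via SVD of the centred data matrix; components
carry a deterministic sign convention (largest-magnitude loading positive).
With fewer training epochs than 1536 the trailing eigenvalues are zero; a
`full_basis` option retains the complete orthonormal basis when exact
reconstruction is wanted.  The top 24 components (1-to-64 reduction) feed a
LARS regression onto ±1 correctness labels (+1 = incorrect).  LARS is run for
`max_steps` variable entries, default 24 — the full path, whose endpoint
coincides with ordinary least squares.  The original study fixed a number
of LARS steps it did not report; 24 uses all selected components and is
configurable.

Cross-validation uses deterministic interleaved folds (trial t → fold
t mod k) for any k dividing 224 except 1.  Interleaving balances blocks and
DoM across folds and needs no extra seed.  PCA and LARS are refit per fold;
nf is always an out-of-fold prediction.  Because predictions regress toward
the training-label mean, the population mean nf sits near 2·(error rate) − 1
(≈ −0.75 at 12.5% errors).

## Decision weights and group fusion

w(x) = exp(−a(x − c)) is strictly decreasing and positive, so confident
votes count more without any vote flipping sign, and a confident minority can
outweigh an uncertain majority.  The constants used in the original study are
not publicly recorded; defaults a = 1, c_RT = 4.0 s, c_nf = 2.5 were chosen
to satisfy the two constraints that are recorded — the two shifts differ by
1.5, and the RT- and nf-weight scales are comparable — and they reproduce the
reported median RT weights from the reported median RTs to within 2%.  The
RTnf mixture coefficient α = 0.75 follows the stated design intent of
trusting the behavioural measure more; all four constants are configuration.

Weighted fusion compares summed weights of yes- vs no-voters; exact weight
ties (measure zero with continuous weights, but possible with degenerate
inputs) receive expected credit 0.5, mirroring the majority tie rule.
Error percentages are credit-weighted: (trials − Σcredit)/trials × 100.
Every C(m, n) group is enumerated; group RT is the maximum member RT.
Fastest-responder fusion selects the v smallest member RTs per trial (ties
broken by ascending participant index) and reports the v-th order statistic
as the group RT.  The best-member gap compares each group's fused error rate
with its best individual member's, median across groups.

## Evaluation statistics

Weight distributions are skewed, so comparisons are rank-based.  The
Kruskal–Wallis H uses the tie-corrected statistic with a chi-square p-value
(an exact permutation mode exists for tiny samples).  The paired test is an
exact Wilcoxon signed-rank: zeros dropped, tied absolute differences given
averaged ranks, and the conditional null of W⁺ enumerated over all 2ⁿ sign
assignments by shift-convolution (ranks doubled to integers), so ties are
handled exactly; two-sided p doubles the smaller tail, capped at 1.  This
follows the convention of exact implementations that remain defined under
ties; edge-case conventions of other software are not asserted identical.

ERP contrasts are grand averages — means of per-participant means, never
pooled epoch means — with per-(channel, time) p-values from the pooled
Kruskal–Wallis over all epochs and the paired exact Wilcoxon over the 10
per-participant condition means.  No multiple-testing correction is applied
by default (a Bonferroni option exists), matching how such pointwise maps are
usually read.  Weight densities use Gaussian kernels with Silverman's
bandwidth.

## Synthetic data generator

The generator emulates the reported statistics of the original 10-observer
study; it is the package's study condition, not a tuning knob.

* **Decisions.**  Per observer, error probability on non-identical pairs is
  logistic in DoM (slope 0.4 log-odds per unit, centred at DoM 2.5), with the
  base rate solved so the observer's overall error rate hits its target;
  default observers span 5–20% (mean 12.5%).  Identical pairs are nearly
  always detected: exactly 0 or 1 misses per observer per experiment.
  Errors on non-identical pairs are answered "identical" (false matches),
  the direction the original study reported dominant.
* **Response times.**  Log-normal (σ = 0.25) with condition medians 690 ms
  (correct) / 880 ms (incorrect), plus +30 ms per DoM unit centred at DoM 3.
  The DoM term keeps the overall condition medians at their configured values
  while making harder trials slower whatever their outcome — without it,
  identical pairs (almost always answered correctly, yet empirically answered
  *slowly* and weighted lowest of all DoM levels) would receive the highest
  median weight, contradicting the reported difficulty ordering.
* **EEG.**  Response-locked epochs are a centro-parietal-gained half-sine
  "P300" (onset/peak 400/200 ms pre-response on correct trials, 600/400 ms
  on incorrect, a further 15 ms per DoM unit of latency shift) in AR(1)
  noise (coefficient 0.9 at 16 Hz — coloured like post-chain EEG; white
  noise would be unrealistically easy after decimation), independent across
  channels.  Amplitude 8 µV at Pz and noise sd 8 µV were calibrated so the
  out-of-fold nf separation between conditions lands on the scale implied by
  the reported weight medians (median nf ≈ −0.8 correct vs −0.6 incorrect).
  Continuous 2048 Hz segments with the same structure (noise coefficient
  raised to the 16/2048 power to preserve the low-frequency spectrum) support
  end-to-end pipeline tests; a miniature fixture (4 observers × 56 trials)
  exercises every stage in seconds.
* **Seeds.**  The trial sequence and the behaviour/EEG use separate seeds, so
  "same stimuli, different observers" is preserved; each observer gets an
  independent substream.  Same seeds give byte-identical output.

What the generator does **not** model — and what passing tests therefore do
not show about real data: volume-conducted channel correlations and realistic
topographies beyond a fixed gain map; eye-blink artifacts (a blink template
exists only to exercise the ocular correction); per-trial latent confidence
coupling RT, EEG and accuracy beyond the condition/DoM structure; and, most
importantly, *between-observer error correlation*.  Simulated observers err
conditionally independently given DoM, so group errors shrink with size
faster than for real observers who share stimulus-driven failure modes; the
group-level results are therefore checked directionally (ordering of
methods, groups vs individuals), never against the published error
percentages.

## Problem sizes and numerics

The reference analyses run the full 10 × 224 population with k = 16
cross-validation (160 PCA/LARS fits on 210 × 1536 matrices), evaluate all
1023 groups of sizes 1–10 under four rules, and compute 64 × 24 pointwise
ERP maps — about half a minute in total on one CPU, so everything is computed
fresh on every run.  Orthonormality and LARS-vs-OLS agreements are asserted
at 1e-6–1e-8; exact-test p-values are compared to enumeration oracles
exactly.  Degenerate inputs are defined, not avoided: one-class LARS returns
the constant label; all-identical samples give H = 0, p = 1; an all-zero
difference vector is an explicit error; empty summary cells are NaN.
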