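# Methods

## Signal model and preprocessing

All estimators operate on band-limited phase. A real series is filtered
with a fourth-order Butterworth band-pass applied forward and reverse
(zero phase; the cross-correlation between a band-limited input and its
filtered output peaks at lag 0), the analytic signal is obtained by
Hilbert transform, and the complex samples are normalized by their
amplitude to give 2D unit-circle coordinates (x, y) of the phase.
Samples with exactly zero analytic amplitude have undefined phase; they
are flagged and dropped pairwise (probability zero for continuous
data, but quantized inputs must not produce non-finite values). The
default band is 5 ± 2 Hz (3–7 Hz), the syllable-rate band in which
matched audiovisual speech signals cohere. The first and last second of
every filtered series are excluded from estimation windows to remove
filter edge effects.

The wideband auditory envelope is computed over 8 sub-bands spanning
100–10,000 Hz, spaced equidistantly on the Greenwood cochlear map
f(x) = A(10^(αx) − k) with A = 165.4, α = 2.1, k = 0.88 (constants are
module-level and overridable). Per band: band-pass, Hilbert amplitude;
amplitudes are averaged across bands and resampled to 250 Hz with a
polyphase anti-aliased resampler (the 48 kHz → 250 Hz ratio is large
and non-integer; polyphase resampling avoids spectral leakage).
Resampling can ring slightly below zero, so the envelope is clipped at
0 — it is a magnitude.

Neural signals are assumed to lag the stimuli; `lag_align` pairs
stimulus[t] with neural[t + lag] (default 100 ms, i.e. 25 samples at
250 Hz) and truncates the non-overlapping ends. Indexing is 0-based;
positive lag always means the neural signal follows the stimulus.

## GCMI

Each variable's ranks (average ranks on ties) are mapped through the
standard-normal quantile function at r/(n+1); mutual information is
then H(X) + H(Y) − H(X,Y) with Gaussian closed-form entropies of the
empirical covariance (1/(n−1) normalization; covariances are
standardized to correlation where a fitted model is stored — MI is
scale-invariant). Every entropy term carries the analytic digamma
small-sample bias correction, so null estimates are centred near zero;
they may be slightly negative and are reported as computed — the
surrogate subtraction downstream assumes an unbiased, not a clipped,
null. By the rank construction every estimate is invariant, bit for
bit, to strictly monotone samplewise transforms of any input column.

Two practical caveats, both verified by the test suite:

* The 2D phase MI is only *approximately* invariant to a constant
  phase offset (rotation): rank normalization is per coordinate, so a
  rotation is not exactly an orthogonal transform of the Gaussianized
  variables. The deviation grows with coupling strength — about 15% of
  the MI value at moderate coupling, up to ~25% when the phase
  difference is strongly concentrated.
* Band-limited signals are autocorrelated, so the *absolute* MI between
  independent narrowband series sits above the i.i.d. null floor. All
  inferences therefore use time-shifted surrogates, which share the
  autocorrelation structure, never the analytic null.

## The decomposition

The joint 6-dimensional covariance of (M, A, V) — two phase coordinates
each — fully describes the Gaussian-copula dependence. The three MIs
I(M;A), I(M;V), I(M;[A,V]) come from that covariance with the same
bias-correction setting as the MI estimators, so the PID identities
hold exactly rather than approximately.

Redundancy is the expectation of the pointwise common change in
surprisal. The expectation is taken under the maximum-entropy surrogate
P̃ with the (M,A) and (M,V) pairwise marginals fixed; for Gaussians
this is the closed-form model with A and V conditionally independent
given M (cross block Σ_AM Σ_MM⁻¹ Σ_MV). The closed form is verified in
the tests against a numerical constrained log-determinant maximizer.
The local joint term in the sign conditions, i(m;a,v), is evaluated
under P̃ as log₂ p̃(m,a,v)/(p(m) p̃(a,v)) — the same quantity that
appears in the local co-information — so a single surrogate model
underlies both the integration measure and the integrand. Monte-Carlo
integration uses a seeded generator (default 100,000 samples; the
per-subject pipeline uses 15,000–50,000, which puts the MC standard
error near 0.003 bits, well below between-subject variation); densities
are evaluated in log space via Cholesky factors and converted to bits
at the end.

Unique terms and synergy are derived by subtraction, so red + uni_a =
I(M;A), red + uni_v = I(M;V), the four terms sum to I(M;[A,V]), and
syn − red equals the interaction information — all to machine
precision, by construction. Terms may be negative; the suite asserts
identities and planted-structure orderings, never non-negativity.

A consequence of the P̃ construction worth stating explicitly: the
measure is invariant to the A–V dependence, so a predictor that
literally duplicates the other is indistinguishable from one that is
conditionally independent of it given M. For noisy Gaussian duplicates
the redundancy therefore comes out near 0.6 of I(M;A), not equal to
it (deterministic Gauss–Hermite quadrature of the same integral
confirms the Monte-Carlo value). Exact recovery of I(M;A) under
duplication holds only in degenerate cases (e.g. noiseless binary
predictors) where the marginal constraints force the duplication into
the surrogate.

Local structure can be visualised with 1D blocks (the band-passed real
signals): `local_pid_map` bins Monte-Carlo samples by the sign of each
variable (0 is the median after copula normalization) and accumulates
probability-weighted local information per cell; the cells sum to the
corresponding global quantity within MC error. Redundant systems
concentrate sign-consistent co-information where A and V agree;
difference-coupled systems load the opposite-sign cells.

`pid_regions_to_stimulus` applies identical machinery with two neural
signals as predictors and a stimulus as target.

## The synthetic cohort

The generator emulates the structure the pipeline is designed to
detect, with every study-level constant fixed at the conditions the
analysis assumes: 44 subjects, 250 Hz sampling, a 3–7 Hz band, a 100 ms
stimulus-to-brain lag, 60 s/30 s surrogate shifts.

* **Stimuli.** A matched envelope/lip-area pair shares a band-limited
  latent drive (white noise filtered to the band — not a sinusoid, so
  phase distributions are non-degenerate) riding on independent
  broadband noise; both series are made strictly positive by an affine
  offset (magnitudes), not by rectification (which would distort the
  spectrum). The broadband noise is essential: noise confined to the
  analysis band gives flat in-band coherence and lets narrow spectral
  slivers at the band edge dominate the phase-MI profile; with
  broadband noise the profile peaks at the band centre, and nonmatched
  pairs (independent drives) are flat at the surrogate null. The
  default noise level puts the in-band audiovisual correlation near
  0.93. The audio–lip lag within a matched pair defaults to 0 ms and is
  configurable; nothing in the analysis depends on it.

* **Nodes.** Each neural node is gain × drive (delayed by the neural
  lag, circularly so length and stationarity are preserved) + noise.
  The node noise is *band-limited to the analysis band*: the pipeline
  filters every node into that band, so only in-band noise limits how
  well the stimuli predict the node — purely broadband node noise would
  vanish under the filter and make every planted node look
  deterministic given the stimuli, i.e. spuriously synergistic. A small
  broadband component is added for realism. The drives:
  * *redundant* — the latent shared drive itself (a region encoding
    the common source). Driving it instead by the sum of the two
    observed band signals would make the node an exact function of
    (A, V), so its synergy would grow without bound as gain rises; the
    latent-drive node's terms saturate at the source-identifiability
    limit, keeping its synergy small, negative and nearly flat in gain.
  * *unique_a / unique_v* — one band-limited modality alone.
  * *synergistic* — the normalized difference of the two band-limited
    modalities: each alone is weakly informative about the difference,
    jointly they determine it. A multiplicative (product) interaction
    was considered and rejected: a product of two in-band signals has
    zero covariance with each modality and its spectral content falls
    at DC and at twice the band centre, so a covariance-based estimator
    operating inside the band is blind to it by construction.
  * *null* — noise only.

* **Cohort.** Per-subject gains are Gamma(16, g/16) (mean g = 1,
  CV = 0.25, strictly positive); the comprehension score is
  0.6 + 0.2 × (redundant gain) + N(0, 0.05²), clipped to [0,1] — mean
  ≈ 0.8, matching the comprehension accuracies typical of audiovisual
  sentence tasks, with rare clipping. Centring the gains where the
  redundant node's synergy term is flat makes the behavioral link load
  on redundancy and not on synergy, the dissociation the statistics
  stage must resolve. One master seed; per-subject streams come from a
  counter-based `SeedSequence` split, so any subject is individually
  reproducible.

What the generator does *not* emulate: source leakage and spatial
correlation between nodes, nonstationarity of natural speech, 1/f
neural background spectra, eye movements and other artifacts, or any
forward-model mixing. Passing tests therefore demonstrate correctness
of the estimators and the statistics under the planted model, not
robustness to these real-data complications.

## Statistics

Surrogate maps recompute the full decomposition with circularly
time-shifted stimuli (auditory 60 s, visual 30 s; circular shifts
preserve length and spectra) and are subtracted within
subject/node/term. Group contrasts are dependent-sample t statistics
with sign-flip permutation p-values (the observed labelling counts as
one permutation, so p ≥ 1/(n_perm+1)); behavior regressions shuffle the
scores, one-sided for positive association by default; t statistics are
converted to Z by two-sided tail-probability matching, and Z maps are
subtracted between conditions with a default display threshold of
P < 0.005. FDR uses the Benjamini–Hochberg step-up rule. Permutation
count defaults to 5,000; calibration tests use 199 permutations and 200
null cohorts to stay fast while bounding the type-I rate within its
binomial confidence interval.

## Problem sizes

Default test and acceptance runs use 20-subject cohorts of 120 s for
recovery (where the planted-kind classification accuracy exceeds 90%)
and a 44-subject cohort of 90 s for the behavior analysis; these sizes
give per-subject MI estimation error well below the between-kind
separation, so longer recordings change nothing qualitatively.
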