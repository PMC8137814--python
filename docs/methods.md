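# Methods

## The analysis

`interbrain` implements a cross-brain prediction analysis for fNIRS
hyperscanning dyads (two people — here called teacher and student —
recorded simultaneously, 18 channels each: prefrontal cortex on channels
1–8, temporo-parietal junction on 9–18). For every student channel *j* a
linear model

  S_j(t) = Σ_{i=1..18} w_i · T_i(t) + b

is fitted on the chronologically first half of the recording and applied
to the teacher's second half to predict the student's unseen signal. Two
families share this model class: ordinary least squares, and
ε-insensitive support vector regression with a linear kernel. Accuracy is
the Spearman rank correlation ρ between predicted and observed student
test series (rank-based, hence robust to outliers and monotone
distortions).

Significance is assessed against a moving-block bootstrap null: the
teacher's full-length series is cut into contiguous blocks whose length is
the first lag at which the teacher's sample autocorrelation falls to
|ACF| ≤ 0.05 (computed per channel on the training segment, aggregated
across the 18 channels by the median rounded up); the blocks are permuted
jointly across channels, the series re-split at the original boundary, the
model refitted and re-scored against the *unpermuted* student, B times
(B = 1000 by default). The p-value is the literal exceedance ratio
p = #(null ρ > observed ρ)/B; a +1/+1 "corrected" estimator is available
but off by default. Benjamini–Hochberg FDR adjustment is applied across
the 18 channels of one dyad and family (per-dyad tables report S, P and
FDR columns); a batch summary counts significant channel-pairs out of
channels × dyads (e.g. "x/90" for five 18-channel dyads).

## Preprocessing

Raw two-wavelength (760/850 nm) intensities pass an automated quality
screen (saturation = ≥5 % of samples within 0.1 % of the device rail;
missing = ≥5 % non-finite/zero samples; flat = variance below 1e-12 of the
squared mean — an algorithmic surrogate for visual inspection), a
zero-phase order-3 Butterworth band-pass at 0.01–0.2 Hz (forward–backward,
so the phase response is exactly zero — phase matters when two people's
series are regressed on one another), and the modified Beer–Lambert law
with the **whole-series mean** as the optical-density baseline,
differential pathlength factors (7.25, 6.38) for (760, 850) nm, a default
source–detector separation of 30 mm, and a documented default extinction
table (Prahl/Gratzer compilation, 1/(mM·cm)); all constants are
overridable. The band-pass may be applied to optical densities (default)
or to concentrations — MBLL is linear in ΔOD, so the two are numerically
equivalent — or, approximately, to raw intensities.

One consequence of the whole-series-mean baseline deserves emphasis: the
recovered concentration changes are determined only up to an additive
constant per channel (any constant shifts the baseline intensity, which
the ratio removes). The simulator's raw-intensity renderer and `mbll` are
exact mutual inverses *modulo that constant*; round-trip checks compare
mean-removed series, where agreement is at machine precision (≪1e-9
relative). Since both regression families carry an intercept and Spearman
ρ is shift-invariant, the constant has no effect on any downstream result.

## The synthetic dyad generator

No public recordings of this kind exist, so the generator defines the
study conditions: ~15 min (900 s) at 7.81 Hz (≈7 000 samples), 18 channels
per subject. Channels are built from

* a latent task signal: quasi-regular event onsets (a jittered grid, 45
  events per 15 min; jittered-regular rather than uniform placement keeps
  low-frequency rate fluctuations small so that <5 % of the latent power
  falls outside the 0.01–0.2 Hz analysis band) convolved with a canonical
  double-gamma HRF (peak 6 s, undershoot 16 s at ratio 1/6, dispersion 1 s);
* per-channel idiosyncratic activity of the same construction;
* physiological noise: cardiac (1.2 Hz), respiratory (0.3 Hz) and Mayer
  (0.1 Hz) oscillations, an AR(1) component (coefficient 0.95), a
  random-walk drift, and white measurement noise, with amplitudes of order
  0.25–0.5 µM around a 0.5 µM signal scale.

The oscillatory components carry Wiener phase noise (0.1 rad/√sample,
i.e. a coherence time of ~13 s) instead of fixed phases: two independent
subjects with *pure* sinusoids at a shared in-band frequency correlate at
cos(Δphase) regardless of record length, which would make a "null dyad"
ill-defined. Phase diffusion makes the components mixing, so null-dyad
correlations vanish with record length — though slowly; see Limitations.

Student channels receive `coupling_gain @ teacher_signal_parts` (the
noise-free teacher components, optionally lagged) plus independent noise
drawn from a separate child stream of the master seed; `target_snr`
rescales each coupled channel's noise so var(signal)/var(noise) hits a
requested value. An all-zero gain matrix is a null dyad whose two
recordings are independent by construction. Identical configurations
(including seed) reproduce output bit for bit.

What the generator does **not** emulate: motion artifacts, optode-scalp
coupling changes, short-channel physiology, task-correlated systemic
responses, or any behavioural structure. Passing tests therefore
demonstrate the statistical machinery under controlled dependence and
coupling, not robustness to real-world artifact regimes.

## Numerical choices

* **Split**: boundary = ⌈fraction · n⌉; odd samples go to training.
* **OLS**: dense least squares after a QR-with-pivoting rank check;
  rank-deficient predictor matrices raise an error naming the collinear
  channels rather than silently using a pseudo-inverse.
* **SVR**: libsvm's ε-SVR via scikit-learn, C = 1 and ε = 0.1 by default
  (the defaults of the canonical ε-SVR implementations), solver tolerance
  1e-3. Predictors and response are z-scored internally and the solution
  mapped back, so reported weights apply to raw series; ε is then a tube
  width on the standardized response. Note the ε-tube *deliberately*
  shrinks weights below any generating gains; exact parameter recovery
  holds only in the ε→0, C→∞ limit, where the SMO solver no longer
  reports formal convergence although its iterate is at the optimum (a
  `check_convergence` flag accepts such iterates for that use).
* **Block length**: |ACF| ≤ 0.05 first crossing per channel, median
  (rounded up) across channels; the estimated lags on simulated data land
  at a few tens of samples, matching the regime such recordings produce.
  Remainder samples beyond the last full block are dropped and the
  student test tail trimmed to match.
* **Bootstrap**: one joint block permutation per replicate serves all 18
  response channels (preserving the teacher's inter-channel covariance,
  which the models depend on); the student is never permuted; shuffling
  precedes the split so train and test are both resampled. Replicate
  failures are recorded; >5 % failures aborts. In the OLS family the
  replicate loop runs through a vectorised multi-response normal-equations
  path with ordinal (double-argsort) ranks — identical to average ranks on
  the tie-free continuous data it sees, and several-fold faster.
* p ∈ {0, 1/B, …, 1}: with the literal exceedance rule, the null
  probability of p ≤ α is (⌊αB⌋ + 1)/(B + 1) under exchangeability —
  0.011 at the default B = 1000, 0.0149 at the scaled B = 200 used in the
  package's calibration experiments. Calibration must be judged against
  this finite-B level, not α itself.

## Calibration: what the experiments show

`experiments.null_calibration` measures the per-channel rate of p ≤ 0.01
over simulated null dyads with AR(1)-plus-white noise (monotone ACF, so
the first-crossing rule is an honest decorrelation length). Two findings:

1. The naive sample-wise permutation control over-rejects by an order of
   magnitude (rate ≈ 0.2–0.25): serial dependence makes the i.i.d. null
   far too narrow. This is the failure mode the block construction exists
   to prevent, and the package demonstrates it directly.
2. The block bootstrap comes close to, but does not exactly reach, the
   finite-B level: measured rates are ≈ 0.022–0.027 against 0.0149. The
   residual inflation is intrinsic to the block rule: permuting blocks of
   length L removes all cross-block covariance, leaving the null statistic
   a variance deficit of roughly 2·Σ_k k·ρ_T(k)ρ_S(k)/L relative to the
   observed one. For AR-type dependence the crossing lag L scales with the
   dependence length, making the *relative* deficit (~10–15 % of the
   variance, so ~7 % of the sd) nearly invariant to the AR coefficient.
   An independent univariate Monte-Carlo oracle and the analytic
   calculation agree with the pipeline's measurement. Larger blocks
   (several times the ACF crossing) or circular/tapered blocks would
   close the gap at the cost of departing from the defining rule; the
   package keeps the rule and documents the bias instead.

On band-passed recordings (the production path) a further caveat applies:
band-limited series have oscillatory ACFs whose first near-zero crossing
can badly understate the dependence range, so p-values near the
significance threshold deserve extra caution there.

## Power and family comparison

With coupling planted on TPJ channels at SNR 1 (n ≈ 7 000, B = 100),
detection concentrates on the truly coupled channels (rate ≳ 0.9 coupled
vs ≲ 0.1 uncoupled in the standard experiment) and grows monotonically
with gain across a 0.1–0.4 gain grid that spans the power curve. Under
heavily collinear predictors (18 channels mixing two latent factors),
SVR's held-out Spearman matches or beats OLS in ≈ 90 % of replicates —
the practical argument for the SVR family on multicollinear montage data,
where OLS with ~18 predictors and a modest effective sample size (n over
the dependence length) overfits.

## Problem sizes in the standard experiments

The packaged experiments and checks use: 200 null dyads × B = 200 for
calibration (plus a 30-dyad i.i.d. control), 8–10 coupled dyads per gain
point × B = 100 for power, 100 replicates for the collinearity
comparison, and a 5-dyad structural batch at 110 s × B = 25 with both
families to exercise the full result geometry (18 × 2 models per dyad,
per-dyad S/P/FDR tables, x/90 summaries). These sizes were chosen so the
whole characterisation runs on a laptop-class single core in minutes
while keeping Monte-Carlo error well below the effect sizes being
checked; all of them are parameters, not constants.

## Known limitations

* The mild anti-conservativeness of the block test quantified above.
* Null-dyad channel correlations vanish only in expectation; on a single
  900 s record, narrowband (Mayer-wave) components shared across subjects
  can produce |ρ| up to ~0.2 on a few channels, and such channels can
  reach small p. False positives in the production regime are therefore
  somewhat more likely than the AR-noise calibration suggests.
* Coupling is instantaneous and linear (the model class of the fitted
  regressions); a lag option exists in the generator for robustness
  checks only.
* HbR is synthesized as −HbO2/3 plus noise solely to support the
  two-wavelength round trip; the analysis uses HbO2 only.
* No motion-artifact correction or short-channel regression; negative
  couplings are not tested (the test is one-sided by construction).
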