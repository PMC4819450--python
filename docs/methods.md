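# Methods

This note records the models implemented in `stochtex`, the defaults and the
reasoning behind them, what the simulated data do and do not emulate, and
the numerical choices a user should know before trusting or extending the
results.

## Texture generator

Tokens are sums of modulated narrowband noise carriers. The carrier banks
(20 or 8 carriers, ~500–4000 Hz) are fixed tables of centre frequency and
equivalent rectangular bandwidth (ERB); centre frequencies sit at even steps
of the ERB-rate scale (0.86 ERB-numbers apart for the 20-carrier bank, 2.33
for the 8-carrier bank). Each carrier is Gaussian noise through a two-pole
(AR(2)) resonator. The table gives only (cf, ERB), so the resonator is
solved numerically: the pole radius is bisected until the realized power
response has the tabulated ERB (∫|H|²df / max|H|²), and the pole angle is
then adjusted so the response peak lands exactly on cf (a raw two-pole
filter peaks slightly below its pole frequency). Filters are normalized to
unit noise gain, so every carrier has unit variance.

Modulators are generated at the full audio rate (the highest modulation-rate
parameter used, 103 Hz, is far below the 16-kHz sampling rate, so an
internal lower rate would only add a resampling step). The Gaussian low-pass
stage is realized in the frequency domain — multiply the DFT of white noise
by `W(f) = exp(−f²/(2f₀²))`, symmetric in ±f — which avoids kernel
truncation; the output is rescaled analytically so that its standard
deviation equals the gain parameter `A` in expectation. The softplus stage
uses `log1p(exp(·))` in its numerically stable `logaddexp` form. Shared and
private modulators come from independent RNG streams spawned from the token
seed, so a token is a pure function of its parameters (bit-identical across
runs) and channels are exactly independent at `C = 0`.

Each parent waveform is synthesized with an extra 50 ms at both ends, which
is discarded before use so AR(2) warm-up transients never reach the analysis
(the generator's own choice; onset ringing otherwise contaminates short
tokens). Tokens are rms-normalized to 0.05 full scale exactly; presentation
level is a playback property with no numerical role.

A property worth knowing: the softplus modulator's statistical modulation
depth (SMD, σ/μ) is **not monotone in A**. Exact quadrature of
`softplus(A·ξ − B)` for `ξ ~ N(0,1)`, `B = 1.5` shows the SMD rising
steeply from 0.46 at `A = 0.5` to a maximum of 1.62 near `A ≈ 4.5`, then
declining slowly toward the rectified-linear limit (≈1.49). All
token-level SMD statistics inherit this saturation, and so does simulated
discrimination performance for gain changes: percent correct rises over
`A ≈ 1–5` and flattens or slightly reverses beyond. Directional claims
about "SMD grows with A" therefore hold on the rising region only.

## Auditory model

Analysis uses a 24-channel fourth-order gammatone filterbank
(`scipy.signal.gammatone`), centre frequencies evenly spaced on the
ERB-rate scale. Channel envelopes are extracted by half-wave rectification,
zero-phase 2nd-order Butterworth smoothing, clipping at zero (the smoothing
can undershoot), and power-law compression. Channels are time-aligned by
advancing each by the peak time of its envelope-domain impulse response,
measured through the same rectify-and-smooth stage (the textbook gammatone
delay `(n−1)/(2πb)` is several milliseconds off for the lowest channels of
this IIR design, and smoothing shifts the peak of asymmetric envelopes);
after alignment a broadband click peaks in every channel within ±1 sample.
Channels whose envelope mean falls below 10⁻⁶ of the strongest channel are
excluded from channel-averaged statistics.

Four auditory-model settings are free parameters of any such model, and the
defaults were calibrated jointly so that the model reproduces the reference
simulation results (the z-score triple, the SMD differences at the gain
threshold, and the click-train correlation — see the acceptance script):

| setting | default | role |
|---|---|---|
| channel span | 100–7999 Hz, 24 channels | coverage of the stimulus band plus skirts |
| envelope low-pass | 105 Hz, 2nd-order Butterworth, zero-phase | passes all modulator rates (≤103 Hz), removes fine structure |
| compression exponent | 0.65 | compressive envelope transduction; sets the scale of SMD differences |
| statistics window | central 0.27 s of a token | steady-state estimate; sets the token-to-token variability of the statistics |

Each is a documented field of `FilterbankConfig`. Compression matters twice:
it flattens the SMD-vs-gain slope into the observed ≈0.07 range, and it
symmetrizes the envelope distribution, which is why higher-order moments
carry so little information about the gain parameter. Envelope skew and
kurtosis are computed by default on the **logarithm of the summed
envelope** (a dB-like scale; linear-sum and per-channel variants are
available via the `base` argument). Kurtosis uses the non-excess
convention (Gaussian = 3).

The mean pairwise correlation excludes self-pairs. The identity
`across = within · sqrt((1+(N−1)ρ̄)/N)` is exact for envelope sets with a
common channel mean and variance and is enforced to 10⁻¹⁰ in tests; on real
tokens, where means and variances differ across channels, the prediction
still tracks the obtained across-channel SMD with r > 0.99 over the
generator's parameter range.

One known deviation: with these defaults the across-channel correlation of
fully comodulated textures (`C = 1`, A = 5.5) is ≈0.8. A ceiling of ≈0.6
would require markedly less envelope smoothing or no compression, but every
variant explored moves the click-train correlation down in lockstep —
within this model family the click-train value of ≈0.87 and a 0.6 texture
ceiling cannot hold at the same time. The defaults favour the click-train
calibration; the corresponding ceiling assertion in the acceptance suite
fails and is left failing by design.

## Simulated observer

The observer replaces human listeners; it makes no claim to reproduce human
thresholds. For a three-interval oddest-man-out trial it computes one
decision statistic per interval (any of the three summary statistics, or
the modulation-spectrum centroid as a rate cue), adds zero-mean Gaussian
internal noise (sd 0.02 in statistic units by default — modest relative to
the exemplar-to-exemplar statistic sd of ≈0.05–0.07, so performance is
limited mainly by stimulus stochasticity, as argued for real listeners),
and responds with whichever of intervals 2 and 3 lies farthest from the
other two (sum of absolute differences; exact ties broken by a fair coin).
This minimal differencing rule yields the 50% chance floor and monotone
psychometric functions over the steep region. Trial sequences balance the
four orderings (TTS, TST, STS, SST) within block and are drawn without
replacement; fresh exemplars are synthesized for every interval.

Dissimilarity ratings map `|d₁ − d₂|` through `2/(1+exp(−g·Δ)) − 1` (0 for
identical decision variables, saturating at 1) plus rating noise, clipped
to [0, 1]. The default gain `g = 1.5` uses most of the rating scale for
the stimulus sets the pipeline builds; a lower gain (≈0.5) keeps the map
quasi-linear, which matters for metric recovery (below). Within a listener
the rated tokens are fixed across repeats, as in the rating experiment the
pipeline mirrors.

## Psychometric fitting

Percent correct is fitted by the three-parameter modified Weibull
`P(x) = 0.5 + (0.5 − λ)(1 − exp(−(x/α)^β))` by unweighted least squares on
proportions (a binomial-likelihood fit would weight levels unequally; the
unweighted form matches common practice for averaged psychometric data),
with a multi-start over a log-spaced α grid and three β starts. The lapse
rate is bounded at 0.25 by default — free-lapse fits on noisy simulated
proportions collapse the asymptote into the data ceiling — and the JND is
the closed-form inverse at 71% correct (the 2-up-1-down convergence point).
JNDs outside the tested level range are flagged as extrapolated.
Bootstrap confidence intervals resample binomial counts per level and refit
warm-started from the point estimate.

## Perceptual analysis

Mean ratings over both presentation orders fill a symmetric dissimilarity
matrix (405 trials for 9 stimuli at 5 repeats per ordered pair). MDS uses
SMACOF with isotonic-regression disparities (scikit-learn) from a classical
(Torgerson) start plus seed-controlled random restarts; random-start
non-metric solutions that collapse into degenerate clusters (near-zero
stress with clearly lower rank agreement) are discarded. Solutions are
centred and rotated to principal axes, since "dimension 1" is meaningful
only up to the rotation gauge; stress is Kruskal's stress-1. A caution
learned from an independent-implementation cross-check: for 9 points,
genuinely near-zero 1-D non-metric stress is common — rank constraints are
weak at this size — so stress values for small stimulus sets should not be
over-interpreted.

The variance partition regresses per-listener dimension-1 coordinates
(sign-aligned and z-scored) on a listener factor, then adds one candidate
statistic (z-scored within listener, since each listener has their own
stimulus set) and reports the incremental R² ×100, with partial η²
alongside. Williams' test compares dependent correlations sharing one
variable (t on n−3 df). The two-way repeated-measures ANOVA computes
per-effect Huynh–Feldt epsilons from orthonormal-contrast covariances and
evaluates F at epsilon-scaled degrees of freedom; main-effect epsilons
match pingouin's exactly, and the type-I error rate under a spherical null
is 5% within simulation error.

An identifiability note: over a 3×3 comodulation-by-gain stimulus set the
three candidate statistics are strongly collinear, and with rank-only
(non-metric) scaling the recovered axis is only monotonically — not
affinely — related to the driving statistic, so which of the three wins the
variance partition can change from run to run even when the observer
provably used one of them. With the metric embedding and a quasi-linear
rating map the planted statistic is recovered first, at ≈100% incremental
R², reliably. This mirrors the substantive point that across-channel SMD
and across-channel correlation are nearly interchangeable descriptions of
the same cue.

## Simulated-data scope

The synthetic observer exercises every stage of the pipeline but emulates
only a statistic-plus-noise decision process: no attention lapses
correlated over time, no learning, no loudness or rate cues beyond the
chosen statistic, and no across-listener heterogeneity except what the
JND-based stimulus construction induces. Passing tests therefore validate
the machinery (synthesis, statistics, fitting, scaling, partitioning) and
the internal consistency of the model chain — not any claim about human
listeners, whose thresholds and stress values are outside the package's
scope.

## Problem sizes

Default experiment scales were chosen as the smallest that leave the
reported quantities stable: 2000 exemplar pairs for the z-score comparison,
32 tokens per condition for the SMD differences, 8 tokens per grid point
for parameter curves, 160 trials per psychometric function (4 blocks × 40),
and 405 rating trials per listener. The test suite uses reduced token
durations (0.25–0.5 s) for directional checks where absolute values do not
matter.
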