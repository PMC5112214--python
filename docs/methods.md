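# Methods

## Cochlear IO model and masking predictions

The model treats the basilar-membrane response at the 2-kHz signal place
as two input–output functions: an active, compressive *tip* response
`f_a(L) = L + G(L)` for the signal and the on-frequency masker, and a
linear *tail* response `f_p(L) = L − P` for the off-frequency masker.
`G(L)` is piecewise linear: constant `G_max` below `BP1`, falling with
slope `c − 1` to zero at `BP2`, zero above.  The three tip parameters are
mutually constrained by `G_max = (1 − c)(BP2 − BP1)`; internally the
package stores `(G_max, c, BP1)` and derives `BP2`, which removes the
redundancy from the fit space.  `BP_ctr = (BP1 + BP2)/2` is exposed for
reporting.

Forward masking assumes the masker's internal effect decays with the
masker–signal gap `t` and that threshold corresponds to a fixed intensity
ratio `k` between signal response and decayed masker effect.  Units are
pinned as follows: `mu` is in dB/ms — the decay divides the masker-effect
*intensity* by `10^(mu·t/10)`, so the off-frequency TMC in dB rises at
exactly `mu` dB/ms, which is what makes `mu` directly readable off the
data.  `k` is a linear intensity ratio entering thresholds as
`−10·log10(k)` dB.  Levels are dB SPL; gaps are ms between −3-dB points.

The elicitor is modelled as reducing `G_max` by `dG` (sign-unconstrained)
with the break points fixed, which forces the with-elicitor compression
exponent `c~ = 1 − (G_max − dG)/(BP2 − BP1)`.  The effective with-elicitor
gain is floored at zero, so `c~ ≤ 1`; `dG` itself is never clamped.  The
signal level is the same fixed value in both elicitor conditions (it is
not re-referenced to a with-elicitor quiet threshold; the quiet-threshold
shift observed experimentally is sub-dB).  Direct excitatory masking by
the elicitor is represented as an attenuation of the signal response,
implemented exactly as a scaling of `k`; it shifts both TMCs down equally
and leaves the inferred IO function invariant, which is the geometric
signature that distinguishes it from gain reduction.

One sensitivity caveat: with fixed break points, a change in `G_max` also
moves the off-frequency TMC (through `f_a(L_s)`) together with the
on-frequency TMC's long-gap section, leaving the short-gap section fixed.
The on/off difference limits — `G_max + P` at short gaps, `P` at long
gaps — are unaffected.  The `c` and `BP_ctr` variations leave the
off-frequency TMC exactly unchanged.

## Fitting

Per listener, the six baseline parameters `(G_max, c, BP_ctr, k, mu, P)`
minimize the summed squared deviation over all without-elicitor on- and
off-frequency thresholds, using bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) with bounds
`G_max ∈ [0, 60]` dB, `c ∈ [1e−3, 1]`, `BP_ctr ∈ [10, 90]` dB SPL,
`k ∈ [0.05, 20]`, `mu ∈ [0.01, 3]` dB/ms, `P ∈ [−20, 60]` dB.  `c` is
capped just below 1 in the optimizer so the compressive-range width stays
finite, and the constructor rejects `c < 1e−3` to keep the tip inverse
well conditioned.  Starts form a fixed 3×3×3 lattice over
`(G_max, c, BP_ctr)` crossed with central `(k, mu, P)`; the lowest SSE
wins, ties to the first start in lattice order.  Tolerances are 1e−10
with at most 2000 evaluations per start.  Because the residuals are
piecewise linear (non-smooth), a start can sit at the minimum while
crawling along a kink until the evaluation budget ends; the fit is
reported as converged when the best SSE is corroborated within 1 %
relative by a start that terminated on a tolerance criterion.

The with-elicitor fit varies only `dG`, carrying all baseline parameters
over; it works with on-frequency rows alone because the off-frequency
elicitor effect is a uniform `dG` shift.  Without any off-frequency rows,
`P` is unidentifiable and is held at a configured value (default 20 dB)
with the result flagged.

### Identifiability

All six parameters are jointly identifiable only when (i) the signal sits
on the linear segment below `BP1` — otherwise `f_a(L_s)` absorbs the
`BP1` dependence and a continuum of `(G_max, BP_ctr)` pairs predicts
identical TMCs — and (ii) the required masker output traverses both break
points, since the low segment pins `k`, the mid segment pins `c` and
`BP1`, the upper segment separates `G_max` from `P`, and the off-frequency
intercept then pins `P`.  With the classic 6-gap, 5–30-ms design these
conditions hold only for favorable parameter combinations; the synthetic
recovery studies therefore use per-subject gap grids that place several
gaps in each segment (`identifiable_design`).  Similarly, `dG` is unique
only while the with-elicitor gain stays positive: at `dG ≥ G_max` the
likelihood is flat in `dG` (the reference cohort's two `c~ = 1.00` rows
sit on this boundary).

## Synthetic data generator

`PopulationSpec` draws subjects uniformly from ranges bracketing the
reference cohort: `G_max` 13–36 dB, `c` 0.05–0.65, `BP_ctr` 37–53 dB SPL,
`k` 0.69–3.0, `mu` 0.12–0.97 dB/ms, `P` 11–35 dB, `dG` −1–22 dB, signal
level 28–39 dB SPL (10 dB above quiet thresholds of roughly 18–29 dB
SPL).  Two constraints encode the method's premises rather than the
marginal ranges: the signal level is capped at `BP1 − 2` dB (low-level
linear-segment signal), and `dG` draws are capped at `0.9·G_max` (gain
reduction cannot exceed the available gain without losing uniqueness, as
above).

Thresholds are produced by simulating the experiment's three-alternative
forced-choice adaptive tracking: masker level follows a two-up, one-down
rule converging on 70.7 % correct, steps of 10 dB until the first
reversal, 5 dB until the second, 2.5 dB for the remaining ten; the track
ends after 12 reversals and the estimate is the mean of the last ten
reversal levels.  Six estimates per condition are reduced by averaging
the subset (any size ≥ 3, contiguity not required) with the minimum
standard error of the mean; ties prefer the larger subset, then the
lexicographically first.  The simulated observer answers by a cumulative-
Gaussian psychometric function of masker level with spread `noise_sd`
(dB), offset so that the 70.7 %-correct point lies exactly at the true
threshold; `noise_sd → 0` is a step observer that guesses at 1/3 above
threshold, and `noise_sd = 0` in the generator bypasses tracking and
returns exact model thresholds.  Tracks start 20 dB below the true
threshold, so the masker ascends from a weakly masking start and the
early 10-dB steps are exercised.  All randomness flows from one
`numpy.random.Generator`.

CEOAE recordings are emulated as a deterministic emission — four
exponentially decaying tone bursts (1–3 kHz) with latencies of 7.5–12 ms,
longer for lower frequencies, peak amplitudes ~0.1–0.15 mPa — plus
independent replicate noise scaled as `1/sqrt(n_trials)` for the
2000-trial online average.  The default per-trial noise (1 mPa) was set
so the post-filter replicate reproducibility averages ≈ 0.95, matching
the reported replicate correlations of real recordings.  A with-elicitor
recording scales the emission by the suppression factor `s`, so the
pipeline's ΔCEOAEn converges to `100·(1 − s)` as noise vanishes.  The
generator does not emulate middle-ear-muscle contamination, attention or
session-order effects, spectral fine structure of real emissions, or
probe-fit drift — so passing tests demonstrate correctness of the
analysis chain, not robustness to those real-world nuisances.

## Group statistics

The bootstrap of the sample mean is computed *exhaustively*: all
`C(2N−1, N)` multisets of the N values, each weighted by its multinomial
multiplicity, which reproduces the iid bootstrap exactly (weights sum to
`N^N`; the weighted mean of resample means equals the sample mean and the
weighted sd equals population-sd/√N, both used as self-checks).  For
N = 12 that is 1,352,078 resamples, enumerated vectorially in seconds;
N > 14 falls back to a seeded Monte-Carlo operation.  The Gaussian
density is fitted by weighted moments.  The Nakagami density
`f(x) = 2 m^m x^(2m−1) e^(−m x²/Ω) / (Γ(m) Ω^m)` is fitted by weighted
maximum likelihood on the strictly positive resample means (the excluded
probability mass is reported; it is ~1e−4 for the reference `dG` column):
`Ω` is the weighted mean square and `m` solves
`log m − ψ(m) = log Ω − E[log x²]`, the gamma-ML condition for `x²`.
Published density parameters for the same data were obtained with an
unstated fitting method, so small method-dependent differences in `(m, Ω)`
are expected; the recomputed values agree within a few percent.
Percentiles use linear interpolation between order statistics
(inclusive).  Regression slopes carry confidence intervals from the same
exhaustive paired-case bootstrap, excluding (and reporting) degenerate
resamples with fewer than two distinct abscissa values.

## CEOAE analysis

The chain is filter → window → co-spectrum, in that order: a second-order
Butterworth band-pass (250–6000 Hz) applied forward and backward (zero
phase), a 6–16-ms post-click window with 2-ms quarter-sine/cosine edges,
then the amplitude as the square root of the band-limited integral of the
co-spectrum (real cross-spectrum) of the two replicates, floored at zero.
The root makes the quantity a linear pressure amplitude, so ΔCEOAEn =
`100·(A_without − A_with)/A_without` is an amplitude proportion; it is
invariant to the integration band only when suppression is spectrally
flat, and the band is fixed to the filter band in the absence of a
stated alternative.  A recording is valid when replicate correlation
(reproducibility) exceeds 0.7.  Trial-level artifact rejection (> 5 mPa
within 6–16 ms) is applied when raw trial buffers are available; online
averaging itself belongs to the generator.

## Numerical conventions and edge cases

- Tip inversion is closed-form piecewise linear (slopes 1, 1/c, 1); the
  round-trip error is < 1e−9 dB over a dense grid.
- `with_gain_reduced` re-derives the effective gain from the clamped
  `c~` so the `G_max = (1 − c)(BP2 − BP1)` constraint stays exact.
- Constant columns skip density fits with a reason; constant inputs make
  rank correlations undefined and raise.
- The zero-gain limit `c = 1` requires `G_max = 0` and uses a nominal
  1-dB compressive range.
- All delimited outputs of the CLI carry the run-configuration hash in a
  header comment; a manifest records seed, version and outputs.

## Problem sizes

Default test and validation sizes: 100-subject cohorts for the noisy
recovery study, 6 tracks per condition with ~60–150 trials per track,
500-track convergence checks, 1e5-draw Monte-Carlo cross-checks, and the
full 1.35-million-resample enumeration for N = 12 columns.

## Known limitations

- The model is phenomenological: no travelling-wave mechanics, no
  middle-ear transfer, no suppression between simultaneous components in
  excitation patterns (single tones only, symmetric roex shapes).
- Subject fits are independent; no hierarchical pooling across listeners.
- The tip/tail combination rule in excitation patterns (intensity
  summation) and the normalization `g = (f − f_c)/f_c` are conventions
  chosen here, as is post-filter application of the compressive gain.
- Estimation near the `dG = G_max` boundary is one-sided by construction;
  fitted `c~` values of exactly 1.00 should be read as "at least the full
  gain was removed".
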