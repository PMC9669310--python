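# Methods

## Data model and conventions

All times are in seconds, zero at CS onset; windows and binarization
moments are half-open `[start, end)`. A *moment* is 1 ms of trial time;
validated spike trains never carry two spikes within one moment (Purkinje
cells have a several-ms absolute refractory period), so binarization is
lossless to within one moment. Input data violating the rule are rejected
at load with the offending CSV row, or merged under `--clip`.

## The change-point detector

### Priors from the peri-CS histogram

The peri-CS histogram pools spikes over trials in 15-ms bins spanning
[−0.3 s, *T*] (*T* = CS–US interval; the span is trimmed down to a whole
number of bins when *T* is not a multiple of 15 ms). Bin height is the
momentary probability: pooled count / (n_trials × bin width in ms). Three
statistics parameterize the detector: the anchor bin (minimum height
within (0, *T*]), its height `p_low`, and the mean pre-CS height `p_pre`.

With few trials the in-CS minimum is typically a plateau of zero-count
bins rather than a unique bin. Ties are therefore resolved per direction:
the retrospective (onset) sequence is anchored at the **latest** minimal
bin and the forward (offset) sequence at the **earliest**, so each
sequence spans the whole stretch of trial time the histogram attests to
be silent. With a unique minimum both anchors coincide. This matters
quantitatively: anchoring both directions at the earliest minimal bin
leaves the onset model only the sliver of pause before that bin, and
detection collapses (≈8% of injected pauses at 60 Hz instead of ≈81%).

Segment priors are `Beta(κp + ε, κ(1−p) + ε)` with ε = 0.5 and prior
strength κ = 300 pseudo-moments by default. κ reflects that `p_low` and
`p_pre` come from hundreds of pooled moments, not from the single trial
being analysed. The choice is load-bearing: with a weak prior (κ ≈ 10)
the *no-change* model's Beta marginal simply adapts to the pooled spike
fraction of a pause-containing trial and absorbs most of the step's
evidence; median weights of evidence fall to ≈0.3 (odds 2:1) and nothing
crosses the 10:1 detection criterion. Performance is flat for κ between
roughly 150 and 1000.

### Model comparison

For a binarized sequence `x₁…xₙ`, the no-change model holds the momentary
probability constant under the `p_pre`-centred prior; the one-change model
puts the first `c` moments (the anchor side) under the `p_low` prior and
the rest under the `p_pre` prior, with a uniform prior over the n−1
admissible split points. Both marginals are exact Beta–Bernoulli
integrals (log-Beta functions on cumulative counts; O(n) per trial). The
weight of evidence is the log₁₀ Bayes factor with 1:1 prior odds on the
two models; the reported change point is the maximum-a-posteriori split
(ties broken toward the anchor end), mapped back to trial time — onset
latencies may be negative. Exactness is enforced in the test suite by
exhaustive enumeration against an independent sequential-predictive
oracle on every binary sequence up to length 12 (tolerance 1e−10 in log
space).

### Detection rule and pause parameters

A pause is detected when the onset evidence exceeds 1 (10:1 odds) and the
estimated pre-CS-side probability exceeds the in-pause probability; on
the rare trials where firing accelerates during the CS no pause is
detected regardless of the evidence. For probe trials the mirrored
conditions apply to the offset before width is filled in. The longest
within-pause ISI is the maximal interval intersecting [↑, ↓], with the
analysis-window edges standing in (and flagged as censoring) when no
bounding spike exists; censored rows are excluded from longest-ISI
statistics by default. Abruptness is the latency from ↑ to the start of
that interval, floored at zero. The onset window is [−0.3 s, onset
anchor); the offset window runs to `min(record end, T + 0.7 s)`; both are
configurable. Priors are built once per cell (from probe trials when
present, else all trials).

### Known limits of single-trial onset readout

The data contain no information about the shutdown time beyond the last
observed spike, so the MAP onset sits at the boundary of the pause-defining
ISI. Relative to a latent shutdown command the estimate is early by the
renewal backward-recurrence gap: at a 60-Hz mean rate its median is
≥ 8.3 ms for *any* ISI law (the equilibrium-distribution bound), and the
gap is occasionally tens of milliseconds when the shutdown supervenes on
a spontaneous long ISI — exactly the mechanism that produces apparently
negative onset latencies. Two consequences, quantified by the acceptance
suite: (i) recovered onset latencies are biased early by ≈10–20 ms with
heavy-tailed scatter, so the coefficient of variation of *measured*
onsets (≈0.28) exceeds the generative 0.2; (ii) group mean latency ratios
across CS–US intervals are slightly inflated because the bias is additive
rather than proportional. The same battery applied to the generator's
ground-truth latencies recovers the generative CoV and the exact 2:1 mean
ratio, isolating the effect to the readout. At 60 Hz and *T* = 0.3 s the
per-side 10:1 evidence requirement sits near the information floor
(~6 expected spikes' worth of signal per side against a log(n) location
Occam factor), giving ≈80% both-sides detection on default synthetic
cells; real cells with earlier onsets or higher rates sit further from
the floor.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes;
defaults (one per line, with why):

| parameter | default | rationale |
|---|---|---|
| `base_rate` | 60 Hz | centre of the 40–80 Hz spontaneous range |
| `refractory` | 5 ms | centre of the 3–8 ms refractory floor |
| body ISI law | shifted exponential | abrupt rise then steep decline |
| `tail_mix` / `tail_median` / `tail_shape` | 0.02 / 45 ms / 0.6 | log-normal mixture giving ISIs > 100 ms at a low but regular rate |
| `rate_cov_between_trials` | 0.15 | log-normal per-trial rate multiplier; puts most cells' between-trial Fano factors beyond the 0.01 stationary-Poisson limit, as in the recordings |
| `onset_fraction` | 1/3 | onset near 100 ms when *T* = 0.3 s |
| `offset_fraction` | 1.0 | recovery near the anticipated US |
| `onset_cov` / `offset_cov` | 0.20 / 0.15 | scalar variability; offset CoV below onset CoV |
| `coupling` | 0 | onset and offset drawn independently |

Latencies are truncated-at-zero normals with sd = CoV × mean (redrawn on
the rare inverted pair); the pause is realized by deleting every spike in
[L_on, L_off], so it supervenes on the spontaneous train as one long ISI
and deletion can never create a sub-refractory interval. `poisson_mode`
yields a homogeneous Poisson train with a 1-ms dead time (the
one-spike-per-moment floor) whose exponential rate is adjusted to keep
the requested mean rate; its count Fano factor is (1 − rate·0.001)² ≈ 0.88
at 60 Hz, comfortably inside the limits used by the calibration tests.
Stimulation-locked spikes (50-Hz pulse train, fixed 2-ms latency,
per-pulse probability, multiplicative suppression inside the pause) are
optional and merged under the 1-ms rule. Per-cell seeds derive
deterministically from one master seed.

What the generator does **not** emulate: complex spikes and US-evoked
responses, post-US dynamics, slow within-trial rate trends, bursting, or
any biophysics. Passing recovery tests therefore demonstrate that the
pipeline correctly reads out the statistical structure it models — not
that real recordings contain no further structure.

## Fano analysis

Fano = unbiased sample variance / mean of counts. Plausibility limits
under the stationary-Poisson null come from two routes: quantiles of
χ²(n−1)/(n−1) (exact in the large-mean limit) and Monte-Carlo quantiles
of the statistic over replicate Poisson count sets, which stay calibrated
at small mean counts; the suite checks they agree at moderate means and
that the Monte-Carlo route self-calibrates (exceedance ≈ α). Between-trial
analysis counts spikes in the 1 s before CS onset (one-sided upper limit
by default); within-trial analysis tiles each trial's pre-CS span with
0.1-s subwindows (two-sided by default); both sidednesses are available.
The exponential ISI fit subtracts the minimum interval and uses the ML
rate (reciprocal mean); tail excess is the empirical/fitted survival
ratio at the fitted 95th percentile — with a small tail mixture the
divergence is concentrated deeper in the tail, so tests probe it with an
elevated mixture.

## Acquisition

Per trial, the rate difference is count([−T, 0))/T − count([0, T))/T; the
cumulative record of these differences slopes upward once the pause has
appeared. The published analysis invokes an external slope-change
algorithm without restating it, so the rule here is a documented
reconstruction in two stages: a least-squares two-segment constant-mean
split of the differences locates the candidate trial, and the candidate
is accepted when the mean difference from it onward exceeds the criterion
(10 Hz, configurable). When even the pre-candidate mean exceeds the
criterion the pause was present from the outset and trial 2 is reported —
the first trial on which prior experience can be expressed. Recovery on
synthetic records is within ±1 trial at a 20-Hz effect.

## Statistics battery

CoV = unbiased sd / mean, computed over detected trials only; quartiles
by linear interpolation of the empirical CDF. Correlations are
product-moment (Pearson); degenerate pairs are flagged NaN rather than
dropped silently. The backward ISI regression is OLS of interval duration
on backward index (1 = nearest the pause), restricted to trials with at
least five interspike intervals between CS onset and the anchor; both
anchorings are available (estimated onset, or the start of the longest
within-pause ISI as the stricter check), and the 95% confidence limits
come from the t distribution. Population aggregation groups cells by
CS–US interval and emits mean/CoV tables, quartile collections for width
and longest ISI, and per-pair correlation distributions.

## Numerical choices and degenerate inputs

Marginal likelihoods are computed in log space with `betaln` and
`logsumexp`; posteriors over split locations are normalized explicitly.
Constant-ISI regressions return a flat fit (slope 0, R² 0) rather than a
0/0. Zero-mean count sets, all-NaN difference records, empty trial
selections, sub-moment ISIs, duplicate cell ids, unsustainable generator
rates, and degenerate location priors all raise descriptive errors.
Problem sizes in tests (50-cell populations, 20 probe trials, 300
training trials, 100k Monte-Carlo sets) were chosen so each suite section
completes in seconds while holding Monte-Carlo error well inside the
asserted tolerances.
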