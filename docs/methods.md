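# Methods

This note documents the models, estimators, numerical conventions and design
choices behind `noctivitals`, and states what the simulation-based tests do
and do not establish about real monitoring data.

## The analysis in one paragraph

The unit of classification is the *person-time sample*: one participant, one
anchor night, and the t-day trimmed mean of each nightly feature over the
anchor night plus the t−1 most recent earlier QC-passing nights
(t ∈ {1, 7, 14, 30}). Nightly features are ten statistics of a night's
beat-interval tachogram and per-minute respiratory-rate series (Table-style
definitions below). After night-level QC, features indistinguishable between
cases and controls are screened out by a Mann–Whitney test, the remainder
enter an unregularized binary logistic regression, and performance is read
off the ROC curve: trapezoidal AUC with DeLong confidence intervals,
accuracy/sensitivity/specificity at probability 0.5 for model scores, and
Youden-optimal cutoffs on the raw feature scale for single-feature screening
rules.

## Nightly features

| feature | definition | unit |
| --- | --- | --- |
| SDNN | sample SD (n−1) of the night's beat intervals | ms |
| TP | spectral power of the tachogram over (0, 0.40] Hz | ms² |
| ULF / VLF / LF / HF | band powers: (0, 0.0033), [0.0033, 0.04), [0.04, 0.15), [0.15, 0.40) Hz | ms² |
| LF/HF | ratio of LF to HF power | – |
| HR | modal per-minute mean heart rate | beats/min |
| RR | modal per-minute respiratory rate | breaths/min |
| RRF | minutes with respiratory rate strictly above 21 | min |

Band edges are closed on the left, open on the right. Modes are computed by
rounding per-minute values half-up to integers and taking the most frequent
value, ties resolved to the smaller value (the device-style "mode" leaves the
resolution and tie rule open; these conventions are fixed here and tested).
RRF counts whole minutes — the device reports one rate per minute, so the
minute is the atomic unit — and "faster than 21" is strict: a minute at
exactly 21 contributes nothing.

## Spectral estimation

The tachogram is irregularly sampled by construction, so band powers are
estimated with the classical Lomb–Scargle periodogram of the mean-subtracted
interval series (interval i placed at its onset beat time), avoiding the
interpolation bias of resample-and-FFT approaches. The periodogram is
evaluated by the Press–Rybicki FFT/extirpolation algorithm — a whole night is
~36,000 beats on ~70,000 frequencies, out of reach for the direct O(n·nf)
sum — and the implementation is validated against the direct evaluation on
small inputs (agreement to <0.5% of the peak).

Numerical conventions: frequency grid f = df, 2df, …, 0.5 Hz with
df = 1/(5·span) (oversampling factor 5); the periodogram is rescaled so its
integral over the full grid equals the interval variance (ddof = 1), which
makes TP ≈ SDNN² and band powers absolute ms². Records shorter than 30 min
are rejected; ULF and VLF are reported as NaN below a 5 h span (the slow
bands are not resolvable); a constant tachogram returns all-zero powers and
an undefined (NaN, never infinite) LF/HF; LF/HF is likewise NaN when HF is
exactly zero. Powers are reported in ms² throughout — no normalized-unit
("nU") scale is emitted, since normalized units are bounded by 100 by
convention and cannot accommodate cutoffs in the thousands.

On synthetic 8 h tachograms with known band targets the estimator recovers
LF and HF with a median relative error around 1% (the acceptance suite
enforces ≤15% over 100 seeds).

## Synthetic cohorts

### Signal level

`simulate_tachogram` synthesizes an interval series by random-phase spectral
synthesis: each band's target power is spread over the Fourier bins inside
the band with deterministic amplitudes and uniform phases, so the realized
grid variance equals the summed targets exactly; the modulation is added to
the mean interval and integrated to beat times. A nonzero band target
requires ~12 resolvable bins (e.g. ULF needs ≥ ~1 h), otherwise the call is
rejected. `simulate_respiration` draws Gaussian baseline minutes around the
nightly mean rate and replaces a Poisson number of minutes with tachypneic
values in (21.5, 30).

### The population model

Each participant draws person-level offsets; each recorded night draws
night-level offsets around them:

* band powers: lognormal, `band ~ median · exp(σ_b·u_person + σ_n·e_night)`
  with σ_b = 0.50 and σ_n = 0.46 per band;
* heart and respiratory rate: additive Gaussian
  (HR: σ_b = 5.0, σ_n = 4.2 beats/min; RR: σ_b = 1.3, σ_n = 1.0 breaths/min);
* tachypnea propensity: per-person lognormal median rate, nightly RRF
  Poisson around it.

Features co-vary: a per-person severity factor loads on all features
(variance shares: bands 0.35, HR 0.20, RR 0.30, tachypnea 0.30), the four
band offsets share a common band factor (0.35), and nightly band offsets
share a common nightly factor (0.50). Without this correlation a
multivariate classifier combines many quasi-independent reads of the person
effect and separates simulated cohorts perfectly — something real vital-sign
panels never do. The LF/HF set point is modelled as an exact individual
constant (the LF person offset equals the HF offset; the nightly log-ratio
jitters with SD 0.25), so the pooled LF/HF distribution is identical between
groups at every level.

### Calibration of the group phenotypes

Case/control levels were set from the binormal identity
AUC(t) = Φ(δ/√(2(σ_b² + σ_n²/t))) so that single-feature and category AUCs
of pooled person-time samples fall where nocturnal COPD monitoring places
them: HF ≈ 0.89 and RR ≈ 0.86 at t = 7, RRF ≈ 0.95, heart rate weak
(≈ 0.65–0.69 across t), respiration > HRV > HR as categories, and combined
panels in the high 0.90s. The resulting defaults: controls at mean interval
984 ms (≈61 beats/min), ULF/VLF/LF/HF = 1500/1000/600/400 ms², RR 14.8,
tachypnea 0.08 min/night; cases at 930 ms (≈64.5 beats/min),
2163/1560/1506/1004 ms² (LF/HF = 1.5 in both groups), RR 16.8, tachypnea
2.5 min/night. Compliance defaults to 0.73 and nights-per-person to a
lognormal with median 56.5 (IQR 32–113), the monitoring intensity of a
realistic home cohort; QC-violation rates default to 2–3% per rule and 0.5%
for zero-vital nights; exacerbations strike cases at 0.15 events per 30
nights with 3–10-day durations (no published duration distribution exists;
this is a package choice).

### Two generation paths

`generate_cohort` emits raw recordings (synthesized signals plus QC
metadata); `generate_feature_cohort` emits the nightly feature table directly
from the same per-night parameter draws, adding independent lognormal
estimator noise (σ = 0.08 on band powers and TP, 0.04 on SDNN, 0.06 on
LF/HF) that stands in for spectral-estimation error. The fast path makes
cohort-scale experiments (tens of thousands of nights) run in milliseconds;
the signal path is used wherever the estimator chain itself is under test.
QC-violating nights and exacerbation windows are injected through metadata
only, independently of the signal, so each exclusion rule can be tested in
isolation.

### What the simulator does not emulate

No raw 1 kHz waveforms, heartbeat detection errors, ectopic beats or motion
artifacts in the signal itself; no sleep staging, circadian drift within the
night, seasonal trends, or feature drift around exacerbations; person-time
samples are exchangeable given the person, whereas real nights are serially
correlated. Tests passing on these cohorts establish that the analysis code
is correct and that the pipeline recovers planted effect structure — not
that the published effect sizes hold in any real population.

## Quality control

A night is excluded iff: artifact motions ≥ 600 (boundary excluded); sleep
< 5 h or > 9 h (boundaries kept — the wording is strict); data loss ≥ 60 min
(boundary excluded); modal HR or RR equal to 0; or the night date lies in
[window_start − 7 days, window_end] of an acute-exacerbation window
(calendar-date arithmetic; "during" is read as through the window's last
recorded day). Decisions are per-night, idempotent and order-free, and
relaxing any threshold can only keep more nights (tested against a
brute-force restatement of the rules).

## Aggregation

The t-day statistic removes exactly one occurrence of the maximum and one of
the minimum and divides by t − 2; t = 1 passes the nightly value through
(the formula is undefined there) and t = 2 is rejected. Windows are
*rolling* over the t most recent kept nights, calendar gaps allowed: at
compliance ~0.73 strict calendar consecutiveness would leave almost no
30-day windows, and rolling windows reproduce the characteristic
non-increasing person-time counts across t. Whether windows should be
disjoint instead is genuinely open; rolling was chosen and is documented as
a choice. Windows containing a non-finite feature are dropped.

## Screening, regression, ROC

* **Screening** uses the Mann–Whitney U test, reported through the
  tie-corrected, continuity-corrected z. p-values follow the standard
  two-regime policy: exact permutation null for small tie-free samples,
  normal approximation otherwise. The screen runs once, on the
  shortest-timescale (nightly) samples, and its verdict applies to every
  timescale: overlapping rolling windows at large t share up to t−1 nights,
  which inflates the pooled rank test's effective design effect by roughly a
  factor of t and would make the screen anti-conservative.
* **Logistic regression** is unregularized maximum likelihood via
  Newton/IRLS (tolerance 1e-8 on coefficient change, 100 iterations),
  internally standardized for conditioning with coefficients mapped back to
  the original scale. A rank-deficient design is an error; perfect
  separation raises an explicit error naming a single separating feature
  when one exists. The pipeline additionally applies an SPSS-style tolerance
  screen (dropping columns with tolerance < 1e-4 against the already
  accepted set — after long-window trimming, TP is numerically the sum of
  its band powers) and, when a multivariate fit still separates, scores
  samples by an iteration-capped quasi-Newton fit, since the diverging
  coefficient direction still ranks the samples and the ROC needs only the
  ranking.
* **ROC**: thresholds at the unique score values with the score ≥ threshold
  convention; AUC by trapezoid (equal to the tie-corrected U/(n₁n₂)
  pair-counting statistic); 95% CI and the AUC-vs-0.5 test from the DeLong
  placement-variance estimator; paired model comparisons by the DeLong
  paired test. The Youden-optimal threshold maximizes tpr − fpr, ties going
  to the lowest threshold. Reported `youden_index` is
  sensitivity + specificity − 1 at the applied cutoff — probability 0.5 for
  model scores, the Youden threshold for raw single features — so the
  identity holds exactly in every evaluation row; under the Youden rule it
  coincides with the curve maximum.
* **Statistical unit**: person-time samples are pooled across participants,
  ignoring within-person correlation. This mirrors the design the pipeline
  reproduces and is a known limitation: pooled CIs and p-values are
  anti-conservative relative to a cluster-aware analysis, and models are
  evaluated on their training samples (apparent performance) unless
  `cross_validate=True`, which switches to stratified out-of-fold scoring.
  Covariate adjustment (age, sex, BMI category as regression terms) is
  available but off by default, since the adjustment method behind the
  original design is unstated.

## Sample size

For a proportion p with relative tolerance r at two-sided level α, the
normal-approximation precision formula n = ⌈z²₁₋α/₂ · p(1−p)/(r·p)²⌉ gives
74 for p = 0.90, r = 0.10, α = .01. The group whose precision demand is
larger fixes the size of the group it measures (under a 1:2 case:control
allocation the specificity side fixes 74 controls) and the other group
follows from the ratio (37 cases, 111 total). Enforcing both demands jointly
would instead require 74 cases and 148 controls; the implemented rule is the
one consistent with the 1:2 design. Dropout inflation (default 10%) is
reported separately and excluded from the headline total.

## Problem sizes used in tests

Module tests run on cohorts of 4–40 participants; the qualitative
reproduction check uses 50 replicate cohorts of 50+50 participants × 60
scheduled nights via the feature-level path, and spectral recovery uses 100
synthetic 8 h tachograms. These sizes give stable majority-vote verdicts on
the orderings (AUC non-decreasing in t; respiration > HRV > HR;
RRF > HF > RR; LF/HF screened out) while keeping the full suite fast.
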