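# Methods

## The two window statistics

The intrinsic timescale of a regional signal is summarized by two lag
statistics of its sample autocorrelation function (ACF):

- **ACW-50**: the first lag `k >= 1` (converted to ms as `k * 1000 / fs`)
  at which the normalized ACF falls strictly below 0.5, half of its lag-0
  maximum of 1.
- **ACW-0**: the first lag at which the ACF reaches zero, i.e. the first
  non-positive coefficient.

The ACF is the biased estimator (denominator `n`): the signal is
demeaned, zero-padded to at least twice its length, transformed with an
FFT, and the inverse transform of the power spectrum is normalized by
the lag-0 value. The biased estimator keeps every coefficient in
`[-1, 1]`, so the lag-0 maximum is always 1 and the two crossings are
well defined whenever they exist. Crossings are reported at whole lags
(no interpolation) by default, because the statistics are defined as
"first lag" quantities; a linear-interpolation mode exists behind a flag
for users who want sub-sample resolution. When a crossing does not occur
within the computed lags the result carries an explicit `found = False`
flag — never a sentinel value — and downstream stages drop such regions
explicitly.

`max_lag` defaults to `min(n - 1, 10 s of samples)`. Ten seconds of lags
exceeds cortical ACW values (tens to hundreds of ms) by two orders of
magnitude, so the default never truncates a realistic crossing.

Key identities used by the tests: a pure sinusoid of frequency `f` has
ACF `~cos(2*pi*f*k/fs)`, so its ACW-0 is its quarter period `1/(4f)` and
its ACW-50 is the first lag past `fs/(6f)`; an AR(1) process with
coefficient `phi` has ACF `phi^k`, putting ACW-50 at the first
`k > ln(0.5)/ln(phi)`.

## Core-periphery divisions

Two parcellation templates are modelled: 200 regions / 7 networks
(Schaefer-style) and 360 regions / 12 networks (Ji-style). Three
core-periphery labellings operate on them:

- **SCP** (7-network template): periphery = Visual, Somatomotor, Dorsal
  Attention, Salience; core = Limbic, FPC, DMN.
- **JCP** (12-network template): periphery = Visual1, Visual2, Auditory,
  Somatomotor; core = the remaining eight networks.
- **RCP**: periphery as JCP; core restricted to Cingulo Opercular, FPC,
  DMN; the other five transmodal networks are excluded.

Real atlas surface files are not shipped: every analysis needs only the
(region, network, anterior-posterior coordinate) relation, so the
package generates synthetic region tables with the correct counts,
realistic per-network proportions and per-network coordinate
distributions.

## Synthetic cohorts

The cohort generator emits parcellated rest/task recordings whose
timescale structure is known exactly. Each region's signal is

    x = a * s_slow + (1 - a) * s_fast + amp * s_alpha + w * s_white

with unit-variance components: `s_slow` is pink (1/f) noise over
0.3-8 Hz, `s_fast` pink noise over the full 1.3-50 Hz analysis band,
`s_alpha` a sinusoid at a region-stable frequency in 8-13 Hz, and
`s_white` white noise. The slow weight `a` sets the region's intrinsic
timescale; every realized `a` is recorded as ground truth.

Design choices that matter, and why:

- **The slow component extends below the analysis band** (floor 0.3 Hz).
  With both components sharing the 1.3 Hz lower edge, that edge alone
  dictates where the ACF first reaches zero and ACW-0 barely responds to
  `a` (measured: flat near 75 ms across the whole weight range). Letting
  the slow component carry infra-slow power — as real slow cortical
  fluctuations do — makes the zero crossing move continuously from tens
  to hundreds of ms as `a` grows, which is the phenomenon under study.
- **Per-region white-noise level**, drawn once per region from
  U(0.25, 0.55) and shared across subjects and conditions. Adding white
  noise rescales the ACF uniformly over positive lags: it drags the
  half-maximum crossing earlier but cannot move the zero crossing. The
  noise-level topography therefore (i) expresses the core-periphery
  contrast predominantly in ACW-0, and (ii) gives ACW-50 a reproducible
  spatial map that is orthogonal to the core-periphery gradient — the
  synthetic analogue of the spatially varying SNR of source-reconstructed
  recordings. This is what makes the long window the more informative
  scale for core/periphery discrimination in the default cohort, while
  both scales retain high rest-task spatial similarity.
- **Weight composition.** `a = clip(base + cp_effect * ramp(network) +
  jitter(region) + subject_effect, 0.02, 0.98) * task_factor`, clipped
  again after task modulation. The network ramp spaces the template's
  networks evenly from the periphery end (0) to the core end (1),
  centred; `cp_effect = 0` therefore collapses all network means to
  `base_weight`, giving an exact null for calibration runs. Defaults:
  `base_weight = 0.35`, `cp_effect = 0.3`, regional jitter SD 0.05.
- **Subject effects** follow a two-component Gaussian mixture: a
  fraction (default 0.5) of subjects is shifted by `mixture_shift`
  (default 0.18) relative to the rest, each component with SD 0.03. The
  mixture emulates two subject subpopulations whose interaction with
  regional structure produces a double-peaked pooled ACW-0 density. The
  `mixture_cohort_spec()` preset strengthens the mixture (shift 0.35)
  against a milder regional gradient (cp_effect 0.08, jitter 0.05) so
  the phenomenon is expressed cleanly: pooled per-(subject, region)
  values are bimodal, while subject-averaged regional values — and both
  poolings of ACW-50 — stay unimodal.
- **Task modulation** is multiplicative on `a`, mild (factors 0.9-1.08),
  with network-specific signatures per condition (e.g. auditory/language
  regions up during story listening, somatomotor down during the motor
  task). Mild modulation preserves the rest topography, which is what
  produces the high rest-task spatial correlation regime.
- **Durations.** Recordings default to 60 s per condition at
  fs = 508.62 Hz. The catalogue's per-signal duration defaults to 10 s.
  Both are configurable; 60 s keeps the ACF stable at the lags of
  interest while keeping simulation tractable.
- **Determinism.** One RNG stream per run, seeded from the spec; all
  draws (region tables, topographies, subject effects, noise) come from
  it in a fixed order, so equal specs give bit-identical cohorts.

## Signal catalogue

Four categories of pseudo-aleatory signals — pink noise, sine waves,
pink + sine, and pink + sine + white — are simulated in the 1.3-50 Hz
band at fs = 508.62 Hz, 5000 signals per category by default (20,000
total). Mixture categories draw independent U(0, 1) weights per
component, and sine frequencies are uniform over the band. Pink noise is
synthesized in the frequency domain (Gaussian spectral coefficients
shaped to a 1/f power target inside the band, zero outside), which gives
the exact target spectrum at O(n log n) cost. The amplitude
normalization before weighting (each component standardized to unit
variance) is a package choice; outputs are standardized.

## Statistics

- Core-vs-periphery contrasts use Student's (pooled-variance) t with
  Cohen's d on the pooled SD, reported as periphery - core (negative
  when the core is slower); Welch's correction is available behind a
  flag. The observational unit is the region after subject averaging.
- One-way (network) ANOVA uses the classical between/within
  decomposition with `eta^2 = SS_between / SS_total`. Two-way (task x
  CP) ANOVA fits the full-interaction OLS model with Type-II sums of
  squares; the designs here are balanced or near-balanced, so SS types
  coincide or nearly so, and the 6-cell model on a 200-region template
  across 3 tasks yields the structural error df 594 (360 regions:
  1074). Eta-squared is each effect's share of the total SS, so the
  decomposition sums to one.
- Tukey HSD adjusted p-values come from the studentized-range
  distribution over all pairwise comparisons of the six cells; the
  reported per-contrast t and d are the plain two-cell Student
  statistics, since the adjusted p and the effect size answer different
  questions.
- Multiple comparisons use Benjamini-Hochberg step-up FDR. Regional
  rest-task correlations are corrected per task condition across
  regions (the unit of the corresponding figure panel), not pooled over
  tasks.
- The anterior-posterior axis is removed by OLS of the regional values
  on the y coordinate with intercept; residuals are mean-zero and
  orthogonal to the axis by construction.

## Rest-task comparison

Subject-averaged maps feed the spatial correlation (one Pearson r per
rest-task pair across regions) and the OLS regression of task on rest;
regional correlation uses subject-level values (one r per region across
subjects, BH-FDR at alpha = 0.05). Regions whose lag-quantized values
are constant across subjects have undefined correlation and are
reported as r = nan, never significant. The rest-task difference is
`(rest - task) / rest * 100` per region per subject — positive when the
timescale shortens during the task — averaged over subjects before the
task x CP ANOVA.

## Density and classification

ACW values are min-max scaled to [0, 1] before density estimation.
Densities are Gaussian KDEs with Silverman's-rule bandwidth evaluated on
a 512-point grid; the trapezoidal integral is ~1 by construction.
Bimodality is declared only when two indicators agree: the KDE shows at
least two prominence-filtered modes, and a 2-component Gaussian mixture
beats a 1-component fit by BIC with components separated by more than
1.5 pooled SDs (the separation guard prevents BIC from splitting a
skewed unimodal sample). The Gaussian-mixture route also covers the
reading of kernel density estimation as an EM-fitted mixture.

Core/periphery classification treats each (region, subject, condition)
ACW observation as a sample, labelled by its region's division
assignment (excluded regions dropped; `core` is the positive class for
precision/recall). Logistic regression and an RBF-kernel SVM run under
stratified 20-fold cross-validation, shuffled with a configured seed;
features are standardized inside each training fold only. Metrics
(accuracy, precision, recall, AUROC) are fold means on the 0-100 scale.
The subject-variability analysis labels subjects high/low by the median
of their region-averaged resting ACW, fits a one-feature logistic model
on task values, and reports the AUROC of its scores — a rank statistic
of the task values. Mutual information between one ACW scale and the
binary labels uses the k-nearest-neighbour estimator (k = 3), reported
in nats and clipped at zero; only orderings of MI scores are treated as
meaningful.

## Problem sizes used by the tests and the acceptance script

The shipped checks run on synthetic cohorts sized as a package choice:
the 200-region rest+task cohort uses 12 subjects x 60 s per condition;
the 360-region rest-only cohort 6 x 60 s; the mixture preset 8 x 30 s;
the null-calibration study 200 replicate cohorts of 200 regions x 2
subjects x 10 s; the signal catalogue runs at its full default 20,000
signals. These sizes keep every regime of interest (nominal type-I
rate, recovery correlation > 0.8, rest-task R^2 > 0.85, pooled
bimodality, ACW-0 > ACW-50 informativeness) comfortably expressed.

## What the generator does and does not emulate

Passing tests show that the estimators and statistics behave correctly
on signals whose ground truth is known, and that the pipeline detects
exactly the structure the generator injects. The generator emulates
band-limited scale-free fluctuations, an alpha-band oscillation,
spatially varying noise level, network-level timescale hierarchy,
subject heterogeneity and mild task modulation. It does not emulate
sensor-level physics (source leakage, head geometry), non-stationarity,
cross-regional correlation (regions are generated independently, so
spatial autocorrelation of real cortical maps is absent), or
task-evoked transients. Conclusions about real recordings therefore
rest on the estimators' correctness, not on the generator's realism.

## Known limitations

- ACW values are quantized to the sample period (~1.97 ms at
  508.62 Hz); at short windows this makes ACW-50 coarse, which is
  visible in the regional-correlation stage (constant columns) and is
  handled explicitly there.
- The bimodality decision is a heuristic pair of indicators, adequate
  for well-separated mixtures but not a formal dip test.
- The restricted division (RCP) drops excluded regions, so its task
  ANOVA error df reflects the included region count rather than the
  full template.
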