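# Methods

This note documents the models, windowing rules, numerical choices and
limitations of `icpsi`, in the order data flows through the package.

## Synthetic recordings

The generator exists to give every downstream stage a controllable input
with the signal features the analysis assumes. It is a *surrogate*
emulator, not a physiologically validated cardiovascular model: each
mechanism is the simplest construction that produces the feature the
analysis consumes.

**Cardiac pulse.** One beat is the sum of three positive Gaussian sub-waves
at fixed fractional latencies 0.15 / 0.35 / 0.55 of the beat, normalised to
[0, 1]. The compliance-impairment parameter c ∈ [0, 1] drives the height
laws h₁ = 1 − 0.35c, h₂ = 0.65 + 0.55c, h₃ = 0.45 + 0.35c and a common
width σ = 0.05 + 0.04c (fractions of the beat). These constants were
calibrated once so the template satisfies the morphology narrative the
classifier targets: at c = 0 three distinct peaks with P1 > P2 > P3 and a
crisp dicrotic notch; a monotone-increasing P2/P1 ratio in c; and a merge
into a single rounded peak (fewer than three resolvable maxima) as c → 1.
Per-beat latency jitter (σ = 0.005) and inter-beat-interval jitter (3 %)
give natural variability.

**Slow dynamics.** Mean ICP follows the exponential pressure–volume curve
P(t) = P₀·exp(k·V(t)) with defaults P₀ = 10 mmHg and k = 0.11 mL⁻¹, chosen
to put the baseline in the normal adult range and give a realistic elastance
scale; the cardiac pulse amplitude scales with the local PV slope k·P(t)
(gain 5 mmHg per mmHg/mL) so volume loading steepens both mean and pulse
pressure, which is what RAP measures. ABP carries two superimposed
sinusoidal slow waves in the B-wave band (0.5–2 cycles/min, random
frequencies and phases, peak amplitude 4 mmHg by default) — chosen
specifically to exercise the 10-s/5-min windows of RAP and PRx. The
autoregulation parameter a ∈ [0, 1] transmits the slow ABP wave into ICP
with net gain (2a − 1)·0.5: fully pressure-passive coupling at a = 1
(PRx → +1), counter-regulated negative coupling at a = 0 (PRx → −1),
neutral at 0.5.

**Artifacts.** Events arrive at a Poisson rate (`artifact_rate`/hour),
half spikes (1–3 samples at 210–260 mmHg, caught by the range filter), half
flat-line dropouts (5–60 s at 0 mmHg, caught by the flat-line detector and
by beat segmentation). Ground-truth channels (per-sample artifact flags,
per-beat nominal class, noiseless mean ICP) ride along for tests.

**Cohorts.** One root `SeedSequence` spawns independent per-patient child
streams, so a patient's recording is reproducible regardless of cohort
size. Per-patient c ~ Beta(2, 2.5), a ~ U(0, 1), age ~ N(45, 16) clipped to
16–90, GCS ~ U{3..12}, volume load ~ U(0, 6) mL. GOS is drawn from a
proportional-odds ordinal model whose linear predictor rises with preserved
compliance (1 − c) and falls with mean-ICP burden; a configurable fraction
of patients is flagged DC-treated/unknown (25 %) or missing outcome (15 %)
to exercise the screening cascade. Waveform-level cohorts default to
30-minute recordings; two auxiliary generators produce hourly-resolution
cohorts (latent AR(1) PSI trajectories whose effect on hourly mean ICP is
delayed by a configurable lag, with 60 minute-level draws per hour) and
minute-resolution cohorts (bounded-random-walk PSI with ICP/PRx/CPP as noisy
monotone functions of it, GOS falling with the fraction of time at
PSI > 2.5) for the burden and heatmap analyses, where simulating days of
waveform per patient would add nothing but runtime. Defaults throughout
(70 bpm, ABP 90/40 mmHg, noise σ = 0.2 mmHg, fs 50–250 Hz) are ordinary
neuro-ICU magnitudes.

**What passing tests do not show.** Real ICP waveforms have respiratory
modulation, plateau waves, posture/drainage events, sensor drift and
morphology that varies beat-to-beat independently of any single latent
parameter. Recovery of c and a by the pipeline demonstrates internal
consistency of the chain, not clinical validity of PSI.

## Beat segmentation and morphology grading

Segmentation is ECG-free: the 0.5–10 Hz band-passed ICP derivative is
peak-picked (prominence one SD of the derivative, minimum spacing 0.6 of
the dominant cardiac period estimated by Welch in the 40–180 bpm band), and
each upstroke is walked back along the 15-Hz low-passed signal to the foot
of its rising run. Segments implying beat rates outside 40–180 bpm are
emitted pre-labelled as artifacts. An all-constant signal yields no pulses.

Sub-peaks are local maxima of the 15-Hz zero-phase low-passed pulse
(prominence ≥ 5 % of pulse height), assigned to P1/P2/P3 by fractional
latency windows [0.03, 0.26) / [0.26, 0.46) / [0.46, 0.75); two maxima in
one window keep the higher (stability under noise). Heights are measured
above the pulse minimum; the notch depth is the drop from the smaller of
P2/P3 to the trough between them. Absent sub-peaks are reported absent,
never as zero.

The grader is a transparent rule set with config-exposed boundaries
(`ClassifierConfig`), since no published decision surface exists for the
four classes beyond the P1/P2/P3 ordering narrative:

| class | rule (defaults) |
|---|---|
| artifact | amplitude < 0.5 or > 50 mmHg, baseline outside −30…200 mmHg, or non-cardiac rate |
| 4 | ≤ 1 resolvable sub-peak (rounded mono-peak, indistinct notch) |
| 3 | P2/P1 > 1.1 (tidal wave clearly dominant, notch degraded) |
| 2 | P2/P1 ∈ [0.9, 1.1] (tidal rises toward systolic) |
| 1 | P1 > P2 > P3 all present, notch depth ≥ 5 % of pulse height |

## Index battery

All windows (1.5 s, 10 s, 1 min, 5 min, 1 h) are left-closed/right-open and
anchored at recording start — phase is otherwise unspecified in bedside
practice, and fixed anchoring makes outputs deterministic.

* ICP range filter: strictly below −30 or strictly above 200 mmHg rejected
  (the literal reading of "below/above"; the endpoints survive).
* A flat-line detector (3-s window, peak-to-peak < 0.01 mmHg) stands in for
  the manual artifact editing of bedside software.
* PSI per 5-min window needs ≥ 30 non-artifact beats, else absent — a
  guard for the weighted mean in sparse windows; the quorum is a package
  choice, exposed as a parameter.
* AmpICP: per-second 1.5-s min-to-max values (windows containing any
  invalid sample are skipped), median per 5-min window, retained only in
  (0.04, 40) mmHg.
* 10-s means require ≥ 50 % valid samples per bin (common neuromonitoring
  quorum); the fundamental-harmonic amplitude (largest rFFT magnitude in
  the 40–180 bpm band, scaled so a pure sinusoid of amplitude A returns A,
  floor 0.04 mmHg) requires the whole segment valid.
* RAP/PRx: trailing (causal) windows of 30 ten-second pairs emitted on the
  minute — the bedside "updated every minute" semantics — requiring ≥ 15
  valid pairs and nonzero variance in both channels.
* Up-sampling of PSI and AmpICP to the minute grid is by value-hold, which
  preserves the meaning of the 5-min statistic; interpolation would invent
  intermediate states.
* Patient summaries: per-channel medians over each channel's own GMT, and
  the %GMT of PSI in the six 0.5-wide bins over [1, 4] (last bin closed),
  which always sum to 100 % of valid PSI time.

## Burden prediction

Hours are 60-minute bins needing ≥ 30 valid minutes (published bedside
practice fixes no quorum; ours is exposed as a parameter). ICP dose is the Riemann sum of
max(ICP − thr, 0) over valid minutes (mmHg·min, thresholds 20 and 22);
insults are maximal runs of consecutive valid minutes strictly above
threshold, with invalid minutes terminating a run (no gap tolerance —
the most conservative definition); counts are reported for any duration and
for runs ≥ 5 min. Lagged designs pair hour t outcomes with hour t − lag
predictors strictly within patient.

Mixed models are fitted by REML (statsmodels `MixedLM`) with a random
intercept per patient, optionally a random slope on the predictor or on
time; candidate structures can be compared by information criteria.
Marginal R² is Nakagawa–Schielzeth — fixed-effects variance over the sum of
fixed, random (averaged zᵢᵀΣzᵢ over rows) and residual variance. Singular
fits (a variance component at ~0 relative to total variance) are flagged,
never silently dropped. An AR(1) residual structure is not offered by the
backend; requesting it raises `NotImplementedError` rather than silently
fitting independence.

## Outcome heatmaps

The four grids are fixed by construction: PSI (6 cells, width 0.5 over
[1, 4]), PSI × ICP (6 × 20, ICP 0–40 by 2 mmHg), PSI × PRx (6 × 20, −1–1 by
0.1), PSI × CPP (6 × 30, 40–100 by 2 mmHg). A patient's denominator is the
minutes where *all* grid variables are valid; in-range cell percentages
plus an out-of-range remainder sum to 100.

Cell eligibility needs ≥ 5 patients each contributing ≥ 5 min to the cell.
By default the correlation sample is *all* grid-valid patients, with %GMT
set to 0 for sub-threshold contributors — the exposure logic (a patient who
never visits a cell has zero exposure, which is information, not
missingness); `include_zero_contributors=False` switches to
contributors-only. Zero variance on either side masks the cell.

Rendering replicates each cell into 6 × 6 subpixels and blurs with a
Gaussian of σ = 1 pixel (6 subpixels), truncated at 3σ, reflective
boundaries, as *normalised convolution* — masked cells carry zero weight,
so no colour bleeds into or out of them, and they are re-set to NaN (white)
afterwards. Outcome values are clipped to |r| ≤ 0.3 before rendering.
Density maps default to per-patient normalisation (each patient's counts
divided by their own maximum cell count, then averaged); a `global`
alternative (pooled counts over pooled maximum) is provided because the
phrase "normalised per patient by the highest cell count" admits both
readings. Colour mapping (blue = favourable/frequent) is presentation
metadata; the numeric arrays are the analysis surface.

## Cohort statistics

The screening cascade applies, in fixed precedence, (1) missing outcome,
(2) DC performed or unknown, (3) < 12 h monitoring, counting each patient
under the first step they fail. Group comparisons are two-sided
Mann–Whitney U with medians and IQRs; no multiplicity adjustment is applied
(mirroring exploratory practice), and the number of tests is part of the
output. Logistic models use patient *medians* of the monitoring period as
covariates — consistent with summarising skewed physiological channels by
medians elsewhere in the chain; means are the obvious alternative and
differ little on stationary recordings. Separation and non-convergence are
flagged on the result rows.

GAM curves of PSI against ABP/ICP/AmpICP/RAP use cubic B-splines (basis
dimension 10 — the conventional default; the source analyses do not state
one) with the penalty weight selected by statsmodels' cross-validation
criterion (`select_penweight`); REML smoothing selection is not available
in this backend, and on the smooth monotone relationships involved the two
criteria select indistinguishable fits. Exactly-degenerate (noiseless)
responses fall back to unpenalised least squares on the same basis. The
pooled fit ignores within-patient correlation and is documented as
exploratory; sensitivity variants drop minutes with simultaneous ICP > 40
mmHg, and age stratification is done by subsetting before the call. Fewer
than 100 in-range points are refused.

## Problem sizes in tests and the acceptance script

Simulation-backed checks use 10-min recordings for pulse/PSI recovery
(9-point impairment grid), 40-min recordings at 50 Hz for PRx recovery
(the trailing 5-min correlation needs ~35 min to yield a stable median),
50-patient × 48-h hourly cohorts for the mixed-model properties, and
60-patient × 8-h minute cohorts for the heatmap sign structure — sizes at
which every targeted effect is comfortably resolved while the whole suite
runs in about a minute.

## Known limitations

* The rule-based grader is a transparent stand-in for the trained
  neural-network classifier whose labels it cannot reproduce exactly;
  its thresholds are explicit precisely because the original decision
  surface is not public.
* The simulator omits respiration, plateau waves, drainage and drift (see
  above); PRx/RAP magnitudes on synthetic data are cleaner (closer to ±1)
  than clinical values.
* AR(1) residual correlation in the mixed models is declared, not
  implemented, in this backend.
* Insult counting is per-hour; an episode spanning an hour boundary counts
  once in each hour it touches.
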