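# Methods

This note documents the models, the parameter choices that matter, the
numerical conventions, and what the synthetic generators do and do not
emulate.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## pfUS chain

**Despiking.**  Power-Doppler motion artifacts are short (1–3 frame)
multiplicative transients.  Detection: a sample is flagged when its
deviation from a rolling median exceeds `k` × the rolling MAD of those
deviations, with `k = 5` and an 11-sample base window.  Three
refinements make the detector robust in practice:

* *iteration* — detection is repeated on the progressively cleaned trace
  (flagged samples replaced by linear interpolation) until no new flags
  appear, because clustered bursts corrupt first-pass rolling statistics
  in both directions (inflated MAD hides part of a burst; a shifted
  median falsely flags clean neighbours);
* *a global MAD floor* — the threshold scale is floored at the global
  median absolute first-pass residual, preventing runaway flagging where
  interpolation has made the trace locally noise-free;
* *a second, coarser scale* (2·window + 1) — outlier runs long enough to
  capture the short rolling median itself (overlapping bursts) are still
  caught at the coarser scale.

At the cohort level, a sample flagged in at least half of the ROIs
(`consensus_fraction = 0.5`) is censored in *all* ROIs: motion hits every
ROI in the same frames, and any residual frame-global transient would
otherwise masquerade as coherent signal and inflate every pairwise
correlation in its window.

**Band-pass.**  Zero-phase (forward–backward) 2nd-order Butterworth,
0.01–0.2 Hz.  Zero-phase filtering is used so that window timing is not
shifted relative to the injection schedule.  Traces must be at least
three filter lengths (3·fs/f_low samples) long.

**ΔCBV/CBV.**  Computed on despiked, unfiltered traces:
100·(x − B)/B with B the mean over the final 5 min before the drug
(non-positive B is an error).  The percent series is averaged in 60 s
bins before testing — one test per region per minute keeps the BH family
bounded; the bin width is configurable.  The family tested is all
region × post-drug-bin cells.

**Sliding-window connectivity.**  Window 300 s, step 60 s (the protocol
fixes only the 5-min baseline window; both parameters are exposed).
Pearson r per ROI pair per window, clipped into ±(1 − 1e−7) before
atanh so duplicated/degenerate traces stay finite; zero-variance pairs
propagate as missing (never as 0) and are excluded from every average.
The diagonal is excluded throughout.  Regional strength is the mean z
over a ROI's incident edges (7 in the 8-ROI set); the PFC–SM curve is
the mean over the 16 PFC×SM edges.  Signed z values are averaged (not
|z|).

**Delta statistics.**  Δz references the final window fully inside the
pre-drug period ([900, 1200) s in the standard session).  Per post-drug
window, the per-subject deltas are tested against zero (equivalent to
the paired test of window value vs own baseline value); the window
family is BH-corrected at q = 0.05.  AUC is the per-subject trapezoidal
integral of Δz over post-drug window starts, in z·s; the integration
span (drug time → end of recording) and the trapezoidal rule are
package conventions.  Between-group AUC comparison uses the two-sided
unpaired t-test (pooled variance by default, Welch by flag).

## Unit-fc chain

Spike counts per 50 ms bin (half-open bins, trailing partial bin
dropped) are smoothed with a normalized discrete Gaussian, σ = 2 bins
(100 ms), truncated at 4σ, reflected boundaries — reflection avoids edge
attenuation of the analysed span.  Rows are z-scored over the analysed
15-min span of each block separately, so vehicle and drug blocks are
normalised symmetrically; zero-variance units are flagged and excluded.

Windowed correlations use 60 s windows slid by 30 s (29 windows per
900 s span).  Static fc is the per-pair mean of the windowed *z* values
(Fisher-domain averaging; raw-r averaging available by flag); the
difference matrix is drug − vehicle; per-unit Δz is the mean of each MOs
unit's difference row over all SSp units.  The analysis span starts at
the recorded injection time (configurable lag, default 0).  The
within-region analogue (same-probe pairs, diagonal masked) is supported
through the same entry point.

Group statistics pool units across animals: per group a two-sided
one-sample Wilcoxon signed-rank test against zero (exact null via
dynamic programming over signed midranks for n ≤ 25, tie- and
continuity-corrected normal approximation above; zero differences are
dropped and counted), across groups Kruskal–Wallis (tie-corrected) with
Dunn's pairwise z statistics, BH-adjusted across pairs (Bonferroni by
flag).  Pooling units treats them as exchangeable; see the caveat under
*Limitations*.

## OD profiling

The profile is the mean intensity across the rectangle's short axis.
The peak summary concretises "high signal around the rectangle centre"
as: central 40 % span (configurable), baseline = median of the two
pooled flank segments, AUC = trapezoidal integral of
max(profile − baseline, 0) over the central span.  The AUC is invariant
to constant image offsets and scales linearly with band amplitude.
Higher pixel value = stronger signal; inverted film scans are negated on
input via a flag.

## Synthetic generators

All generators are pure functions of (config, seed); identical seeds
give bit-identical data, and every injected effect is recorded in a
ground-truth object.

**pfUS sessions.**  1 Hz sampling (the analysis band needs only
fs > 0.4 Hz; the acquisition frame rate is irrelevant to the band),
40-min sessions, vehicle at 5 min, drug at 20 min.  Each ROI's relative
fluctuation is c·f₀ + p·f_G + e·η: f₀ a common OU factor, f_G a
group factor (PFC or SM), η white idiosyncratic noise, with
c² = baseline cross-group correlation (default 0.3),
p² = drug coupling delta (default 0.3), e² the remainder.  Only the
shared factors carry slow (OU, τ = 20 s) structure; making η white
reflects that idiosyncratic hemodynamic noise is broadband.  After the
drug, the two group factors mix into a single bridge factor
(exponential onset, τ = 120 s), raising the cross-group correlation by
exactly the delta while leaving within-group correlation unchanged —
within-group correlation is therefore fixed at baseline + delta, and
feasibility requires baseline + delta < 1.  The prefrontal CBV response
is a gamma kernel (shape 3, scale 120 s) scaled to the configured
fractional drop (default −15 %).  Artifacts are multiplicative bursts
(1–3 samples, ~1/min, gain ≈ 0.8) applied to all ROIs at the same
frames, as motion does.  Fluctuation amplitude is 5 % of the baseline
level, white measurement noise 1 %.

**Spike sessions.**  Three contiguous 20-min blocks (baseline, vehicle,
drug), injections at block starts.  Per-unit intensity
λ_u(t) = exp(μ_u + a_u·f_region(t) + b_k·f_shared(t)) with unit-variance
OU factors (τ = 2 s, simulated at the 50 ms bin step) — a doubly
stochastic Poisson model.  μ_u is normalised per block so expected rates
(log-normal around 5 Hz, log-sd 0.5) are independent of the coupling
schedule: drug effects are purely correlational.  The control regime
drops the shared coupling in the drug block (0.3, 0.3, 0.05); the
knockout regime has no shared-factor modulation (0, 0, 0).  Within-region
loadings are sign-balanced (a_u = ±0.15): units couple to their
population factor with either sign.  Two properties motivated this
design: (i) with single-signed loadings, the *realised* correlation of
the two region factors over a block is a random cohort-common offset in
every cross-region pair, and a pooled test over hundreds of units
detects any such offset almost surely — sign-balancing makes the offsets
symmetric about zero; (ii) the log link rectifies even-order terms
(cov ∝ exp(a_i a_j ρ) − 1 contains (a_i a_j ρ)²/2 > 0 for every pair,
scaling as a⁴), so the loading magnitude is kept modest.  Together these
make the pooled per-unit statistics behave as the analysis assumes under
the null, which is exactly what the generator is for.

**OD images.**  Background + vertical Gaussian band (amplitude, centre,
width configurable) + white pixel noise, emulating the dense mRNA
stripe of a labelled region crossing a section.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: hemodynamic response variability across
subjects and regions beyond a fixed kernel, non-stationary baseline
drift, anesthesia-state changes, spike-sorting contamination and unit
drift, burst/refractory spike statistics (spikes are Poisson given the
rate), inter-animal heterogeneity in the unit pool (units are pooled
i.i.d. draws), and real autoradiograph geometry (curved bands, uneven
background).

## Validation sizes

Simulation-based checks use these problem sizes (single-CPU friendly):
pfUS null type-I, 300 runs of 10-subject cohorts (the acceptance script
uses 200); group-comparison null, 100 run-pairs of 60+30-unit cohorts
(script: 60); pfUS effect recovery, 60 runs (script: 40) plus 20 runs
for the CBV trough (script: 10); unit-chain effect recovery, 40
run-pairs of 250+60-unit cohorts; despiking, 5 cohorts × 8 ROIs; OD
linearity, 20 seeds per amplitude.

## Numerical conventions and degenerate inputs

* Correlations are clipped into ±(1 − clip_eps), clip_eps = 1e−7,
  before atanh; missing values (zero in-window variance, excluded
  units) propagate as NaN and are excluded from averages, never
  imputed.
* All times are seconds from acquisition start; intervals half-open
  [start, end); the last partial bin/window is dropped.
* Wilcoxon zero differences are dropped (count reported); an all-zero
  group is reported as non-significant with a degeneracy flag rather
  than an error when it appears inside a group comparison.
* Kruskal–Wallis on completely tied data returns H = 0, p = 1.
* Degenerate t-tests (zero variance) raise; pipeline-level tests catch
  this and record a flagged non-significant result so one flat window
  cannot abort a cohort analysis.
* BH-FDR follows the step-up adjusted-p definition, capped at 1,
  restored to input order; rejection ⇔ adjusted p ≤ q.

## Limitations

* Pooling units across animals ignores animal-level dependence; the
  per-animal aggregation flag exists but the pooled form is the default.
  Real shared population dynamics (which the knockout-regime generator
  deliberately omits) would make the pooled Wilcoxon anticonservative.
* The despiking parameters were chosen for transient multiplicative
  bursts; slow artifacts (drift, vasomotion changes) pass through.
* The baseline-referenced Δz inherits the sampling noise of the single
  baseline window; with few subjects this is the dominant variance
  component.
* The AUC integration span and the 60 s CBV bin width are package
  conventions, exposed in the config, not protocol constants.
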