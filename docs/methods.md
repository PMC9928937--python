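# Methods

This note documents the statistical procedures implemented by `pavlophys`,
the defaults behind them, what the synthetic generator does and does not
emulate, and the choices made where the design was genuinely open.

## Task structure and the synthetic study

A discrimination session interleaves 75 reward (CS-E) and 35 punishment
(CS-A) trials. Each trial is a 4 s pure tone whose unconditioned stimulus
(Ensure reward or airpuff) arrives at a uniformly jittered delay of
1–1.5 s after tone onset; consecutive tones are separated by an
inter-trial interval of 20 ± 4 s, which we read as uniform on [16, 24] s
(no distribution is implied by a "±" range; the bounded uniform is the
simplest faithful reading). Trial order is an unconstrained seeded
shuffle — no run-length constraint is imposed.

`synthetic.simulate_study` generates `n_subjects` sessions with four
labeled subpopulations per subject (defaults 14 untagged MGN, 8 MGN→BLA
projectors, 12 out-of-network BLA, 6 in-network BLA ≈ 40 units/subject,
proportioned like a typical dual-region array yield). Spike trains are
inhomogeneous-Poisson realizations, by thinning, of

    rate(t) = baseline + phasic(t; cue type) + sustained(t) + slope · trial(t)

where the phasic kernel is a signed rectangular onset at a stated latency
with exponential decay (response shapes in the source data are described
only graphically; an onset-plus-decay transient is the minimal shape with
controllable amplitude, latency and duration), the sustained term is a
constant offset over the tone, and the tonic term grows linearly with
trial index across the whole trial epoch, matching the linear-regression
detection model. `tonic_slope_spikes_per_trial` is expressed as spikes per
trial over a 1 s window, i.e. Hz per trial; by default 20% of units drift
at 0.05 spikes/trial (a drift of ~4 spikes over a session against a
baseline of 8 Hz — subtle enough that trial-averaged analyses miss it,
which is the regime the between-trial method exists for). Rates are
rectified at zero.

Licking is Poisson: 1 Hz during ITIs and 6 Hz during reward anticipatory
windows for a learner (non-learners use the ITI rate everywhere). These
magnitudes are tuning knobs, not claims about real animals: the source
study reports no lick rates. They produce session-level statistics
(difference-score t-tests passing at p < 0.01, anticipatory response rate
near 1) comparable to a well-trained subject.

A photostimulation epoch is appended 10 s after the last trial, within the
same session: five 1 s pulses, 120 five-ms pulses at 1 Hz, and 50 each at
10 and 20 Hz. Tagged projectors fire one evoked spike per pulse with
reliability 0.9 at a per-unit latency drawn from 3–8 ms (0.5 ms jitter);
in-network BLA units respond at 15–40 ms with reliability 0.8 and broader
jitter, emulating polysynaptic propagation. Classification uses only the
1 Hz block, as in the protocol; the 10/20 Hz trains are present but not
analyzed.

What the generator does **not** emulate: bursting and refractoriness
(spiking is Poisson), spike-sorting artifacts, non-stationarities other
than linear drift, within-session learning dynamics, correlated
population noise, and free-reward trials. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to every property of real recordings.

## Behavior

Licks are detected as downward threshold crossings of the IR beam-break
voltage; crossings closer than 30 ms are merged (mouse licking tops out
near 10 Hz, so a 30 ms refractory only removes sensor chatter; no value is
given in the source).

Per trial, anticipatory licks are counted in [cue onset, US onset) and
compared with a duration-matched window immediately preceding cue onset.
The bootstrap power analysis resamples n trials **with replacement**
(1000 iterations, α = 0.05 paired t-test) for n = 1…50 and reports the
detection probability per n.

Learning criteria:

* **acquisition** — paired t-test of anticipatory vs ITI counts on the
  first 20 and last 20 reward trials; a subset passes iff p < 0.01 *and*
  the anticipatory mean is greater. The session passes if **either**
  subset passes, mirroring the discrimination criterion's explicit
  "any of the three tests" (the source states no conjunction rule for
  acquisition).
* **discrimination** — two-sample t-test of per-trial difference scores
  (anticipatory − ITI), reward vs punishment, over the first-20, last-20,
  and a seeded random-20 subset (drawn without replacement; the seed is
  recorded in the outcome). A subset passes iff p < 0.01 and the raw
  reward lick count exceeds the punishment count. The session passes if
  any subset passes *and* more than half of reward trials contain at
  least one anticipatory lick.

The pairing choice (paired within-trial for acquisition, two-sample on
difference scores for discrimination) follows the matched-window design of
each comparison. Trial outcomes are labeled hit / miss / false alarm /
correct rejection by crossing CS type with presence of anticipatory
licking; the labels partition the trials by construction.

## Photoidentification

Per 5 ms 1 Hz pulse, spikes are counted in [0, w) after onset against a
duration-matched pre-pulse window (w = 10 ms for MGN, 50 ms for BLA). MGN
units use a paired Wilcoxon signed-rank test, BLA units a rank-sum test,
exactly as the criteria are named. The z-score trace is the 1 ms-binned
pulse-aligned response normalized by the pre-pulse bins' mean/SD (1 ms is
the finest stable resolution for a 10 ms window); `z_peak` is the maximum
bin z within the window — "z > 3.5 within 10 ms" could mean peak-bin or
window-mean z, and peak is used (a single-bin evoked spike at fixed
latency is exactly what a projector produces). When the pre-pulse SD is
zero the SD floor is one spike per pulse count, so a silent baseline with
reliable evoked spiking still yields a large finite z. First-spike latency
is the across-pulse median. The 10 ms threshold is a fixed constant
justified by ex vivo patch-clamp evidence of no recurrent excitation; the
ex vivo measurement itself is out of scope.

## Responsiveness and valence categories

Task responsiveness compares per-trial spike counts in [0, 100 ms) after
stimulus onset against a duration-matched baseline window taken 3 s back
in the preceding ITI ([−3, −2.9) s relative to cue onset), with a paired
signed-rank test at α = 0.01. **Design note:** the obvious alternative —
counting over the full 3 s baseline and rescaling to 100 ms — makes the
signed-rank test anticonservative (measured ≈3.5% false positives per
stimulus at α = 0.01) because rescaled counts have far smaller dispersion
than raw 100 ms counts and the rank of every difference is dominated by
the response side. Matching the window durations restores exact
calibration (<1% false calls), so the duration-matched reading is used.
The US window is handled symmetrically (0–100 ms after US onset).

The excited/inhibited sign is the mean response z (response mean minus
baseline mean over baseline SD); a sign of exactly zero (a
probability-zero tie) leaves the unit sign-indeterminate without
crashing. The valence decision tree crosses per-cue significance and sign
into nine labels (E±A±, single-cue E±/A±, none).

Category-level statistics: proportion comparisons use a chi-squared test
unless a 2×2 table holds any cell below 5, in which case Fisher's exact
test is used. Prevalence comparisons build leave-one-subject-out count
distributions (k samples per category for k subjects), run Kruskal–Wallis,
and on significance compare the largest-mean category pairwise (rank-sum)
against the others at α = 0.05 divided by the number of pairs tested.

## Neural trajectories

Per-condition z-PSTHs (50 ms bins, baseline −2–0 s) are smoothed with a
causal Gaussian and concatenated along time; PCA is fit on the combined
bins×units matrix (bins as observations, units as features, features
centered) separately per region, so all of a region's conditions share one
basis. Smoothing windows: 25 previous bins for the two-condition (CS-E vs
CS-A) analysis, 10 for the four-outcome analysis. PC signs are fixed by
orienting each component's largest-magnitude loading positive. Trajectory
length is the polyline length over the first 3 PCs (both analyses are
displayed in 3D; the component count is a parameter). Leave-one-subject-out
statistics refit the basis after removing the left-out subject's units —
whether the original basis should be frozen is unstated, and refitting
keeps every leave-one-out replicate self-consistent. Pairwise trajectory
distances are per-bin Euclidean distances; window summaries average over
1 s pre-cue and 1 s post-cue. Two-group comparisons use rank-sum; ≥3
groups use Kruskal–Wallis with Bonferroni-corrected largest-vs-rest post
hocs.

## Phasic clustering

Features are per-condition 100 ms-bin PSTHs, z-scored against each unit's
−2–0 s baseline, causally smoothed (10 prior bins), and concatenated
across conditions so one tree spans all conditions. Units with zero
baseline SD (z undefined) are removed and reported. The tree uses Ward's
method on the Euclidean metric and is cut at a fraction of the **maximum
merge height** — the standard dendrogram-cutoff reading of "0.23 of the
max value in the set". Presets: 0.23 (two-condition), 0.30
(four-outcome), 0.20 (tonic). Clusters under 3 members are discarded:
their units are flagged, never reassigned, and excluded from prevalence
and composition tables. Cluster labels are canonicalized by descending
size with ties broken by smallest member index, so unit order cannot
affect reported memberships.

## Tonic change detection

Per unit, condition, and trial, spikes are counted in three fixed windows
around cue onset: ITI baseline [−3, −2), pre-cue [−1, 0), response
[0, 1) s. Window placement is validated against the previous trial's
tone/US epoch. Pre-cue and response counts are z-scored — subtract mean,
divide by SD ("the mean and standard deviations … were subtracted" is read
as standard z-scoring; subtracting an SD is not a defined normalization) —
against one of two references:

* `"window"` (default): the baseline window's across-trial mean/SD;
* `"first_trials"`: the series' own first 10 trials (the habituation
  reference used for display normalization in the source's figures).

The two references behave differently in the presence of drift: the
within-trial window absorbs a session-long drift into its SD, capping the
attainable z-range near √12 ≈ 3.5 for a dominant linear drift, while the
habituation reference displays drift at full contrast. The methods-text
reference is the default.

Smoothing across trials uses a Gaussian-weighted moving average; the
"smoothing factor" f ∈ [0, 1] maps to a trailing window of
max(3, ⌈f·n_trials/2⌉) trials with σ = window/5. This mapping is a
qualitative stand-in for an unpublished convention and is exposed in
configuration. The four z-scored series per unit are concatenated in the
order E-pre, E-response, A-pre, A-response and Ward-clustered at cutoff
0.20.

The tonic test fits OLS of the cluster's mean per-trial count on trial
number and flags a change iff the t-based CI (default 95%; no level is
named in the source) excludes zero. The regression uses **raw, unsmoothed**
counts by default: smoothing induces serial correlation that inflates the
flag rate (the suite records this inflation without asserting a value),
and the raw fit keeps the t-based CI exact — null flag rate 3–7% and
slope-CI coverage 95 ± 2% over 1000 simulations. Fitting the smoothed
series is a configuration option. Four fits are reported per cluster (two
windows × two conditions); whether the source fit one concatenated series
or four is unstated, and per-window fits are strictly more informative.

## Numerical conventions

* All bins and windows are half-open `[lo, hi)`; times are seconds from
  session start.
* The causal Gaussian kernel over the current and k previous bins uses
  σ = k/5 with weights normalized to 1; at the start of a series the
  kernel is truncated and renormalized so constants are preserved.
* Rank-sum tests use the exact null distribution for group sizes ≤ 25
  (leave-one-out samples are small), the normal approximation otherwise;
  signed-rank tests return p = 1 when all paired differences are zero.
* Degenerate inputs fail loudly: empty traces, missing conditions,
  too-few trials/pulses/subjects, and cutoffs outside (0, 1] raise
  descriptive errors rather than propagating NaNs.

## Problem sizes

Defaults were chosen so the full simulated study (3 subjects, 120 units,
110 trials/session) runs end-to-end in well under a minute on one core,
and calibration loops (1000-seed null/coverage checks) complete in
seconds. Larger studies only change `SimConfig` counts.

## Known limitations

* The Poisson spiking model understates count dispersion for bursty units;
  calibration statements are exact only under the model.
* The tonic z-range ceiling under the default normalization (above) means
  strongly drifting units can cluster with weakly drifting ones; the
  habituation reference avoids this at the cost of sensitivity to early
  session nonstationarity.
* Cluster counts and per-cluster p-values are properties of a dataset,
  not of the method; the suite asserts recovery of known synthetic
  structure, never specific counts.
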