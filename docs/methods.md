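# Methods

`nocturn` implements the analysis chain of a standard mouse sleep
phenotyping experiment — 24-h EEG/EMG baseline recording, 6-h sleep
deprivation from lights-on, 18-h recovery — together with a synthetic
study generator so the whole chain can be exercised and validated
without animal recordings.

## Recording model and conventions

Recordings are sampled at 64 Hz (two EEG derivations plus one EMG
channel) and scored in 4-s epochs (256 samples), so the spectral grid
is exactly 0.25 Hz.  Zeitgeber time (ZT) is measured from lights-on;
the schedule is 12 h light : 12 h dark with lights on at 7:00.  Epoch
`i` covers the half-open interval `[4i, 4(i+1))` s, and an epoch is in
the light phase iff its ZT modulo 24 h is below 12 h.  Each epoch
carries a best-guess vigilance state (WAKE / NREM / REM) and a separate
artifact flag: artifact epochs are excluded from all spectral averages,
but by default contribute their best-guess state to architecture
metrics (a switch excludes them there too, in which case they break
bout runs and contribute no transitions).

## Synthetic data generator

**State dynamics.**  Vigilance states follow a first-order Markov chain
at epoch resolution with two row-stochastic 3×3 transition matrices,
one per lighting phase.  This is the simplest generative mechanism that
yields geometric bout-duration distributions and a light/dark rhythm in
occupancy, which is what the downstream metrics assume.  Wake→REM
transitions are set to zero in all shipped presets (REM is entered from
NREM), although the data model counts all six ordered transitions.
Recordings start at ZT0 in WAKE.

**Sleep-deprivation protocol.**  The `sd_recovery` protocol simulates a
continuous 48-h session; epochs in [ZT0, ZT6) of day 2 (exactly 5,400
epochs) are forced to WAKE, emulating gentle handling, and the chain
evolves freely elsewhere.  A study splits the session into a 24-h
baseline day and a 24-h recovery day, which keeps the homeostatic
process continuous across the two days.

**Homeostatic process.**  A dimensionless scalar `S` relaxes
exponentially toward a ceiling during WAKE and REM (time constant
`tau_rise_h`) and toward a floor during NREM (`tau_decay_h`), and
multiplies the amplitude of the NREM delta spectral component.  `S` is
a minimal two-process-style stand-in: no quantitative homeostatic model
is fixed by the underlying experimental literature for these lines, so
the time constants are free parameters.  Defaults: floor 0.7, ceiling
1.8, `S(0)` = 1, rise 10 h / decay 3 h for the normal-anxiety line.
`S` provably stays inside `[floor, ceiling]`.

**Signals.**  Each epoch's EEG is synthesized in the frequency domain:
an amplitude spectrum composed of a `1/sqrt(f)` background plus
Gaussian components (per state), multiplied by complex Gaussian noise
and inverse-transformed.  A bin-centered component of amplitude `A`
therefore contributes `A²/2` expected power to its bin, which makes
spectral assertions exact.  Default signatures: NREM — strong delta
component (2 Hz, scaled by `S`) plus a sigma/spindle component (12 Hz);
REM — sharp theta peak (7 Hz for the normal line) over a weak
background; wake — mixed low-amplitude theta/delta.  EMG is white noise
with per-state RMS (wake 3.0 > NREM 1.0 > REM 0.45, arbitrary units).
Artifact epochs (default rate 0.005/epoch) receive an additional
broadband high-amplitude component (60 µV/bin), mimicking movement
artifacts.

**Line archetypes.**  Three presets encode the *directions* of the
published phenotypes of mouse lines bred for high (HAB), normal (NAB)
and low (LAB) anxiety-related behavior; the magnitudes are this
package's own choices, not fitted values:

* **NAB** — consolidated sleep; light phase ≈ 50–55 % NREM, dark phase
  ≈ 78 % wake; transition rates calibrated analytically from the
  stationary distribution of the chain.
* **LAB** — low wake-exit probability at light onset (0.007/epoch vs
  0.022 for NAB), producing long wake bouts, elevated light-phase
  wakefulness and a several-fold longer latency to consolidated NREM
  sleep; slow homeostatic rise (16 h), so the delta rebound after
  deprivation is blunted; extra beta-band NREM component; REM theta
  peak 0.8 Hz slower than NAB.
* **HAB** — elevated exit rates everywhere (fragmentation), frequent
  NREM→REM entries, reduced dark-phase wakefulness, stronger NREM
  delta component (22 vs 18 µV) and fast homeostatic rise (6 h), hence
  the largest post-deprivation delta rebound; REM theta peak 0.9 Hz
  slower than NAB.

The LAB latency separation trades occupancy realism for robustness:
LAB's light-phase wake fraction (~60 %) overshoots the published
difference so that the ordering of group-median latencies is stable at
cohort sizes of 10.

**What the generator does not emulate.**  No ultradian or intra-phase
circadian structure beyond the two rate sets; no transition "ramp" at
phase boundaries (latencies are therefore minutes, not the tens of
minutes seen in vivo); EEG epochs are independent realizations
(no phase continuity across epochs); artifacts are broadband bursts
only.  Tests passing on this generator demonstrate that the analysis
code implements its definitions correctly and recovers known structure;
they do not certify classifier performance on real recordings.

## Spectral analysis

Per-epoch power spectra are magnitude-squared FFTs, one-sided, DC
dropped.  The default taper is a Hann window renormalized to unit mean
square so that broadband power is conserved; with this convention the
sum of bin powers equals the windowed mean-square signal exactly for
bin-centered tones at or above 0.5 Hz (the rectangular taper is
available and exact for all bin-centered tones).  Band definitions:
delta 0.5–5 Hz, theta 6–9 Hz, sigma 10–15 Hz, beta 16–23 Hz (inclusive
bin centers; the 5–6 Hz gap is deliberate).  A 0.5–4 Hz delta variant
is provided as a named preset for time-course figures that use the
narrower band.  "Total power across 0.25–32 Hz" is evaluated up to the
last full bin below Nyquist (31.75 Hz at 64 Hz sampling), since the
one-sided Nyquist bin is not a full-width bin.

Artifact rejection flags epochs whose total 0.5–29 Hz power exceeds
`k = 8` times a centered rolling median (±450 epochs), plus any epochs
flagged upstream.

Two normalizations:

* **NREM delta time course** — per time bin, mean delta power of the
  bin's unmasked NREM epochs divided by a per-animal scalar (mean total
  0.5–29 Hz power over all unmasked NREM epochs of the 24-h *baseline*
  day) × 100.  The same baseline scalar normalizes the recovery day,
  so deprivation-induced changes are visible.  Bins with no NREM
  epochs are missing (NaN), never zero.
* **State spectral profiles and band tables** — state-mean bin (or
  band) power divided by the grand mean total power of all unmasked
  epochs over 24 h, × 100.  The profile of a single-state recording
  sums to exactly 100 %; in general the sum equals
  100 × (state mean total)/(grand mean total).  The grand-mean
  denominator pools all states; a per-state denominator would make
  every profile sum to 100 % and erase between-state power differences.

All normalized quantities are invariant to global EEG amplitude
scaling.  REM theta peak frequency is the argmax bin of the profile in
[6, 9] Hz, ties resolving to the lower frequency.

## Scoring

An explicit, reproducible decision rule rather than a re-implementation
of any particular laboratory's semi-automatic program — the validation
target is recovery of known synthetic labels:

1. WAKE if EMG RMS ≥ wake cut (muscle tone outranks the EEG);
2. else REM if EMG RMS ≤ atonia cut **and** theta:total ≥ its cut;
3. else NREM if delta:theta ≥ its cut;
4. else the nearest class by cut-relative log-distance, normalized by
   each feature's log spread.  Epochs with undefined ratios (zero EEG
   power) are scored by EMG alone.

Quantile calibration uses the recording's own distributions: EMG cuts
at the 60th/20th percentiles of log EMG RMS (these land between the
wake cluster and the sleep clusters for typical occupancies), ratio
cuts at the deepest KDE antimode between the two tallest modes, with
fixed-quantile fallbacks (50th for delta:theta, 80th for theta:total)
when the distribution is effectively unimodal.  Because every cut is a
quantile or antimode of the recording's own features, jointly rescaling
EEG and EMG leaves the labels unchanged.  Supervised calibration
greedily refines each cut over a quantile grid (two coordinate passes)
to maximize accuracy against a partial reference hypnogram.

Smoothing is a single left-to-right pass relabeling isolated one-epoch
states flanked by an identical pair — an automated stand-in for visual
confirm-and-correct; `apply_corrections` applies pointwise manual
overrides and retains an audit log.

## Architecture metrics

Bouts are maximal runs of identical state; runs spanning the light/dark
boundary contribute a clipped bout to each side.  Transitions are
counted over adjacent epoch pairs with differing states; a pair
straddling the boundary is credited to the interval containing the
second epoch.  Under these conventions the bookkeeping identity is:
outgoing transitions of state X within an interval = bouts of X in the
interval − [the interval's last bout is X] + [the pair entering the
interval exits X].  Per interval, bout lengths sum to the interval
length and state percentages (plus the artifact-excluded fraction) sum
to 100.

**Sleep latency** is the time from a reference (lights-on, or the end
of deprivation at ZT6) to the start of the first consolidated episode:
a window starting and ending with the target state, spanning ≥ 15
epochs, containing ≤ 6 non-target epochs.  "Lasting at least 15
epochs" is read as the episode's span including allowed interruptions,
with the 6-epoch allowance as a per-episode total; the alternative
net-duration reading (≥ 15 target epochs) is available via
`rule="net"`.  No qualifying episode → missing.  Latency is antitone in
the allowance and isotone in the minimum span (property-tested).

Units follow field convention: durations in min/bout, counts per 12-h
interval, amounts in percent time; the light-minus-dark percent
difference per state is the circadian-amplitude index.

## Deprivation rebound and statistics

Recovery-minus-baseline differences are computed per matched ZT bin
(2-h or 6-h) for NREM %, REM % and normalized NREM delta power.  Bins
inside the deprivation window are retained, flagged, for
wake-enforcement QC but excluded from sleep-rebound summaries.
Missing bins propagate as missing; nothing is imputed.  The operation
is antisymmetric under swapping the two days.

Group statistics are the conventional surface — one-way and two-way
fixed-effects ANOVA (interval treated as a fixed between factor, since
a repeated-measures treatment is not clearly warranted and the
fixed-effects reading is the conservative default here),
Bonferroni-adjusted pairwise t-tests, Tukey HSD for circadian-amplitude
contrasts, two-tailed paired t-tests within line, α = 0.05, SEM error
bars — delegated to scipy/statsmodels; the package's contribution is
upstream of them.  Groups with zero variance are reported as
non-testable rather than returning NaN.

## Validation scale and numerical choices

The test suite validates bouts/transitions/latency against independent
brute-force oracles (itertools run-length encoding, pair counters,
exhaustive window scans) on 10⁴ random 21,600-epoch hypnograms with
per-realization persistence 0.88–0.98 (realistic bout structure);
classifier recovery on nine 24-h recordings (3 per line; accuracy
≥ 90 %, Cohen's κ ≥ 0.8, REM recall ≥ 80 %); generator calibration by
conditional transition frequencies at ≥ 10⁵ epochs per phase (total
variation < 0.02) and mean bout length within 5 % of the geometric
closed form 1/p; rebound direction on 10 simulated animals; the
three-line phenotype ordering at n = 10/line; and the ANOVA surface
against a closed-form oracle plus a 1,000-replicate null simulation of
the type-I error (3 × 4 animals of 6-h hypnograms per replicate).
Problem sizes were chosen so the full suite completes in a few minutes
on one CPU.

Known limitations: the latency scale (minutes) is compressed relative
to real mice because sleep onset inherits the Markov wake-exit rate;
EDF export quantizes to 16 bits over a per-channel symmetric range;
the KDE antimode calibration assumes at least a few hundred epochs per
state and falls back to fixed quantiles otherwise.
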