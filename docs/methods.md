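# Methods

`codefrp` implements a complete fixation-related-potential (FRP) analysis
of a two-condition code-reading experiment — confusing code (containing a
small misleading pattern, an "atom of confusion") versus clean,
semantically equivalent code — together with a synthetic-data generator
that emulates the recording setup end to end. This note documents the
models, the defaults and their units, the numerical choices, and what the
synthetic validation does and does not establish.

## Study model

The emulated design: 24 participants read 72 Java-like snippets each
(three blocks of 24 trials), one member of each of 72 snippet pairs, 36
per condition. Each trial shows a fixation cross (5 s default) and then
the snippet (3–30 s; real viewing times are self-paced and only their
range is constrained here, so the uniform draw is a convention). Gaze is
sampled at 1200 Hz, EEG at 500 Hz from 28 scalp electrodes (10–20
placement, including A2), four EOG electrodes, and two mastoids, with the
left mastoid as the online reference (its recorded trace is identically
zero). Presentation orders are pseudo-randomized so that no more than
three same-condition trials occur in a row and trials sharing an atom are
separated by at least two other trials; condition assignment is
counterbalanced so each pair's two versions are seen by equally many
participants.

Orders are produced by seeded *greedy sequential construction with
restarts*: each slot is filled uniformly at random from the trials still
admissible under both constraints and the per-block condition quota, and
a dead end restarts the order. Whole-sequence rejection sampling is not
viable here: with 72 trials and eight same-atom trials per atom, a
uniform shuffle satisfies the atom-separation constraint with probability
on the order of 1e-5.

## Synthetic data generator

**Stimulus layouts.** Each snippet is a stack of vertically ordered line
bounding boxes; a configurable subset of lines is *uninformative*
(brace-only lines that carry no execution-relevant content). One area of
interest (AOI) — the central third of a randomly chosen informative line —
marks the atom's location; both members of a snippet pair share the same
geometry.

**Gaze.** A planned scanpath (line index, dwell) is rendered at the
eye-tracker rate. Fixation targets sit at line-box centres; reading
behaviour is approximated as a top-to-bottom pass over the informative
lines with occasional regressions and rare stray glances at brace lines
(readers have no reason to fixate them — the premise of the
informative-only correction variants). Degradations, all configurable:

| parameter | default | meaning |
|---|---|---|
| jitter_sd_px | 5 px | white Gaussian within-fixation scatter |
| y_drift_lines | 0.5 | linear vertical drift over the trial, in line heights |
| x_offset_px | 0 | constant horizontal calibration offset |
| missing_fraction | 0.05 | share of invalid (tracking-loss) samples |
| missing_gap_ms | 300 ms | maximum length of an inserted loss gap |

Ground truth records every planned fixation (onset, duration, empirical
centroid, line, in-AOI flag). Real gaze noise is temporally correlated
and saccades have finite velocity profiles; the generator uses white
jitter and instantaneous position jumps, which makes change-point
detection slightly easier than on real data.

**EEG.** Per recorded channel, 1/f-shaped Gaussian background noise
(spectrum flattened below 0.1 Hz; SD 10 µV by default) plus an optional
10 Hz oscillation; the left mastoid is the online reference, so its own
trace is zero and the noise SD describes the recording as observed. Every fixation event adds an
occipitally weighted early deflection (lambda-like Gaussian bump, peak
110 ms, SD 35 ms, 5 µV) for realistic early FRP morphology. Events of the
effect condition additionally receive a boxcar positivity — default 2 µV
at the maximally weighted channel, 390–660 ms after fixation onset, with
a frontal Gaussian topography peaking at Fz. The boxcar is locked exactly
to fixation onset (no latency jitter) so that recovery targets are sharp;
jitter is available as a stress knob. Channels are spatially independent,
unlike real EEG; this makes electrode-level clustering conservative with
respect to spatial smearing. A small fraction of trials (1.5%) receives a
large (120 µV) slow artifact on one random channel, and 2% of trials get
severely degraded gaze, so the exclusion machinery is exercised in every
full run.

## Gaze processing

1. **Trial quality.** Trials with more than 25% invalid samples, or any
   invalid interval longer than 1 s, are excluded.
2. **Fixation detection.** A two-means / change-point scheme in the I2MC
   family: invalid gaps up to 100 ms are filled by monotone cubic (PCHIP)
   interpolation; 200 ms windows slide in 20 ms steps over usable runs;
   each window is split at the change point minimising the two-segment
   sum of squares — the two-means objective restricted to time-contiguous
   clusters, which is exactly solvable and fully vectorisable. A window
   votes for its change point only if the split explains at least 25% of
   the window's variance, so structureless windows abstain. Votes,
   normalised by window coverage, form per-sample saccade evidence;
   samples above mean + 2 SD are transition samples. Runs between
   transitions become fixations, merged when closer than 30 ms and 0.7°
   (at a configurable 40 px/°), and kept at ≥ 200 ms duration. The
   detection parameters follow published I2MC defaults; only the 200 ms
   minimum duration is a fixed protocol parameter.
3. **Outliers.** Fixations farther than 2 line heights (vertical
   distance) from every line box are removed — a quantified stand-in for
   the original manual "clear outlier" review.
4. **Constant offset.** Per block, the median displacement between
   fixations and their (nearest-line) anchors is subtracted. Anchors are
   line-box centres; recovering a horizontal offset this way relies on
   the generator placing fixation targets at line centres, and would be
   biased on real data where within-line landing positions spread — a
   deliberate simplification matched to the synthetic setting.
5. **Line correction.** Two drift-correction algorithms suited to
   non-linear reading: *cluster* (optimal 1-D k-means over fixation
   y-values — dynamic programming over contiguous sorted segments, so no
   initialisation sensitivity — with as many groups as candidate lines,
   each group mapped to its nearest line centre) and *stretch* (grid
   search over a vertical scale in [0.9, 1.1] and offset in ±2 line
   heights minimising summed distance to line centres, then
   nearest-line assignment; coarse-to-fine, ties keep the coarse
   optimum). Each has an *informative-only* variant that drops brace-only
   lines from the candidate set. Correction changes only line assignments
   and centroid y; onsets, offsets, durations, and x are untouched.
6. **Method selection.** The original dual-rater review is replaced by a
   deterministic rule: the variant maximising the fraction of fixations
   on informative lines wins, ties broken cluster_informative >
   stretch_informative > cluster > stretch. Because the informative
   variants attain the maximal score by construction, the rule
   effectively prefers cluster_informative; the non-informative variants
   remain available for configurations without brace-only lines.
7. **Event selection.** The first fixation whose centroid lies inside the
   AOI (boundary inclusive) becomes the FRP time-lock; trials without one
   are excluded.

## EEG processing

Filtering is a zero-phase order-4 Butterworth band-pass, 0.05–30 Hz, plus
a 50 Hz notch (Q = 30). A 0.05 Hz corner cannot be realised by a
low-order FIR filter, so the band-pass is implemented as a zero-phase
(forward–backward) order-4 IIR — the functional standard across ERP
practice. Channels are demeaned
before filtering and the forward–backward pass uses reflective padding of
0.5/low_hz seconds (≈ 10 s at the default corner), because the 0.05 Hz
high-pass has a multi-second impulse response whose edge transients
otherwise bleed far into the recording.

Scalp and mastoid channels are re-referenced to the mastoid mean
(reconstructing the implicit all-zero left-mastoid trace first); EOG
channels are untouched. Epochs span −300 to 1000 ms around fixation
onset (651 samples at 500 Hz, both ends inclusive); gaze time is mapped
to the nearest EEG sample via the shared trial-start markers. Events less
than 300 ms after snippet onset lack a baseline; events whose 1000 ms
tail crosses snippet offset overrun the trial — both are excluded with
their reason recorded. Baseline correction subtracts the per-channel mean
over [−300, 0) ms.

Artifact screening evaluates three criteria on the baseline-corrected
epoch (the canonical signal), ignoring EOG and reference electrodes:
reject when any consecutive-sample step reaches 30 µV, when the
peak-to-peak range within any sliding 0.2 s window exceeds 100 µV, or
when the absolute amplitude exceeds 70 µV anywhere. The quoted
inequalities are applied literally (step ≥ 30 rejects; range and absolute
reject strictly above their bounds). Sliding (not tiled) windows are
used; the range maximum over all full windows is computed with
O(n) running max/min filters.

Accepted epochs are averaged per participant × condition × electrode;
the grand average is the unweighted mean of participant averages;
difference waves are confusing − clean per participant. Averages are
downsampled to 100 Hz by non-overlapping 5-sample bin means (time stamps
at bin centres, trailing partial bin dropped) — bin averaging rather than
decimation, for noise reduction. A stimulus-onset ERP control is
available by passing snippet-onset events through the same machinery.

## Cluster-based permutation test

Per (electrode, time) point of the difference waves — restricted to
100–1000 ms and to the 24 analysis electrodes (T7, T8, O1, O2 excluded) —
a paired t statistic is computed (df = n − 1; defined as 0 when mean and
variance are both zero, sign-consistent infinity when only the variance
is). Points exceeding the one-sided critical t at p < .05 are clustered
under spatial adjacency (neighbouring electrodes, same time point) OR
temporal adjacency (consecutive time points, same electrode); clusters
need at least two members; the cluster statistic is the mass (sum of
member t values, the field-standard default for this test family).

Electrode adjacency ships as a fixed JSON neighbour list derived once
from a Delaunay triangulation of schematic 2-D 10–20 coordinates
(azimuthal-equidistant projection of the standard montage sphere), with
edges longer than 1.5× the median pruned; Fp1–Fp2 is an edge, and the
list is editable. A2's only neighbour is T8, so after the default
exclusion A2 participates through temporal adjacency alone.

The null distribution of the maximum (greater direction) or minimum
(less) cluster mass is built by flipping each participant's
difference-wave sign: exhaustively over all 2^n assignments when
2^n ≤ 2^20, otherwise by seeded Monte Carlo (10,000 draws by default,
identity assignment always included, so p ≥ 1/N; an opt-in cap raise
reproduces the full 2^24 = 16,777,216 enumeration of the 24-participant
design). Permutations without clusters contribute 0. A cluster's p is
the proportion of null extrema at least as extreme as its mass; two
one-sided tests (confusing > clean and confusing < clean) are run at
α = .05 with no correction across the two directions. The permutation
engine computes all flipped t-maps by matrix algebra (sign flips leave
second moments invariant) and labels suprathreshold components with
sparse connected-components; an independent cross-check against MNE's
spatio-temporal cluster test reproduces the cluster masses exactly.

## Design utilities

Chance-level correctness is the option-count-weighted mean of 1/2 and
1/3 (38% for 21 two-option and 51 three-option snippets). The paired
effect size from a 1-df repeated-measures F is dz = √(F/n) (0.701 for
F(1,23) = 11.8). A priori power uses the noncentral t distribution
(ncp = dz·√n, df = n − 1), returning the smallest n reaching the target
(18 at dz = 0.701, α = .05, power = .8, two-sided) — the noncentral-t
convention matches standard a priori power tools.

## Problem sizes in the shipped validation

The validation suite scales the simulations to desk size. Parameter
recovery runs 20 studies with the study's own layout — 24 participants,
three blocks of 24 trials, 72 pairs — but with viewing times shortened
to 2.5–4.5 s and a 0.5 s cross, which after exclusions leaves roughly
25–30 usable epochs per participant × condition cell — the epoch budget
a real session of this design yields (the permutation tests in these
runs use 5,000 Monte-Carlo draws). The injected 2 µV frontal positivity must be
recovered as a significant confusing > clean cluster overlapping at
least half of the 390–660 ms window in ≥ 90% of studies, and each
study's grand-average Fz difference inside the window must bracket the
injected amplitude within three times its standard error across
participants. Trial counts matter here: at half-length sessions
(18 nominal epochs per cell) the realized study-level effect fluctuates
by ±0.7 µV and detection power drops well below the target, so the
epoch budget is a design condition, not a free knob. Type-I calibration runs 200 zero-effect studies of 10
participants × 8 trials and requires the per-direction significant-study
rate to stay inside the 95% binomial interval around .05; ten
participants give exhaustive 1024-assignment nulls whose attained level
(51/1024 ≈ 4.98%) matches the nominal alpha, whereas coarser nulls are
measurably conservative (256 assignments attain 4.69%). Passing these establishes that the pipeline's
inference is calibrated and sensitive *under the generator's
assumptions*; it does not certify performance on real recordings, whose
noise is spatially and temporally structured in ways the generator
simplifies (see above).

## Known limitations

- No ICA or ocular-artifact regression: blinks/saccade potentials are
  not modelled, and real co-registered data would require them.
- The constant-offset estimator assumes symmetric within-line landing
  positions (exact in the generator, approximate in reality).
- The automated correction-method selection cannot reproduce
  case-by-case human judgement; it is a fixed, reproducible rule.
- Exhaustive permutation is capped at 2^20 by default; the full 2^24
  enumeration is available but takes correspondingly longer.
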