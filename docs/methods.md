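# Methods

## The coding model

Behavior of each partner in a dyadic object-oriented interaction is coded at
the video frame rate (default 30 fps, one code per 1/30 s ≈ 33 ms) on three
binary dimensions: socioemotional (SE, positive/neutral vs. negative affect),
sensorimotor (SM, voluntary object contact vs. none/passive) and cognitive
(C, attention on object/partner vs. elsewhere). A main code of 1 marks
play-congruent activity on that dimension. Sub-codes refine main codes
(SE: 2 levels for either main code; SM main 1: 3 levels, main 0: none;
C main 1: 5 levels, main 0: none); they are validated and tallied but never
enter state derivation, which uses main codes only.

The per-frame triple defines one of 8 social states in a fixed canonical
numbering (1 = `[1 1 1]`, the play-congruent state, through 8 = `[0 0 0]`).
States are deterministic functions of the codes — no smoothing or latent-state
inference — so every downstream quantity is an exact function of the coded
timeline. Two identities follow and are enforced by tests: each dimension's
mean score equals the summed frequency of the states with that dimension at 1,
and the joint distribution's marginals equal the partners' individual state
frequencies.

## Time base and rasterization

Frames are 0-based and half-open: frame *i* covers `[i/fps, (i+1)/fps)`, and a
time landing exactly on a boundary belongs to the later frame. Coder intervals
are half-open in the same way, making rasterization unambiguous: frame *i*
takes the code of the interval containing its onset `i/fps`; the frame count
is `round(duration_s × fps)`. Within a dimension, overlapping intervals are
hard errors. Coverage gaps are hard errors by default — the coding style this
supports codes every timepoint, and silently filling gaps would hide coder
error — but a per-dimension fill code can be configured for sparse styles.
Floating-point jitter at interval boundaries is absorbed by a 1 ns tolerance.

Partner timelines are assumed to share a session clock (two synchronized
cameras); alignment therefore only truncates the longer recording to the
shorter frame count and never resamples. A frame-rate mismatch is an error.

## Segments and event export

State segments are maximal same-state runs with half-open frame bounds; with
`min_duration_frames = 1` segmentation is the exact run-length encoding (the
default — no minimum-duration rule is applied before frequencies or any other
statistic). With a larger minimum, sub-threshold runs are absorbed shortest
first (ties: earliest) into the longer adjacent run (ties: the preceding run)
and equal neighbors re-merged, until all runs meet the minimum or one remains.

Event export writes one row per segment in a BIDS-events-like TSV (`onset`,
`duration`, `trial_type`). At 30 fps frame onsets are not whole milliseconds,
so rendered times (3 decimals) are lossy; every row therefore also carries
`frame_start`/`frame_end`, and re-import reconstructs segments from the frame
columns exactly. The BIDS-like layout is a portability choice, not a
requirement of any particular neural-analysis toolchain.

## Condition comparison

For each participant group (infants; adults), each social state's session
frequency — a proportion, so sessions of unequal length are comparable — is
compared between two conditions with a two-sided paired *t*-test over dyads
(`scipy.stats.ttest_rel`); a state absent from all sessions yields t = 0,
p = 1 rather than 0/0. The 8 raw p-values within one group form the
Benjamini–Hochberg FDR family; the step-up adjustment is implemented from its
definition (adjusted p at rank k is `min_{j≥k} min(1, m·p_(j)/j)`) and
cross-checked in tests against statsmodels and an exhaustive
threshold-enumeration oracle. The effect size is the paired-design Cohen's d,
d_z = t/√n — the unique convention consistent with all five published (t, d)
pairs of the 5-dyad worked example this implementation is validated against.
Default FDR level: α = 0.05.

## Reliability

Inter-rater agreement is frame-wise on main codes over the frames both coders
covered, reported as percent agreement per dimension (the published
reliability surface); whether the original figures were frame- or
interval-wise is not documented, and frame-wise is this package's documented
default. Cohen's kappa from the 2×2 main-code confusion table is provided as
a chance-corrected supplement and flagged undefined when either coder is
constant (chance agreement 1). Sub-code agreement is available behind a flag.

## The dyad simulator

The simulator emulates two coupled 8-state behavioral streams, not the
physics of real interaction. The adult is a first-order Markov chain; at each
frame the infant copies the adult's current state with probability κ and
otherwise steps by its own chain. Per-frame copy-with-probability-κ is the
simplest mechanism giving a tunable, monotone synchrony dial (expected
same-state probability is non-decreasing in κ; κ = 1 duplicates the adult
stream, κ = 0 decouples the partners). Decoded main codes come from the state
bijection; sub-codes are drawn uniformly from each (dimension, main code)'s
legal set, as no empirical sub-code distribution is available to emulate. One
`numpy` generator seeded by the single `seed` parameter governs every draw,
so identical parameters give byte-identical timelines.

Preset transition matrices are built as `stay·I + (1−stay)·π`, which has
stationary distribution exactly π while `stay` sets dwell time; with
`stay = 0.97` at 30 fps mean dwell is ≈ 1.1 s, a plausible time scale for
behavioral bouts in object play. The two presets encode the contrasting
regimes of a didactic versus a play-conducive session:

| preset | infant π peak | adult π peak | κ |
|---|---|---|---|
| `teaching-like` | state 2 `[1 0 1]` (0.40) | state 1 (0.34) | 0.003 |
| `play-like` | state 1 `[1 1 1]` (0.48) | state 1 (0.50) | 0.012 |

κ values look small because coupling acts per frame at 30 fps: with dwell
parameter `stay`, the stationary share of infant time governed by the adult is
κ/(κ + (1−κ)(1−stay)) ≈ 0.09 (teaching-like) and ≈ 0.29 (play-like). The
profiles were fixed once so that 10-minute sessions robustly show the target
modal states (infant 2 vs. 1, adult 1 in both) and clearly separated
synchronous-play levels (≈ 8–9% vs. ≈ 27–29% of frames in 5-dyad runs); the
adult profile's margin between states 1 and 2 (0.34 vs. 0.22) is wide enough
that sampling noise at ≈ 550 effective bouts per session cannot flip the mode.

What the simulator does **not** reproduce: semi-Markov (heavy-tailed) dwell
times, turn-taking and lagged contingencies, condition-specific sub-code
structure, coder disagreement, or drift between cameras. Tests passing on
simulated corpora therefore validate the analysis pipeline's arithmetic and
its statistical machinery under known ground truth — they are not evidence
about real infant behavior.

## Numerical choices and degenerate inputs

* Modal-state ties are broken toward the lowest state index and explicitly
  flagged, never silently resolved.
* Frequency vectors must sum to 1 within 1e-12; transition-matrix rows within
  1e-9. Transition estimation flags never-visited source states and leaves
  their rows NaN rather than inventing a distribution.
* Empty timelines/sequences are errors everywhere rather than returning empty
  statistics.
* Statistics are computed on proportions; percentages appear only in rendered
  output (t and d are scale-invariant to this choice).
* Problem sizes used by the test suite and the acceptance script — 10-minute
  sessions for regime checks, 100k frames for transition recovery, 40 s × 30
  seeds per grid point for the coupling-monotonicity check, 1000 randomized
  timelines for the identity suite — were chosen to make sampling error small
  relative to the margins being tested.

## Known limitations

Two participants per session only; no clock-drift correction; no automated
behavior recognition (inputs are human annotations); no lagged
synchrony/cross-correlation analysis; no repeated-measures ANOVA (the paired
per-state comparison is the supported inference); no reading or writing of
neural data formats — only the event tables such tools consume.
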