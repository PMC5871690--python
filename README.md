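# dyadplay

Frame-level analysis of dyadic adult–infant play from dimensional behavioral
coding.

Developmental researchers studying play — in particular groups combining
behavioral coding with concurrent neural recording (EEG hyperscanning) — need
behavior quantified at a temporal resolution compatible with neural data.
`dyadplay` implements a dimensional coding framework for object-oriented
adult–infant interaction: at every video frame (30 fps, i.e. one code per
~33 ms) each partner is coded on three binary dimensions,

* **SE** (socioemotional): 1 = positive/neutral affect, 0 = negative affect,
* **SM** (sensorimotor): 1 = voluntary contact with the object, 0 = none/passive,
* **C** (cognitive): 1 = attention on object or partner, 0 = elsewhere,

optionally refined by integer sub-codes (e.g. C sub-code 3 = object-specific
exploration). The per-frame triple `[SE SM C]` defines one of 2³ = 8 **social
states**, numbered so that state 1 = `[1 1 1]` is the *play-congruent* state;
a dyad's concurrent pair (infant state, adult state) is one of 64 **joint
states**, and the proportion of frames in joint state (1, 1) is **synchronous
play**.

From coder-marked interval annotations the package computes, per session:

* gap-free rasterized code timelines and per-frame state sequences;
* dimensional mean scores (e.g. mean SM = 0.7 ⇒ the infant had active
  possession of the toy 70% of the time);
* state frequency distributions and modal states (ties flagged);
* the 8×8 joint distribution, synchrony measures, and per-dimension
  concordance;
* maximal state segments exported as BIDS-events-style TSV
  (onset, duration, trial_type, plus exact frame indices) for time-locking
  neural data;
* inter-rater reliability (frame-wise percent agreement and Cohen's kappa).

Across sessions it compares state frequencies between two experimental
conditions with per-state paired *t*-tests, Benjamini–Hochberg FDR correction
over the 8 states within a participant group, and the paired-design effect
size *d_z* = *t*/√*n* — exposed statsmodels-style as a
`StateFrequencyComparison` model whose `fit()` returns a `ComparisonResult`
with a `summary()` table.

Because real coded-video corpora are rarely shareable, the package includes a
coupled-Markov **dyad simulator**: the adult evolves as an 8-state Markov
chain; at each frame the infant copies the adult's current state with
probability κ (the synchrony dial) and otherwise steps by its own chain.
Presets `teaching-like` and `play-like` reproduce the two canonical regimes
(infant modal state `[1 0 1]` with low synchrony vs. `[1 1 1]` with elevated
synchrony; adult modal state `[1 1 1]` in both).

## Worked example

```python
import dyadplay as dp

params = dp.make_condition_presets("play-like", duration_s=300, seed=11)
dyad = dp.simulate_dyad(params)                    # a 300 s session at 30 fps

summary = dp.session_summary(dyad.infant)
print(summary["modal_state"], summary["dimensional_means"])
# 1 {'SE': 0.865, 'SM': 0.585, 'C': 0.685}

sync = dp.synchrony(dp.joint_states(dyad))
print(round(sync.p_joint_play, 3), round(sync.p_same_state, 3))
# 0.267 0.408
```

The infant's modal state is 1 (`[1 1 1]`: play-congruent), it shows
positive/neutral affect 86.5% of the session and holds the object 58.5% of
it, and the dyad is in synchronous play on 26.7% of frames (same state on
40.8%). Comparing five simulated dyads recorded under both regimes:

```python
res = dp.compare_conditions(freqs_by_dyad, group="infant",
                            conditions=("teaching-like", "play-like"))
print(res.summary())
```

```
Paired comparison of social-state frequencies — infant
play-like minus teaching-like, n = 5 dyads, df = 4, BH-FDR alpha = 0.05, d_z = t/sqrt(n)
 state codes  mean_diff        t  df   p_raw   p_fdr       d  significant
     1 1 1 1     0.2943  20.7879   4  0.0000  0.0001  9.2966         True
     2 1 0 1    -0.1980 -20.0666   4  0.0000  0.0001 -8.9741         True
     ...
```

The play-congruent state is ~29 percentage points more frequent in the
play-like regime (FDR-corrected p ≈ 1e-4), while the attentive hands-off
state 2 drops correspondingly — the signature separating playful from
didactic interaction.

The same workflow is available from the shell: `dyadplay simulate`,
`validate`, `rasterize`, `states`, `summary`, `joint`, `compare`,
`agreement`, `events`, and `dyadplay run config.yaml` for a whole corpus
(see `dyadplay --help`).

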