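# Methods

This note documents the models, defaults and numerical choices behind
`triadsim`: what the simulator holds fixed by design, what the agent
generator assumes, and what the statistics report does and does not show
about real data.

## Paradigm model

Time is continuous (seconds, millisecond precision) and event-driven; there
is no frame tick, because the paradigm is specified entirely in durations.
Trial indices are 1-based throughout, matching the "after every 10th/15th
trial" convention of the probe schedule.

A stress-induction trial consists of a pre-cue stimulation period (6.0 s),
a cue, and a response window (1.0 s).  The per-trial maximum stress
duration covers the *total* stimulation including the pre-cue period — so
an escapable trial's duration is `pre_cue + RT` when terminated, otherwise
the cap.  In the one-cue variant the cap is 15 s on all 40 trials; in the
three-cue variant it starts at 10 s and decreases by 0.5 s after every
15th of the 60 trials (10.0/9.5/9.0/8.5 s).  The two-group variant's
pre-cue duration and inter-trial interval are not separately specified by
the paradigm and inherit the one-cue values (6.0 s; 1 s ± 250 ms uniform
jitter); both are ordinary config fields and can be overridden.

Cue order is a seeded balanced permutation (each cue exactly
`n_trials/n_cues` times) with no run-length constraint, which is all the
design requires.  Timeline construction, and every other simulated
quantity, is a pure function of `(config, seed)`; per-participant,
per-purpose streams are derived by hashing `(root_seed, participant,
label)` with SHA-256, so any participant or component can be regenerated in
isolation.

### Yoking

One-to-one yoking copies the escapable partner's per-trial durations
bit-for-bit.  Pseudo-yoking takes the per-trial arithmetic mean over the
whole escapable pool (no trimming) and applies a seeded random permutation;
the output multiset therefore equals the mean-vector multiset exactly and
total exposure is conserved up to floating-point summation.  Yoked cue
onsets are drawn uniformly from 1–4 s before stressor offset.  Because
escapable durations always include the 6-s pre-cue period, durations are
≥ 6 s and the onset law never needs clipping in practice.

One modelling decision deserves emphasis: the decremented per-trial cap is
interpreted as bounding *response-contingent* stimulation.  A predetermined
(pseudo-)yoked duration may exceed the decremented cap of the trial it is
shuffled onto — the package warns but does not alter it, because altering
it would silently break the conservation property that is the entire point
of yoking.  Predetermined durations are bounded by the session's base
maximum by construction.

Control trials mirror escapable timing with zero stimulation; a response
inside the window is logged (it "shortens the session" from the
participant's perspective) but nothing is terminated, so control reaction
times remain comparable to the stress groups.

### Escape behaviour test

The grid is 15×15 with four safe cells hidden uniformly at random,
excluding the start cell (7,7) (0-based centre) so no trial starts solved.
Safe cells reveal themselves ("light up") when entered in either phase.
Moves are discrete orthogonal key presses emitted by the agent's policy at
its move interval; a press into the edge leaves the position unchanged but
counts as activity, because the read-outs count key presses, not
displacement.  In the one-block variant the position persists from
exploration into stress within a trial; the two-block variant resets the
position to the centre at every phase start and independently resamples all
four safe cells for block 2 (overlap with block 1 is possible by chance and
flagged in the record).  Agent memory of safe locations persists across
trials and, stale, across the relocation.

## Agents

The agent model is deliberately minimal: the simplest families able to
express the group-level phenotypes the paradigm measures.

* **Reaction times** — shifted lognormal (`shift + LogNormal(mu, sigma)`)
  with a miss probability.  The shift captures irreducible motor latency;
  the lognormal the right-skew of human RT.
* **Cue–button learning** — per-cue candidate-set elimination driven by the
  only feedback the task provides (the stressor stops or it does not), with
  a lapse probability.  A failed press removes the button from the cue's
  candidate set unless removal would empty it (guarding inconsistent
  feedback such as a correct press delivered too late).  A zero-lapse
  learner therefore commits at most two errors per cue.  Yoked participants
  do not update: their feedback is non-contingent noise that the
  elimination rule would be misled by.
* **Ratings / affect** — linear trend across probes plus Gaussian noise,
  rounded and clipped to 1–7; affect totals are Gaussian pre-scores with an
  additive Gaussian pre-to-post shift.
* **Navigation** — four families.  `random_walk` (uniform moves), `sweep`
  (a deterministic outward coverage scan: the cells are ordered in an
  expanding spiral from the start cell and the agent walks toward the next
  cell it has not yet covered), `memory_guided` (sweep, but under stress it
  takes a shortest Manhattan path — rows first, distance ties broken by
  smallest (row, col) — to the nearest remembered safe cell), and `frantic`
  (a momentum-biased walk, repeating its last move with probability
  `momentum`, that pursues the nearest remembered safe cell with
  probability `goal_bias`, but only for the first `stale_persistence` moves
  of each phase).

### The two presets

`ec_like` (controllable-stress phenotype): RT shift 0.20 s, median ≈
0.45 s, σ = 0.25, 5 % misses; elimination learner with 10 % lapses;
`memory_guided` navigation at one move per 0.30 s with full memory
retention.  On discovering that a remembered cell is no longer safe it
restarts its coverage scan from scratch (after at most `stale_persistence`
= 3 further pursuit moves), i.e. it re-searches the grid systematically
after the relocation.

`yc_like` (uncontrollable-stress phenotype): RT shift 0.25 s, median ≈
0.60 s, σ = 0.30, 12 % misses; random button presses (the contingency is
not learnable for this group anyway); `frantic` navigation at one move per
0.12 s (≈ 500 presses/min vs ≈ 200 for `ec_like`), momentum 0.5, full
pursuit (`goal_bias` 1.0) capped at 13 moves per phase, full memory
retention and **no unlearning on contact** (`unlearn_prob` 0): the agent
rigidly returns to remembered safe locations at the start of every phase
even after they have stopped being safe.  This perseveration is what makes
the unannounced relocation costly: every block-2 phase begins with up to 13
moves spent revisiting stale locations, after which only the remaining
budget is available for undirected search.

Rating and affect parameters differ between the presets in the directions
the paradigm induces (lower perceived control, higher helplessness and
exhaustion, slightly higher negative affect in the yoked phenotype);
aversiveness is identical by construction, since both groups receive the
same stimulation.

An earlier design expressed the yoked phenotype as fast memory *decay*
(low retention).  It cannot produce the block-wise signature: if memory
washes out between trials, both blocks pay the same discovery cost and the
relocation changes nothing.  Perseveration — intact but rigid memory — both
matches the observed behaviour (much activity, ineffective after the
relocation) and produces the asymmetry.

The experiment pipeline adds between-participant heterogeneity around a
preset (RT shift SD 0.05 s, lognormal location SD 0.20, rating-baseline SD
0.8 scale units); identical agents would otherwise differ only through
sampling noise, making group tests on ratings and RT unrealistically
powerful.  Navigation parameters are not jittered.

## Metrics

Exploration is unique cells per minute of stress-free exploration:
per-trial distinct-cell counts (start cell included), summed over trials
and divided by pooled exploration time (per-trial and pooled normalisation
differ only by a constant here, since phase durations are fixed).  Escapes
count stress phases terminated on a safe cell.  Efficiency is stress-phase
moves per minute of time *actually spent* under stress (an escaped phase
contributes its latency, not the cap) divided by the number of escapes;
with zero escapes it is undefined and propagates as missing, which reduces
the degrees of freedom of the downstream repeated-measures analysis via
listwise deletion — the dropped count is reported in every ANOVA row.
Clamped edge presses count as moves.  All metrics are pure functions of
the logs: recomputation from the written CSVs is exact, which the test
suite verifies against independent brute-force scans.

## Statistics

* Quartiles for the 3×IQR extreme-outlier rule use linear interpolation
  (type 7), the default of the common statistical environments.  In the
  analysis report the rule is applied per design cell (condition × block,
  or condition × time) — the box-plot-per-group convention — because pooled
  fences would remove genuine group-level signal rather than recording
  artefacts.
* χ² tests default to Yates continuity correction for 2×2 tables and none
  otherwise — the only convention consistent with both published sex-table
  values (0.03 uncorrected 2×3; 0.06 corrected 2×2).
* *t* tests are Student (pooled variance, df = n₁+n₂−2).  Cohen's *d* uses
  the average-variance denominator √((s₁²+s₂²)/2) — identical to the pooled
  SD for equal group sizes, and the convention of the R effect-size
  routines this pipeline mirrors; it is what reproduces the published age
  *d* = −0.36 from the printed summaries (the pooled-SD form gives −0.37).
* One-way ANOVA and the *t* test accept either raw data or printed
  `(n, mean, sd)` summaries; the sums of squares are recovered exactly from
  the summaries, and both paths agree exactly when the raw data match.
* The mixed repeated-measures ANOVA uses the textbook two-factor
  (between × within) sums-of-squares decomposition with weighted means,
  supporting unequal group sizes; it matches `pingouin.mixed_anova` on
  balanced designs to machine precision.  Greenhouse–Geisser ε is estimated
  from the pooled within-group covariance of the level scores
  (double-centred trace form, clipped to [1/(k−1), 1]) and applied to the
  within and interaction tests when k > 2; for k = 2 sphericity holds
  trivially and ε ≡ 1.
* Holm adjustment is the step-down form with monotonicity enforcement;
  family-wise Bonferroni is `min(1, p·m)` with a declared family size.
  The report groups variables into three families — acute-phase measures
  (helplessness, exhaustion, [frustration], RT), affect change (three
  questionnaire totals), escape indices (exploration, escapes, efficiency)
  — and Bonferroni-adjusts within each; manipulation checks (aversiveness,
  perceived control) are reported uncorrected.  The family memberships are
  a documented package choice: the source analyses state the rule but not
  the lists.
* In the three-group design, group comparisons of Likert-rating means use
  Kruskal–Wallis (with η²_H = (H−k+1)/(N−k), reported as-is even when
  negative) on the grounds that they are ordinal; RT and other continuous
  measures use one-way ANOVA.  Aversiveness is compared between the two
  stress groups only — the control group never experiences the stressor.

## Problem sizes and what the tests show

The qualitative-pattern check simulates 50 `ec_like` + 50 `yc_like`
participants through the full two-group pipeline and asks whether the
efficiency group × block interaction is significant (α = 0.05 after
Bonferroni over the three escape indices) with the yoked group worsening
from block 1 to block 2; the package recovers it in ≈ 99 of 100 replicate
experiments.  Replicates use independent hashed sub-seeds of one root
seed.  Per replicate, roughly 10–15 of the 100 simulated participants are
dropped from the efficiency analysis (zero-escape blocks plus cell-wise
extreme outliers) — more than the handful dropped in typical human samples,
a consequence of the agents' coarser escape-count distribution.

What passing these checks shows is that the *pipeline* — scheduling,
yoking, the grid task, the metrics and the statistics — faithfully
implements the paradigm and can detect the phenotype it was built to
detect at realistic sample sizes.  What it does not show is anything about
human behaviour: the agents are stylised generators, their parameters are
package choices (no attempt is made to fit, e.g., the observed 0.60
correct-response rate of human escapable-group participants, which depends
on unmodelled attentional factors), within-session dynamics such as
fatigue or habituation are absent (rating trends are linear by fiat), and
the simulated groups are more homogeneous than human samples even with the
added between-participant jitter.  Statistical results on simulated data
should therefore be read as engine validation, not as reproductions of
empirical effect sizes.

## Known limitations

* The escapable-group agents show a slight efficiency *decline* from block
  1 to block 2, where human escapable groups tended to improve slightly;
  the coverage-scan agent cannot beat its own block-1 head start.  The
  interaction's substance (yoked collapse after relocation) is unaffected.
* Degenerate inputs are handled conservatively: zero-variance *t* tests
  return t = 0 (equal means) or flag infinity; all-tied Kruskal–Wallis
  returns H = 0; report rows whose design cells are too small after
  exclusions carry missing statistics rather than failing.
* Hardware-facing aspects of the paradigm (shock calibration, decibel
  verification, stimulus rendering, keyboard capture) are out of scope; the
  simulator begins at the level of trial timing and responses.
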