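# triadsim

Simulator and analysis toolkit for the **triadic stressor-controllability
paradigm** — the translational human adaptation of the classic
learned-helplessness design, including its shuttle-box-style escape
behaviour test.

## The scientific problem

Animal research separates the effects of *stress* from the effects of
*uncontrollable* stress with the triadic design: an escapable-stress group
(EC) that can terminate an aversive stimulus by its own action, a yoked
group (YC) that receives exactly the same stimulation but without any
action–outcome contingency, and a no-stress control group (CC).  Helpless
phenotypes are then read out in a transfer task — classically a shuttle box
in which previously stressed animals must escape again.

The human translation this package implements works as follows:

* **Stress induction.**  Trials deliver aversive stimulation (noise, plus
  shocks in the original three-group variant) for up to a per-trial maximum.
  A cue appears after a 6-s pre-cue period; an EC participant who responds
  within a 1-s window — with any press (one-cue variant, 40 trials, 15-s
  cap) or the correct one of three buttons learned by trial and error
  (three-cue variant, 60 trials, 10-s cap decreasing by 0.5 s after every
  15th trial) — terminates the stressor immediately.
* **Yoking.**  YC stress durations are predetermined: copied trial-for-trial
  from an EC partner (one-to-one yoking), or set to a random permutation of
  the EC group's per-trial mean durations (pseudo-yoking for group testing).
  The YC cue is shifted to 1–4 s (uniform) before stressor offset, so
  termination never follows the participant's own response.
* **Escape behaviour test.**  A 15×15 grid with four hidden safe cells.
  Each trial has a stress-free exploration phase and a stress phase that
  ends when a safe cell is entered (an escape) or at a cap.  The improved
  variant runs two 5-trial blocks with 5-s phases and — unannounced —
  relocates the safe cells for block 2.
* **Read-outs.**  Exploration (unique cells/min), escapes, efficiency
  (moves-per-minute / escapes; higher = *less* efficient), cue-locked RT,
  1–7 Likert ratings (aversiveness, perceived control, exhaustion,
  helplessness, …) after every 10th/15th trial, and pre/post questionnaire
  totals (state anxiety–depression, positive/negative affect).
* **Statistics.**  The full group-comparison pipeline: 3×IQR extreme-outlier
  exclusion, χ², Student *t* with Cohen's *d*, one-way ANOVA with partial
  η² (computable from printed group summaries alone), Kruskal–Wallis with
  η²_H, two-way mixed repeated-measures ANOVA with Greenhouse–Geisser
  correction, Holm and family-wise Bonferroni adjustment.

Human participants are replaced by generative **agents**: a shifted-lognormal
reaction-time model, an elimination learner for the cue–button task, grid
navigation policies (systematic memory-guided search vs. a high-tempo
perseverative "frantic" walk), and linear-Gaussian rating/affect models.
Two presets, `ec_like` and `yc_like`, encode the controllable- and
uncontrollable-stress phenotypes.

## Worked example

Simulate the full two-group experiment (50 escapable-like vs 50 yoked-like
agents) and test the escape-behaviour indices:

```python
from triadsim.pipeline import run_study2_experiment

res = run_study2_experiment(n_ec=50, n_yc=50, seed=7)
print(res.block_df.groupby(["condition", "block"])[
    ["escapes", "moves_per_min", "efficiency"]].mean().round(1))
row = res.report.query(
    "variable == 'efficiency' and effect_name == 'interaction'").iloc[0]
print(f"group x block interaction: F({int(row.df1)}, {int(row.df2)}) "
      f"= {row.statistic:.2f}, adjusted p = {row.p_adj:.2e}")
```

prints

```
                 escapes  moves_per_min  efficiency
condition block
EC        1          3.9          197.2        59.2
          2          3.2          196.2        60.7
YC        1          4.5          498.4       118.9
          2          2.8          495.8       236.8
group x block interaction: F(1, 73) = 18.32, adjusted p = 1.68e-04
```

The yoked group is more active (≈500 vs ≈200 moves/min) yet converts that
activity into *fewer* escapes once the safe cells are relocated: its
efficiency score roughly doubles from block 1 to block 2 while the
escapable group is stable — the group × block interaction the escape test
is designed to detect.  (Denominator degrees of freedom fall below 98
because efficiency is undefined for zero-escape blocks; those participants
are dropped listwise, as in the original analyses.)

The bundled published a-priori summaries can be re-analysed directly:

```bash
$ triadsim tables
sex_chi2_study1: chi_square statistic=0.0326 ... -> reported value 0.03 (published: 0.03)
sex_chi2_study2: chi_square statistic=0.0617 ... -> reported value 0.06 (published: 0.06)
wm_iq_partial_eta2: ... partial_eta2=0.0205 -> reported value 0.02 (published: 0.02)
alertness_partial_eta2: ... partial_eta2=0.0404 -> reported value 0.04 (published: 0.04)
age_cohen_d_study2: ... cohen_d=-0.3637 -> reported value -0.36 (published: -0.36)
```

## Command line

```
triadsim simulate     --study {1,2} --condition {EC,YC,CC} --n N --seed S --out DIR
triadsim escape-test  --variant {study1,study2} --agent ec_like --n N --seed S --out DIR
triadsim metrics      --sessions DIR --escape DIR --out DIR
triadsim analyze      --participants CSV --blocks CSV --out report.csv
triadsim tables
triadsim reproduce    --seed S --n-ec N --n-yc N --out DIR
```

All outputs are plain CSV/JSON; every run writes a manifest with a config
snapshot, the root seed and file checksums, and identical seeds give
byte-identical outputs.

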