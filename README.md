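# funcmeas

Functional-measurement analysis for factorial rating experiments: who combined
which cues, by which algebraic rule, with what weights.

The package targets the workflow of multisensory information-integration
studies in which participants rate a bipolar quantity — here emotional
valence on a −100…+100 track bar — for unimodal stimuli (a voice expression
alone, an air-jet touch alone) and for every bimodal combination, across a
within-subject factorial design. It provides, end to end:

- **Designs and trial tables** — the 5 audio × 3 tactile (+ both unimodal
  margins) × 6 repetitions layout (138 trials/subject) and long-format CSV I/O.
- **Synthetic cohorts** — subjects simulated from an algebraic integration
  rule (averaging with equal or differential weights, adding, multiplying)
  with Gaussian trial noise and track-bar clipping; ground truth retained for
  parameter-recovery studies.
- **Subjective values (Ψ)** — marginal-mean estimates per stimulus level and
  integration-graph tables (one line per level of the other factor).
- **Rule diagnosis** — repeated-measures ANOVA with Greenhouse–Geisser
  correction and partial η², the bimodal parallelism test, crossover
  detection, and the decision table *parallel + crossover → averaging;
  parallel without crossover → adding*.
- **Averaging-model fitting** — per-subject least squares for the
  equal-weight averaging model (and its differential-weight variant),
  BIC selection, residual-ANOVA goodness of fit, and normalized importances.
- **Population statistics** — centroid-linkage subject clustering, paired and
  independent Cohen's *d* with noncentral-*t* confidence intervals, and
  *t*-based fiducial limits on weight differences.

## The model

A rating of a cell is modelled as a weighted average of the subjective scale
values s of the cues present, together with an initial state (w₀, s₀):

    R = (w₀·s₀ + Σᵢ wᵢ·sᵢ) / (w₀ + Σᵢ wᵢ)

Unimodal cells drop the absent cue from numerator *and* denominator — the
set-size mechanism that makes single cues read more extreme than their
contribution to a bimodal cell, and the only thing that identifies the
weights. Weights are ratio-scale: the fit pins w₀ = 1 and reports the rest
relative to it; only weight ratios and normalized importances
wᵢ / (w₀ + Σ wⱼ) are comparable across subjects.

## Worked example

```python
import funcmeas as fm

design = fm.paper_design()                       # 138 trials/subject
cohort = fm.simulate_cohort(fm.make_paper_like_config(seed=7))
table  = fm.cell_means(cohort.records, design)

fm.marginal_psi(table, "audio").values
# {'AS-100': -49.5, 'AS-50': -27.2, 'AS0': -2.4, 'AS+50': 26.1, 'AS+100': 47.8}

verdict, interaction, cross = fm.diagnose_cohort(table)
verdict
# RuleVerdict(parallelism='supported', crossover='present', suggested_rule='averaging')
# interaction: F(8,176)=1.34, eps=0.78, p_gg=0.242

from funcmeas.averaging import AveragingModel
res = AveragingModel(table.subject_cell_means("S01"), design).fit(seed=0)
print(res.summary())
# Averaging model (equal weights), w0=1
#   cells fitted: 23   parameters: 11
#   sse: 138.199   bic: 75.73   converged: True
#   s0: -6.266
#   w_audio:   1.0411454210754723
#   w_tactile: 0.49690268861541964
#   s_audio:   [-116.05, -56.85, -8.38, 59.34, 108.73]
#   s_tactile: [77.54, -8.71, -78.59]
res.importance().entries
# {'w0': 0.394, 'audio': 0.41, 'tactile': 0.196}
```

The Ψ values are the marginal means of the group cell means per audio level:
an almost linear subjective continuum from strongly negative (anger morph) to
strongly positive (joy morph). The non-significant GG-corrected bimodal
interaction (parallel lines) together with the detected crossover of the
unimodal line classifies the cohort as averaging. The fitted subject weights
audio about twice as strongly as touch (true generating weights were
wA = 1.54, wT = 0.51); the importance profile says 41% of the judgment
weight sits on the voice, 20% on the touch, the rest on the initial state.

## Command line

```bash
funcmeas simulate --config sim.json --out cohort/          # trials.csv + truth.json
funcmeas analyze  --trials cohort/trials.csv --out report/ # tables + summary.json
funcmeas recover  --config sim.json --out recovery/        # simulate -> fit -> errors
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
simulates the full 23-subject study-like cohort at the given seed, runs the
complete pipeline (Ψ estimation → ANOVAs and rule diagnosis → clustering →
per-cluster averaging-model fits with residual goodness of fit → importance
and effect-size statistics), and writes the target report to `--out` with a
full pipeline summary (`*_summary.json`) beside it.
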