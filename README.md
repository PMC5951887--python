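# likertdif

Differential item functioning (DIF) analysis for Likert-scale
instruments, using the hybrid ordinal-logistic-regression / item
response theory approach common in patient-reported-outcomes research
(the lordif-style workflow).  Built around the measurement-invariance
question faced by instruments such as Berger's HIV Stigma Scale when
they are used across cohorts, countries or genders: *do respondents
with the same latent trait level answer an item differently depending
on the group they belong to?*

## What it computes

Items are calibrated with Samejima's graded response model: the
probability of endorsing category *k* or higher on item *i* is
`P(u_i ≥ k | θ) = σ(a_i(θ − b_ik))` with discrimination `a_i`, ordered
thresholds `b_ik`, and latent trait `θ ~ N(0, 1)`.  For each item,
three nested proportional-odds models are compared:

    Model 1:  logit P(u_i ≥ k) = α_k + β1 θ
    Model 2:  … + β2 · group
    Model 3:  … + β2 · group + β3 · (θ × group)

Changes in Nagelkerke pseudo-R² between Models 1→2 flag **uniform
DIF** (a constant group effect) and 2→3 flag **non-uniform DIF** (an
effect varying with trait level).  Flagging thresholds are empirical:
Monte-Carlo simulations of DIF-free samples from the fitted
calibration, with the threshold set on a 0.01 grid strictly above the
largest simulated statistic.  An iterative purification loop
re-estimates trait scores from non-flagged anchor items until two
successive rounds agree.  For flagged cells, the cumulative
individual-level impact of DIF is measured as `initial − purified`
trait score per person, with |difference| ≥ 0.20 SD counted as
salient.  Per-subscale unidimensionality is screened with polychoric
parallel analysis and the Empirical Kaiser Criterion.

The package ships the revised 32-item HIV Stigma Scale definition
(subscales *Personalized stigma* 11, *Disclosure concerns* 8,
*Concerns about public attitudes* 6, *Negative self-image* 7 items;
items 8 and 21 reverse scored) and a synthetic-study generator that
emulates a three-cohort design (n = 250/188/598) with injectable
uniform/non-uniform DIF for validation.

## Worked example

```sh
likertdif simulate --out study/ --seed 7 --missing-rate 0.02 \
    --inject item06:SE:uniform:0.9 --inject item17:SE:uniform:0.9
likertdif run-all --data study/ --contrast cohort=group \
    --subscale disclosure_concerns --mc-reps 50 --seed 3 --out results/
```

which prints (exactly this, from the commands above):

```
contrast            subscale   n       seed  threshold  n_flagged flagged_items  iterations  converged  n_salient error
  cohort disclosure_concerns 899 1840262038       0.02          1        item06           2       True         35
```

Reading: of 1036 simulated respondents, 899 were complete on the
8-item *Disclosure concerns* subscale; the Monte-Carlo threshold for
this analysis came out at 0.02; one item (`item06`, one of the two
with planted DIF at a shifted-threshold magnitude of 0.9 for the SE
cohort) exceeded it; purification converged after 2 rounds; and with
the DIF-adjusted recalibration, 35 respondents' trait scores moved by
at least 0.20 SD.  `results/` holds the per-item statistics table
(`*.dif.tsv`: d12, d23, flags, threshold), per-person impact tables
(`*.impact.csv`), dimensionality reports and a run summary.

The same workflow is available as a library:

```python
from likertdif import (DIFConfig, StudySpec, generate_study,
                       run_dif_purification)

study = generate_study(StudySpec(seed=7))
sub = study.responses.subset_items(study.scale.subscales["disclosure_concerns"])
result = run_dif_purification(sub, study.groups, DIFConfig(seed=3))
print(result.thresholds.shared, sorted(result.flagged_items))
```

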