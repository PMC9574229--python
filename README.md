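# msrehab

Responder classification and imaging-based response prediction for
cognitive rehabilitation trials in multiple sclerosis (MS).

Cognitive training helps some people with MS and not others, and group-level
statistics hide that heterogeneity. This package implements, as a tested and
reusable pipeline, the analysis strategy of a three-arm rehabilitation trial
(healthy controls assessed at baseline; waiting-list and intervention arms
assessed at baseline T0, post-intervention T1 and follow-up T2):

* **Responder classification by practice-corrected reliable change.**
  For each cognitive test, direction-aligned change scores are standardized
  against the change distribution of untreated waiting-list controls,

      RCI_i = (Δ_i − mean(Δ_ctrl)) / SD(Δ_ctrl),

  so that practice effects are subtracted and the control SD of change plays
  the role of the standard error of difference. A change is a reliable
  improvement when RCI > +1.64 (the 90% central-interval normal quantile,
  strict), a reliable decline when RCI < −1.64. A patient is a **responder**
  when at least 2 of 6 cognitive domains (verbal memory, processing speed,
  visuospatial memory, working memory, verbal fluency, attention) improve on
  at least one test.

* **Whole-brain-normalized between-network functional connectivity.**
  Atlas regions are assigned to resting-state networks (DMN, DAN, VAN, FPN)
  by maximal voxel overlap; per subject, the mean Pearson correlation of each
  between-network region-pair block is divided by the mean over all
  off-diagonal region pairs ("average brain connectivity"), removing global
  scaling differences between subjects.

* **White-matter damage from FA skeletons.** Per-voxel z-scores of
  fractional anisotropy against a healthy-control reference are summarized
  as **severity** (mean z) and **extent** (number of voxels with z < −3.1).

* **The statistical layer.** Baseline contrasts with Bonferroni correction;
  linear mixed models (random intercept, group × time fixed effects) with
  the standardized mean difference of change as effect size; and blockwise
  backward logistic regression (demographics → volumetrics → DTI → FC,
  likelihood-ratio removal at p ≥ 0.10) reporting Nagelkerke R² and
  per-class accuracy at a 0.5 cutoff.

* **A seeded synthetic-cohort generator** (`msrehab.synth`) producing
  longitudinal scores with test-level practice effects and a latent
  responder subgroup, network-structured timeseries with prescribed
  normalized-FC profiles, and Gaussian FA-skeleton maps — so the whole
  pipeline is exercised end-to-end without any patient data.

## Worked example

```python
import msrehab as m

report = m.run_pipeline(m.RunConfig(outdir="example_run", seed=7))
s = report["responder_summary"]
print(f"responders: {s['n_responders']}/{s['n_determined']} "
      f"({s['responder_rate_pct']:.1f}%)")
print(report["prediction"].retained)
```

With seed 7 and the default configuration (21 HC / 24 waiting-list / 58
intervention, latent responder fraction 22/58) this prints:

```
responders: 32/58 (55.2%)
['severity', 'norm_DMN-VAN']
```

All 22 latent responders are recovered; the remaining 10 are reliable-change
false positives, a realistic consequence of estimating practice corrections
from only 24 controls. The group table written to
`example_run/fc_group_table.csv` shows the configured connectivity regime —
normalized DMN–VAN coupling near 0.85 for responders and 0.97 for
non-responders versus 0.79 in healthy controls — and the backward logistic
model retains DMN–VAN connectivity (and, at this seed, white-matter damage
severity) as predictors of response (Nagelkerke R² = 0.39; per-class
accuracy 77%/88%).

A shell interface wraps the same stages:

```bash
msrehab run --config run.yaml        # full pipeline + manifest
msrehab synth --out cohort/ --seed 1
msrehab classify --scores cohort/scores.csv --out labels.csv
msrehab profile --ts timeseries/ --overlaps overlaps.csv
msrehab damage --maps maps.csv --ref ref.csv
msrehab predict --features f.csv --labels l.csv
```

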