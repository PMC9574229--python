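# Methods

This note documents the models implemented in `msrehab`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Reliable change and responder classification

The package uses the practice-corrected, control-referenced reliable change
index. For subject *i* on a given test, with Δ the direction-aligned change
between two sessions and Δ_ctrl the changes observed in untreated
waiting-list controls on the same test:

    RCI_i = (Δ_i − mean(Δ_ctrl)) / SD(Δ_ctrl)

Subtracting the control mean removes the expected practice effect; the
sample SD of control change (n−1 denominator) estimates the standard error
of difference. This is the standard control-referenced reading of a
practice-adjusted RCI; the classical Jacobson–Truax denominator
`SD_baseline · √2 · √(1−r)` is available through
`rci.sediff_denominator` when a retest reliability *r* is preferred, and
`compute_rci` accepts any threshold. Which exact denominator the original
analysis used is not recoverable from the published text, so the chosen
formula is an explicit assumption of this package.

Decision rules, all surfaced as parameters:

* threshold 1.64 exactly (the printed two-decimal 90% normal quantile, not
  1.6449), strict inequalities on both sides, so an RCI of exactly ±1.64 is
  not a reliable change;
* reliable decline is computed and reported but plays no role in responder
  status;
* a domain improves when ≥1 of its tests improves; a responder has ≥2
  improved domains (of 6);
* missing data: a domain with no valid test is *undetermined*; a definitive
  non-responder label requires ≥5 determined domains, otherwise the subject
  is labelled undetermined with the reason logged. A subject with ≥2
  improved domains is a responder regardless of missingness.

Healthy-control-referenced cognition uses z-scores of direction-aligned
values against the HC baseline sample, averaged first within domain, then
across the six domains ("average cognition"); impairment is z < −2.0
(strict) on ≥2 tests.

## Normalized between-network functional connectivity

Regions are assigned to DMN/DAN/VAN/FPN by maximal voxel overlap with a
network atlas (deterministic tie-break toward the earlier network in the
order DMN, DAN, VAN, FPN, other; ties are logged). Association is plain
Pearson correlation of regional timeseries — no Fisher transform, because
the normalization is a ratio of means on the correlation scale and the
published group values (~0.8–1.2) are consistent with that choice. For a
network pair (A, B) the raw value is the mean correlation over all region
pairs with one region in A and one in B; the whole-brain mean is the mean
over **all** off-diagonal unordered region pairs, including within-network
pairs and regions assigned "other"; normalized FC is their ratio. Signed
correlations are averaged (no absolute values). A non-positive whole-brain
mean makes the ratio meaningless and is treated as an error, never silently
signed. Whether the original analysis averaged signed or absolute values,
and what entered the denominator, is not recoverable from the published
text; these choices are flagged assumptions.

Two consequences are tested as invariants: multiplying every off-diagonal
correlation by k > 0 leaves normalized values unchanged, and on small
matrices the pair means equal exhaustive enumeration.

## White-matter damage

FA-skeleton voxel vectors are z-scored voxelwise against a healthy-control
reference (per-voxel mean and SD). Severity is the mean z over all skeleton
voxels — consistent with a healthy group sitting at 0 by construction.
Extent counts voxels with z strictly below −3.1, reading "exceeding
z = −3.1" in the damage direction (lower FA = damage); the strictness
matters only on a set of measure zero but is pinned by tests. Whether the
original z-scoring was voxelwise or global, and whether extent used a
cluster rule, is unknown; voxelwise scoring with no cluster rule is the
simplest reading consistent with a near-zero healthy extent.

## Statistical layer

* **Baseline contrasts**: Student's *t* for continuous variables,
  chi-square without continuity correction for categorical (so the 2×2
  statistic equals the textbook value), Mann–Whitney U when a variable is
  flagged non-normal. Bonferroni multiplies raw p by the family size of the
  requested table, capped at 1.
* **Group × time mixed model**: subject-level random intercept, categorical
  group, time and interaction fixed effects, REML. The interaction is
  tested with a joint Wald chi-square on the interaction coefficients. This
  is an asymptotic test; a Satterthwaite-type denominator correction would
  be preferable at very small samples but is not available in the fitting
  backend, so the package documents the test and verifies its null
  calibration empirically (p-values uniform by KS over 500 simulations at
  40 subjects/group). In balanced complete data the fixed-effect cell means
  reproduce the observed cell means, and for 2×2 designs the
  difference-in-differences contrast is reported directly.
* **Standardized mean difference**: the between-group difference of
  pre-to-post change divided by the SD pooled over all four group × time
  cells with n−1 weights. This denominator reproduces the published
  working-memory effect size (0.37) from the published cells; pooling only
  the baseline cells is available via `denominator="baseline"`.
* **Backward logistic regression**: predictors are organized in four entry
  blocks (demographics; cortical grey-matter volume; white-matter damage
  severity; DMN–FPN, DMN–DAN, DMN–VAN normalized FC) but eliminated in a
  single backward pass over their union — the block order is retained for
  reporting only, since no per-block stopping rule is published. Removal is
  by likelihood-ratio test with elimination at p ≥ 0.10, the conventional
  backward(LR) default. Nagelkerke R² is the Cox–Snell R² rescaled by its
  maximum, computed from the model and intercept-only log-likelihoods.
  Classification uses a 0.5 probability cutoff; a probability exactly at
  the cutoff is classified positive (logged). Perfect separation is
  flagged with a warning and the (divergent) coefficients reported rather
  than raised, so small cohorts still produce a report. Note that with
  seven null predictors the p ≥ 0.10 removal rule retains roughly one
  spurious predictor per run in expectation; this is a property of the
  rule, not a defect, and the recovery tests account for it.

## Synthetic-data generator

The generator exists so every downstream stage can be tested end-to-end;
its defaults are the trial's design conditions.

**Scores.** Three arms (21 HC, 24 waiting-list, 58 intervention), HC
assessed only at baseline. Per subject and test,

    y(k) = μ + u + k·practice + gain·[k ≥ 1] + e(k)

with u ~ N(0, ρ·σ²) a stable subject-by-test ability and
e(k) ~ N(0, (1−ρ)σ²) session noise, giving marginal SD σ and retest
correlation ρ (default 0.75, a typical neuropsychological test–retest
reliability; change scores then have SD σ√(2(1−ρ)) ≈ 0.71σ). Test-level
means/SDs default to the published healthy-control and patient baseline
cells, and practice effects to the published waiting-list first-retest
drifts. A latent responder fraction (default 22/58) receives `responder_gain`
(in units of the test's score SD, improvement direction, from the first
retest onward); the default gain profile (2 SD on LNS, DSB, CVLT)
concentrates improvement on working and verbal memory, the domains where
trained patients most often improved. Tests are independent given the
subject, which makes the null responder rate exactly computable by
enumeration (per-test tail probability → per-domain → 2-of-6 rule) — the
oracle used in the tests. Draws are Gaussian throughout; heavy tails,
floor/ceiling effects, item-level structure and missingness are not
emulated, so passing tests demonstrate correctness of the statistics, not
robustness to non-Gaussian real data.

**Timeseries.** A block-constant region×region correlation matrix is
solved so that each between-network analysis block equals `target · g`
(g = requested whole-brain mean off-diagonal correlation, default 0.2) and
every remaining off-diagonal entry takes the common value that makes the
whole-brain mean exactly g — hence each achieved normalized ratio equals
its target identically. If the solved matrix is not PSD it is projected
(eigenvalue clipping, diagonal renormalized) and the achieved ratios are
re-reported from the projected matrix; all group-level profiles used in the
package are PSD without projection. Region counts (12/8/8/10 analysis
regions + 22 "other", 60 total) are a scaled-down parcellation keeping the
four-network block structure. Timeseries are zero-mean Gaussian draws from
this covariance; no hemodynamics, autocorrelation, motion or nuisance
structure is simulated, so FC estimates converge to the target as the
series lengthens (verified at T = 10⁴ within 0.02). In full pipeline runs
each subject's targets are jittered around the group profile
(SD 0.12, matching published between-subject spreads of ~0.1–0.2) so that
prediction operates on realistic between-subject variance rather than
near-duplicate profiles.

**Skeleton maps.** Per-voxel FA is Gaussian around the reference mean with
a group-level decrement of `group_shift` HC-SDs and a subject-level global
offset (SD 0.23 in z units, reproducing the between-subject dispersion of
mean skeleton z in healthy cohorts). Mean severity is therefore −shift by
construction. A uniform Gaussian shift cannot simultaneously reproduce the
published patient extent values (thousands of voxels), which arise from
focal lesions; the generator matches severity marginals only, and extent
behaviour is tested against its analytic Gaussian tail instead.

**Covariates.** Age, sex, education, EDSS, cortical grey-matter volume at
cohort-typical levels, independent of latent responder status — matching a
trial in which demographics and structural measures do not separate
responders from non-responders.

## Problem sizes in the test suite

Monte-Carlo properties run at sizes chosen to make their tolerances sharp:
the null false-positive analysis uses 10⁵ intervention subjects against
2×10⁴ controls (binomial 99% bounds); band coverage uses 5000/5000 cohorts;
FC round trips use 2000–10⁴ timepoints; mixed-model calibration uses 500
simulated trials of 40 subjects/group; backward-elimination recovery uses
200 replicates of n = 400. The full suite runs in a few minutes on one CPU.

## Known limitations

* The RCI denominator and the FC/damage summary conventions are assumptions
  where the published text is silent (see above); all are parameterized.
* The mixed-model interaction test is asymptotic (Wald chi-square); at very
  small samples it is mildly anti-conservative.
* The generator's Gaussian, cross-test-independent score model understates
  the correlated multi-test false-positive patterns real batteries can show
  when a control arm is small.
* Atlas overlap tables are consumed precomputed; no volumetric resampling
  is performed.
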