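# Methods

## Preprocessing model

A chip profile is a table of (probe id, probe type, linear signal, flag)
records. Quality control fails a chip when *either* criterion holds:
flagged-spot count strictly greater than `max_flags` (default 10) or
negative-control coefficient of variation (sample sd / mean, untrimmed)
strictly greater than `max_cv` (default 0.15). The either-fails reading is
the conservative interpretation of the usual wording of such dual
criteria.

Background is estimated per chip from the negative-control spots after
removing `floor(0.05·n)` spots from each extreme of the signal ranking
(rank ties broken by probe id, so trimming is deterministic). A miRNA is
present iff its signal strictly exceeds `trimmed_mean + 2·trimmed_sd`;
present signals have the *trimmed* mean subtracted — the same statistic
that defines the threshold, chosen because the protocol names only "the
average of the negative controls" and using one statistic for both keeps
the presence/adjustment pair consistent.

Normalization is a per-sample linear scale factor: the cohort reference is
the mean over samples of the per-sample mean background-adjusted signal of
the three internal-control miRNAs (defaults miR-4463, miR-2861,
miR-149-3p — the third id is configurable, as the name printed in the
original protocol is not a valid miRBase name and is presumed a typo for
miR-149-3p), and each sample's factor is reference / own control mean.
After scaling, values move to log2; absent or non-positive adjusted values
are floored at 0.1 before the log (log2 0.1 ≈ −3.3219). After
normalization every sample's control mean equals the reference to 1e-9
relative tolerance by construction. Whether the reference should be
cohort-wide or a fixed vendor constant is not documented anywhere we know
of; cohort-wide is used because it is self-contained and idempotent.

geNorm stability for candidate reference miRNAs is the classic M value:
for candidate j, the mean over other candidates k of the sd across samples
of the pairwise log2 ratio (difference on the log2 scale). Lower M = more
stable; candidates are returned ranked.

The expression filter keeps a miRNA when its normalized log2 value exceeds
6 (signal > 2⁶) in strictly more than 50% of the cancer samples *or* of
the non-cancer samples. Both comparisons are strict; a miRNA at exactly
50% in both classes is dropped. The filter is applied to the normalized
log2 values; applying it to linear signals > 2⁶ is equivalent.

## Cohort operations

Exclusion reasons: QC-failed array (any sample); and for cancer samples a
prior history of other cancer, pre-collection treatment, missing smoking
or stage information, or a serum-to-surgery interval ≥ 180 days
(inclusive). Reasons accumulate, so per-reason counts may sum to more than
the excluded-sample count; the report keeps both.

Propensity matching fits a logistic model of case status on age, sex and
smoking (statsmodels ML fit; perfect or quasi-separation is reported as an
error with advice to jitter or match exactly), scores on the logit scale,
and matches greedily one-to-one without replacement, cases in descending
score order with ties broken by id. A pair is accepted only within a
caliper of 0.2 sd of the logit scores — the common caliper convention,
since no width is standard in the protocol class this mirrors. Cohort
summaries use one-way ANOVA for continuous variables and Pearson
chi-square *without* continuity correction for categorical ones (the
uncorrected statistic reproduces the published p = 0.002 on the validation
sex table); a constant variable yields p = 1 with a warning rather than an
exception.

## Discovery

`fit_fisher_lda` uses pooled covariance with the (n₁+n₀−2) denominator and
equal priors, so the method generalizes beyond balanced cohorts; the
intercept places index 0 at the midpoint of the projected class means, and
the cancer class always projects to a non-negative mean because
wᵀ(μ₁−μ₀) = (μ₁−μ₀)ᵀS⁻¹(μ₁−μ₀) ≥ 0. A relative ridge (1e-8 · trace/p) is
added to the pooled covariance only when it is singular or ill-conditioned
(condition number > 1e12), which keeps well-posed fits exactly
affine-equivariant while letting constant features survive.

LOOCV refits the discriminant for every held-out sample and classifies it
by index ≥ 0. The production path computes all leave-one-out fits in
closed form — rank-1 downdates of the class means and pooled scatter,
batched across candidate panels and held-out samples with vectorized
small-matrix solves (here the ridge is applied unconditionally, as
LOOCV must not crash on a degenerate column). The batched path is tested
for exact score agreement against a naive refit loop.

Beam search ranks candidates by LOOCV accuracy, breaking ties by apparent
AUC and then lexicographic panel ids (full determinism). Width 20 follows
the published procedure ("best 20 discriminants" per size); candidate
panels are deduplicated as sets. When the width covers all panels the
search provably equals exhaustive enumeration, which is asserted in tests
for small numbers of miRNAs.

DeLong's test uses midrank placements (O(n log n)) and the structural-
component covariance of the two correlated AUCs; it is verified to 1e-12
against a direct O(n²) implementation and against R's pROC. Zero variance
of the AUC difference returns p = 1 when the AUCs are equal and is an
error otherwise (a perfectly separated curve has no sampling variance to
test against). Model selection compares consecutive-size champions only —
advance from k to k+1 only if AUC increases and p < α (default 0.05) —
because that is the nested structure the published footnotes describe.

`apply_model` uses the inclusive rule: index ≥ 0 calls cancer, including
exactly 0.

## Evaluation

AUC is the Mann–Whitney probability with midrank ties. Confusion metrics
are percentages rounded to one decimal (the display convention of the
tables this mirrors); an empty predicted-positive (or negative) cell makes
PPV (NPV) NaN with a warning. Subgroup positive rates partition cancer
samples by pstage/T/N/M/histology. The pre/post comparison is a two-sided
paired t-test — the original reports only means ± SE with p-values and
names no test, and the paired t is the standard choice. Odds ratios come
from a statsmodels logistic ML fit with Wald 95% CIs; the exposure unit is
the continuous index by default, with 0/1 positivity as the documented
alternative, since the published OR's exposure unit is not stated.

## Synthetic cohorts (`simchip`)

The generator emulates the data structure the pipeline assumes, not serum
chemistry. Signals are log2-normal: target probes at baseline log2 mean 8
(sd 1.0), with 35% of probes near background (log2 3) so presence calling,
flooring and the expression filter all have real work; negative controls
at log2 3 (within-chip sd 0.1); internal controls at log2 10 (sd 0.1). A
per-sample technical scale factor (log2 sd 0.3) multiplies every spot —
exactly the artifact internal-control normalization removes. Planted
markers shift the cancer-class mean of chosen probes by a configured log2
effect, up or down; all other probes are class-identical by construction.
QC-failing chips are engineered explicitly (alternately ≥11 flags or
negative-control spread inflated to CV ≈ 0.3) at rate 4.4%, so both QC
rules have deterministic coverage. Clinical covariates link to class
through a logistic weighting (age +0.05/yr, male +0.3, smoker +0.8) so
propensity matching faces genuine imbalance; exclusion-reason rates
(prior cancer 1.9%, missing info 1.5%, pretreatment 1.1%, long interval
0.24%) and stage/histology frequencies follow a large resectable-lung-
cancer case series. Pre/post pairs share a patient-level profile with
chip-level noise (log2 sd 0.3); after resection each planted marker moves
`postop_decay` log2 units *toward the non-cancer baseline* (up-markers
fall, down-markers rise), which is what makes every marker's contribution
to the diagnostic index decrease post-operatively.

What the generator does not emulate: spatial chip artifacts, dye
chemistry, probe cross-hybridization, batch/storage effects, heavy-tailed
or correlated miRNA co-expression, and any real biological covariance
between markers. Passing tests therefore demonstrate that the *pipeline*
recovers structure it is pointed at under its own assumptions — they say
nothing about diagnostic performance on real serum data, which depends on
the deposited cohort and is out of scope here.

## Problem sizes and calibration facts

The simulation studies run at 500 miRNAs with 200/200 cohorts: 20 seeds
for planted-marker recovery (expected: a size-2 model containing both
markers in ≥ 90% of seeds) and 5 seeds for null calibration. Under the
null the per-feature LOOCV accuracy has sd ≈ 0.07 (leave-one-out folds are
correlated, well above the binomial 0.026), so the best of ~325 surviving
candidates is an extreme-value statistic that lands at 0.56–0.62 per
cohort; the calibrated quantity is the mean champion score across
cohorts (~0.59), and that is what tests and the acceptance script check.
The same extreme-value effect puts the largest single-probe null AUC
deviation near 3 sd (~0.09–0.10 across 500 probes), so null AUC checks are
distributional (mean 0.5, ≥95% of probes within ±0.08) rather than a cap
on the maximum.

## Known limitations

- The per-miRNA sub-model intercepts printed alongside published pair
  models are not derivable from the pair coefficients; single-miRNA models
  here always use the midpoint-intercept convention.
- Greedy caliper matching is not optimal matching; with a 1:1 control pool
  it can leave many cases unmatched, which is why the end-to-end pipeline
  leaves matching off by default and treats it as a cohort-construction
  tool for unbalanced pools.
- The GEO series-matrix reader supports reanalysis of deposited cohorts
  but no network access or deposited data is bundled; all shipped results
  are simulation-based.
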