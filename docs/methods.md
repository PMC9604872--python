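# Methods

This note documents the models, algorithms and numerical choices behind
`rulestrat`, the assumptions they make, and what the bundled synthetic data
can and cannot demonstrate.

## Data model

Genotypes are treated as *categorical allele-slot features*: each biallelic
variant occupies two allele columns in a PLINK `.ped` file, and each column
is one feature named `chrom:pos_1` / `chrom:pos_2` with allele-string values
("A", "T", "CA", ...). The missing code "0" never satisfies an equality
condition and is excluded from mode and association computations; this keeps
covering/error denominators well defined (denominators always count all
samples of a class, never excluding missingness). Coordinates are 1-based
inclusive. Sex is a binary feature (F/M); the HLA region is represented by a
single ordinally recoded SNP — the region's best-associated variant per
cohort (1-df allelic chi-square without continuity correction, two alleles
per sample) recoded as homozygous-low = 1 / heterozygous = 2 /
homozygous-high = 3. Which allele is "high" is configurable; by default the
minor allele is taken as the risk allele, with lexicographic tie-breaking.
Unrecodable genotypes (missing or third allele) become the missing code and
are flagged in the log.

## Feature selection

Three filter stages, no wrapper or information-criterion step (so the rule
learner's own multivariate behaviour is what is evaluated):

1. **Mode filter** (`mode_threshold`, default 0.95): a feature is dropped
   when its most frequent non-missing value accounts for strictly more than
   the threshold among non-missing observations. Sex and the HLA ordinal are
   exempt.
2. **Univariate ranking** by Cramér's V against status,
   `V = sqrt(chi²/(N·min(r−1,c−1)))` with the plain Pearson chi-square (no
   continuity correction, no bias correction). Ties are broken
   lexicographically by feature id so rankings are reproducible.
3. **Greedy forward selection**: candidates are scanned in rank order (the
   highest-V remaining candidate is, by construction, the next in rank order,
   since V against the output never changes) and accepted iff their V with
   every already-accepted feature is at most the cap `t`. Selection stops at
   `nsel` accepted features or when the top `npresel` candidates are
   exhausted.

Defaults `npresel = 200`, `nsel = 40` suit the desk-scale synthetic cohorts
(~700 features after the mode filter); at biobank scale these are the main
tuning axes, and the grid module treats them as such.

## Rule induction

The learner produces conjunctions of equality conditions predicting `case`
or `control`. Quality is measured on the training table as

* covering = 100 · |class samples satisfying all conditions| / |class samples|
* error = 100 · |other-class samples satisfying all conditions| / |other class|

and every accepted rule must satisfy `error ≤ 100·errmax`.

The search is **weighted sequential covering with beam search**, fully
deterministic:

* Per class, sample weights start at 1. One conjunction is grown at a time by
  a beam of width 5 (default): the beam retains the partial conjunctions with
  the largest weighted-covering-minus-error margin, a heuristic that keeps
  high-covering branches alive while their error is still falling; every
  feasible child (error within errmax, positive covering) competes for the
  best-so-far by higher weighted covering, then lower error, then the
  lexicographic tuple of condition keys.
* Because a conjunction's matched set only shrinks as conditions are added,
  any branch whose weighted covering no longer exceeds the best feasible
  covering is pruned exactly; the search stops when no branch survives or at
  `max_conditions` (default 13).
* An accepted rule must reach `min_covering` (default 0.4 %) on the
  *unweighted* table; reported covering/error are always unweighted
  full-table values, so the errmax guarantee holds on the training data
  as published, not merely under the internal weights.
* After acceptance, the weights of covered same-class samples are multiplied
  by 0.1 (down-weighting, not removal, so overlapping rules are possible).
  If the best conjunction found duplicates an already-emitted rule the class
  is finished — this guarantees termination, since down-weighting alone never
  removes a rule from consideration. A per-class rule cap (default 40) bounds
  runtime on noise-dominated data.
* Consequence of this design: the first rule emitted for a class always has
  covering at least that of the best feasible single-condition rule
  (singletons are enumerated in the first beam expansion).

Per-feature **relevance** is a package-defined surrogate: the sum over rules
containing the feature of `max(0, covering − error)/100`, reported raw and
rescaled so the top feature is 1. It orders features by the quality of the
rules they participate in; it is not comparable in absolute value to any
proprietary relevance measure.

## Cross-cohort rule transfer

When a second cohort lacks some of the ruleset's variants, each missing
condition `c` is considered for replacement by a condition `c′` on a variant
present in both cohorts, restricted to the same chromosome within 500 kb
(the scale over which linkage disequilibrium makes a proxy plausible).
Correlation is the all-confidence score
`supp(c ∧ c′)/max(supp(c), supp(c′))`, computed on the **training** cohort
(the only place both conditions are observed), with support = fraction of all
samples satisfying the condition. Every observed value of every candidate
feature is tried; the maximum all-confidence wins (ties: smaller distance,
then lexicographic feature id, then value) and must reach 0.9. Replacement is
decided once per unique condition, not per rule. Rules still containing an
unreplaced missing condition are dropped, since a boolean AND cannot be
evaluated; adapted rules keep their training covering/error metadata. Sex and
the HLA ordinal have no coordinates and are never replaced.

## Forecast score and metrics

The score is anchored at 0.5 and moved by the rules the sample meets:

    score = 0.5 + 0.5 · (W⁺_met / W⁺_tot) − 0.5 · (W⁻_met / W⁻_tot)

where W⁺/W⁻ sum the weights of the case/control rules (met vs all). Weights
are the rules' covering by default (stronger rules move the score more) with
a `uniform` switch; both satisfy the defining endpoints — all case rules and
no control rule gives exactly 1, the mirror exactly 0, no rules met 0.5 — and
the score is monotone in the set of rules met. A class with no rules
contributes 0 to its term. Classification uses threshold 0.5 with the tie
assigned to `control` (the majority class in the intended cohorts; the
threshold and tie rule are package choices).

Metrics: the standard confusion-matrix statistics (zero denominators yield
NaN rather than errors); AUC by the Mann-Whitney rank statistic with midranks
for ties and a DeLong-type asymptotic 95 % CI from placement-value variances;
calibration by a one-predictor logistic recalibration of status on the score
(statsmodels Newton iterations, tol 1e-8; a zero-variance score collapses to
the intercept-only model, i.e. risks = prevalence; separation or
non-convergence falls back to the raw scores, logged), followed by a
ten-decile table of mean predicted vs observed case fraction where tied risks
all land in the lower bin; Brier score = mean squared error of the risks with
a seeded 2000-replicate percentile bootstrap CI over (risk, outcome) pairs
(the logistic fit is not refit per replicate). Score distributions between
cases and controls are compared by the two-sample Wilcoxon/Mann-Whitney
rank-sum test — the groups are independent, so the rank-sum (not the paired
signed-rank) test is the applicable variant; exact enumeration is used for
tie-free groups of ≤ 10, otherwise the normal approximation with tie
correction. Post-test risk supports the exact odds-form Bayes update and the
published likelihood-ratio rule of thumb (add 19·ln(LR+) percentage points,
rounded to the nearest 5 — hence LR+ 2/4/5/10 add 15/25/30/45 points).

## Pipeline

Cross-validation is stratified (round-robin within each shuffled class) and
pools held-out scores into a single metric bundle. Feature selection runs
inside each fold by default; a `selection="global"` switch reproduces the
alternative design where one selection precedes the folds, at the price of
optimistic bias (a unique-sample-identifier leak test in the suite
demonstrates the per-fold default does not profit from fold-transcending
associations). The hyperparameter grid enumerates (t, npresel/nsel pairs,
errmax) in a fixed order, appends each record to a JSON-lines file and skips
already-recorded configurations, so completed grids rerun as no-ops. The
winning configuration maximizes pooled specificity subject to accuracy and
PPV within 0.05 of their respective maxima ("good balance" made concrete;
the bands are overridable), with ties broken by Youden's J and then
enumeration order. A master seed fans out to per-stage seeds through a keyed
blake2b hash (all derived seeds < 2^31), making every stage independently
reproducible.

## Synthetic cohorts

The generator produces the structure the pipeline assumes, at desk scale by
default: 200 cases / 400 controls (validation 110/250, preserving the ~1:2
case/control make-up of realistic registries), 10 locus windows ≥ 1 Mb apart
on distinct chromosomes, 40 variants per locus at 1 kb spacing in LD blocks
of 10 (members copy their block anchor's allele with probability ρ = 0.85,
else redraw at the variant's allele frequency, per allele slot
independently), allele frequencies uniform on (0.1, 0.5), 10 % indel alleles.
Disease status is drawn directly from a logistic model combining a sex effect
(log-odds from female fractions 0.92 in cases vs 0.47 in controls, matching
the female predominance of autoimmune liver disease), an HLA-like ordinal
effect (odds 1.6 per step of a designated chr6 top SNP), and planted
conjunctions — by default one 3-condition rule at odds 8 on the chr17-like
locus. The intercept is tuned by bisection on a 5000-sample pilot so the
population case probability matches the cohort's case fraction; exact counts
are then met by rejection sampling with a bounded number of batches.

Design choices worth stating:

* Planted variants have allele frequency fixed at 0.40 and are drawn
  independently of their surrounding LD block. The first keeps conjunction
  carriers at a few percent of a desk-scale cohort, so the planted signal is
  present but not dominant; the second makes the planted conjunction
  identifiable by its own conditions — otherwise a correlated block mate can
  legitimately stand in for a planted variant during correlation-capped
  selection, which is realistic but makes "did the learner find the planted
  conditions" unanswerable.
* Cross-cohort heterogeneity is planned at layout time: 10 % of variants
  (never block anchors, planted variants, or HLA-locus variants) are marked
  absent from the validation cohort, and each is generated as a
  probability-0.95 copy of its immediate (1 kb) retained neighbour, so a
  qualifying proxy provably exists. At `proxy_ld = 1` the dropped variant's
  conditions have exactly their proxy's support.
* No missing-genotype process is simulated: the intended inputs are imputed
  genotype panels, which are complete by construction. The missing-data code
  paths are exercised by hand-built tables in the unit tests instead.
* Phase is not modelled (allele slots are independent given the block
  anchor), matching the pipeline's view of slots as independent categorical
  features; haplotype-level claims are out of scope.

What passing tests on these cohorts shows: the pipeline discriminates when
planted effects exist (pooled cross-validated AUC > 0.65 across seeds),
stays at chance under the null, recovers planted conditions into accepted
rules, and transfers ≥ 70 % of rules across a 10 % variant-dropout gap using
the mining layer. What it cannot show: performance on real LD landscapes,
ancestry structure, genotyping artefacts, or effect sizes of real complex
traits — the generator's effects are chosen to be detectable at n = 600,
which is generous relative to single-locus effects in real rare-disease
cohorts.

## Numerical details and degenerate inputs

Chi-square statistics drop empty contingency rows/columns and return 0 for
degenerate (single-category) tables; monomorphic variants score chi² = 0,
p = 1 in the association scan. Cramér's V excludes pairs with a missing value
in either vector. Equality comparisons on covering/error in tests are exact
(the quantities are ratios of integer counts scaled by 100); errmax
feasibility uses a 1e-9 slack to absorb float division. Empty rulesets
degenerate to all-0.5 scores and a flagged metric bundle rather than an
error at forecast time, because an adapted ruleset can legitimately be empty.
Fold construction retries with a re-derived seed if a fold misses a class
(only possible when a class count is below the fold count) and fails loudly
after ten attempts.

## Known limitations

* The induction beam heuristic (covering-minus-error retention) is one
  defensible choice among several; rules near the errmax boundary can differ
  under other retention rules, though the covering/error/errmax semantics and
  the singleton-dominance guarantee hold regardless.
* Replacement mining is pairwise and single-hop; transitive chains of proxies
  are not attempted.
* Interval or inequality conditions on the ordinal HLA feature are not
  learned — conditions are equality-only, matching the rule vocabulary this
  package targets.
* Binary PLINK (.bed/.bim/.fam), imputation and phasing are out of scope;
  inputs are expected as quality-controlled text .ped/.map.
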