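# Methods

This note records the models, parameter choices and numerical conventions
behind each pipeline stage, what the synthetic generators do and do not
emulate, and the design decisions taken where more than one reading was
defensible.

## 1. nCounter normalization (`gbmpanel.normalization`)

Three multiplicative stages, applied in order:

1. **Background subtraction.** The per-lane background is the geometric
   mean of the 8 negative control probes.  Non-control counts become
   `max(count − background, 1)`; values that would fall below 1 are floored
   at 1 and counted in the report (`floored_count`).  Control probe rows are
   left untouched for audit.  If any control probe used in a geometric mean
   is zero, a +1 offset is applied to that probe block (geometric means are
   undefined at 0); the adjustment is logged.
2. **Positive (lane) normalization.** `factor_lane = mean_over_lanes(g_l) /
   g_l`, where `g_l` is the lane's geometric mean over the 6 positive
   spike-in probes.  The numerator is the arithmetic mean of per-lane
   geomeans — the nSolver convention.  Factors are applied to every probe,
   so after this stage all lanes share the same positive geomean exactly.
3. **Content normalization.** Same factor formula over a small reference
   set (panel default: CC2D1B, GPATCH3, MRPS5, PIK3R4, SF3A3), applied to
   all non-control probes.  Applying the factor to the reference genes
   themselves is deliberate: it makes the equal-reference-geomean invariant
   hold exactly and matches how content normalization behaves in practice;
   an implementation that rescaled only the other endogenous probes could
   never equalize the anchor genes it is defined by.

Data-driven reference selection (`select_reference_genes`) filters genes by
percent coefficient of variation (`100·sd/mean`, sample sd with n−1;
default ≤ 15%) and grows a set greedily from the most-correlated admissible
pair, requiring every admitted pair's Spearman ρ ≥ 0.75, ties broken by
lower %CV then symbol.

Edge conventions: flooring uses `< 1` after subtraction (so a count exactly
equal to background, which subtracts to 0, is floored); a single-lane run
degenerates to background subtraction with all factors 1.

## 2. Signature reduction (`gbmpanel.reduction`)

**Stage 1 — informativeness.** Each gene's expression across samples is fit
with univariate Gaussian mixtures of 1..5 components and the component
count is chosen by an information criterion; genes whose best model is a
single component are removed.  Two choices matter:

* *Equal-variance (tied) components.* The phenomenon being modeled is a
  location split (expressed vs silenced subpopulations); per-component
  variances are weakly identified at panel sample sizes (n ≈ 100–150) and
  letting them float mostly lets the null overfit.
* *AIC3 selection* (penalty 3 per free parameter; a mixture-model criterion
  intermediate between AIC and BIC).  Measured at a 3σ component separation
  with n = 120: BIC detects the split barely half the time even when scored
  with the true parameters, while plain AIC false-splits >15% of unimodal
  genes when up to 5 components are entertained.  Tied-variance AIC3
  reaches ~97% sensitivity at a ~3–7% false-split rate.  `BIC` and `AIC`
  remain selectable; BIC is the right choice when samples are plentiful or
  when an exact, conservative call matters more than power (the engineered
  reduction fixture is paired with BIC for exactly that reason).

Constant genes short-circuit to 1 component.  Fits are seeded and
deterministic.

**Stage 2 — redundancy.** All-pairs Spearman ρ among survivors; while any
pair exceeds the threshold (default 0.75, strict `>`), remove the gene with
the largest mean |ρ| over its above-threshold partners (ties: larger
overall mean |ρ|, then the lexicographically larger symbol, so the smaller
symbol survives) — the convention of cutoff-based correlation filters.
Each removal records the strongest still-retained partner.

**Fidelity.** The reduced list's preservation of the full list's structure
is quantified as the Spearman correlation between the upper triangles of
the sample×sample Spearman matrices computed on the full vs reduced gene
sets.  This is a summary of "do the two gene sets sort samples the same
way".  Note that a random subset *of the signature itself* typically scores
well on this metric — it inherits the full set's noise dimensions — so the
meaningful baseline is an equal-size set of *unrelated* genes, which the
kept set beats essentially always on planted fixtures.

## 3. FastEMC (`gbmpanel.fastemc`)

Fixed-size subset search (`m = 20`) by simulated annealing at a fixed
temperature γ = 0.03, with `n_outer = 10 000` outer iterations of
`n_inner = 20` Metropolis moves each (defaults; simulations in the tests
and acceptance script scale `n_outer` down to 30–200 to keep runtimes in
seconds — problem sizes there are 80–120 samples × 100–200 genes).

* **Moves.** Swap `u ~ Uniform{1..m}` members for genes outside the set
  (`u = m` allows a complete replacement).  Acceptance:
  `min(1, exp(ΔF/γ))` on the fast objective.  A geometric cooling schedule
  was considered and rejected as default: a single stated γ implies a fixed
  temperature, and the dual-objective design already separates exploration
  (fast) from retention (full).
* **Objectives.** Classifier F-score under stratified k-fold CV, per-fold
  confusion matrices summed before scoring.  Multiclass F is
  macro-averaged; a two-class problem scores the positive class's F1.
  Z-scoring is refit on each training fold and applied to the validation
  fold (no leakage).  For the non-iterative nearest-centroid classifier the
  fast/full budget split is realized as 2-fold vs 5-fold CV; for logistic
  regression and linear SVM the fast budget caps training iterations at
  `fast_budget_ratio` (default 0.1) of the full budget.  "Periodically
  checked against full" is implemented as once per outer iteration.
* **Best list and final signature.** Capacity-40 list ordered by full
  score, evicting its minimum, rejecting duplicate sets; its minimum is
  monotone non-decreasing.  The final signature ranks genes by appearance
  frequency across the list (ties: mean full score of the containing sets,
  then symbol) — one multiclass run, or the union of per-class one-vs-rest
  runs (`per_class_classifiers`, each keeping `size/n_classes` genes), both
  provided because either composition is defensible.
* **Null behaviour.** On label-permuted data the selector's best full score
  is compared against a matched-budget random-search null (the same number
  of full evaluations on random subsets of the same data).  This is the
  fair "no optimism beyond chance" comparison: annealing on a correlated
  fast objective legitimately explores more than blind sampling, and the
  measured excess stays within ~1 SD of the null's best-of-budget
  distribution (bound: 3 SD).
* **Early stopping** is a fixed iteration cap; no monitored-quantity
  patience rule is implemented.

Nearest-centroid classification (`fit_nearest_centroid` /
`predict_nearest_centroid`) uses per-class means of z-scored training
values and Euclidean distance; prediction ties resolve to the first class
in sorted order; per-sample per-class distances are emitted for
distance-profile plots.

## 4. Concordance (`gbmpanel.concordance`)

Z-scores are computed per gene across **all samples pooled** (n−1 sd;
constant genes are flagged and zeroed).  Within each PDX line, each model
pair (cells–microtumor, cells–spheroid, microtumor–spheroid) contributes
`sign(z_A · z_B)`; replicates are averaged first; missing models yield NA,
never errors.  A zero product counts as discordant by default
(conservative; `ignore` available).

**Aggregation to the Venn classes.** A pair "agrees" for a gene if it is
concordant in at least `line_fraction` of the lines with data for that
pair.  The default is a **two-thirds supermajority**: a null gene's
per-line sign product is a fair coin, so bare-majority aggregation would
classify roughly one null gene in five as core, while at 2/3 the null core
rate stays well under 5% and genes with genuine shared line-level structure
(≈95% per-line concordance at a 2σ line effect) still pass every pair.
`core` = all three pairs agree; `none` = no pair agrees; otherwise the
label names the agreeing pairs.

Per-line Pearson correlations between model profiles (optionally restricted
to a gene subset) reproduce, on planted panels, the phenomenon that core
genes correlate better across models than the full panel does.
Model-specific genes are screened by Kruskal–Wallis (scipy, tie-corrected)
at p ≤ 0.01; variance filtering ranks genes by across-sample variance
(ties by symbol); bi-clustering is average-linkage on correlation distance
(1 − Pearson), falling back to Euclidean with a warning when constant rows
make correlation undefined.

## 5. Differential expression (`gbmpanel.diffexp`)

Counts → CPM (each sample scaled to 10⁶) → log₂(CPM + 1).  Group difference
is a Welch t-test (Mann–Whitney selectable); log₂FC is responder mean minus
non-responder mean.  A gene is significant iff p ≤ 0.05 **and**
|log₂FC| ≥ 2 — a raw-p, large-effect screening rule; no multiple-testing
correction by default (Benjamini–Hochberg behind `fdr=True`).  The
fold-change condition is two-tailed (|log₂FC| ≥ 2 covers both directions).

Properties worth knowing:

* Swapping the group labels negates every log₂FC and leaves every p
  unchanged, exactly.
* On fully null count data the fraction of genes at p ≤ 0.05 matches the
  Welch test's intrinsic small-sample level (~0.045 at n = 6+6) — slightly
  conservative, never inflated.
* CPM is a *relative* measure: genes with large true fold changes shift
  library sizes and hence depress the CPM of unchanged genes (composition
  effect).  With a handful of 8-fold genes on a 200-gene panel this
  measurably inflates the raw-p rate on the remaining genes; the
  two-condition rule (|log₂FC| ≥ 2) is what keeps the final call list
  clean.  This is inherent to per-sample total scaling, not a defect of the
  test.

Response-associated screening reuses the Kruskal–Wallis machinery with the
drug-response label as the grouping; untested samples are excluded.
`intersect_signature` is a sorted set intersection used to derive
response-concordance signatures.

## 6. Synthetic data (`gbmpanel.synth`)

All generators are pure functions of a spec + seed (bit-identical reruns)
and serialize their ground truth next to the data.

* **nCounter lanes.** Endogenous counts are log-normal-then-rounded:
  `round(lane_scale · 2^(μ_g + N(0, 0.5)))` with μ_g ~ U(5, 10); lane
  scales default to log-uniform in [0.8, 1.25] (a realistic lane-efficiency
  spread).  8 negative probes ~ Poisson(6); 6 positive probes on a 4×
  geometric ladder × lane scale with 1% log-normal wobble (spike-ins carry
  only counting noise); 5 housekeeping genes named as the panel reference
  set, sharing the lane factor with near-zero (0.02 log₂) biological
  variance.  Log-normal rather than negative-binomial noise: nCounter
  per-probe noise is near log-normal at moderate counts and nothing
  downstream models dispersion.
* **Labeled multiclass expression.** Balanced classes; marker genes get
  per-class ±effect offsets (default 10 markers at 1.5σ, guaranteed
  non-flat), or one-class shifts in `per_class` mode; genes are z-scored.
* **Signature panels.** Unimodal genes N(0,1); bimodal genes
  `Bernoulli(½)·sep + N(0,1)` (sep in within-component SD units);
  redundant blocks share one bimodal latent plus independent noise
  calibrated so pairwise correlation hits the target ρ.  The engineered
  40-gene fixture (15 unimodal + 16 singleton bimodal + blocks of 4/3/2 at
  ρ = 0.97, sep = 5, n = 250) reduces to exactly 19 genes under BIC, robust
  across seeds.
* **Multi-model panels.** 11 lines × {cells, microtumor, spheroid},
  350 genes, noise σ = 1.  Core genes carry a line-specific ±2σ level
  (signs balanced across lines so the pooled mean stays near zero) shared
  by the line's models; model-specific genes add +2σ in spheroids;
  response-associated genes add +2σ in responder lines (half the lines);
  3 lines lack spheroids, mirroring panels where spheroids could not be
  generated.  Note that response-associated genes are *also* line-level
  effects shared across models, so a handful legitimately classify as core.

**What passing tests on these data do and do not show.** The generators
reproduce the *structures* each method assumes — control-probe anatomy,
planted class separation, shared line-level effects, planted fold changes —
under clean Gaussian/log-normal noise with independent genes outside the
planted blocks.  They do not emulate real GBM co-expression networks,
probe-level chemistry, batch structure, or count overdispersion, so green
tests demonstrate correctness and calibration of the algorithms under their
stated models, not their behaviour on any particular real cohort; published
headline figures from real PDX/TCGA cohorts (e.g. ~92% subtyping accuracy,
specific core-gene counts) depend on data that were never deposited and are
deliberately not targets here.

## 7. Problem sizes

Simulated studies use the layouts above at desk scale: FastEMC recovery at
120 samples × 200 genes with 200 outer iterations; null controls at
80 × 100 with 30 outer iterations over 20 seeds; filter operating points at
n = 120 over 20 seeds; differential expression at n = 6+6 over 100 seeds
(50 in the acceptance script).  These sizes were chosen so the full test
suite and the acceptance script each run in well under a minute of compute
per stage while keeping every measured proportion's Monte Carlo error small
relative to the bounds being checked.

## 8. Known limitations

* The RCC reader implements the documented text layout only; binary RLF
  codeset files are not parsed (probe classes must come from CodeClass or a
  sidecar table), and no HGNC symbol aliasing is attempted.
* The mixture filter's operating point is tuned to n ≈ 100–150 samples; at
  much larger n, AIC3 will over-split and `BIC` should be preferred.
* `line_fraction` aggregation treats lines as exchangeable; there is no
  weighting by per-line data quality.
* CPM + raw-p screening is faithful to the screening-rule design but is not
  a substitute for a dispersion-modeling DE framework when counts are deep
  and replicated; the `fdr` flag and Mann–Whitney option are provided for
  that reason.
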