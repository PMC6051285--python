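# Methods

This note documents the statistical procedures implemented in `sensmark`,
the assumptions behind them, the tunable parameters that matter, and the
design decisions taken where the procedure was genuinely open.

## Group definition

Sensitivity groups are defined by dichotomizing IC50 (µM) at a threshold
(default 1 µM). A sample is Sensitive when IC50 is *strictly below* the
threshold; a value exactly at the threshold is called Resistant. The
boundary rule is a deliberate conservative choice — a line exactly at the
cut-off is not nominated as sensitive.

## Stepwise filtering

Three stages run in fixed order, each recorded separately in the filter
report:

1. **Invariant removal** — genes constant across all samples carry no
   contrast information: never/always-mutated genes, copy-number genes with
   a single loss/normal/gain category, zero-variance expression genes.
2. **Expression floor** — a gene survives if its *maximum* log2 value
   across samples reaches the user floor. The max-rule (rather than mean or
   all-samples) keeps genes expressed only in one group, which are exactly
   the candidates of interest, while removing background-only probes.
3. **Point-biserial correlation** — Pearson r between each gene and the
   group indicator (Sensitive = 1). Genes with |r| below the cutoff
   (default 0.1) or with undefined r (zero variance) are removed. Only |r|
   is used, so the 0/1 encoding direction cannot change the retained set;
   a test asserts this. The filter is applied uniformly to all three data
   types.

The retained set is monotone in the cutoff and invariant (as a set) to gene
order; report counts reconcile exactly with matrix dimensions.

## Marker engines

**ANOVA.** One-way two-group ANOVA per gene, df (1, n_S+n_R−2); F equals
the square of the pooled two-sample t identically (property-tested).
Effect is mean(S) − mean(R): a log2 fold change on log2-scale expression
(no re-logging), a plain difference of ordinal codes for copy number.
Identical group means report F = 0, p = 1.

**Moderated t.** Gene-wise residual variances s²_g (d = n_S+n_R−2 df) are
shrunk toward a prior s₀² with d₀ prior df:
s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), t̃ = Δmean/(s̃_g √(1/n_S+1/n_R)),
p two-sided on d₀+d df. The hyperparameters are estimated across genes by
the method of moments on e_g = log s²_g − ψ(d/2) + log(d/2): the excess of
var(e) over the chi-square sampling noise ψ′(d/2) identifies ψ′(d₀/2)
(inverted by Newton iteration), and mean(e) identifies s₀². When the
observed spread is no larger than sampling noise, d₀ = ∞: complete
shrinkage with a normal-reference p. `prior_df=0` disables shrinkage and
reproduces the ordinary pooled t exactly. Zero-variance genes are excluded
from hyperparameter estimation; an all-zero-variance matrix is an error.

**Hypergeometric.** For a gene mutated in a of n_S Sensitive and b of n_R
Resistant samples, with K = a+b and N = n_S+n_R, the enrichment tail is
P(X ≥ a) and the depletion tail P(X ≤ a) for X ~ Hypergeom(N, K, n_S).
The reported two-sided p is 2·min(tails), capped at 1 — simple and
conservative; the exact test's discreteness makes it conservative under
the null (calibration-tested as ≤ α + 3·SE).

**Odds ratio.** OR = (a·d)/(b·c) from the 2×2 table, reported as log10 OR.
If any cell is zero, 0.5 is added to all four cells (Haldane–Anscombe),
keeping log10 OR finite so that the conventional |log10 OR| > 1 marker
filter remains applicable. The odds-ratio table carries the companion
hypergeometric p in its p-value column; the measure itself has no separate
test.

**Marker filtering.** Strict comparisons: p < p_max AND |effect| >
effect_min. For hypergeometric tables the effect is a mutation-rate
difference, so only the p threshold applies; the |log10 OR| threshold
belongs to the odds-ratio engine. Output is sorted by ascending p with
gene-name tie-break.

## Stability elastic net

The group response (Sensitive = 1, Resistant = 0) is treated as numeric and
regressed with a squared-error elastic-net penalty — the regression-style
formulation is stable for p ≫ n; a penalized-logistic variant is available
via `family="logistic"`. Per run (default 100):

* a stratified bootstrap resample of samples is drawn, preserving group
  sizes and forcing ≥ 2 distinct samples per class;
* features are standardized within the resample (constant features get
  coefficient 0);
* the penalty strength is selected by internal cross-validation
  (default 3-fold, 50-point grid) at fixed mixing l1_ratio (default 0.5);
* the nonzero-coefficient set and coefficients are recorded.

A gene's `frequency_pct` is the percentage of runs with a nonzero
coefficient; `mean_beta` is its average standardized coefficient over the
runs where it was retained (sign preserved; zero only if never retained).
Averaging over retained runs only reports effect size conditional on
selection — the frequency column already encodes the selection rate.
What varies across runs is the resample; this stability-selection reading
makes the frequency a robustness measure rather than a repeated identical
fit. Both groups must have ≥ 4 samples. Fits run in a canonical sorted-gene
order internally, making results exactly invariant to the caller's feature
ordering (coordinate descent is order-sensitive at tolerance level).
Everything is deterministic given the seed.

## Transfer classification

The signature genes are intersected with the target matrix; missing genes
are dropped with a warning. Cell-line and tumor expression live on
different global scales, so by default each retained continuous gene is
z-scored *within each dataset separately* before training and prediction
(`harmonize="none"` disables this); binary mutation and ordinal copy-number
features pass through. A forest of classification trees (default 100,000;
bootstrap per tree, √p features per split, unlimited depth) is trained on
the training labels. Each clinical sample receives the fraction of trees
voting Sensitive; the label is Sensitive iff that fraction exceeds 0.5, and
an exact tie is called Resistant (do not nominate a patient on a coin
flip). Tests run at 2,001 trees (odd, so ties cannot occur); the vote
fraction is an unbiased estimate of the same quantity at any ensemble size.
Swapping the label encoding at training flips every vote fraction to 1−v
(verified exactly on continuous data, where trees grow to pure leaves).

## Clinical association ranking

Per declared variable type:

* **continuous** — two-sided Mann–Whitney; the exact null distribution is
  used when both groups have ≤ 8 observations and no ties (cheap and
  exact), the tie-corrected normal approximation otherwise;
* **categorical** — Pearson chi-square on the R×2 contingency table
  without continuity correction, df = R−1; cells with expected counts < 5
  set a `low_expected_count` flag rather than silently switching tests;
* **survival** — two-group log-rank (1 df) with Kaplan–Meier step
  coordinates exported per group; a survival_time variable `X` pairs with
  the event column `X_event`.

Missing values are dropped per variable (never imputed) with logged
counts; degenerate variables (single category, an empty predicted group,
no events) are skipped with a warning. The table is ranked by raw p
(ties broken by variable name); Benjamini–Hochberg q-values are appended
as an extra column because many variables are tested, but the raw-p order
remains the primary ranking.

## Clustering and plot data

Expression and copy number use Ward's variance-minimizing criterion on
Euclidean distances (the ward.D2 convention — stated explicitly because
the two historical Ward variants differ). Mutation profiles use Hamming
distance as a *count* of discordant positions with average linkage (the
linkage for binary profiles was an open choice; average is the common
convention). Leaf order follows the dendrogram with the library's
deterministic tie rule. Heatmap data can optionally be row-z-scored
(`row_zscore=True`); raw values are clustered by default. Volcano defaults
flag p < 0.05 and |log2FC| > 1; scatter rows pass copy-number (size) and
expression (color) values through unchanged.

## Synthetic data: what it emulates and what it does not

`SimulationConfig` states the simulated world once:

* **Cell-line panel** (8+8 by default, 300 genes, unit log2 noise SD): a
  10-gene amplicon block is gained as a whole-block per-sample event with
  probability 0.9 in sensitive lines (0.02 in resistant) and overexpressed
  by 3 log2 units in gained samples — co-amplification with
  co-overexpression, the classic amplicon pattern. A driver mutation is
  carried by all sensitive lines and exactly one resistant line (the
  discordant-carrier situation that real panels show). IC50s are
  log-uniform in (0.01, 0.5) µM for sensitive and (2, 30) µM for resistant
  lines, so the 1 µM threshold reproduces the intended groups.
* **Clinical cohort** (120 samples, 30% prevalence by default): samples on
  a tumor-scale baseline (global +2 log2 shift, 1.5× noise) so that
  harmonization is actually exercised. Latent profile carriers are defined
  by *carrying* the molecular profile (deterministic amplicon and driver
  given the latent label) — probabilistic penetrance belongs to the
  IC50-defined cell-line groups, while the cohort's latent truth must
  coincide with the molecular profile for accuracy scoring to be
  meaningful. Annotations: an IHC-like category with strong 3+ enrichment
  in carriers (0.75 vs 0.10 — the dominant-effect situation the workflow
  targets), an age-like shift of −6 years against a 12-year SD (a modest
  effect of the size reported for real cohorts), and exponential survival
  with hazard ratio 0.5 and uniform censoring on (0, 72) months.

The generator does not attempt realistic expression covariance, batch
structure, subclonality or annotation missingness; a green end-to-end test
establishes that the pipeline recovers planted structure of realistic
effect size through a dataset-scale shift — not that it would rank markers
correctly under real-data confounding.

## Numerical and operational choices

* p-values are floored at 1e-300 so they stay in (0, 1] and survive TSV
  round-trips at full `%.17g` precision.
* Strict (<, >) threshold comparisons everywhere, so published-style
  threshold pairs are reproducible exactly.
* Duplicate gene rows at load collapse to the highest-variance row (logged);
  expression NAs are allowed at load but NA genes are dropped (with a
  logged count) before any engine runs; mutation/copy-number missing values
  are rejected at load.
* Marker thresholds are analysis knobs, not constants of the method. The
  defaults (p < 1e-4, |log2FC| > 1.5) mirror a published large-panel
  analysis; at the simulator's desk scale (8+8 lines) the end-to-end tests
  use p < 0.01 with |log2FC| > 1.5, which keeps signatures nearly pure of
  false positives while retaining power — chosen once by pilot simulation.
* All pipeline randomness derives from the single run seed via hashed
  per-branch substreams; reruns are byte-identical (manifest timestamp
  aside). The forest default honors 100,000 trees; tests and the
  acceptance script run 2,001 (odd to avoid ties), identical in
  expectation.
* When several engines are selected, each produces its own signature and
  downstream branch; signatures are never merged, and each data type is
  analyzed in its own branch (no cross-omic fusion in one forest).
* In the orchestrated workflows a training group smaller than 4 skips the
  elastic net with a warning while other engines run; calling the elastic
  net directly with such a group is an error.

## Known limitations

* No covariate adjustment, batch correction or imputation anywhere.
* Only two-group contrasts; no multi-class or continuous-response designs.
* The moderated-t prior assumes a single variance distribution across all
  genes (no intensity-dependent trend).
* Vote fractions are not calibrated probabilities.
* The chi-square path never switches to an exact test at small expected
  counts; it flags them instead.
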