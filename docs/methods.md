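# Methods

This note documents the models, estimators and conventions implemented in
`beconcord`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Differential expression and panel selection

**Model.**  For each probe g, log2 expression in two groups (normal squamous
epithelium vs Barrett's metaplasia) with n₁ and n₂ samples.  The effect
estimate is the least-squares two-group contrast, logFC_g = mean(BE) −
mean(normal).  The residual variance s²_g has df_g = n₁ + n₂ − 2 degrees of
freedom.  Gene variances are modelled as exchangeable draws from a scaled
inverse-chi-square prior σ²_g ~ s₀²·d₀/χ²(d₀); the posterior variance

    s̃²_g = (d₀ s₀² + df_g s²_g) / (d₀ + df_g)

replaces s²_g in the t-statistic t_g = logFC_g / (s̃_g √(1/n₁ + 1/n₂)),
which under the null follows a t distribution with df_g + d₀ degrees of
freedom.  Two limits are exposed for validation: d₀ = 0 recovers the
classical pooled two-sample t exactly, and d₀ = ∞ pools every variance to
s₀².

**Hyperparameter estimation.**  (d₀, s₀²) are estimated by matching the
first two moments of log s²_g.  Under the model, log s²_g is a shifted
log-F variable: E[log s²_g] = log s₀² + ψ(df/2) − log(df/2) − ψ(d₀/2) +
log(d₀/2) and Var[log s²_g] = ψ′(df/2) + ψ′(d₀/2), where ψ and ψ′ are the
digamma and trigamma functions.  The excess of the empirical variance of
log s²_g over the mean ψ′(df/2) term is inverted through the trigamma
function (Newton iteration from the asymptotic start ½ + 1/x) to give d₀;
the mean equation then gives s₀².  Non-positive excess variance means the
variances show no more spread than sampling alone explains, and the
estimator returns the pooled limit d₀ = ∞.  Parameter-recovery tests
(2000 genes, 7 per group, d₀ = 4, s₀² = 0.05) recover d₀ within [2.5, 6.5]
and s₀² within [0.035, 0.07] in ≥ 90% of seeded runs.

**Multiple testing.**  Benjamini–Hochberg step-up adjustment, implemented
directly (sort, p_(j)·n/j, suffix cumulative minimum, cap at 1) and checked
in the tests against both a brute-force min-over-suffix oracle and
statsmodels.

**Selection rule.**  A gene enters the panel iff it is present in every
dataset considered and at least one dataset shows |logFC| > 2 (strict, per
"higher than 2 or lower than −2") together with adjusted p < 0.05, all
qualifying datasets sharing the sign.  Qualifying datasets with opposite
signs yield a distinct `conflict` status rather than a silent selection.
Thresholds are configurable (`SelectionCriteria`); raising the fold
threshold or lowering alpha can only shrink the panel (tested property).
α is accepted in [0, 1): α = 0 is the degenerate select-nothing
configuration used to test pipeline behaviour on an empty panel.  Multiple
probes per gene are evaluated independently and a gene qualifies if any
probe does.  Input matrices are assumed log2-scaled.

On the packaged evidence table (three BE-vs-normal biopsy comparisons) the
rule reproduces the 23-gene panel and excludes KRT10, KRT17, KRT19, MUC1,
MUC5AC, MUC12, MUC15, MUC17 and MUC21.  MUC4 also fails the criteria on the
printed values and is excluded; the original report's exclusion list omits
it — we document rather than resolve the discrepancy.

## qPCR relative quantification

**Aggregation.**  Replicate wells (duplicates or triplicates) are averaged
per (sample, gene) first; a (sample, gene) is undetected when a strict
majority of its replicate wells are missing, so a duplicate with one
missing well keeps the present value.  The token `Undetermined` on input
reads as missing, the common qPCR export dialect.

**Normalisation.**  Two reference genes (ACTB/GAPDH by default) are
combined by the arithmetic mean of their mean Cts, equivalent to the
geometric mean of their linear quantities.  Per sample,
ΔCt = mean target Ct − mean reference Ct, which makes every RQ invariant to
a constant Ct shift of a whole sample (tested property).  ΔΔCt for a
condition is its mean ΔCt minus the mean ΔCt of the reference condition
(untreated cells / intact rats), and RQ = 2^−ΔΔCt, so the reference
condition has RQ 1 by construction.  A reference gene undetected in any
sample is a hard error: normalisation would silently bias every target.

**Significance.**  Tests run on per-sample ΔCt values (approximately
normal), not on RQ.  Two conditions: two-sided pooled Student t.  More:
many-to-one Dunnett comparisons against the reference condition sharing the
pooled within-group variance.  The many-to-one contrast correlations always
factorise as ρ_ij = λ_i λ_j with λ_i = √((1/n₀)/(1/n_i + 1/n₀)), so the
k-dimensional probability P(max_i |T_i| ≥ t) reduces to a two-dimensional
integral over the shared normal factor (Gauss–Hermite, 128 nodes) and the
pooled chi scale (Gauss–Legendre on its probability scale, 256 nodes).
This quadrature covers unbalanced designs exactly as well, so no
Monte-Carlo fallback is needed; it agrees with a 10⁶-draw Monte-Carlo
oracle within 0.005 and reduces to the two-sided t within 1e−6 at k = 1.
Degenerate zero-variance groups (which arise in noiseless simulations) are
resolved by the mean difference: equal means give p = 1, unequal p = 0.

**Direction calls.**  `up` requires RQ ≥ 2 and p < 0.05; `down` RQ ≤ 0.5
and p < 0.05 (boundaries inclusive: "at least a two-fold" change is
relevant); anything else detected is `no_change`.  A gene undetected in all
experimental conditions of a system is `na` (no amplification); a gene not
assayed in a system is `nd`.  Both the fold and the significance criterion
must hold — biological relevance gates statistical significance.

## Concordance scoring

The profile table holds one row per panel gene with the human direction
(always `up` or `down`, taken from the selection stage, never re-derived)
and one status per model system.  Per-system concordance counts genes whose
model status equals the human status; `nd` genes leave the denominator,
while `na` and `no_change` genes remain and count as non-matches — the only
denominator rule consistent with the published counts (rat 10/22 with one
`nd` gene; cell lines out of 23).  The combined score counts a gene as
matched if at least one listed system matches (set union over match sets)
and drops only genes `nd` in every listed system; union dominance over the
best single system is a tested invariant.

Percentages are reported as exact fractions plus integer renderings under
two named conventions, `nearest` (half up) and `floor`, because the
published figures mix both (13/23 = 56.5 → 57 nearest; 17/23 = 73.9 → 73
floor); which convention a report uses is always stated alongside.  The
packaged profile records MUC5B's human status as `up` — it passes the
selection criteria although the published summary table leaves that cell
blank.  Venn partitioning of 2–3 named gene sets enumerates the 2^k − 1
exclusive regions, which are disjoint and sum to the union cardinality by
construction.

## Synthetic data

The expression generator draws gene variances from the same scaled
inverse-chi-square prior the moderated-t stage assumes and adds the
programmed logFC to the BE group mean; it emulates the two-group biopsy
design (default scale: 7 samples per group, matching the smallest packaged
comparison; d₀ = 4, s₀² = 0.05, plausible microarray values).  It does not
emulate probe-level artifacts, normalisation effects, between-array
correlation or annotation noise — passing recovery tests therefore
validates the estimators under the assumed model, not robustness to real
microarray pathology.

The Ct generator produces replicate threshold cycles Ct = base_ct −
log2(fold) + N(0, noise_sd²), with reference genes fixed at fold 1 and
designated `na` genes always missing.  Replicate noise for real assays is
not published; the default noise_sd = 0.15 cycles is a modelling choice in
the typical range for TaqMan technical replicates.  The default design is
3 replicates and 3 samples per condition (5 where the recovery tests say
so).  Amplification-efficiency differences, plate effects and melt-curve
failures are not modelled.  In the noiseless limit the downstream pipeline
recovers ΔΔCt = −log2(fold) exactly, which the tests assert.

`ct_spec_from_calls` encodes a set of direction calls as a simulation spec
(up → fold 4, down → fold 0.25, no_change → 1, na → never amplifies, nd →
left off the assay); with zero noise the full pipeline reproduces the
encoded profile exactly, giving an end-to-end identity between the
fixture-based and simulation-based concordance reports.

## Numerical and interface conventions

* All randomness flows through one `numpy.random.default_rng(seed)` per
  call; identical spec + seed gives byte-identical outputs, and the
  pipeline's report JSON is byte-stable across reruns.
* p-values are two-sided throughout.
* Probes with zero residual df are dropped with a warning; all-zero
  variances raise a degenerate-variance error.
* Gene labels are canonicalised on input: the combined keratin-6 row is the
  single entry KRT6, MUC3 is an alias of MUC3A/B, and case is folded
  upward.  The published arrow symbols (↑ ↓ ↔, n.a., n.d.) are accepted on
  input and serialised as ASCII tokens.
* The problem sizes used by the test and acceptance runs (2000-gene
  matrices, 50-seed recovery loops, 200-seed RQ recovery, 10⁶-draw
  Monte-Carlo oracle) were chosen as the smallest scales at which the
  stochastic envelopes are stable.

## Known limitations

* The selection stage consumes pre-tabulated evidence (gene, dataset,
  logFC, adjusted p, presence) or expression matrices in the package's TSV
  format; it does not fetch or parse GEO series archives.
* Dunnett comparisons assume homoscedastic groups (pooled variance), as the
  classical procedure does.
* Concordance is reported as raw percentages without a significance test,
  matching the analysis it implements; weighting genes by effect size is
  out of scope.
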