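# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the known limitations of `phyloexpress`.

## Study design assumed throughout

Each of S species contributes two treatment groups (PBS control vs alum
stimulus) of head-kidney 3'TagSeq samples quantified against a
species-specific reference transcriptome. 3'TagSeq counts are proportional to
transcript abundance and independent of transcript length, so no length
correction is applied anywhere. Transcripts are grouped into orthogroups
(many-to-one per species); all cross-species statements are made at
orthogroup level, restricted to the "core" set with at least one copy in
every species. The ordinal fibrosis score (0–3) is carried as sample metadata
only; no stage models it.

## Normalization and aggregation

Size factors are DESeq2's median-of-ratios, computed within species: for each
sample j, `s_j = median_t count(t, j) / geomean(count(t, ·))` over the
reference transcripts with strictly positive counts in every sample, then
rescaled to geometric mean 1. The median is taken on the ratio scale (for an
even reference count this differs in the 5th decimal from the log-scale
median some implementations use; the package's tests pin the ratio-scale
definition). When no transcript is positive everywhere the default is an
error; an explicit flag enables a pseudo-reference over transcripts positive
in at least half of the samples.

The orthogroup expression matrix is built in the stated order — normalize
first, then sum normalized transcript values per orthogroup per sample.
Aggregation is linear and is tested against masked brute-force sums.
Unassigned transcripts are excluded from orthogroup matrices but retained for
transcript-level work; the unassigned fraction is reported per species.

## Differential expression

Per species, each unit (transcript or orthogroup) is tested with a
negative-binomial Wald test: log-link GLM `counts ~ treatment` with
`log s_j` offsets and Var = μ + αμ². Because the single-factor design is
saturated, the GLM MLE decouples into one 1-D Newton solve per treatment
group (solved in the group log-mean; Fisher information Σ μ/(1+αμ) gives the
SE), which the package vectorizes across all units; tests verify equality
with `statsmodels` GLM fits. lfc is reported in log2 with alum as numerator;
p-values are two-sided normal tails of lfc/SE; BH adjustment counts only
non-missing hypotheses.

Dispersion is estimated by method of moments on normalized counts, pooled
across the two groups by residual degrees of freedom, then moderated by a
trendless empirical-Bayes step: log dispersions are shrunk toward the
across-gene median with weights given by the trigamma approximation of the
sampling variance against a prior variance (observed spread minus sampling
noise, floored at 0.25²). The moderation exists because the raw plug-in
estimator is visibly anticonservative at this study's group sizes (5–6
samples per group); with it, the permutation-null type-I rate at nominal 5%
moves from ~8% to ~6–7% under the generator's conditions. The residual
anticonservatism is a property of the Wald approximation itself at these
group sizes — the full DESeq2 machinery shows the same direction on identical
data — and should be kept in mind when interpreting absolute significance
counts; relative quantities (signs, rankings, cross-species correlations of
Wald statistics) are unaffected. Deliberately omitted relative to DESeq2: the
mean-dispersion trend, lfc shrinkage, independent filtering, and Cook's
outlier handling.

Orthogroup-level DE takes the summed normalized matrix, rounds half-to-even
to integers, and re-estimates size factors on that matrix — i.e. it treats
the summed matrix exactly as a count matrix handed to the estimator. Two
significance conventions coexist deliberately: `alpha_screen = 0.1` on raw p
for the ANOVA screen fractions, and `alpha_de = 0.1` on BH-adjusted p to
define the DE transcript sets fed to GO enrichment.

## Effect-size decomposition

Per orthogroup, OLS of summed normalized expression (untransformed by
default; `log1p` available) on `treatment + species + treatment:species`.
Type-II sums of squares by model comparison — SS(treatment) =
RSS(species) − RSS(species + treatment), etc. — which remains correct under
the mild imbalance of the 158-sample design; all orthogroups share one
design, so the four model projections are QR-factorized once and applied to
the whole matrix. η² = SS_effect / SS_total; on a balanced design the three
effects plus the residual share sum to 1 (tested at 1e-10), and the residual
df is N − 2S (130 for 158 samples and 14 species). Interpretation caveat: the
interaction carries S−1 noise degrees of freedom against the treatment's one,
so under weak effects interaction η² exceeds treatment η² even without any
true interaction; the regime tests therefore contrast strong effect scales
(2.0 vs 0.1 in log2).

## Cross-species correlations

Pairwise species similarity is the Pearson correlation of per-orthogroup Wald
vectors (pairwise-complete over finite entries; pairs with fewer than 3
shared units are flagged). The distribution of the S(S−1)/2 correlations is
tested against zero with a one-sample two-sided t-test. The pairs share
species and are not independent, so this t-test is anticonservative by
construction; it is implemented this way because it is the field's standard
summary for this design, and the caveat transfers to any use of its p-value.
The |lfc|–copy-number correlation pools (orthogroup, species) pairs with at
least one copy.

## GO enrichment

Per species, the universe is the annotated, tested transcripts; each GO term
gets a 2×2 table of DE × term membership. The two-sided exact p sums all
hypergeometric point masses ≤ the observed one, and the odds ratio is the
conditional MLE of the noncentral hypergeometric — both matching R's
`fisher.test`, stated explicitly because two-sided exact tests have competing
definitions. Boundary tables: a = 0 gives OR 0, b or c = 0 gives ∞, degenerate
margins give NA. Cross-species comparison correlates raw odds ratios over
shared terms (matching the axes of the published figure this mirrors);
infinite ORs are excluded by default, with a Haldane-corrected sample-OR
policy as the alternative; a log-OR option exists for robustness work. No GO
graph propagation is performed.

## Congruence (MAST / Icong)

The top k (default 30) orthogroups are ranked by the maximum |Wald| over
species (ties by orthogroup id). Species profiles over those orthogroups are
clustered with Euclidean distance and complete linkage — the defaults of the
R heatmap function this mirrors; both the ranking statistic and the linkage
are config keys since the source analysis does not state them. The rooted
MAST of the dendrogram and species tree is computed by the standard dynamic
program over node pairs (match the two child pairings or drop a child;
exhaustive-search-verified at 6 leaves). Icong divides the observed MAST size
by its Monte-Carlo expectation for independent Yule topology pairs on the
same leaves, and the p-value is the add-one randomization estimate
(1 + #{null ≥ obs}) / (n_null + 1), which keeps p in (0, 1]. A
leaf-permutation null is available as a flag.

## Pagel's λ

Response: the per-species orthogroup Wald statistic (lfc optional). The tree
correlation C comes from shared root-to-MRCA path lengths scaled to unit
diagonal. The model `y = μ + u + e`, `u ~ N(0, σ²_p C)`, `e ~ N(0, σ²_e I)`
gives marginal covariance (σ²_p + σ²_e)(λC + (1−λ)I) with
λ = σ²_p/(σ²_p + σ²_e) — so the variance-ratio definition used here coincides
with the classical λ-transform parameter. Estimation is a fully conjugate
Gibbs sampler run in the eigenbasis of C, where the u-update is diagonal;
this lets all orthogroups (which share C) run as one vectorized batch.
Priors: inverse-gamma(0.001, 0.001) on both variances (MCMCglmm-style);
prior sensitivity is exercised in tests via the prior-matched calibration
check, which also validates the sampler (95% CI coverage within 0.95 ± 0.03).
Chains default to 1,000 burn-in + 20,000 iterations thinned by 10 — sized so
a 500-orthogroup batch runs in seconds — with the longer 10,000/600,000
schedule available in config. Split-R̂ of the λ chain is reported per unit
and values above 1.1 are flagged.

DIC uses the observed-data (marginal) deviance — u integrated out, cheap in
the eigenbasis — for both the full and the reduced (no-u) model, with
Spiegelhalter's p_D. The conditional-deviance focus was measured to prefer
the full model on ~90% of pure-noise units (the plug-in deviance at the
shrunk posterior-mean u yields incoherent p_D) and was rejected; with the
marginal focus, pure noise prefers the reduced model and strong Brownian
signal the phylogenetic model in clear majorities, which is the comparison
the method needs. ΔDIC = DIC(reduced) − DIC(full), positive favoring
phylogeny. Signal classes: negligible (λ ≤ 0.05), weak (≤ 0.2), moderate
(≤ 0.4), strong (> 0.4), boundaries to the lower bin.

The ML cross-check profiles μ and total variance analytically and maximizes
the resulting 1-D likelihood over λ ∈ [0, 1] (bounded search plus endpoint
checks); it reproduces `phytools::phylosig(method="lambda")` to four decimals
on fixture data. A flat profile (star tree, C = I) is flagged unidentifiable.
Small-sample behavior to be aware of with S = 14 species: the Gibbs posterior
mean of a bounded ratio is shrunk away from the endpoints (≈ 0.27 at truth 0,
≈ 0.80 at truth 1 under high signal), while the ML estimate piles on the
boundary (mean ≈ 0.36 at truth 0.5). Neither is an implementation defect —
coverage is calibrated and the ML matches its reference — but point estimates
at S = 14 should be read alongside their (wide) intervals.

## Synthetic data generator

The generator draws, per orthogroup g, species s, sample j with treatment
indicator x:

    counts(t, j) ~ NB(mean = s_j · w_t · exp(b_g + u_{g,s} + x·ln2·(β_g + δ_{g,s})),
                      Var = μ + αμ²)

with baseline b_g ~ N(4.6, 1.2²) on the natural-log scale (≈100 counts),
species effects u ~ N(0, 1²), shared treatment lfc β_g ~ N(0, τ_t²) in log2,
interaction deviations δ_{g,·} ~ MVN(0, τ_i²·(λC + (1−λ)I)) centered to
sum to zero across species (so treatment and interaction variance are
identifiable in the ANOVA sense; the centering projects the covariance, and
tests compare against the projected matrix), per-sample size factors
lognormal(0, 0.4²), NB dispersion α = 0.3, and symmetric-Dirichlet transcript
weights w within each orthogroup × species. Copy numbers are zero-truncated
geometric (mean 1.5) for core orthogroups; non-core orthogroups have 1 to
S−1 species zeroed out. GO terms are assigned at random (70% of transcripts
annotated, ≈3 terms each from a 300-term vocabulary), with an optional bias
of a 10% term block toward truly DE transcripts. A spike mode replaces the
Gaussian β with ±`de_lfc` on a `de_fraction` of orthogroups for FDR studies.

Defaults are the study conditions: 14 species, 158 samples split as evenly as
possible over the 28 species × treatment cells (18 cells of 6, 10 of 5),
interaction scale (0.5) above the shared-treatment scale (0.25), λ = 0.5. The
desk-scale orthogroup count is 2,000 with 85% core; the real study's ~73k
orthogroup universe with ~10% core is not emulated — the analysis operates on
the core set either way, and problem sizes were chosen so the full pipeline
and test suite run in minutes on one CPU. Species trees are Yule (pure-birth)
with tips extended by one extra waiting time, so all branch lengths are
strictly positive.

What the generator does not emulate, and hence what passing tests cannot
show: read-level noise and mapping ambiguity, 3' coverage bias, between-
transcript correlation within an orthogroup beyond shared means, GO term
semantics and the GO DAG, batch structure, and any dependence of expression
on the fibrosis phenotype. Conclusions about those require real data.

## Numerical choices

- NB group fit: Newton in the log-mean, 60 iterations max, steps clipped to
  ±3, convergence at 1e-12; all-zero groups yield flagged NA rows rather than
  infinite lfc.
- Dispersion bounds: α ∈ [1e-8, 100].
- Rounding of summed matrices: half-to-even (pandas/numpy `round`).
- Type-II SS: tiny negative SS from floating-point cancellation are clamped
  at 0; constant responses are flagged, not tested.
- Eigen-decomposition of C: eigenvalues below 1e-10 trigger a 1e-8 jitter
  with a warning.
- Ties in the top-k ranking and clustering: broken by orthogroup id and by
  species label order respectively, so every pipeline stage is deterministic
  given its seed.
- Randomization p-values use the add-one estimator; every stochastic stage
  derives its own sub-seed from the global seed via `SeedSequence` and
  records it in the run manifest.

## Limitations

- Absolute significance counts at 5–6 samples/group inherit the Wald
  approximation's anticonservatism (above); screens at raw p < 0.1 are best
  read as descriptive fractions, as in the source analysis.
- The pairwise-correlation t-test treats dependent pairs as independent (a
  documented convention, not a recommendation).
- λ point estimates at S = 14 are weakly identified; the credible intervals,
  ΔDIC, and the cross-estimator agreement are the robust outputs.
- Orthogroup summation mixes paralogs; the copy-number correlation check
  quantifies, but does not remove, copy-number effects on lfc.
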