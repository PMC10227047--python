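# Methods

This note documents the models and procedures implemented in
`speechsyntax`, the assumptions behind the synthetic-data generator, the
parameters that matter, and the numerical choices made where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Syntax metrics

Annotations are sentence-level: token count, a coordination flag, and a
flat multiset of subordinate clauses over the fixed 13-type taxonomy
(temporal, local, modal, causal, conditional, adversative, final,
consecutive, concessive, comparative, relative, complement,
indirect_question).  Embedding depth is deliberately not represented; a
sentence with four embedded clauses of one type contributes 4 clause
tokens and 1 distinct type.  Sentence categories overlap in one direction
only: a sentence may be both coordinated and complex, while *simple* means
neither.  Because of that overlap, simple + coordinated + complex rates
sum to ≥ 1, with equality exactly when no sentence is in both categories
— this is asserted as a property test.

Aggregation choices that the measure definitions leave open:

- **Weighted sum normalization.** The per-sentence score (clauses ×
  distinct types) is aggregated by summing over sentences and dividing by
  the total number of sentences, consistent with the other per-sentence
  measures and with the scale on which group values of this measure are
  conventionally reported (≈ 0.7–1.3, bracketing the extended relative
  sum).
- **Per-type rates** count *sentences containing* the type over total
  sentences (sentence-level); clause-token rates are exposed separately
  (`clause_token_rates`) because both conventions are defensible.
- **MLU** is the ratio of totals (words / sentences) per transcript; group
  MLU is the mean of per-transcript MLUs.
- **Types / TTR** use case-folded word strings, no lemmatization.
- Missing values (MLU of an empty transcript, pure complexity of a
  transcript without complex sentences, TTR without word strings) are
  explicit `None`/empty cells, never 0.

## 2. Synthetic cohorts

The generator emulates a three-group cross-sectional study (SSD n=34, MDD
n=38, HC n=40) at the level of its published group means and SDs — the
five syntax measures, the descriptives, six clinical covariates (semantic
/ phonemic / alternating verbal fluency, verbal episodic memory, negative
FTD = SANS alogia, positive FTD = SAPS positive formal thought disorder),
and demographics (age, sex, education).

Per participant, a latent syntax severity `z ~ N(0,1)` drives:

- the sentence-category mixture: the total complex probability is tilted
  on the logit scale (`severity_complexity_scale = 0.45` per unit z, set so
  the between-participant SD of the relative sum matches the published
  SDs once binomial sampling noise at ~60–80 sentences is added);
- subordination depth: complex sentences embed `1 + Poisson(lam)` clauses,
  `lam = extra_subordinates_mean · exp(0.5·w − 0.125)` with
  `w = 0.4·z + sqrt(1−0.16)·ξ` — a mean-preserving log-normal tilt whose
  severity-alignment (0.4) was chosen so that the covariance between
  complex-sentence rate and clauses-per-complex-sentence reproduces the
  small gap between the published extended relative sum and the product of
  relative sum and pure complexity, while the idiosyncratic part keeps the
  pure-complexity SD realistic;
- clause types: participant-specific propensities drawn from a Dirichlet
  centred on the group type distribution (concentration 15–26 by group).
  This heterogeneity is essential: with i.i.d. type draws every speaker
  would eventually use every frequent type and transcript-level diversity
  would overshoot the published means by several tenths of an SD.  Types
  printed as 0.00 in the source table keep a small positive floor
  (0.0035–0.014) so diversity has the right ceiling behaviour.  Within a
  sentence, each clause after the first repeats an already-used type with
  probability `type_repeat_prob` (0.10–0.12), which sets the
  weighted-sum/extended-sum ratio without disturbing diversity;
- covariates: `value = mean + sd·(κ·d·z + sqrt(1−κ²)·ε)` with coupling
  `κ = cross_domain_coupling` (default 0.3; a free parameter — the source
  study reports no syntax–covariate correlations beyond network edges),
  direction `d = +1` for cognition and `−1` for FTD, and residuals `ε`
  correlated 0.4 within the neuropsychology and psychopathology blocks and
  uncorrelated across blocks.  The two FTD scales are bounded below by 0
  and are sampled as zero-censored normals whose latent mean/SD are
  moment-matched (via `fsolve`) so the *censored* moments hit the
  published values — naive truncation would bias the HC means upward by
  more than half an SD.  Education couples to severity with loading 0.75,
  which together with the between-group gradient reproduces a pooled
  education–diversity correlation of ≈ 0.33; age and sex are independent
  of severity, as no such associations are reported.

Word tokens are Zipf-distributed over a synthetic 5 000-word vocabulary
(exponent 1.15), chosen so type counts and TTR at ~1 000–1 200 tokens per
transcript land on the published values.  The tokens are distributional
stand-ins, not German.

Calibration was done once by simulation at n = 4 000 per group, adjusting
the baseline complex probability, mean extra subordinates, Dirichlet
concentration and repeat probability; the frozen defaults reproduce all
five headline group means within 0.1 printed SD at large n (property
test at n = 2 000) and within 0.5 SD at the published sizes (acceptance
tests).  Correlation *among* the five syntax measures is never imposed; it
emerges from the shared latent severity, which is the central modelling
choice of the module.

**Cluster mode** replaces the diagnostic groups by four latent complexity
profiles (mixing proportions 39/19/20/34 out of 112) realised as severity
offsets on a size-weighted pooled parameter set.  The default offsets
(2.7, 1.3, −0.7, −3.4; within-profile SD 0.1) are deliberately uneven:
the severity→measure mapping is exponential in the subordination channel,
so equal latent spacing would give one huge gap at the complex end and
overlapping clusters at the simple end.  In cluster mode subordination
depth is driven fully by the profile (alignment 1.0), making the planted
partition identifiable from the syntax features.  Coupling defaults to 0.6
so clusters also differ in covariates.

What passing tests on these cohorts do *not* show: real speech has
annotator noise, topic effects, non-Zipf lexicons, and type distributions
that are neither Dirichlet nor stationary within a speaker.  The synthetic
cohorts validate the *pipeline*, not clinical effect sizes.

## 3. Group statistics

Omnibus comparisons run one-way ANOVA when Shapiro–Wilk passes in every
group and Levene's test does not reject homogeneity, both at α = 0.05
(the gate threshold is a convention; the source procedure states only
that the nonparametric path was used when assumptions failed), otherwise
Kruskal–Wallis.  Effect sizes: η² = SS_between/SS_total for ANOVA and
η²_H = (H − k + 1)/(n − k) for KW.  Bonferroni multiplies the raw p by the
family size, which defaults to the number of rows in the emitted table
(the published table's divisor is not stated).  Post-hoc tests (Tukey HSD
/ Dunn-with-Bonferroni) run only when the corrected omnibus p < 0.05.
Dunn's test is implemented directly (rank z-tests with tie correction)
as no post-hoc package is among the dependencies.

## 4. Classification

Linear SVM (C = 1) on the five syntax measures, stratified random 2-fold
CV repeated 200 times (400 fold accuracies).  C, standardization and
stratification are unstated in the source procedure and set to
field-standard defaults; standardization is computed on the training fold
only, and a regression test verifies the protocol differs from (and never
silently degrades into) full-data scaling.  Rows with undefined pure
syntactic complexity are mean-imputed within the training fold by default
(`missing="impute"`), with `"drop"` available; imputation is the default
because dropping can unbalance small cohorts.  The permutation p-value is
`(1 + #{null ≥ observed}) / (1 + n_perm)` over label permutations; each
permutation re-runs the CV with a reduced repetition count (default 20) to
keep 1 000 permutations tractable — passing `null_reps=n_reps` restores
the fully exchangeable protocol, which the calibration test uses.

## 5. Clustering

The reference implementation of the source procedure used a random-forest
clustering whose internals are not fully specified; since its model
selection criterion was the BIC, the primary method here is a Gaussian
mixture (full covariance, 25 restarts per k, BIC = p·ln n − 2·lnL,
smaller is better) on z-scored features.  A random-forest-proximity +
PAM-medoids route is provided as an optional alternative at fixed k.
Numerical choices: component covariances carry a variance floor
(`reg_covar = 1e-4` on standardized features) because syntactic diversity
is a lattice (multiples of 1/13) and an unfloored component can collapse
onto a single lattice value and send the likelihood to infinity; rows are
sorted by participant id before fitting so results are invariant to input
order; a k whose fit fails is recorded with infinite BIC.  Clusters are
relabelled by descending mean relative sum of subordinate clauses, so
cluster 1 is always "extremely complex" and the last "slightly complex".
The diagnosis × cluster interaction per measure is the partial F-test of
the main-effects OLS model against the model with the interaction.

## 6. Networks

Eleven nodes: the five syntax measures, four neuropsychological scores and
the two FTD ratings.  The Pearson correlation matrix feeds a graphical
lasso along a 100-point log-spaced penalty path from `max |r_ij|` down to
1% of it; the penalty is selected by EBIC with γ = 0.25 ("tuning parameter
0.25" is read as the EBIC hyperparameter, the standard reading; γ = 0
reduces to BIC and the γ = 0.5 network is never denser — both are property
tests).  Edge weights are the regularized partial correlations
`−κ_ij/√(κ_ii κ_jj)`.  Input correlations are Pearson on raw scores (no
nonparanormal transform).  Centralities: strength Σ|w|, expected influence
Σw, and shortest-path closeness/betweenness with edge length `1/|w|` on
the nonzero-edge graph; closeness in a disconnected graph is computed
within the node's component and scaled by the share of nodes reached
(isolated node → 0), betweenness is the raw path count.  The ±0.1 edge
threshold affects display files only; stored weights are unthresholded.
Edge stability uses a case-resampling bootstrap (the nonparametric scheme;
resamples that fail estimation are dropped and counted, > 10% failures is
an error).  Layout is Fruchterman–Reingold with |w| as attraction, scaled
to the unit square; a single node sits at (0.5, 0.5).

## 7. Problem sizes and reproducibility

All randomness flows from explicit seeds (numpy `SeedSequence`;
per-participant streams derive from the master seed, so cohorts are stable
under subsetting).  The test suite and the acceptance script use
desk-scale sizes chosen to keep Monte-Carlo error well inside the asserted
tolerances: calibration properties at n = 2 000 per group; permutation
calibration over 200 null datasets with 59 permutations of a 3-repetition
CV (fully exchangeable); support recovery at n = 500 with a planted
max-degree-2 precision matrix (unit diagonal, partial correlations 0.3,
hence positive definite by diagonal dominance); bootstrap checks at
B = 60.  The acceptance script averages each stochastic cohort-level
quantity over six replicate cohorts at the published group sizes.

## Known limitations

- The generator matches first and second moments per group, not higher
  moments or item-level structure of the clinical instruments.
- The weighted-sum aggregation and the Bonferroni family are documented
  inferences, not published specifications.
- BIC values, cluster sizes and centralities of the original participant
  data are not reproducible from synthetic cohorts and are not targeted;
  the pipeline reproduces the *qualitative* pattern (SSD least complex,
  HC ≈ MDD, four complexity clusters, extended relative sum as the
  strongest network node).
- Whether the source study's per-type table rates count sentences or
  clause tokens is ambiguous; sentence-level is primary here, and both are
  computed.
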