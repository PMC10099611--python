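# Methods

## The design and its data

The package models a replicated split-plot field experiment: `p` plots
(default 6), each containing one **ambient** and one **addition**
(fertilized) subplot, with ~100 focal individuals of a single annual plant
species per subplot. Individual records carry four traits — height (mm),
leaf count, specific leaf area (SLA, mm² mg⁻¹), and first-flowering day —
plus total fruit count `W` (lifetime fitness through female function), a
herbivory flag, and a fitness-exclusion flag for individuals whose fruits
could not be counted reliably (they stay in trait-only analyses). Survival
is derived, not stored: an individual survived to reproduction iff
`fruit_count > 0`, which prevents a stored flag and the counts from
disagreeing. Subplot-level inputs are species-biomass harvests and PAR
readings by canopy height.

## Selection estimation

Traits are standardized to mean 0, sample SD 1 (ddof = 1) **within
subplots**, and fitness is relativized to mean 1 within subplots including
the zeros — the scale on which neighbouring individuals actually compete.
Selection differentials `S_i` come from separate regressions of `w` on one
standardized trait; gradients `β_i` from the joint regression on all four.
The mixed backend (`method="mixed"`) fits statsmodels `MixedLM` with a
subplot random intercept and *independent* random slopes (a diagonal
random-effect covariance; with 12 subplots a full covariance is poorly
identified). Per-subplot coefficients default to fixed + conditional modes
(BLUPs); `per_subplot="subplot_ols"` switches to independent subplot-wise
OLS fits. The pooled backend (`method="pooled"`) is closed-form OLS on the
pooled standardized data; because traits are centred within subplots this
equals the precision-weighted average of subplot regressions, and it is the
backend each bootstrap replicate uses at scale.

Joint models use complete cases; differentials use each trait's available
cases. Individuals that never flowered have no flowering date and are
excluded from models that involve that trait — note this conditions the
complete-case joint model partly on survival, which measurably shifts its
estimand (see *Oracles*). Gradients are estimated on linear-scale
standardized traits; the sqrt/log variance-stabilizing transforms apply
only to the trait-mean treatment tests. Quadratic gradients are reported as
**twice** the squared-term regression coefficient (recorded in the output
metadata); correlational gradients are the cross-term coefficients. A joint
design matrix with condition number above 1e6 attaches a collinearity
warning rather than refusing.

## Fitness model

Fecundity is zero-inflated and overdispersed, so treatment effects on
fitness use a hurdle: a binomial mixed model for survival (logit link,
plot and subplot random intercepts) and a zero-truncated negative binomial
(log link) for survivors' counts. statsmodels has no maximum-likelihood
binomial GLMM, so the zero part uses `BinomialBayesMixedGLM` (variational
Bayes; the Wald statistic is formed from the posterior mean/SD, and the
objective's internal use of the legacy global RNG is pinned so reruns are
bit-identical), with a plot-blocked fixed-effects GLM fallback. No mixed
zero-truncated NB exists in statsmodels either; the count part is
`TruncatedLFNegativeBinomialP` with plot as a fixed blocking factor,
warm-started at the Poisson GLM solution (the truncated-NB likelihood
diverges from a cold start on overdispersed counts). Every result records
the method actually used. EMMs are back-transformed (inverse logit;
marginal standardization over plots for the count part).

## Resampling inference

*Cases bootstrap.* Each replicate resamples individuals with replacement
independently within every subplot (sizes preserved), re-standardizes,
re-relativizes, and re-runs the estimator; replicate `b` of subplot `i`
draws from `default_rng([seed, b, i])`, so ensembles are reproducible and
any replicate can be regenerated in isolation. Estimator failures are
recorded as NaN rows (kept, so replicate indices stay aligned) and an
ensemble with > 5% failures is flagged invalid. CIs are percentile with
linear interpolation between order statistics (the convention is recorded);
treatment differences pair replicate `b` of the two independent ensembles
and take percentile bounds of the per-pair differences, ordered
addition − ambient. A vectorized pooled-backend bootstrap reproduces the
generic path's draws exactly (pinned to 1e-10 in tests) and makes
B = 500–1000 ensembles cost seconds.

*PERMANOVA.* Pseudo-F uses the McArdle–Anderson trace form on the Gower
centring of the squared Euclidean distance matrix, which handles factor and
continuous predictors alike and reduces to the one-way ANOVA F for a
univariate two-group response (asserted to 1e-9 against an independent
oracle, and cross-checked against scikit-bio's statistic). Permutations
shuffle the predictor within plot blocks; with all blocks of size 2 and at
most 4096 relabellings the restricted set is enumerated exhaustively and
`p = #(F* ≥ F)/2^k` (identity included, so p ≥ 1/64 for six plots);
sampled schemes use the add-one rule. Degrees of freedom are reported as
(1, n_subplots − 2); the blocking restricts the permutation null rather
than adding a model term, and a config switch allows free permutation
instead. Exchangeability simulations (500 null studies) put the rejection
rate at nominal 0.05 within [0.01, 0.09] — the grid of attainable p-values
makes exact 5% unattainable.

*Multiplicity.* Bonferroni families mirror the analysis structure: 4
(community metrics; trait means), 3 (community-metric associations), with
the per-test α recorded in each result.

*Small-sample reference.* Treatment and covariate tests on subplot-level
responses report the Wald chi-square statistic but take their p-value from
a t reference with plots − 1 degrees of freedom: on 12 values from 6 plots
the chi-square reference has measured size ≈0.09 at nominal 0.05, while the
paired-design t restores calibration (≈0.04, verified by simulation in the
test suite). Individual-level models, where the Wald approximation is
adequate, keep the chi-square reference.

## Opportunity for selection

`I = var(w)` per subplot over all fitness-eligible individuals, computed
identically as `var(W)/mean(W)²` (the equivalence is asserted to 1e-9 on
every input). Its N-treatment LMM also reports the plot variance share
`var(plot)/(var(plot)+var(residual))` from the REML fit — a
variance-component ratio whose convention is stated in the output, since
"share of variance" is not unique. Three documented constructor helpers
realize the textbook scenarios in which raising mean fitness lowers
(absolute gains), preserves (proportional gains), or raises (gains
concentrated in high-fitness individuals) the opportunity for selection.

## The synthetic generator

`SyntheticParams` defaults *are* the study conditions: 6 plots × 2
subplots × 100 individuals; trait means per treatment (height 262/397 mm,
leaf count 5.32/6.05, SLA 28.0/31.1 mm² mg⁻¹, flowering shifted +4 d);
treatment-specific trait correlation matrices (both positive definite);
survival logits targeting ≈84.3%/81.5%; survivor fecundity means ≈28.9/106
(the log-mean intercept subtracts `½β'Rβ` plus the cluster-shift variance
so the stated values are *marginal* means despite the selection term);
negative-binomial dispersion k = 0.8 (strong overdispersion, var =
μ + μ²/k); herbivory 13%/18%; ANPP ≈430/900 g m⁻²; Dirichlet species
shares with lower evenness under addition; PAR declining at 0.020/0.035
ln-units cm⁻¹. Where the field values were not stated (trait SDs,
dispersion, plot/subplot shift SDs = 0.25/0.10 trait-SD units and
0.30/0.15 on log fecundity, PAR noise), magnitudes were chosen once as
field-realistic and are fixed defaults. Selection enters both the survival
logit (scaled by 0.3) and the log fecundity mean, with coefficients on the
within-subplot standardized scale.

Two fitness surfaces: `"hurdle"` (the field model, default) and
`"lognormal"` (`W = exp(β'z) ×` noise), for which Stein's lemma makes the
population gradient exactly `β` and the differential vector exactly `Rβ` —
the oracle surface for estimator identities and coverage checks.

*Oracles.* `expected_differentials` returns `Rβ`. `hurdle_nb_moments`
gives the closed-form marginal mean/variance when no selection operates.
`mc_total_gradients` is the brute-force ground truth for what the pipeline
estimates: it simulates a large trait sample, forms
`E[W|z, survival] = survival · μ(z)/(1 − p₀(μ(z)))`, relativizes over
everyone and regresses on z; with `complete_case=True` the regression is
restricted to individuals that would enter the joint model (dead plants
missing a flowering date drop out), which raises the estimand noticeably —
e.g. 1.026 vs a nominal 0.9 height gradient under default missingness.
Parameter-recovery tests compare estimates to this oracle, not to the
nominal coefficients.

*What the generator does not emulate*, hence what passing tests do not
show about real data: no spatially explicit competition or growth dynamics
(light asymmetry appears only as its metric signature); seedling-class
sampling imbalance is not reproduced (classes are assigned at the field
proportions but traits are drawn from the full distribution); and because
selection enters log-linearly with field-magnitude gradients, the
generated fitness distribution is heavier-tailed than the field data — the
per-subplot opportunity for selection runs higher (roughly 2–30 across
subplots) than values typical of such experiments (≈1–3). Estimates and
tests behave correctly on this harder distribution, but absolute I levels
should not be read as field-calibrated.

## Numerical choices and degenerate inputs

Sample (n−1) variances throughout. Missing values read as empty fields or
`NA`, written as empty. Zero within-subplot trait variance, all-zero
fitness subplots, single-height PAR profiles, nonpositive PAR, < 3 QC
pairs, and subplots absent from the design all raise typed errors naming
the offender. Mixed fits fall back (flagged) to paired-by-plot comparisons
(treatment tests on 12 subplot values), plot-demeaned OLS (covariate
models), or pooled OLS (selection models) when REML fails on the small
design. Ties in permutation F-values count as ≥ (tolerance 1e-12).

## Problem sizes in the test suite

The suite exercises: 100 randomly parameterized studies for the exact
standardization/relativization invariants; n = 5000/subplot for the
`S = Pβ` identity (tolerance 0.05); 50 replicate studies at n = 300 for
gradient recovery (mean absolute error < 0.1 per trait against the
Monte-Carlo oracle); 200 studies × B = 500 for bootstrap coverage
(observed 94.5%, band 93–97%); 500 null studies for PERMANOVA calibration;
and a byte-identical end-to-end rerun. These sizes are the package's
standing verification conditions.

## Known limitations

Percentile bootstrap intervals undercover when the fitness distribution is
extremely skewed (the default hurdle surface at small cluster counts shows
~88–93% instead of 95%) — a well-known small-sample property of the
percentile method, not of the clustered resampling; BCa or studentized
intervals are out of scope. The variational binomial GLMM gives
approximate Wald statistics. Mixed models on 6 plots estimate variance
components poorly; fallbacks are flagged rather than hidden. No genotypic
selection analysis, heritability prediction, selection-episode
partitioning of I, or environmental-covariance correction is attempted.
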