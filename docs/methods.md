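# Methods

## The analysis model

The unit of observation is the subject; the outcome attributed to subject
*i* is the number of affected members in *i*'s family (all cases,
non-aggressive cases, or aggressive cases, by endpoint), and the
covariates are *i*'s own dominant-coded carrier statuses.  This
convention — every genotyped member of a family, cases included, carries
the family count — is what makes the contingency-table column totals
equal subject counts, and it is the convention the fitted intercepts
imply (exp(1.1878) ≈ 3.28 matches the subject-weighted mean family case
count, not the family-weighted 228/76 = 3.0).  The Poisson models are
fitted by maximum likelihood assuming independent observations; the
consequences of that assumption are analysed below.

Dominant coding: carrier = at least one copy of the declared risk
allele.  Risk alleles are mandatory configuration because the literature
itself is inconsistent about which rs10486567 allele confers risk; the
package never guesses.

Missing genotypes are never imputed.  Model fits are complete-case on
the union of required covariates, with the surviving row indices
(`kept_rows`) carried through to the report manifest so every n is
auditable; on the fixture cohort the two-locus models use 943 of 947
subjects (4 lack the rs10486567 genotype), single-locus rs4242382 models
use all 947.

## The GLM engine

Fisher-scoring IRLS on the working response, log link (identity link
available as an additive-risk extension).  Numerical choices:

* initialisation β₀ = log(ȳ + 0.5), other coefficients 0;
* convergence when the relative deviance change < 1e-8 (max 100
  iterations); the deviance is non-increasing by construction — a full
  step that would increase it (or, for the identity link, leave the
  positive-mean region) is halved, up to 40 times;
* the linear predictor is clipped at ±30 before exponentiation;
* rank is checked by pivoted QR before fitting and collinear columns are
  named in the error;
* covariance = inverse Fisher information at the optimum; the reported
  log-likelihood includes the log y! term so AIC = −2ℓ + 2k is absolute;
* non-convergence returns the fit flagged `converged=False` with a
  warning, never an exception, so ladders can report partial results.

A family-clustered sandwich covariance is available behind
`fit_poisson(..., robust=True)`; it is an extension beyond the source
analysis, which treats subjects as independent.

The LRT clips 2Δℓ at zero and returns p = 1 for df = 0.  The
contingency chi-square is the Pearson statistic on the K×2 table
(df = K−1) via `scipy.stats.chi2_contingency` without continuity
correction; the original analysis does not name its test, so a
Cochran–Armitage-style trend test (scores = bin values, "k+" scoring k)
is provided as an alternative, and neither is claimed to reproduce the
source's secondary p-values (0.0383, 0.546) exactly.

## Epistasis classification

* **Multiplicative scale**: sign of β₃, gated by the
  additive-vs-multiplicative LRT at α (default 0.05, no multiple-testing
  correction by default; a Bonferroni divisor is available).
* **Additive (risk) scale, within-fit**: sign of
  λ̂₁₁ − λ̂₁₀ − λ̂₀₁ + λ̂₀₀ from the interaction fit.  With all-positive
  coefficients this contrast is necessarily positive (exp is
  supermultiplicative), so it mainly discriminates genuinely
  sub-additive joint effects.
* **Additive scale vs. single-locus marginals**: the joint risk
  increment λ̂₁₁ − λ̂₀₀ minus the sum of the two single-locus fits'
  increments.  This is the comparison under which a positive log-scale
  interaction can still look slightly antagonistic on the risk scale —
  at the published coefficients the within-fit contrast is +0.30 while
  this marginal contrast is −0.007 — and both are reported so the
  scale-dependence of "epistasis" is explicit rather than a single
  label.

Under the log link an age term multiplies all four fitted means by the
same factor, so classification contrasts are evaluated at age 0; their
signs are invariant to the age setting.  Penetrance profiles, which need
absolute rates, require an explicit age (callers typically pass the
cohort mean).

## Multiplex-family risk

P(Y ≥ k) = 1 − F(k−1; λ̂), the Poisson upper tail at the fitted rate —
the only construction consistent with "probability of at least k cases
predicted by the Poisson model".  At the published coefficients the
double-carrier vs double-noncarrier contrast for k = 4 is 0.527 − 0.394
≈ 0.13, i.e. a 13-percentage-point (1.33-fold) higher multiplex risk;
both the difference and the ratio are reported because either reading of
"13% higher risk" is defensible.

## The synthetic cohort generator

`simulate_cohort` draws: family sizes (default uniform on 9–16 members,
76 families ⇒ ≈947 subjects — the study's 2–6 range refers to *affected*
members per family, whose distribution {2:30, 3:26, 4:12, 5:6, 6:2}
emerges here from the Poisson outcome at the published coefficients,
mean ≈ 3 cases/family); founder carrier status per locus from the
Hardy–Weinberg dominant probability 1 − (1 − q)², q = 0.224 / 0.249;
each member copies the founder with probability `within_family_sharing`
(default 0.5) else draws fresh; the family case count
Y ~ Poisson(exp(β₀ + β₁G₁ + β₂G₂ + β₃G₁G₂)) with G the family's modal
carrier statuses, truncated at family size (the truncation fraction is
negligible at the default rates; a warning reports it when parameters
make it material); affected members uniform; aggressiveness Bernoulli
(0.25) among the affected; ages normal(62.3, 8) truncated at 40.
Genotype pairs are back-filled as AA : AG = q : 2(1−q) among carriers.
Sharing is phenomenological (copy-founder), not meiotic: the analysis
never uses pedigree structure, so Mendelian transmission is out of
scope, as are linkage disequilibrium between the loci (different
chromosomes) and realistic age-at-onset structure.  What passing tests
on these cohorts show is therefore that the *estimators* behave as
claimed under the model's own assumptions — not that real family data
satisfy those assumptions.

`fixture_table1` is a synthetic, fully deterministic reconstruction of
the published margins: subjects are allocated over (case-count bin ×
aggressive-count bin) cells by an integer transportation solution whose
row sums match the all-cases panel and column sums the aggressive panel
(refined so total aggressive cases come to 57 = 25% of 228), then
carrier statuses per locus are allocated by the same construction within
cells.  Joint structure the table does not constrain — who is a carrier
at both loci, which members are affected, ages — is fixed by arbitrary
deterministic conventions, so the fixture supports exact tabulation
checks but not inference about the real joint genotype distribution.

## Clustering: why two different LRT rates are reported

Attributing one family outcome to every member duplicates each family's
(y, G) roughly 12× when genotypes are shared within families.  The
subject-level likelihood then overstates the information by about the
family-size factor, Wald CIs shrink by its square root, and the naive
interaction LRT is strongly anti-conservative: in the fully-shared
replication regime the additive-vs-multiplicative LRT "rejects" ≈53% of
the time *under the null* and ≈57–61% at the published interaction
coefficient.  The published interaction statistic (χ²₁ ≈ 13.9 at
n ≈ 943) is reproducible in magnitude only in this regime — i.e. it is
dominated by the shared-outcome inflation, not by interaction
information, which at 76 effective families and β₃ ≈ 0.08 is modest.

The package therefore separates three regimes:

1. **Calibration** (`simulate_design`): independent per-subject Poisson
   outcomes, the regime where the likelihood is correctly specified.
   Here the interaction LRT attains its nominal level (empirical type-I
   ≈ 0.05 over 2000 replicates) and its null statistic is χ²₁ by a KS
   check.
2. **Replication** (`replication_preset`, sharing = 1): the naive
   subject-level analysis of fully genotype-concordant families —
   exactly the source design.  Its rejection rate is reported as the
   "replication power", always alongside the calibration rate so it
   cannot be mistaken for calibrated power.
3. **Recovery**: for coverage checks, fits collapse to one row per
   family (modal carrier status, `build_design(..., family_level=True)`),
   under which the Poisson likelihood is exactly the generative model;
   classical Wald 95% CIs then cover each published coefficient in
   ≈93–96% of 200 study-scale replicates.  With partial sharing (0.5)
   the member-level dominant code matches the family's modal code only
   ~75% of the time, attenuating subject-level coefficient estimates
   roughly 2× toward zero — a property of the design, not of the
   estimator, and the reason coverage experiments use the collapsed fit.

The cluster-robust sandwich covariance is the subject-level remedy and
is available behind a flag, but the headline replication keeps the naive
covariance because that is what the source analysis used.

## Problem sizes

Simulation studies use 50 random instances (oracle equivalence), 200
cohorts of 76 families (recovery and replication power; 300 in the
acceptance script), and 2000 null replicates of n = 943 (type-I) — sizes
at which the binomial noise on every reported rate is well inside the
bands being checked.

## Known limitations

* No overdispersion handling (quasi-Poisson/negative-binomial) and no
  family random effects; the truncation of Y at family size is present
  in the generator but ignored by the analysis model, exactly as the
  source's Poisson is.
* The secondary contingency p-values that depend on the source's unnamed
  test are not reproduced, only bracketed.
* Figures' numeric values are not targets; only the tail-probability
  construction behind them is implemented.
* PED input carries no ages, so age-adjusted models require the TSV
  format.
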