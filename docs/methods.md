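# Methods

## Statistical model

Association is tested one SNP at a time with a logistic regression of case
status on minor-allele dosage, P(y=1 | x) = σ(α + βx), and the Wald statistic
W = (β̂/se(β̂))² referred to χ²(1); p-values are two-sided throughout.  The
fit is a batch-vectorised Newton/IRLS: every SNP is a two-parameter problem
whose score vector and 2×2 observed information are accumulated by matrix
reductions over the whole genotype panel at once, so scanning thousands of
SNPs costs a handful of dense passes rather than thousands of solver calls.
Convergence requires the largest absolute coefficient update to fall below
1e-8 within 25 iterations; linear predictors are clipped at ±30 and IRLS
weights floored at 1e-12 for numerical safety.  Columns that fail to converge
(quasi-complete separation) or never vary are flagged `converged=False` with
NaN p-values and are treated downstream as insignificant — conservative with
respect to false positives.  The fit is checked against statsmodels GLM to
1e-6 relative tolerance in the test suite; statsmodels is never used in the
implementation path.

**The intercept.**  The model includes an intercept by default even though
the single-parameter form σ(βx) is the textbook minimal model: the
collaborating parties' case:control ratios differ *by design* in the
heterogeneity scenarios, and an intercept-free fit would absorb that
imbalance into β.  `intercept=False` restores the literal single-parameter
fit for users who want it.

The Cochran–Armitage trend test uses additive scores (0, 1, 2) and the score
variance R·C·(N·Σs²nᵢ − (Σsnᵢ)²)/N³, i.e. z² = N·r² with r the Pearson
correlation between score and case indicator; it is affine-invariant in the
scores.  The Bonferroni helper returns α/n.

## Protocol semantics

Phase 1 screens each party locally at `mu_phase1` (default 0.3; a
Bonferroni-level threshold here would discard weak true signals, the point of
the lenient value) and prunes the intersection of the parties' insignificant
sets.  Non-converged local fits count as insignificant; a party holding a
single phenotype class cannot screen and abstains (contributing the empty
set, so nothing is pruned on its account), while phase 2 still works as long
as the *pooled* sample has both classes — the case-only/control-only
collaboration remains valid.

Phase 2, per iteration T: the surviving SNPs are partitioned into batches of
at most `m` (default 300); when chromosome tags exist, batches are
chromosome-homogeneous and the leading chromosome rotates with T, removing
cross-iteration linkage cues.  Each party draws K individuals uniformly
without replacement — a fresh, independent draw every iteration, with no
case/control stratification; this is what makes the closed-form exposure
1 − (1 − K/N)ᵀ exact.  Columns are permuted with the batch's common seed
(identical across parties), rows with a party-private permutation, all
identifiers are stripped, and the (K × (m+1)) integer blocks go to the
server, which row-concatenates them and computes only on what it received
this iteration — server work is therefore O(T·K·m) fits, which the
implementation asserts by explicit fit-count accounting.  Labels are
l(i,T) = [p(i,T) ≤ mu_phase2], majority-voted across iterations with exact
ties resolved to insignificant; the run halts when the majority-label map is
unchanged between consecutive iterations (a window of one — the narrowest
reading of "labels remain constant") or at `max_iterations` (default 9).

`mu_phase1` and `mu_phase2` are independent knobs (defaults 0.3/0.3).  An
optional per-batch freeze (off by default) stops re-sharing a batch whose
labels were unanimous and unchanged over the last two iterations; no
principled freezing criterion exists in the literature we follow, so the
feature is opt-in plumbing.

**Seed discipline.**  All randomness derives from one `master_seed` through
named substreams (`("plan", T)`, `("rows", party, T)`, `("rowperm", party,
T, batch)`, ...) hashed into `SeedSequence` spawn keys, so any single stage
can be reproduced in isolation and two parties can never collide streams.

## Synthetic cohorts

Genotypes are Binomial(2, f) under Hardy–Weinberg equilibrium with per-SNP
MAF f ~ U[maf_low, maf_high], default [0.1, 0.5] so the conventional
MAF ≥ 0.1 QC filter holds by construction.  SNPs are independent: there is no
linkage disequilibrium, population structure, relatedness or missingness.
Phenotypes follow a liability-threshold model: `n_causal` SNPs (default 20)
receive standard-normal effects on standardised genotypes, the genetic score
is rescaled to variance h² (default 0.5), independent N(0, 1−h²) noise is
added, and the top-ranked individuals by liability become cases.  Ranking —
rather than thresholding at a prevalence — is used because the party
scenarios fix exact case counts.  Defaults were chosen to yield a mixture of
strong and weak signals so both protocol phases are genuinely exercised.

Five two-party scenarios (2400 individuals total) express increasing
phenotype heterogeneity by case:control split: (600:600, 600:600),
(450:750, 750:450), (300:900, 900:300), (300:900, 300:900) and
(600:600, 300:900).

**What passing tests do and do not show.**  Because SNPs are simulated
without LD, the pooled ground-truth set at p < 0.005 contains two
populations: strongly associated causal SNPs, and *borderline* members —
weak-effect causals and nulls that cross 0.005 by chance (≈ n·0.005 of
them).  On real genotype data, LD concentrates truth into blocks of strongly
associated SNPs instead.  Results on this benchmark therefore probe the
protocol's behaviour on a harder, more adversarial truth composition than a
real panel would present; see "benchmark numbers" below.

## Evaluation

Ground truth is the pooled single-SNP scan over all parties thresholded at
0.005 (Bonferroni available via the threshold helper).  Sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP); phase-1-pruned SNPs count as
predicted-insignificant (a variant restricting the denominator to phase-2
survivors is available, as the convention differs between reports).  The
harness scores the majority-label state after *every* iteration and reports
both the final iteration and the best one (max sensitivity + specificity),
the reporting rule used for iterative protocols of this kind; experiments
run 5 replicates by default and average.

The random-effects baseline combines per-party summaries — (β̂, se²) from the
logistic fit, or the trend-test z with unit variance — with the
DerSimonian–Laird estimator: τ² = max(0, (Q − df)/C) from Cochran's Q, then
inverse-(v+τ²) weighting.  DL is the canonical moment estimator and reduces
exactly to fixed-effects inverse-variance weighting at τ² = 0; REML is not
implemented.  Inestimable party effects (separation, constant columns) carry
infinite variance, i.e. zero weight.  The implementation agrees with R's
`metafor` to 9 decimals on the frozen fixture in the tests.

## Benchmark numbers and a known tension

On the balanced scenario (2000 LD-free SNPs, 20 causal, h² = 0.5, K = 500,
μ = 0.3, ≤ 9 iterations, truth at 0.005, 5 replicates) the package measures
mean best-iteration sensitivity 1.00 and specificity ≈ 0.89–0.92.  These two
numbers cannot both reach 1 on this benchmark under the protocol semantics
implemented here: with per-iteration labels at μ = 0.3, roughly 30% of
surviving null SNPs are labelled significant each iteration and majority
voting cannot drive that to zero (specificity caps near 0.9), whereas
labelling at the 0.005 truth threshold makes specificity ≈ 1 but drops
sensitivity to ≈ 0.4–0.55, because the borderline members of the truth set
are unrecoverable from a 1000-of-2400 subsample at a stringent threshold.
The gap is a property of the LD-free truth composition plus
per-iteration-only pooling, not of the implementation; both labelling
conventions are exposed in the configuration (`mu_phase2`), and the numbers
reported by `scripts/acceptance.py` use the default μ = 0.3 semantics.

## Privacy audit

Exposure: the audit records every sampled row set and reports, per party, the
cumulative fraction of individuals seen by the server after each iteration;
the closed form 1 − (1 − K/N)ᵀ is exact for fresh uniform draws (K=300:
43.75% and K=500: 65.97% after two iterations at N=1200).

Unshuffling adversary: a server knowing candidate reference MAFs estimates
each shuffled column's allele frequency (column mean / 2) and greedily
matches columns to the nearest unused candidate frequency, ties broken by
candidate order.  This is a deliberate *lower bound* on attack power — real
attackers can also exploit LD and public panels — and the audit reports
accuracy without pass/fail thresholds, since no quantitative privacy target
exists for this setting.  Expected behaviour, verified in tests: accuracy → 1
when frequency gaps dwarf sampling error (large K, coarse MAF grid), chance
level 1/m when candidates are indistinguishable, and well below 1 in the
protocol's operating regime (small K, continuous MAF band, hidden SNP ids).
Decoy columns drawn from reference MAFs can be appended via a config flag
(off by default).  The adversary code never touches party-private
permutations; the audit harness passes the true mapping in explicitly as
scoring ground truth.

## Problem sizes

Default experiment sizes used by the tests and the acceptance script: panels
of 1000–2000 SNPs × 2400 individuals with 5–10 replicates, Monte-Carlo
exposure with 1000 replicates, and 50 randomized 200×400 studies for the
pooled-equivalence property.  These sizes give stable means (binomial
standard errors well inside the asserted tolerances) while keeping a full run
in the low minutes on a single CPU.

## Limitations

* No LD, population stratification, relatedness, imputation or missing data;
  no quantitative traits; no covariates or mixed models.
* Actors are in-process objects honouring the information-flow contract;
  real networking, encryption, private set intersection and compression are
  out of scope.
* The unshuffling adversary underestimates a determined attacker (no LD
  exploitation, no membership-inference power analysis).
* The meta-analysis baseline reproduces the statistical method
  (CATT/logistic + DL), not any particular meta-analysis software.
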