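# Methods

## Model

`nagblup` fits genomic BLUP models in which the genetic value of an
individual is decomposed into additive, additive-by-additive epistatic and
dominance components:

    y = μ1 + Za + Zi + Zd + Wl + e

with a ~ N(0, G σ²_a), i ~ N(0, G#G σ²_aa), d ~ N(0, D σ²_d),
l ~ N(0, I σ²_l) (litter, an environmental effect shared by full sibs) and
e ~ N(0, I σ²_e).  The response is a phenotype already corrected for
non-genetic effects other than litter, so the only fixed effect is the
intercept.  Four named models form a nested family: MA (additive + litter),
MAE (+ epistasis), MAD (+ dominance) and MAED (all three).  All four are
fitted to the same records with the same conventions, so their −2 log
restricted likelihoods are directly comparable.

## Relationship matrices

Let p_i be the frequency of the counted allele (A2) at locus i and
q_i = 1 − p_i, both computed from the analysed sample after QC (external
frequencies can be supplied instead).

* **Additive**: column i of M holds the centered dosages
  (0 − 2p_i, 1 − 2p_i, 2 − 2p_i) and G = MM′ / (2 Σ p_i q_i).
* **Dominance**: column i of H holds the centered heterozygosity coding,
  1 − 2p_i q_i for heterozygotes and −2p_i q_i for homozygotes, and
  D = HH′ / Σ 2 p_i q_i (1 − 2 p_i q_i).  Under Hardy–Weinberg equilibrium
  the per-locus variance of the centered coefficient is 2pq(1 − 2pq), which
  makes this the unique scaling for which E[D_kk] = 1 for a non-inbred
  individual and E[D_kl] = 0 for unrelated individuals.
* **Epistatic**: Hadamard products of lower-order matrices — G#G for
  additive-by-additive, G#G#G and G#G#D for third-order terms.  No
  rescaling is applied after the product (inbreeding is ignored, the usual
  approximation for Hadamard epistatic covariances).

Missing genotypes contribute 0 to both centered codings — the expectation
of a centered coefficient is zero — and the scale sums run over all
retained loci.  Raw dosages are never hard-imputed.  Positive
semidefiniteness is enforced only at model-fit time through diagonal jitter
(1e−10 escalating to 1e−6), not at construction.

## Quality control

Loci are kept when MAF > 0.05 and locus call rate > 0.95 (both computed on
the input), then individuals are kept when their call rate over the
retained loci > 0.95.  All thresholds are strict inequalities.  The order —
locus filters before the individual filter — is fixed and documented
because the criteria themselves do not imply one; frequencies are
recomputed after filtering.  Per-genotype quality masking (e.g. chip
calling scores) is expected to be applied upstream as missingness.

## AI-REML

Variance components are estimated by restricted maximum likelihood using
the criterion (up to a constant)

    −2 logL_R = log|V| + log|X′V⁻¹X| + y′Py,
    V = Σ_j σ²_j Z_j K_j Z_j′ + σ²_e I,

with average-information updates: gradient ∂logL/∂θ_j = −½(tr(PV_j) −
y′PV_jPy) and AI_{jk} = ½ y′PV_jPV_kPy.  Numerical policy:

* **Step control** — a proposed AI step is clamped at the feasible boundary
  component-wise; if it still increases the criterion it is halved up to 10
  times, after which one EM-REML step (θ_j ← θ_j + θ_j²/q_j (y′PV_jPy −
  tr(PV_j))) is taken.  EM never increases −2logL, so progress is
  guaranteed.
* **Bounds** — variances are bounded below at 1e−6 × var(y).  A component
  sitting at the bound with an outward gradient is pinned: excluded from
  the AI system and from standard errors (reported SE 0, flagged).
* **Starting values** — residual 0.5 var(y); each random term
  0.5 var(y)/k for k random terms.
* **Convergence** — relative change in −2logL < 1e−8 and maximum relative
  θ change < 1e−6.  Non-convergence returns a flagged result rather than
  raising.
* **Degenerate input** — a constant response pins every component and
  returns finite likelihood at a tiny positive variance.

Everything is dense (Cholesky factorisations), which is the right regime
for reference populations of order 10³.  SEs come from the inverse AI
matrix at the optimum.  The AI-REML optimum is cross-checked in the test
suite against a derivative-free optimiser on the same criterion and against
an independently coded dense evaluation of the formula.

## Prediction

BLUP solutions at the optimum are u_j = σ²_j K_j Z_j′ P y.  Individuals
without records are predicted by the covariance projection
u_test = σ²_j K_j[test, ref] P y, which is identical to solving the
mixed-model equations with the test records absent (verified in the tests,
along with the exact equivalence of additive GBLUP and ridge-regression
SNP-BLUP at matched shrinkage λ = σ²_e/(σ²_a / 2Σp_iq_i)).  GBV is the
additive-component BLUP; GTV is the sum of all genetic components in the
model (litter and residual excluded).

## Validation statistics

Variance proportions divide each component by the sum of all components in
the model (the model's phenotypic variance).  Nested models are compared by
a likelihood-ratio test with df equal to the number of added variance
components against a plain central χ² — this is deliberate; the 50:50
boundary-mixture correction is available behind a flag.  Reliability of
predicted breeding values is cor(GBV, y)²/h², with h² defaulting to the
narrow-sense estimate from the full MAED model.  Unbiasedness is the OLS
slope of observed phenotype on prediction (± SE).  Dependent correlations
sharing the test phenotype are compared with Williams' t (the form
recommended by Steiger), referred to t with n − 3 df; the test is
cross-checked against a row-swap permutation oracle in the suite.
Correlations are Pearson throughout.

## Synthetic data

The generator emulates a genotyped pig population: founders drawn in HWE at
allele frequencies uniform on [0.05, 0.95]; full-sib litters produced by
Mendelian gamete sampling from randomly mated founders; a test generation
bred from the reference animals, so the reference/test split is by
generation (the analogue of a birth-date cut-off).  Defaults are 1,000
reference + 200 test individuals, 2,000 loci, 200 founders, litters of 5,
and true variances (σ²_a, σ²_aa, σ²_d, σ²_l, σ²_e) = (2000, 500, 300, 500,
2200) around a mean of 1134 — the magnitudes of a corrected daily-gain
analysis.  All randomness flows from one recorded seed; identical
config + seed reproduces a bundle byte-for-byte.

Two effect modes: `mvn` draws each genetic component multivariate normal
from the realized relationship matrices (an exact match to the fitted
model, used for parameter recovery) and `locus` draws per-locus additive
effects, dominance values and random-pair epistatic effects scaled so the
expected component variances hit the same targets (genotype-anchored, used
for robustness).  The generator has no linkage disequilibrium, no
selection, no genotyping error and only two generations of pedigree, so
passing tests demonstrate correctness of the machinery under the model's
own assumptions — not performance on real livestock data, where LD
structure and deeper pedigrees change the information content of G, G#G
and D.

## Problem sizes used in the checks

The parameter-recovery check fits MAED on 20 mvn-mode replicates at 1,200
reference individuals × 2,000 loci; null shrinkage uses 10 replicates at
the same size with zero dominance and epistasis; the model-comparison
accuracy trend uses 50 replicates at 600 + 200 individuals × 800 loci with
strong non-additive variances (2000/1500/1500/100/1800), the regime where
a non-additive model has the most signal to exploit.  The HWE
expectation checks use 500 unrelated individuals × 5,000 loci.  These sizes
make each property measurable at desk scale while keeping the full suite
fast.

Two empirical notes from these checks, both documented in detail where the
tests assert them: with the epistatic variance truly zero, its REML
estimate lands at the boundary in only about half the replicates — the
expected asymptotic behaviour for a variance whose sampling SD (~1,300 at
this size; the corresponding published SE is 429 on an estimate of 529)
dwarfs its truth — and the MAED-vs-MA gain in test-set accuracy is
strongly positive for total genetic value but statistically zero for the
breeding-value component alone.

## Known limitations

* Dense algebra throughout: memory and time scale as n² and n³; not meant
  for reference populations beyond ~10⁴.
* Single-trait, single reference/test split, intercept-only fixed effects:
  phenotypes must be pre-corrected.
* No pedigree or single-step matrices; no LD-aware or MAF-weighted G
  variants; dominance coding is the centered-heterozygosity form only.
* The LRT P-values use the central χ² convention described above; with the
  boundary mixture enabled, P-values are roughly halved for one added
  component.
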