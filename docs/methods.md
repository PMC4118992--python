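# Methods

## The model

`domblup` estimates additive and dominance genetic variation from SNP
genotypes of dairy cows with own phenotypes (yield deviations), and predicts
genetic merit with and without dominance. Four single-trait linear mixed
models are implemented:

- **MA** — `y = 1u + a + e`, additive effects only;
- **MAD** — `y = 1u + a + d + e`, dominance entering as *genotypic dominance
  values* (heterozygote coded against a homozygote baseline);
- **MAD2** — same, but dominance entering as *dominance deviations*, the
  component of genotypic value orthogonal to the additive regression at
  Hardy–Weinberg equilibrium;
- **MAD3** — MAD extended with ungenotyped cows whose genotypes are known
  only as Mendelian probabilities from genotyped ancestors, with separate
  intercepts and residual variances for the sire–dam (SD) and
  sire–maternal-grandsire (S-MGS) groups.

Random effects have `a ~ N(0, σ²ₐG)` and `d ~ N(0, σ²_d D)` with genomic
relationship matrices built from the coding matrices:

    G  = ZZ' / Σᵢ 2pᵢqᵢ            z ∈ {0,1,2} − 2p
    D1 = HH' / Σᵢ 2pᵢqᵢ(1−2pᵢqᵢ)   h = 1{het} − 2pq
    D2 = MM' / Σᵢ (2pᵢqᵢ)²         m ∈ {−2p², 2pq, −2q²}

`p` is the frequency of the counted (B) allele, estimated from the observed
genotyped-cow data and held fixed across cross-validation folds. The
denominators make each matrix's expected diagonal 1 under HWE
(`E z² = 2pq`, `E h² = 2pq(1−2pq)`, `E m² = (2pq)²`); the homozygote
assignment in `M` (`code 0 → −2p²`, `code 2 → −2q²`) is forced by requiring
zero mean and zero covariance with `z` at HWE. A useful exact identity links
the two dominance codings: `h = m + (q−p)·z`, which is why the deviation
parameterization reallocates part of a dominance-value signal into the
additive variance (larger σ²ₐ, smaller σ²_d, similar sum) — the pattern the
qualitative tests assert.

Monomorphic SNPs contribute 0/0 terms and are excluded from all codings and
normalization sums, with a logged count.

## Ancestor-derived genotype probabilities

An ungenotyped cow with genotyped sire and dam has genotype probabilities
from Mendelian transmission: each parent passes allele A with probability
`(2 − code)/2`. With a genotyped sire and maternal grandsire, the dam's
gamete carries the MGS allele with probability ½ and a population allele
(A with frequency `q`) otherwise, so the dam path transmits A with
probability `½(2 − mgs)/2 + ½q`. Probability triples enter the coding
matrices by linear expectation (e.g. `E[z] = P1 + 2P2 − 2p`); the extra
variance from genotype uncertainty is absorbed by the group-specific
residual variances rather than modeled per record. S-MGS daughter groups
are analyzed through their phenotype mean, whose residual variance is the
group variance divided by the daughter count N (multiplier 1/N in the
residual coefficient matrix R).

## AI-REML

Variance components maximize the restricted likelihood

    l_R = −½ [ log|V| + log|X'V⁻¹X| + y'Py ],    V = σ²ₐG + σ²_d D + Σ_g σ²ₑ,g R_g

(the additive constant is dropped; only likelihood differences are ever
interpreted). Updates are Newton steps using the average-information matrix
`AI_jk = ½ y'P V_j P V_k P y` with scores `−½[tr(P V_j) − y'P V_j P y]`.
Numerical policy, fixed and logged:

- step-halving (factor 0.5, up to 20 times) whenever a step leaves the
  parameter space or worsens −2 log L, then an EM-style update
  `σ² ← σ² + σ⁴ (y'PVPy − tr(PV))/q` as last resort (`q` = record count of
  the component);
- genetic variances are clamped at 0 by projection, so exact-zero boundary
  estimates are representable; a parameter held at 0 whose score is
  negative is dropped from that iteration's AI solve;
- residual variances are floored at `1e−8 · var(y)` to keep V positive
  definite;
- convergence requires `|Δ(−2logL)| < 1e−8` and relative parameter change
  `< 1e−6`, within 100 iterations; default starting values are ⅓ of the
  phenotypic variance per component.

Dense linear algebra throughout (Cholesky factorization of V per
iteration); traces use the symmetric identity `tr(PK) = Σᵢⱼ PᵢⱼKᵢⱼ`, so one
iteration costs one factorization plus O(n²) per component. This is
practical to n of a few thousand, the scale of every analysis here.

Nested models (MA within MAD or MAD2) are compared with a likelihood-ratio
test. Because the dominance variance is tested on the boundary of its
parameter space, the null distribution is the 50:50 mixture of a point mass
at zero and χ²₁: `p = ½ P(χ²₁ > Δ)` for `Δ > 0`, else 1. Heritabilities are
`h²ₐ = σ²ₐ/(σ²ₐ+σ²_d+σ²ₑ)` and analogously for `h²_d`; under MAD3 the
denominator uses the S-MGS residual variance, which is the cow-level (not
group-mean-level) residual in that parameterization.

## SNP-BLUP

Marker effects solve the mixed-model equations for
`y = Tβ + e`, `T = [1 (1_SD 1_SMGS) Z W]`, with ridge terms
`λₐ = s_a σ²ₑ/σ²ₐ` on the additive block and `λ_d = s_w σ²ₑ/σ²_d` on the
dominance block (`W, s_w` = `H, s_h` for MAD/MAD3 or `M, s_m` for MAD2) and
rows weighted by inverse record residual variance. These λ follow from
assigning each marker 1/s of the total genetic variance, the only choice
consistent with the G/D1/D2 normalizations: animal predictions `Zâ` and
`Wd̂` from the marker system then equal GBLUP predictions from the matched
individual-level system exactly (asserted to 1e−6 in tests, observed at
machine precision).

Two solvers: direct inversion, and a blend of first- and second-order
Jacobi iteration

    x ← x + ω₁ D⁻¹(rhs − A x) + ω₂ (x − x_prev)

with defaults ω₁ = 0.9, ω₂ = 0.1, relative-residual tolerance 1e−10, at
most 5000 iterations, and a divergence guard (10 consecutive residual
increases). The iterative path exists because expected codings for
descendant groups make the MAD3 coefficient matrix dense and large; both
solvers agree to 1e−8 on every converged run. Per-SNP effects are reported
as a ranked table (|effect| descending, ties broken by chromosome then
position, with each SNP's rank on the other effect scale and optional
chromosome exclusion) in place of Manhattan plots.

## Cross-validation

Genotyped cows are partitioned into 10 random folds differing in size by at
most one. Each fold in turn is the test set; the other nine train the model
(descendant-group records, when a model uses them, are always training
data). By default variance components are re-estimated on every training
fold — the stricter protocol; a `varcomp_source="full"` switch reuses the
full-data estimates. Accuracy is the Pearson correlation between phenotype
and predicted breeding value or total genetic value (their sum with the
dominance value); all models are evaluated on bit-identical test sets, and
fold-wise correlations are compared between models by two-sided paired
t-tests (df = 9; all-zero differences give p = 1 by convention, zero-variance
nonzero differences are reported as 0 with a warning).

## Synthetic data

The generator emulates the study design at desk scale. Defaults:
n = 2000 genotyped cows, k = 1000 biallelic SNPs with B-allele frequency
uniform on [0.05, 0.5] and genotypes at HWE, additive heritability 0.27 and
dominance heritability 0.05 (a Holstein-like milk-yield architecture), unit
phenotypic variance (trait scale is an affine rescaling that affects no
result), intercept 0. Per-SNP effects are Gaussian with variances
`σ²ₐ/s_a` and `σ²_d/s_w`; dominance is generated on the value scale (H) by
default, with a deviation-scale (M) option for parameterization-contrast
experiments. Descendant groups: 500 sire–dam offspring with true genotypes
by per-SNP Mendelian transmission (kept as a hidden truth sidecar) and 200
sire–MGS groups of 20–60 daughters each, groups under 20 daughters flagged
for exclusion (the Holstein group-size rule; real studies run two orders of
magnitude more descendants). Parents are drawn with replacement from the
genotyped set; no selection is simulated. All randomness flows from one
seed through per-stage substreams.

What the generator does **not** emulate — and hence what passing tests do
not establish about real cattle data: linkage disequilibrium and
chromosome structure (transmission is per-SNP independent), major genes
with non-Gaussian effect sizes, pre-selection of elite genotyped animals,
pedigree inbreeding loops, and heterogeneous phenotype precision beyond the
1/N group-mean scaling. Calibration and recovery results therefore speak to
the correctness of the estimators under their own assumptions, not to
expected accuracies in national evaluations.

## Problem sizes used by the test suite

Monte-Carlo checks run at sizes chosen to make their error bars decisive:
heritability recovery at n = 2000, k = 1000 over 20 replicates; LRT null
calibration at n = 500, k = 300 over 500 replicates; qualitative
model-contrast patterns over 10 replicate datasets (n = 600–1000). These
are the package's standard verification sizes.

## Known limitations

- REML is dense-matrix; tens of thousands of records would need the
  iterative SNP-BLUP path with externally supplied variance components.
- The MAD3 likelihood is not comparable across models fit to different
  record sets (different data, different likelihood), so LRTs are only
  defined for MA vs MAD/MAD2 on the genotyped-cow data.
- Percentage-trait derivation and inbreeding/heterosis pre-adjustment
  consume published coefficients; estimating them requires the national
  multi-trait model, which is out of scope.
- X-chromosome SNPs are treated as autosomal.
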