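# domblup

Additive + dominance genomic evaluation for dairy-cattle traits:
GBLUP / SNP-BLUP with dominance parameterized either as genotypic dominance
*values* or as orthogonal dominance *deviations*, an extension to
ungenotyped cows through ancestor-derived genotype probabilities, AI-REML
variance components, boundary-corrected likelihood-ratio model comparison,
and ten-fold cross-validation of prediction accuracy. A synthetic-data
generator with known genetic architecture makes every stage testable
without proprietary records.

## Who this is for

Animal breeders and quantitative geneticists who want to quantify how much
non-additive (dominance) variance a trait carries, whether modeling it
improves genomic prediction, and which markers carry the largest additive
and dominance effects — with cows' own records as phenotypes, since
dominance is invisible in progeny-mean pseudo-phenotypes.

## The models

With genotype codes 0/1/2 counting the B allele (frequency *p*, *q* = 1−*p*):

| model | equation | dominance coding |
|-------|----------|------------------|
| MA    | y = 1u + a + e | — |
| MAD   | y = 1u + a + d + e | H: het = 1−2pq, hom = −2pq (values) |
| MAD2  | y = 1u + a + d + e | M: −2p², 2pq, −2q² (deviations) |
| MAD3  | MAD + SD/S-MGS cows via expected codings | H, three residual groups |

with a ~ N(0, σ²ₐ **G**), d ~ N(0, σ²_d **D₁** or **D₂**), and

    G = ZZ'/Σ2pq,  D1 = HH'/Σ2pq(1−2pq),  D2 = MM'/Σ(2pq)².

An ungenotyped cow's genotype probabilities come from Mendelian
transmission: a genotyped parent passes allele A with probability
(2−code)/2; a dam known only through the maternal grandsire passes the MGS
allele with probability ½ and a population allele otherwise. Sire–MGS
daughter groups are analyzed via their phenotype mean with residual
variance scaled by 1/N.

Variance components are estimated by average-information REML; MA is
compared with MAD/MAD2 by a likelihood-ratio test whose null is the
½χ²₀ : ½χ²₁ boundary mixture. SNP effects come from ridge-type mixed-model
equations (λₐ = s_a σ²ₑ/σ²ₐ, λ_d = s_w σ²ₑ/σ²_d) solved directly or by
blended first/second-order Jacobi iteration; predictions from the marker
system equal GBLUP from the matched relationship matrices exactly. See
`docs/methods.md` for the numerical details.

## Worked example

```python
import numpy as np
import domblup as db

cfg = db.SimConfig(n_animals=500, n_snps=300, h2_additive=0.27,
                   h2_dominance=0.05, n_sd_offspring=0, n_smgs_groups=0, seed=1)
pop = db.simulate_population(cfg)

freqs = db.estimate_allele_frequencies(pop.genotypes)
codings = db.compute_codings(pop.genotypes, freqs)
G = db.build_relationship_matrix(codings, "G")
D1 = db.build_relationship_matrix(codings, "D1")

fit_ma = db.fit_reml(db.ModelSpec("MA"), pop.phenotypes, G=G)
fit_mad = db.fit_reml(db.ModelSpec("MAD"), pop.phenotypes, G=G, D=D1)
lrt = db.likelihood_ratio_test(fit_ma, fit_mad)

mme = db.build_mme(db.ModelSpec("MAD"), codings, fit_mad.estimates, pop.phenotypes)
pred = db.predict_genetic_values(codings, db.solve_direct(mme))

folds = db.make_folds(500, 10, seed=1)
cv = db.cross_validate([db.ModelSpec("MA"), db.ModelSpec("MAD")],
                       db.CVData(codings=codings, y=pop.phenotypes), folds,
                       varcomp_source="full")
```

prints (via the obvious format strings):

```
MA: sigma2_a=0.228 sigma2_d=0.000 sigma2_e=0.719 h2a=0.240 h2d=0.000 -2logL=455.83
MAD: sigma2_a=0.190 sigma2_d=0.105 sigma2_e=0.647 h2a=0.202 h2d=0.111 -2logL=450.68
LRT MA vs MAD: delta=5.15 p=0.0116
corr(true BV, predicted BV) = 0.644
CV test correlation, MA additive:  0.254
CV test correlation, MAD total:    0.272
```

Reading the output: this 500-cow dataset was generated with true
h²ₐ = 0.27, h²_d = 0.05. The MAD fit attributes 20% of phenotypic variance
to additive and 11% to dominance effects (small-sample REML estimates with
large sampling error at n = 500 — the test suite verifies unbiasedness at
n = 2000 over replicates). The likelihood-ratio test detects the simulated
dominance (p ≈ 0.01 against the boundary-mixture null), and the
total-genetic predictor beats the additive-only model in the ten-fold
cross-validation (0.272 vs 0.254 mean test correlation), the expected gain
when real dominance variance exists.

A CLI wraps the same pipeline:

```sh
domblup simulate --seed 1 --n-animals 500 --n-snps 300 --out-prefix sim
domblup varcomp sim.genotypes.tsv sim.phenotypes.tsv --model MA --model MAD
domblup snpeffects sim.genotypes.tsv sim.phenotypes.tsv --model MAD --top 10 --out top.tsv
domblup run --config pipeline.json --seed 1
```

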