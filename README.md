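# nagblup — genomic BLUP with additive and non-additive genetic effects

Complex traits carry genetic variation beyond the additive component that
standard genomic evaluation captures: dominance (interactions between
alleles at a locus) and epistasis (interactions between loci).  `nagblup`
estimates how much of each is present and whether modelling them improves
genomic prediction, for anyone working with a genotyped population and a
corrected phenotype — animal and plant breeders foremost, but the machinery
is generic.

The model family is

    y = μ1 + a + i + d + l + e
    a ~ N(0, G σ²_a)    i ~ N(0, G#G σ²_aa)    d ~ N(0, D σ²_d)
    l ~ N(0, I σ²_l)    e ~ N(0, I σ²_e)

with marker-based relationship matrices: the additive matrix
G = MM′/(2Σp_iq_i) from centered dosages, the dominance matrix
D = HH′/Σ2p_iq_i(1−2p_iq_i) from centered heterozygosity codings, and
epistatic matrices as Hadamard products (G#G, and higher orders such as
G#G#G or G#G#D).  Four nested models — MA, MAE, MAD, MAED — are fitted by
average-information REML; breeding values (GBV) and total genetic values
(GTV) are predicted for unphenotyped genotyped individuals and evaluated
for accuracy (correlation, reliability r²/h²) and unbiasedness (regression
slope), with likelihood-ratio tests between models and Hotelling–Williams
tests between dependent accuracy correlations.  Details and numerical
policy: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a population (300 reference + 100 test pigs, 600 SNP, true
variances 2000/500/300/500/2200), then run QC → relationship matrices →
REML → prediction → validation in one call:

```sh
printf 'n_ref: 300\nn_test: 100\nm: 600\nlitter_size: 5\nseed: 7\n' > sim.yaml
nagblup run-all --config sim.yaml --out demo
cat demo/validate/summary.txt
```

```
narrow-sense h2 used for reliability: 0.405

accuracy and unbiasedness on the test set:
       cor_gtv  cor_gbv  reliability  b_gtv  se_b_gtv  b_gbv  se_b_gbv
model
MA       0.251    0.251        0.156  0.542     0.211  0.542     0.211
MAD      0.262    0.254        0.160  0.584     0.218  0.597     0.230
MAE      0.208    0.254        0.160  0.398     0.189  0.622     0.239
MAED     0.221    0.256        0.162  0.451     0.201  0.685     0.261

likelihood-ratio tests vs MA:
       minus2logl   chi2  df      p
model
MA       2858.277    NaN   0    NaN
MAD      2857.673  0.604   1  0.437
MAE      2857.028  1.249   1  0.264
MAED     2856.636  1.641   2  0.440
```

Reading this: each row is one model; `cor_gbv` is the accuracy of predicted
breeding values against the corrected phenotypes of the 100 test animals,
`reliability` is that correlation squared divided by the MAED narrow-sense
heritability (0.405 here), and the `b_*` columns are the regression slopes
of phenotype on prediction (1 = unbiased; at n = 100 their SEs are large).
The LRT block shows that at this small size the non-additive components do
not significantly improve the fit (P ≥ 0.26) — expected, since dominance
and epistatic variances need far more data than additive ones to pin down.
The per-model variance components live in `demo/reml/<model>/`, e.g. for
MAED:

```
term       estimate  se       proportion  pinned
additive   2477.78   948.829  0.404597    False
epistatic  1992.87   1928.94  0.325415    False
dominance  433.005   699.388  0.0707055   False
litter     0.00614   0        1.00e-06    True
residual   1220.41   1322.84  0.199281    False
```

The same steps are available as library calls (`simulate_genotypes`,
`build_relationship_matrices`, `fit_model_family`, `predict_model_family`,
`validate_predictions`) and as individual subcommands (`nagblup qc / grm /
reml / predict / validate / simulate`).

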