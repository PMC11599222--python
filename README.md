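# mrmediate

Two-sample Mendelian randomization (MR) mediation analysis on GWAS summary
statistics: instrument selection and strength metrics, five univariable MR
estimators with heterogeneity / pleiotropy / outlier sensitivity analyses,
multivariable MR, and product/difference mediation decomposition — plus a
synthetic-GWAS generator with a known causal chain so the whole pipeline is
testable without downloading any real dataset.

## Who this is for

Epidemiologists and statistical geneticists asking *how much of a causal
exposure→outcome effect flows through candidate mediators*, when all they have
are published per-SNP summary associations (beta, SE, allele frequencies,
p-values, sample sizes) from separate GWAS of the exposure, the mediators and
the outcome. The motivating use case is decomposing the effect of insomnia on
myocardial infarction into components mediated by smoking initiation and body
mass index.

## The model

For SNP *j* with exposure association β̂Xⱼ and outcome association β̂Yⱼ, the
Wald ratio β̂Yⱼ/β̂Xⱼ estimates the causal effect under the instrumental-variable
assumptions. The estimators combine the ratios:

- **IVW**: weighted regression of βY on βX through the origin, weights 1/σYⱼ²;
  multiplicative random effects inflate the SE by √max(1, Q/(J−1)).
- **MR-Egger**: the same regression with an intercept (βX oriented ≥ 0); the
  intercept estimates average directional pleiotropy.
- **Weighted median / weighted and simple mode**: order- and mode-based
  estimators robust to invalid instrument minorities.
- **Cochran's Q, Egger intercept test, MR-PRESSO**: heterogeneity diagnosis,
  pleiotropy test, and simulation-based outlier removal.
- **Multivariable MR**: WLS of βY on the matrix of exposure betas (union of
  per-exposure instruments), giving each exposure's *direct* effect.

Mediation decomposition on the log-odds scale, with total effect *c*, direct
effect *c′*, exposure→mediator effect *a* and mediator→outcome effect *b*:

- product method (per mediator): indirect = *a·b*, proportion mediated = *a·b/c*;
- difference method (combined): indirect = *c − c′*, proportion = *(c − c′)/c*.

Instrument strength per SNP: R² = 2·MAF·(1−MAF)·β²/(SE²·N) and
F = ((N−K−1)/K)·R²/(1−R²), with F > 10 the conventional non-weak bar.

## Worked example

The headline decomposition of the insomnia→myocardial-infarction effect, from
the published log-odds (total 0.674, direct 0.309, smoking a=−0.626,
b=−0.317):

```sh
mrmediate mediate --a -0.626 --a-se 0.074 --b -0.317 --b-se 0.045 \
    --c 0.674 --c-se 0.0827 --c-prime 0.309 --c-prime-se 0.1347
```

prints

```
total effect: beta=0.674 (OR 1.96 [1.67, 2.31])
product method: indirect=0.1984 (se 0.03666), proportion mediated=29.4% [18.6%, 45.2%]
difference method: indirect=0.365 (se 0.1581), proportion mediated=54.2% [9.5%, 92.6%]
```

i.e. insomnia raises the odds of myocardial infarction 1.96-fold; smoking
initiation carries about 29% of that effect, and all mediators combined carry
about 54% (CIs are parametric-bootstrap percentile intervals).

The full pipeline is config-driven. Generate a synthetic study at the scale of
the real one (429/77/34/60 instruments, N up to 1.2M, known causal chain) and
run it:

```sh
mrmediate simulate --seed 1 --out-dir sim/          # writes one TSV per trait
mrmediate run --config run.yaml --out-dir report/   # UVMR → filter → MVMR → mediation
```

`report/` then contains `uvmr_estimates.tsv`, `heterogeneity.tsv`,
`pleiotropy.tsv`, `mvmr_estimates.tsv`, `mediator_filter.tsv`, `mediation.tsv`
and a `run_meta.yaml` with all seeds. Mediators whose IVW tests fail BH-FDR
(e.g. the deliberately null "alcohol consumption" in the built-in scenario)
are excluded from the multivariable stage, replicating the screening logic of
the motivating analysis. Everything is also available as a library — see
`mrmediate.ivw_estimate`, `mrmediate.mvmr_ivw`, `mrmediate.product_mediation`,
`mrmediate.simulate_summary_stats`, etc.

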