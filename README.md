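# latertwin

Tools for studying the heritability of language laterality with twins —
from raw functional-transcranial-Doppler (fTCD) recordings to
variance-component estimates.

Cerebral lateralisation of language is usually summarised by a laterality
index (LI): the left-minus-right difference in task-evoked blood-flow
velocity through the middle cerebral arteries, positive when language is
left-lateralised. Twin designs ask how much of the individual variation in
such an index is genetic. This package implements the complete analysis
chain for that question:

* **fTCD pipeline** (`latertwin.ftcd`) — dropout repair, heart-cycle
  integration, normalisation to percent of mean flow, cue-aligned
  epoching with artifact/behaviour rejection, baseline correction,
  mean-based and peak-based per-trial LIs, per-subject summaries with
  Student-t confidence intervals and left/bilateral/right (and
  typical/atypical) categories, split-half reliability, and 5-SD outlier
  exclusion.
* **Handedness scoring** (`latertwin.phenotypes`) — the 10-item
  demonstration version of the Edinburgh Handedness Inventory (0–10) and
  the 21-trial Quantification of Hand Preference card task (0–42).
* **Twin models** (`latertwin.twin`) — maximum-likelihood ACE/AE/CE/E
  variance decomposition of twin-pair data, profile-likelihood CIs,
  likelihood-ratio model comparison, ML intraclass twin correlations,
  Falconer moment estimates, and a trivariate Cholesky AE model fitted by
  full-information ML.
* **Extremes analysis** (`latertwin.extremes`) — DeFries–Fulker-style
  selection of extreme probands with a Welch t-test comparing MZ and DZ
  cotwin means.
* **Power** (`latertwin.power`) — power to detect a² in an AE design by
  the noncentral-chi-square approximation or by Monte Carlo.
* **Generators** (`latertwin.simulate`) — twin phenotypes under known
  (a², c², e²) with optional J-shaped handedness-like marginals, and full
  synthetic fTCD sessions with ground-truth logs, so every stage is
  testable without any external data.

## The model

The classical twin decomposition writes the phenotypic variance as
v = a² + c² + e² (additive genetic, shared environment, nonshared
environment, as proportions). Monozygotic (MZ) pairs share all
segregating genes and dizygotic (DZ) pairs half on average, so the
implied twin–cotwin correlations are

    rMZ = a² + c²        rDZ = ½·a² + c².

Each complete pair is bivariate normal with a common mean and variance;
models are fitted by maximising the summed log-likelihood over both
zygosity groups with components constrained to [0, 1], and nested models
are compared with the likelihood-ratio chi-square. The Falconer moment
estimate a² = 2(rMZ − rDZ) is provided for orientation. Because shared
environment has repeatedly been found negligible for laterality, the AE
submodel (c² = 0) is the primary analysis model.

## Worked example

Simulate a cohort at realistic sample sizes (96 MZ / 98 DZ pairs) with
true heritability 0.25, fit the AE model, and check the design's power:

```python
from latertwin.simulate import TwinSimConfig, simulate_twin_phenotypes
from latertwin.twin import UnivariateTwinModel, compare_models
from latertwin.power import power_ae

cfg = TwinSimConfig(n_mz=96, n_dz=98, a2=0.25, c2=0.0, e2=0.75, seed=42)
table, truth = simulate_twin_phenotypes(cfg, phenotype="li")

ae = UnivariateTwinModel.from_table(table, "li", model="AE").fit()
print(ae.summary())
print("a2 95% profile CI: (%.3f, %.3f)" % ae.profile_ci("a2"))

e = UnivariateTwinModel.from_table(table, "li", model="E").fit()
chisq, df, p = compare_models(ae, e)
print(f"AE vs E: chi2({df}) = {chisq:.2f}, p = {p:.4f}")
print(f"power to detect a2=0.25 here: {power_ae(96, 98, 0.25).power:.3f}")
```

prints

```
Twin variance decomposition (AE model, ML)
  pairs: 96 MZ, 98 DZ   loglik: -510.686
  mean: -0.0408   total variance: 0.8613
  a2 = 0.4094   c2 = 0.0000   e2 = 0.5906
  implied rMZ = 0.4094   rDZ = 0.2047
a2 95% profile CI: (0.242, 0.549)
AE vs E: chi2(1) = 19.77, p = 0.0000
power to detect a2=0.25 here: 0.794
```

This one draw over-estimates the generating a² = 0.25 (the profile CI of
a single cohort of this size is wide — roughly ±0.15); across replicate
cohorts the estimator is unbiased, which the test suite checks. The
genetic term is clearly detected (p < 0.001), consistent with the ~79%
power of this design at a² = 0.25.

A command-line interface mirrors the library:

```sh
latertwin simulate twins --nmz 96 --ndz 98 --a2 0.25 --out pairs.csv
latertwin twin fit --data pairs.csv --pheno pheno --model AE
latertwin twin power --nmz 65 --ndz 76 --a2 0.3
latertwin ftcd process --input raw_dir/ --out results/
latertwin run --out study_out/          # full simulated study bundle
```

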