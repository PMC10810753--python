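# twinlook

Classical twin analysis of infant preferential-looking phenotypes, end to
end: a synthetic twin-gaze generator, extraction of looking measures from
raw gaze samples, full-information maximum-likelihood (FIML) twin models
(univariate ACE family and bivariate Cholesky), and longitudinal
association statistics with cluster-robust standard errors.

## The scientific problem

In a five-object "face pop-out" display an infant can look first at the
face or at a competitor (a face-matched noise patch, a phone, a bird, a
car), and can allocate more or less of their total looking time to the
face. Three phenotypes summarize this behaviour per infant:

- **face orienting** — proportion of valid trials where the face is the
  first object looked at (chance 1/5 = 0.20);
- **face preference** — looking time on the face divided by looking time
  on all objects, averaged over valid trials;
- **efficiency of visual exploration** — number of distinct objects looked
  at in the first 10 s of a trial.

Measuring these in monozygotic (MZ) and dizygotic (DZ) twin pairs lets one
decompose phenotypic variance into additive-genetic (A), shared-environment
(C) and non-shared-environment (E) components: MZ twins share all their
segregating genetic material, DZ twins half on average, and both share C
fully. A bivariate Cholesky model additionally splits trait 2's genetic
variance into a part transmitted through trait 1's genetic factor (shared)
and a trait-2-specific part (unique). Because the infants come in pairs,
downstream regressions of later outcomes (e.g. vocabulary) on the looking
measures use estimating equations with pair-clustered sandwich standard
errors.

## The model

For traits standardized to unit variance, each component X ∈ {A, C, D, E}
is parameterized by a lower-triangular path matrix L_X with X = L_X L_Xᵀ,
so component covariances are positive semi-definite by construction. The
implied pair covariance is

    Σ_within   = A + C + D + E
    Σ_cross,MZ = A + C + D
    Σ_cross,DZ = ½A + C + ¼D

Each pair contributes a multivariate-normal log-likelihood over its
*observed* entries (an absent co-twin's rows are dropped), so partially
complete pairs are retained. Conventions: df = (observed data values) −
(free parameters); AIC = −2LL − 2·df; nested models are compared by
Δχ² = Δ(−2LL) on Δdf, and the selected model is the non-significant
(p ≥ 0.05) nested model with the lowest AIC.

## Worked example

Simulate a study-sized cohort (155 MZ + 130 DZ pairs, 12% incomplete) from
a bivariate AE structure — orienting heritability 0.19, preference genetic
variance split 0.16 shared / 0.29 unique, 97% of preference E unique —
then fit and select among the bivariate models:

```python
import twinlook as tl

spec = tl.GenerativeSpec.bivariate_ae(a11_2=0.19, shared_a2=0.16,
                                      unique_a2=0.29, unique_e_share=0.97)
data = tl.simulate_twin_phenotypes(spec, n_mz=155, n_dz=130,
                                   incomplete_rate=0.12, seed=42)

full = tl.fit_model(tl.ModelSpec(2, "ACE", name="ACE"), data)
nested = [tl.fit_model(tl.ModelSpec(2, c, name=c), data) for c in ("AE", "CE", "E")]
comparisons = [tl.compare_models(full, f) for f in nested]
best = tl.select_best(comparisons)
dec = tl.standardize_components(best)
```

This prints (seed 42):

```
 AE  dChi2=  0.05 ddf=3 p=0.997 AIC=908.26 retained=True
 CE  dChi2= 17.02 ddf=3 p=0.001 AIC=925.23 retained=False
  E  dChi2= 68.55 ddf=6 p=0.000 AIC=970.76 retained=False
selected: AE
  trait component  standardized
trait_1         A         0.212
trait_1         E         0.788
trait_2         A         0.534
trait_2         E         0.466
shared_A = 0.022
unique_A = 0.512
r_A = 0.204
r_Ph = 0.287
```

Reading this: the AE model is retained (dropping C costs essentially no
fit, Δχ² = 0.05 on 3 df) while CE and E fit significantly worse; the total
heritabilities (0.21 and 0.53) and the implied phenotypic correlation
(0.29) recover the generating structure, but the shared/unique split of
trait 2's genetic variance is weakly identified at ~285 pairs — its
sampling spread is wide, which is exactly why such splits are reported
with broad confidence intervals at realistic study sizes. At 4,000 pairs
per zygosity the split recovers to within a few hundredths (see the
reproduction script below).

## Command line

A thin CLI orchestrates the pipeline:

```sh
twinlook run-all --seed 1 --out results/run1       # full chain + report.txt
twinlook simulate --seed 1 --out results/sim       # pedigree + raw gaze CSV
twinlook extract --gaze-csv results/sim/gaze.csv \
    --scenes-yaml results/sim/scenes.yaml --out results/ext
twinlook fit-univariate --pheno-csv results/ext/phenotypes.csv --trait face_preference
twinlook fit-bivariate  --pheno-csv results/ext/phenotypes.csv
```

`run-all` executes simulate → extract → quality-adjust → descriptives →
twin correlations → univariate fits → bivariate Cholesky with model
selection → clustered association with FDR step-up, writing per-stage CSVs
and a human-readable `report.txt`.

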