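# metabosurv

Metabolomic biomarker screening and polynomial Cox risk scores for
hepatocellular-carcinoma (HCC) surveillance in liver-cirrhosis cohorts.

Cirrhotic patients face a high but very unevenly distributed risk of
developing HCC, and surveillance guidelines treat them all alike. One line of
work screens baseline plasma metabolites — ¹H-NMR spectra binned at 0.01 ppm,
followed by chromatographic quantification of candidate metabolites — for
association with *time to* HCC, and condenses the findings into a polynomial
risk score built from age and plasma phenylalanine (Phe) and glutamine (Gln)
concentrations. `metabosurv` implements that entire analysis chain as a
tested, reusable library:

* **`synth`** — seeded synthetic cirrhosis cohorts: covariate marginals of a
  published 475-patient cohort, binned NMR spectra driven by the underlying
  metabolite concentrations, a noisy secondary quantification, and HCC event
  times from a proportional-hazards model with administrative censoring
  calibrated to a target event fraction (default 39/475 ≈ 8.2%).
* **`nmr`** — the untargeted screen: the standard 900-bin axis
  (0.505–9.495 ppm), reference/total-area normalization, Pareto scaling
  \((x-\bar x)/\sqrt{s}\), per-bin Welch *t* statistics between outcome
  groups with a P ≤ 0.01 flag rule, and metabolite annotation from a
  chemical-shift interval lookup.
* **`survival`** — right-censored machinery from first principles: the
  Breslow partial likelihood
  \(\ell(\beta)=\sum_{t\ \mathrm{event}}\bigl[\sum_{i\in D_t} x_i'\beta -
  d_t\log\sum_{j\in R_t} e^{x_j'\beta}\bigr]\)
  maximized by Newton–Raphson (`CoxPH(...).fit()` → `CoxPHResults` with Wald
  HR/CI/p and a `summary()`), Kaplan–Meier, the K-sample log-rank test,
  tertile stratification, and univariate/multivariate screening tables.
* **`gim`** — the algorithmic core: GIM (generalized iterative modelling), a
  penalized greedy search over polynomial terms \(x^p\) of candidate
  covariates that maximizes the Cox partial likelihood
  (`GIMSearch(...).fit()` → `GIMResults` carrying a `PolynomialScore`
  \(R=\sum_k c_k\,x_{v_k}^{p_k}\) and an audit trace). The published
  five-term score
  \(R = 0.0694\,\mathrm{age} + 0.3399\,\mathrm{Phe} - 0.00188154\,
  \mathrm{Phe}^2 - 0.0133\,\mathrm{Gln} + 0.00002244\,\mathrm{Gln}^2\)
  ships as a packaged fixture (`published_risk_score()`).
* **`horizon`** — cross-sectional performance at fixed follow-up horizons
  under right censoring: case / control / excluded labelling, ROC with the
  Hanley–McNeil test against AUC = 0.5, Youden-optimal cutoffs
  (J = Se + Sp − 1) with PPV/NPV, Mann–Whitney U and box-plot summaries.
* **`pipeline` / CLI** — the end-to-end chain (simulate → screen → select →
  search → score → evaluate) with deterministic CSV artifacts and a
  checksummed run manifest.

## Worked example

```python
import metabosurv as ms
from metabosurv.gim import GimConfig, GIMSearch

# a cohort whose true log hazard is the published five-term score (exp(R) form)
cfg = ms.GeneratorConfig(n_patients=2000, seed=1, hr_per_unit=1.0)
cohort, record = ms.generate_cohort(cfg)

search = GIMSearch.from_dataframe(
    cohort, "time_years", "event",
    GimConfig(candidate_variables=("age_years", "phe_um", "gln_um"), max_degree=2),
)
result = search.fit()
print(result.summary())
```

```
GIM polynomial search
=====================
penalty: BIC   terms: 5
final log partial likelihood: -833.147318

term                     coefficient
age_years                0.081091161
gln_um                  -0.019800162
gln_um^2               2.7463245e-05
phe_um                    0.38424592
phe_um^2               -0.0020405785
```

The search recovers the generating five-term structure — age linear, concave
quadratic in Phe (vertex near 90 μM), convex quadratic in Gln — with
coefficients close to the truth (0.0694, 0.3399, −0.00188154, −0.0133,
0.00002244). Scoring and horizon evaluation:

```python
fit = ms.score_hazard_ratio(cohort, result.score)   # Cox on the score
labels = ms.label_at_horizon(cohort["time_years"], cohort["event"], 3.0)
roc = ms.roc_curve(result.score(cohort), labels)
best = ms.youden_optimal(roc)
```

prints a fitted HR of e per score unit on the training data
(`beta 1.0000, hr 2.7183, CI 2.48–2.98`) and
`year-3 AUC 0.936; cutoff 2.018, J 0.734, Se 0.851, Sp 0.883` — the J value
equals Se + Sp − 1 by construction. The full chain runs from the shell:

```bash
metabosurv run-all --seed 1 --output-dir run1 --published-score
```

writing `cohort.csv`, `spectra.tsv`, `screen.csv`, `univariate.csv`,
`score.csv`, `horizon_report.csv`, `biomarker_distributions.csv` and a
`manifest.yaml` whose artifact checksums are identical on re-runs with the
same seed.

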