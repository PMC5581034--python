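# hccmeta

A meta-analysis toolkit for the prognostic and clinicopathologic value of a
dichotomized tumor marker (high vs low expression) in hepatocellular
carcinoma, built around the quantitative synthesis of nine published
Asian cohort studies (1435 patients). It is aimed at biostatisticians and
reviewers who need the complete chain from study-level evidence to pooled
estimates to be scripted, testable and reproducible:

- **Study ingestion** — validated study records (arm sizes, assay,
  follow-up, endpoints, NOS quality score) from CSV/JSON, including the
  packaged nine-study characteristics table.
- **Effect extraction** — every reported form of evidence becomes a
  log-scale effect with standard error: a hazard ratio with 95% CI
  (`se = (ln U − ln L) / (2·1.959964)`), a 2×2 contingency table (Woolf:
  `ln OR = ln(ad/bc)`, `se = √(1/a+1/b+1/c+1/d)`, 0.5 continuity correction
  only when a cell is zero), or a pair of digitized Kaplan–Meier curves
  (piecewise-exponential interval reconstruction). When a study reports
  both univariate and multivariate estimates, the multivariate one is
  selected.
- **Pooling** — fixed-effect inverse variance and DerSimonian–Laird
  random effects: `τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`, with
  Cochran's Q, Higgins' `I² = max(0, (Q − df)/Q)·100`, between-subgroup
  chi-square difference tests, and leave-one-out sensitivity analysis.
- **Publication bias** — Begg–Mazumdar rank correlation (tie-corrected,
  continuity-corrected Kendall z on variance-adjusted deviates) and
  Egger's unweighted regression of `y/se` on `1/se` (intercept t-test,
  k−2 df).
- **Bootstrap re-sampling** — per-study 2×2 tables expanded to
  patient-level (exposure, outcome) pairs; 1000 seeded resample groups of
  5000 draws each give a distribution of group odds ratios and one
  combined five-million-sample table whose Woolf CI is razor-thin around
  the plug-in OR.
- **Synthetic data** — generators that emulate the study conditions
  (exponential event times under proportional hazards, per-study true log
  HR ~ N(ln 1.8, 0.1²), independent censoring, monthly-grid KM curves;
  multinomial 2×2 tables with true OR 1.7), so every stage is testable
  without any external data.

## Worked example

```python
import hccmeta as h

studies = h.included_studies()          # the nine packaged source studies
print(h.summarize_counts(studies).total_patients)   # 1435
print(h.summarize_counts(studies).high_percent)     # 54.2

# pooling a single reported effect is the identity: HR 1.82 (1.49-2.22)
pooled = h.pool_random_dl([h.loghr_from_ci(1.82, 1.49, 2.22)])
lo, hi = pooled.ratio_ci
print(f"{pooled.ratio:.3g} ({lo:.3g}-{hi:.3g})")    # 1.82 (1.49-2.22)
```

The numbered drivers under `analysis/` run the full synthesis on a
synthetic cohort and write their tables under `results/`:

```
python analysis/01_simulate_cohort.py    # 8 survival studies + 8 2x2 tables
python analysis/02_pool_survival.py
python analysis/03_subgroups_sensitivity.py
python analysis/04_publication_bias.py
python analysis/05_resample_tnm.py
```

A run of `02_pool_survival.py` prints, for example,

```
k=8 OS studies; Q=12.094 (df 7), I2=42.1%, significant heterogeneity: False
  reported_ci      fixed     HR 1.731 (1.542-1.943), p 1.3e-20
  reported_ci      random_dl HR 1.722 (1.477-2.009), p 4.5e-12
  km_reconstructed fixed     HR 1.728 (1.548-1.928), p 1.9e-22
  km_reconstructed random_dl HR 1.718 (1.474-2.003), p 4.7e-12
```

i.e. the pooled hazard ratio over the eight synthetic overall-survival
studies (true HR 1.8), its 95% CI and p value, the heterogeneity
statistics, and the agreement between the reported-CI extraction path and
the Kaplan–Meier curve-reconstruction path on the same patients. And
`05_resample_tnm.py` prints the re-sampling structure:

```
1000 groups x 5000 = 5,000,000 samples
group OR distribution: [1.175, 1.761]
combined OR 1.451 (95% CI 1.445-1.456, p 0); CI width 0.0107
```

The same stages are exposed as a CLI (`hccmeta simulate | summarize |
extract | pool | subgroup | loo | bias | resample | report`); `report`
runs the whole pipeline from a YAML/JSON config and writes TSV tables plus
a machine-readable `summary.json`.

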