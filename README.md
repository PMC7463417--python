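# pettex

Pretreatment ¹⁸F-FDG PET/CT texture analysis for predicting the interim
chemotherapy response of primary gastrointestinal diffuse large B-cell
lymphoma (PGIL-DLBCL).

About 40% of DLBCL patients are not cured by first-line R-CHOP
chemotherapy, so a pretreatment readout of who will reach interim complete
response (CR, Deauville score 1–3 at the PET scan after 3–4 cycles) is
clinically valuable. Beyond the classic semiquantitative metrics — SUVmax
and the metabolic tumor volume (MTV, the volume of voxels above 41% ×
SUVmax) — intratumor heterogeneity quantified by texture analysis carries
predictive signal: non-CR tumors tend to be larger, hotter, and more
heterogeneous.

`pettex` implements that workflow end to end as a tested, reusable library
for researchers in quantitative PET imaging:

- **synthetic_cohort** — phantom PET volumes (spherical tumors with
  spatially correlated log-normal heterogeneity), derived CT slices,
  perturbed second-reader masks, and clinical covariates, so the whole
  pipeline is exercisable without patient data;
- **imaging_io** — NIfTI volumes/masks and CSV cohort manifests with strict
  geometric validation, plus the Deauville-based CR/non-CR classification
  rule;
- **metabolic_metrics** — SUVmax, MTV (strict `>` at the 41% threshold),
  ROI volume, and maximal 3-D/in-plane diameters;
- **texture_features** — first-order histogram statistics (mean, SD,
  percentiles, skewness, kurtosis, mode/max-frequency, Shannon entropy) and
  grey-level co-occurrence matrix (GLCM) features
  (entropy = −ΣΣ P log₂ P, energy = ΣΣ P², inertia = ΣΣ (i−j)² P,
  variance = ΣΣ (i−μ)² P) in four in-plane directions;
- **stats_core** — Fisher's exact test (hypergeometric enumeration, one-
  and two-sided), Mann–Whitney U (exact/normal), Wilcoxon signed rank,
  Shapiro–Wilk, ICC(2,1) with qualitative bands, and chi-square/normal tail
  functions;
- **selection_modeling** — two-step feature selection (Mann–Whitney filter
  at α = 0.05, then the lowest-p survivor per category: uptake intensity,
  grey-level distribution, tumor size, heterogeneity), ROC analysis with
  Youden-index cutoffs, the DeLong test for correlated AUCs, and the
  combined logistic "prediction probability" (non-CR on SUVmax, first-order
  entropy, ROI volume, intestinal involvement) with Hosmer–Lemeshow
  calibration.

## Worked example

```python
from pettex.pipeline import analyze_cohort, format_report
from pettex.synthetic_cohort import CohortConfig, generate_cohort

records = generate_cohort(CohortConfig(seed=1))   # 20 CR + 10 non-CR
print(format_report(analyze_cohort(records)))
```

prints (abridged):

```
Cohort: 30 patients (20 CR, 10 non-CR)
...
ROC analysis (positive class: non-CR):
  marker                       cutoff   sens   spec    acc    AUC
  suvmax                     7.37e+03   0.80   0.80   0.80  0.830
  mtv_mm3                    1.19e+05   0.50   0.85   0.73  0.662
  ...
  prediction_probability        0.186   1.00   0.75   0.83  0.925

Hosmer-Lemeshow: chi2=4.383, df=8, p=0.821
MTV vs volume: Wilcoxon Z=-2.890 (p=0.00386); DeLong Z=-2.144 (p=0.032)
```

Each ROC row gives the Youden-optimal cutoff in feature units and the
sensitivity/specificity/accuracy achieved at it; the combined logistic
model's prediction probability attains the highest AUC (0.925 here), and
its Hosmer–Lemeshow p of 0.82 indicates no evidence of miscalibration. The
MTV is systematically smaller than the manually contoured volume (paired
Wilcoxon), while both rank patients similarly.

Runnable walkthroughs live in `examples/` (cohort simulation, texture
extraction, the full analysis, interobserver agreement). A thin CLI covers
the same stages from the shell:

```bash
pettex simulate --seed 9 --out cohort/
pettex extract cohort/manifest.csv --out features.csv
pettex analyze cohort/manifest.csv --out report.json
pettex report report.json
```

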