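# wltb — whole-liver tumor burden biomarkers and survival modeling

Metastatic pancreatic cancer has a dismal prognosis, and clinical scores
built on performance status and serum markers (ECOG, CRP, bilirubin,
CA 19-9) discriminate survival only modestly.  When the liver is involved,
contrast-enhanced CT plus a segmentation of the *whole liver tumor burden*
(WLTB) — the union of all liver metastases, analyzed as a single region —
offers additional quantitative prognostic signal.  `wltb` implements that
analysis end to end for researchers in quantitative imaging biomarkers:

* **13 per-patient imaging biomarkers** from a 3D CT volume plus
  co-registered liver / lobe / lesion label maps:
  * mean lesion attenuation (HU), WLTB volume (cm³) absolute and as % of
    liver volume;
  * **tumor burden score** TBS = √(N² + D²), with N the lesion count and D
    the largest lesion diameter (cm);
  * **bilobar disease** — metastases in both functional liver lobes,
    decided at voxel level;
  * the four-feature radiomics signature: first-order **energy**
    Σ x², shape **compactness** V/(√π·A^{3/2}), **GLRLM gray-level
    nonuniformity** Σᵢ(ΣⱼR(i,j))²/ΣᵢⱼR(i,j) over the 13 unique 3D run
    directions, and the same nonuniformity on an undecimated **wavelet**
    sub-band (default coif1/HLH);
  * **geometric metastatic spread** MSx/MSy/MSz (per-axis extent of the
    lesion union, cm) and the surface-area-to-volume ratio SA/V (1/cm) of
    the lesion union.
* **Survival modeling** (Cox proportional hazards, Efron ties): univariable
  screening at Wald p < 0.2; two established clinical baseline models
  (ECOG≥1 + log CRP + log bilirubin, and ECOG≥2 + CA 19-9 ≥ 1000 U/ml +
  elevated CRP); extension of a baseline with screened imaging candidates by
  **AIC backward elimination** with the clinical terms forced (keeping the
  models nested); nested **likelihood-ratio** comparison and Harrell
  C-index; **median-split risk stratification** with Kaplan–Meier curves and
  the log-rank test; Spearman/Pearson correlation heatmap with dendrogram.
* **A phantom cohort generator** — ellipsoidal two-lobed livers carrying
  1–113 hypodense spherical lesions (segmented count median ≈ 7), clinical
  covariates with realistic marginals, and survival times drawn from a
  proportional-hazards model with configurable ground-truth coefficients —
  so the full pipeline is testable and demonstrable without patient data.

The estimator layer follows scikit-learn conventions
(`WLTBFeatureExtractor`, `CoxPHModel`, `UnivariableCoxScreen`,
`BackwardEliminationCox`, `MedianRiskStratifier`), so the stages compose
with sklearn pipelines and model selection.

## Worked example

Run the whole pipeline on a simulated 75-subject cohort whose hazard is
driven by TBS, bilobar disease and log CRP:

```bash
$ wltb run --out demo --seed 7
C-index 0.581 -> 0.746, LR p = 3.3e-08; retained: tbs, bilobar, energy, glrlm_nonuniformity
```

The clinical baseline alone discriminates survival with C-index 0.581;
adding the imaging biomarkers that survive screening and AIC backward
elimination raises it to 0.746, and the likelihood-ratio test confirms the
extended model explains survival significantly better than its clinical
baseline (p = 3.3·10⁻⁸).  `demo/` then contains `features.csv` (one row of
the 13 biomarkers per subject), `table2.csv` (univariable hazard ratios
with 95% CIs and Wald p per biomarker — here TBS has HR 1.109 per unit,
p = 2.2·10⁻⁹, and bilobar disease HR 4.53, p = 1.4·10⁻⁴), `table3.csv`
(baseline and extended multivariable fits), `stratification.csv`
(median-split high/low risk groups), `correlation.csv` and
`manifest.json` (config hash, per-stage timings, candidate and retained
features).

The same stages are available as library calls:

```python
from wltb import PhantomConfig, generate_phantom, WLTBFeatureExtractor

cfg = PhantomConfig(subjects=10, seed=0)
pairs = [generate_phantom(cfg, i) for i in range(cfg.subjects)]
features = WLTBFeatureExtractor().fit().transform(pairs)   # 10 x 13 DataFrame
```

For real data, `wltb extract --image ct.nii.gz --labels labels.nii.gz
--out features.csv` computes the biomarker row for one subject, `wltb
validate` checks an external cohort (grid/spacing consistency, lesions
inside the liver, exclusion of subjects without visible metastases), and
`wltb fit --features features.csv --clinical clinical.csv --baseline haas`
runs the modeling stage alone.

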