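# fibropet

Quantitative PET/CT analysis for preclinical lung-fibrosis imaging with a
collagen-targeted radiotracer, packaged with a digital mouse-thorax phantom
that simulates whole study designs with known ground truth.

## The problem

Pulmonary fibrosis is an excessive deposition of extracellular-matrix
collagen that replaces aerated lung with dense tissue. In the bleomycin
(BLM) mouse model this can be followed non-invasively two ways:

* **CT**: fibrotic consolidation raises lung attenuation. The lung ROI is
  partitioned by Hounsfield-unit thresholds into *aerated* tissue,
  [-800, -100) HU, and *dense* (non-aerated) tissue, [-100, 300] HU; the
  mean lung density (MLD) and the dense-tissue fraction stage the disease.
* **PET** with a collagen-binding peptide (a gallium-68-labelled
  collagelin analogue): lung uptake is expressed as percent injected dose
  per gram,

  `%ID/g = 100 · c_corr / (A_inj · ρ)`,

  where `c_corr` is the ROI mean activity concentration decay-corrected to
  injection time (`c_corr = c_meas · 2^(t/T½)`, T½ = 67.71 min for Ga-68),
  `A_inj` the injected activity and `ρ` the tissue density. Static uptake
  is the frame-duration-weighted mean over the 15–75 min p.i. window;
  dynamic series yield time-activity curves (TACs) on 2-min frames.

The package implements that whole quantification chain (NIfTI I/O, mask
algebra, density segmentation, decay correction, compartment %ID/g, TACs,
ex vivo biodistribution ratios) plus the nonparametric statistics layer
used in such studies (median ± IQR, Mann-Whitney with exact small-sample
p, Kruskal-Wallis with Dunn-Bonferroni post-hoc, Spearman correlation with
exact permutation p, longitudinal Δ metrics and predictive correlations).

Because no public dataset exists for this design, the `phantom` module is
first-class: it renders CT volumes with controllable consolidation burden
and dynamic PET from a two-term kinetic model (perfusion washout +
saturable collagen binding), simulates five-arm longitudinal cohorts
(control, BLM, BLM+nintedanib, BLM+tofacitinib, BLM+cold-peptide
blocking), and records the ground truth every estimate can be checked
against. See `docs/methods.md` for the model and all defaults.

## Worked example

```python
from fibropet import (default_study_design, simulate_cohort,
                      quantify_cohort, run_study_analysis)

design = default_study_design(n_per_group=4)   # five arms, D0/D8/D15/D22
records = simulate_cohort(design, seed=1)      # 20 virtual animals
df = quantify_cohort(records)                  # CT + PET quantification
report = run_study_analysis(df)                # statistics layer

print(report.summary.query("metric == 'uptake' and day == 22"))
```

Day-22 window uptake (%ID/g, median and quartiles per arm):

```
          group  n   median       q1       q3
            BLM  4 3.055314 2.876513 3.156569
   BLM+blocking  4 0.328089 0.273558 0.391258
 BLM+nintedanib  4 0.535066 0.506390 0.629451
BLM+tofacitinib  4 0.607135 0.549918 0.649333
           NaCl  4 0.018757 0.018749 0.018764
```

Untreated BLM animals retain ~3 %ID/g of tracer at D22 while controls wash
out to background; both drugs pull uptake most of the way back and the
blocking arm (×100 cold peptide, 10% residual specific binding) sits just
above control. The attached tests and correlations:

```
Kruskal-Wallis D22 uptake: H = 17.39, p = 0.0016 **
Dunn-Bonferroni BLM vs NaCl: p = 0.0013
Spearman           pooled: rho = +0.78, p = 2.59e-17 (n=80)
Spearman              BLM: rho = +0.80, p = 0.333 (n=4)
Spearman   BLM+nintedanib: rho = -1.00, p = 0.0833 (n=4)
Spearman  BLM+tofacitinib: rho = -1.00, p = 0.0833 (n=4)
```

The pooled correlation says MLD and tracer uptake track each other across
the study; the per-group rows are the *predictive* correlations of D8
uptake against D8→D22 MLD progression — positive in untreated BLM (sicker
lungs progress more), negative under treatment (sicker lungs respond
more). At n = 4 the exact permutation p-values cannot fall below 0.083;
directions, not significance, are the point at this sample size.

A command-line layer wraps the same functions:

```sh
fibropet simulate --out cohort/ --seed 1
fibropet quantify-ct --ct ct.nii.gz --mask lung.nii.gz --out ct.json
fibropet quantify-pet --frames frames/ --mask lung.nii.gz --meta meta.json --out uptake.json
fibropet analyze --cohort cohort/ --out report/
```

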