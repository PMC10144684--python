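# coclin

Quantitative imaging and omics analysis for co-clinical trials.

A co-clinical trial evaluates a therapy concurrently in a patient cohort and
in a matched cohort of patient-derived xenografts (PDX) — human tumor tissue
engrafted into immunodeficient mice — so that pre-clinical and clinical
responses can inform one another. `coclin` implements the quantitative core
of such a study for breast-cancer MRI plus bulk RNA expression: it turns raw
4-D MRI series into voxel-wise parameter maps, maps into per-lesion
biomarkers, biomarkers into treatment-response tables and waterfall
orderings, and finally correlates imaging response with gene expression
across both cohorts.

## What it computes

**ADC maps** (diffusion-weighted MRI, a cellularity readout). Each voxel's
signal across diffusion weightings *b* (s/mm²) follows the monoexponential
model

    S(b) = S0 · exp(−ADC · b)

and the apparent diffusion coefficient ADC (mm²/s) is estimated per voxel by
bounded nonlinear least squares initialized from the closed-form log-linear
fit. Both the preclinical (b = 0, 150, 700 s/mm²) and clinical
(b = 0, 100, 600, 800 s/mm²) protocols are supported.

**SER maps** (dynamic contrast-enhanced MRI, a vascularity readout). The
semi-quantitative signal enhancement ratio is

    SER = (S_early − S_baseline) / (S_late − S_baseline)

with S_baseline the mean of the first 10 frames, S_early the post-baseline
peak, and S_late the signal six minutes after the peak. Non-enhancing voxels
are NaN.

**Lesion biomarkers.** Longest in-plane diameter, tumor volume, and
mean/median ADC and SER over the lesion mask; plus the bench caliper volume
`length × width² / 2` used to size engrafted tumors.

**Response.** Percent change of any biomarker between pre-treatment (T0) and
on-treatment (T1), per lesion; cohort waterfalls ordered smallest to
greatest response.

**Expression simulation.** On-treatment expression is simulated from
baseline tables by a per-sample 4-factor permutation: four multipliers drawn
uniformly from [0.5, 1.5] fixed per sample, one applied to each gene at
random, with the full assignment retained for audit.

**Association.** Per-gene Spearman correlation of expression (baseline or
delta) with an imaging feature's change, with exact permutation p-values for
small PDX arms (n ≤ 9) and the t-approximation otherwise, BH q-values,
top/bottom-500 ranked gene lists, cross-cohort Venn overlap, and volcano
tables.

A synthetic-phantom module generates complete cohorts (default 21 patients,
9 PDX) with known ground-truth ADC/SER fields, shrinking or growing
ellipsoidal lesions, and expression tables carrying a planted
response-associated gene signal — so every stage can be validated end to
end.

## Worked example

```python
import numpy as np
from coclin import (make_cohort, make_dwi_phantom, make_dce_phantom,
                    fit_adc_map, compute_ser_map, extract_lesion_features,
                    build_response_table, spearman_associate, cohort_overlap)

fx = make_cohort(seed=42)                     # 21 patients + 9 PDX, with truth
truth = fx.subjects[0]
feats = []
for tp in ("T0", "T1"):
    dwi, mask = make_dwi_phantom(truth, tp)
    dce, _ = make_dce_phantom(truth, tp)
    f = extract_lesion_features(mask, adc_map=fit_adc_map(dwi, mask),
                                ser_map=compute_ser_map(dce, mask),
                                subject_id=truth.subject_id, timepoint=tp)
    print(f"{tp}: diameter {f.longest_diameter:.1f} mm, volume {f.volume:.0f} mm^3,"
          f" ADC median {f.adc_median:.2e} mm^2/s, SER median {f.ser_median:.2f}")
    feats.append(f)
records, _ = build_response_table(feats, "volume")
print("volume response rate: %.1f%%" % records[0].response_rate)
```

prints

```
T0: diameter 19.2 mm, volume 2032 mm^3, ADC median 1.16e-03 mm^2/s, SER median 2.50
T1: diameter 17.0 mm, volume 1360 mm^3, ADC median 1.50e-03 mm^2/s, SER median 1.98
volume response rate: -33.1%
```

Subject P01 is a simulated responder (true volume change −32.5%): the
measured −33.1% volume response, rising ADC (falling cellularity) and
falling SER (reduced washout) all reflect the injected treatment effect; the
small discrepancy from truth is ellipsoid digitization plus acquisition
noise. Associating each cohort's baseline expression with the volume
response and intersecting the top-500 gene lists
(`spearman_associate`, `cohort_overlap`) recovers all 20 planted
positively-associated genes in the patient top list and yields overlap
counts `{'patient_only': 363, 'pdx_only': 363, 'shared': 137}` for this
seed.

The same stages run from the shell:

```sh
coclin make-cohort --n-patients 21 --n-pdx 9 --seed 42 --out cohort/
coclin run --manifest cohort/manifest.json --feature volume --seed 42 --out results/
```

`results/` then holds per-cohort response and waterfall CSVs, association
and volcano TSVs, ranked gene lists, the cross-cohort overlap JSON, and a
run log; a rerun under the same seed is byte-identical.

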