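# rectodose

Rectal surface dose mapping and discrimination analysis for HDR
brachytherapy with a protective rectal gel spacer.

## The problem

During high-dose-rate brachytherapy of cervical cancer the rectum is the
critical organ at risk: it sits millimetres behind the target, inside a
dose field that falls off roughly as 1/r² from the source dwell
positions.  One protection strategy injects a gel into the rectum that
inflates it and pushes the posterior rectal wall away from the source.
Quantifying what that does to the dose the wall actually receives
requires more than a scalar DVH point: the fractional doses must be
accumulated on the *wall surface* across fractions, unrolled into a 2D
dose map, and compared feature-by-feature between the paired pre-gel and
post-gel states.

`rectodose` implements that entire analysis for medical-physics
researchers:

1. **Dose accumulation** — per-fraction doses are converted to EQD2,
   `EQD2 = d(d + α/β)/(2 + α/β)` with α/β = 3 Gy, sampled onto a
   parameterized rectal-wall surface (rings × angular samples with
   (u, v) coordinates from a left-lateral anchor), and summed across
   fractions by shared-(u, v) correspondence (a pluggable registration
   interface).
2. **Unfolding** — the cumulative 3D surface dose becomes a 2D rectal
   surface dose map (RSDM) at 1 mm × 1 mm, split per slice at 50% of the
   circumference into anterior and posterior halves.
3. **Features** — 363 per region: 50 dose-volume parameters
   (D_0.1cc–D_5.0cc), 43 textures (global, GLCM, GLRLM, GLSZM, NGTDM)
   and 270 dose-geometric parameters (area, relative area, eccentricity,
   axes, perimeter, centroid distances at 1–30 Gy levels).
4. **Discrimination** — a grid of 24 feature-selection strategies × 8
   classifiers (192 models) under patient-grouped fivefold CV; features
   ranked by top-20 selection frequency among models with mean
   AUC > 0.80; Isomap projection of the top-10 features.
5. **Statistics** — Shapiro–Wilk-gated paired t / Wilcoxon comparisons
   with the matching mean ± SD / median (IQR) summaries.

Because paired clinical CT/plan data of this kind are not public, the
package includes a seeded synthetic cohort generator that reproduces the
study's structure: elliptical rectum cross-sections, a gel effect that
dilates the rectum laterally more than antero-posteriorly and shifts it
posteriorly, inverse-square dose fall-off from dwell positions at the
CTV, and smooth inter-fraction deformation.  See `docs/methods.md` for
the model and every numerical convention.

## Worked example

```python
import rectodose as rd

# paired synthetic cohort: 4 patients, pre+post gel, 5 x 6 Gy fractions
cases = rd.generate_cohort(rd.CohortConfig(n_patients=4, seed=7))
features = rd.DosimetricFeatureExtractor(n_theta=128).fit(cases).transform(cases)

sub = features[features.region == "posterior"].reset_index(drop=True)
pre = sub[sub.condition == "pre"].sort_values("patient_id")
post = sub[sub.condition == "post"].sort_values("patient_id")
print(pre["D_2.0cc"].round(2).tolist())
print(post["D_2.0cc"].round(2).tolist())
```

prints the posterior-wall D_2cc (EQD2 Gy, accumulated over 5 fractions)
for the four patients before and after the gel:

```
[7.69, 5.64, 6.8, 7.89]
[7.52, 5.29, 6.32, 7.53]
```

every patient's posterior wall is spared post-gel (the dose to the most
exposed 2 cm³ drops), which is exactly the effect the configured gel
geometry should produce.  On a 30-patient cohort the paired posterior
D_1cc comparison is significant at p < 1e-10 and the best of the 192
posterior-region discrimination models exceeds a mean AUC of 0.85,
while cohorts generated with the gel disabled stay at chance.

A CLI mirrors the stages:

```bash
rectodose simulate    --config cohort.yaml --out sim/ --seed 1
rectodose features    --config cohort.yaml --out feat/
rectodose discriminate --features feat/features.csv --region posterior --seed 1 --out disc/
rectodose run         --config run.yaml --out bundle/
```

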