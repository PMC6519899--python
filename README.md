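# asphere

Asphericity of functional tumor volumes on SPECT-like images, and its
association with per-lesion morphological treatment response.

## The problem

In peptide receptor radionuclide therapy (PRRT) of somatostatin-receptor
(SSR) positive neuroendocrine tumors, not every metastasis responds.
A candidate imaging biomarker is the *spatial heterogeneity* of SSR uptake:
lesions whose functional volume deviates strongly from a sphere tend to
respond worse. This package implements the full analysis chain behind that
claim, for researchers who want to compute the score on their own volumes
or stress-test the methodology on synthetic ground truth:

1. **Delineation** — a semi-automatic, background-adapted iterative
   threshold segments the functional tumor volume (FTV) from a seed voxel:
   `T = B + q·(A_peak − B)` with the local background `B` re-estimated in a
   shell around the evolving volume of interest (default `q = 0.39`).
2. **Asphericity (ASP)** — for a volume of interest with surface area *S*
   and volume *V*,

   `ASP = 100 · ( (S³ / 36πV²)^⅓ − 1 )` ,

   i.e. the percentage excess surface over a sphere of equal volume: 0 for
   a perfect sphere, ~1–5 % for near-spherical uptake, large for elongated
   or lobulated patterns. *S* is measured on an anti-aliased marching-cubes
   mesh; *V* by voxel counting.
3. **Response** — per-lesion RECIST 1.1 on baseline/follow-up diameters
   (CR/PR/SD/PD), cumulated into responding (RL = CR/PR/SD) and
   non-responding (NRL = PD) lesions, with the study's eligibility
   (≥10 mm, lymph nodes ≥15 mm) and selection (≤2 per organ, ≤5 per
   patient) rules.
4. **Statistics** — Kruskal–Wallis across classes, Mann–Whitney U for
   RL vs NRL, ROC with the Youden-optimal cutoff (`J = sens + spec − 1`),
   Spearman's ρ and Bland–Altman limits of agreement with a ≤5-percentage-
   point concordance rule for paired ASP readings.

Because clinical SPECT data cannot be shipped, the package includes a
first-class synthetic layer: phantoms (spheres, ellipsoids, lobulated
sphere unions) with *closed-form* volume, surface and ASP, and lesion
cohorts whose per-class ASP and diameter distributions follow published
five-number summaries via a piecewise-linear quantile model.

## Worked example

```python
from asphere.shape import measure_voi
from asphere.synthetic import PhantomSpec, ShapeSpec, make_phantom

spec = PhantomSpec(shape=ShapeSpec("ellipsoid", semi_axes_mm=(20, 10, 10)),
                   grid_shape=(92, 92, 92), spacing_mm=(1, 1, 1))
grid, truth, analytic = make_phantom(spec)
m = measure_voi(truth, grid)
print(f"analytic ASP {analytic['ASP_percent']:.2f} %, measured {m.ASP_percent:.2f} %")
```

prints

```
analytic ASP 7.67 %, measured 6.28 %
```

— a 2:1 prolate lesion deviates ~8 % from sphericity and the mesh estimate
lands within the documented discretization tolerance (±2 pp at 1 mm
spacing). The scripts in `examples/` walk through each capability; e.g.
`python examples/04_cohort_study.py` generates the default 131-lesion
cohort (104 RL / 27 NRL) and prints

```
ROC AUC          : 0.917
Youden cutoff    : ASP > 5.84 %  (sens 85 %, spec 88 %)
```

meaning that in this draw an ASP above ~6 % flags a non-responding lesion
with high sensitivity and specificity; the model-implied AUC of the
generating distributions is 0.876 and individual 131-lesion draws scatter
around it.

A thin CLI mirrors the pipeline for shell use:

```bash
asphere simulate --what cohort --seed 1 --out cohort.csv
asphere segment --in vol.nii.gz --seed 36,36,36 --q 0.39 --out mask.nii.gz
asphere asp --vol vol.nii.gz --mask mask.nii.gz
asphere classify --table cohort.csv --timepoint 12m --out labeled.csv
asphere run-all --seed 1 --out-dir study_out --plots
```

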