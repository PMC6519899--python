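# Methods

## The asphericity score

For a delineated volume of interest with surface area *S* (mm²) and volume
*V* (mm³), define `H = S³ / (36π V²)` and `ASP = 100·(H^⅓ − 1)`. *H* is
the cube of the ratio of *S* to the surface of a sphere with volume *V*
(the isoperimetric inequality gives H ≥ 1 for exact geometry), so ASP is
the percentage excess surface over the equal-volume sphere. ASP is
invariant under rigid motions and isotropic scaling and grows with
elongation and lobulation, which is what makes it a shape — not size —
marker of uptake heterogeneity.

### Estimators

* **Volume** is voxel counting: `V = n_voxels · voxel_volume`. This is the
  natural volume of a threshold delineation ("functional tumor volume");
  the volume enclosed by the surface mesh is also reported, as a
  diagnostic only.
* **Surface** is the area of a triangulated iso-surface: the binary mask
  is anti-aliased with a Gaussian of one voxel SD (per axis, in voxel
  units) and the 0.5 level set is extracted by marching cubes honoring
  anisotropic spacing. Two simpler estimators are biased in ways that
  matter here: summing exposed voxel faces overestimates a sphere's area
  by ~50 %, and marching cubes on the raw binary mask still by ~9 %
  (staircase facets); both would shift every ASP upward. With one-voxel
  anti-aliasing the sphere error is below 1 % at 1 mm spacing and falls
  with refinement. The cost is a small curvature-dependent smoothing bias:
  at 1 mm spacing a (20,10,10) mm prolate ellipsoid reads ≈1.4 ASP
  percentage points low, within the package's documented ±2 pp
  discretization tolerance, and a factor ~4 smaller at 0.5 mm.
* ASP is **not clipped at zero**: a rasterized sphere can measure slightly
  negative (the mesh slightly under-estimates *S* relative to the voxel
  count *V*), and clipping would bias averages of near-spherical lesions.
* Masks touching the array border are rejected (the mesh would be
  clipped); a mask too small to survive anti-aliasing (e.g. one voxel)
  falls back to the raw-mask iso-surface so the area stays finite.

## Delineation

The functional tumor volume is segmented by an iterative, locally
background-adapted threshold, the algorithm family used by clinical
SSR-SPECT analysis software:

1. start from the 26-connected component above 50 % of the
   seed-neighborhood peak;
2. estimate background *B* as the **median** activity in a 10–20 mm
   distance shell around the current VOI (median rather than mean for
   robustness to hot neighbors, which can also be masked out explicitly);
3. threshold at `T = B + q·(A_peak − B)` and take the 26-connected
   component containing the seed;
4. repeat until two successive masks are identical (exact equality —
   masks are finite sets) or 50 iterations.

Defaults: `q = 0.39`; `A_peak` is the mean of the 3×3×3 neighborhood
around the hottest VOI voxel (`peak_mean`; plain `max` is provided).
These two choices are exposed as parameters because published descriptions
of the clinical implementations do not pin them down; both defaults are
assumptions, chosen once and validated on phantoms. A lesion is rejected
as "not delineable" when the peak-to-background contrast is below 0.3,
mirroring clinical exclusion of lesions that cannot be clearly delineated.

On noiseless spheres the recovered volume is exact up to the one-voxel
boundary shell; with an 8 mm FWHM PSF and 10:1 contrast the volume error
stays below 15 % for radii 8–24 mm at 2 mm voxels, with the largest error
at the smallest radius (partial-volume effect) — the behavior that
motivates the minimum-size eligibility rules below.

## Response rules

RECIST 1.1 is defined on sums of target-lesion diameters; this package
applies the rules per lesion (matching the lesion-based study design it
follows), with the adaptation flagged here: CR = disappearance (lymph
nodes: normalization to <10 mm short axis), PR = change ≤ −30 %,
PD = change ≥ +20 % **and** ≥ +5 mm, SD otherwise. Thresholds are
inclusive on the response side stated. Eligibility is ≥10 mm baseline
diameter (≥15 mm short axis for lymph nodes), inclusive, because the
clinical exclusion is written as strict "<". When more than two lesions
per organ (five per patient) are available, lesions are ranked by FTV as
a quantitative proxy for "most representative uptake" — the visual
criterion has no quantitative definition — with a lesion-id tie-break for
determinism. A patient-level sum-of-diameters mode exists but is off by
default.

## Statistics

* Kruskal–Wallis (tie-corrected, χ² approximation) across CR/PR/SD/PD;
  all-tied input returns H = 0 by convention. Mann–Whitney U (tie- and
  continuity-corrected normal approximation) for RL vs NRL. Both delegate
  to scipy.stats and are re-verified in the tests against the hand rank
  formula.
* ROC: the positive class is NRL (higher ASP ⇒ poorer response) and is
  asserted, never auto-detected. Candidate cutoffs are midpoints of
  consecutive distinct scores plus ±∞ (if a midpoint is not representable
  strictly between two floats, the lower score itself is used — the
  strict ">" rule still separates exactly). AUC is the trapezoid
  integral and equals U/(n₁n₂) with half credit for cross-class ties.
  The Youden-optimal cutoff maximizes J = sens + spec − 1; ties go to the
  lowest cutoff (maximizing sensitivity, the screening-oriented choice),
  reported with the "greater than" convention.
* Bland–Altman: differences a − b, limits of agreement mean ± 1.96·SD
  (sample SD, n−1; the z-multiplier, not a t-quantile, following standard
  practice). A pair is discordant iff |difference| > 5 ASP percentage
  points — absolute points, not 5 % relative, and inclusive at exactly 5.
* p-values are two-sided; significance is conventionally read at 0.05.

## Synthetic data

### Phantoms

A phantom is an analytic shape (sphere; triaxial ellipsoid; lobulated
union of overlapping spheres) rasterized by the voxel-center rule onto a
grid with given spacing, set to `lesion_activity` inside and
`background_activity` outside (default 10:1), blurred by an isotropic
Gaussian PSF (default 8 mm FWHM, typical of SPECT), with optional Poisson
count noise. Projection, scatter and attenuation are deliberately not
modelled: the phantom emulates a *reconstructed* volume, so passing tests
say nothing about reconstruction artifacts. Closed-form metrics: exact
Legendre elliptic-integral surface for triaxial ellipsoids (prolate/
oblate/sphere limits special-cased), inclusion–exclusion with lens and
spherical-cap formulas for sphere unions (valid for pairwise-only
overlaps, which is verified, on a 1 mm probe grid, and enforced).

### Cohorts

Published cohort results report per-class ASP and per-group diameter
distributions only as median/IQR/range. The generator models each as the
piecewise-linear quantile function through the five points at
probabilities (0, ¼, ½, ¾, 1) — the minimal model that reproduces every
printed summary exactly in the large-sample limit. The defaults are the
five-number summaries of a 131-lesion [177Lu]DOTATATE cohort: ASP medians
0.5 / 1.7 / 3.4 / 11.3 % for CR / PR / SD / PD, group summaries for RL
(104 lesions) and NRL (27), baseline diameters ~19–20 mm median, organ
mix liver 59 : lymph node 48 : bone 19 : pancreas 5. The CR/PR/SD split
of the 104 responding lesions is not published; the default 6/33/65 is a
package choice consistent with the group total. Functional tumor volumes
are an identical lognormal across classes (median 12 ml, log-SD 0.7,
clipped to 2.5–150 ml), reflecting that FTV did not differ between
response groups.

Follow-up diameters are drawn uniformly inside each class's
RECIST-consistent interval (PR: 35–70 % of baseline, floored above the
node-normalization bound; SD: 70.5–119.5 %; PD: from
max(+20.5 %, +5.05 mm) spanning 40 pp; CR: 0), so reclassifying the
generated table recovers the generating labels exactly at both the
4- and 12-month columns — the closed loop every downstream test relies
on. Baseline diameters are truncated at the organ's eligibility
threshold so no generated lesion is filtered out. Lesions are packed
into synthetic patients honoring the ≤2/organ and ≤5/patient selection
rules. Under this model the exact RL-vs-NRL AUC is 0.8756 (closed-form
integration over the 4×4 grid of piecewise-uniform components); note
that the *empirical* AUC of any single 131-lesion draw scatters widely
(roughly ±0.05) around it, and the model AUC is a property of the
printed summaries, not of the original patient data.

For the method-agreement sub-study, 77 latent lesion ASPs from the
RL/NRL mixture receive two independent Gaussian reading errors of SD
3.1/√2 pp each, making the paired difference SD 3.1 pp — chosen so the
1.96-SD limits of agreement sit near ±6 pp and ~10 % of pairs exceed the
5 pp concordance limit, the regime the method-comparison literature for
this score reports.

All randomness flows from one integer seed through CRC-tagged
`SeedSequence` spawn keys, so each stage's stream is independent of call
order and stable across processes.

## Pipeline

`run_study` composes the stages in order (generate/load → eligibility →
selection → classify → statistics), logs every filter decision with
lesion ids, and writes a labeled CSV plus a JSON report whose provenance
block carries the config hash (output paths excluded), seed and version;
no timestamps are embedded, so a rerun with the same seed is
byte-identical. Figures (per-class boxplots, ROC, Bland–Altman) are
optional matplotlib files; cosmetic fidelity is a non-goal.

## Problem sizes and known limitations

Validation uses grids up to ~150³ voxels at 0.5–2 mm spacing, radii
8–24 mm, cohorts of 131 lesions, and 10⁵-sample Monte-Carlo checks —
sizes at which the discretization tolerances above hold with margin.
Known limitations: the quantile model is uncorrelated across ASP, FTV
and diameters (the joint distributions are unpublished); phantoms do not
model reconstruction physics or heterogeneous background anatomy; the
per-lesion RECIST adaptation and the FTV selection proxy are
package-level interpretations of under-specified clinical procedure; the
surface estimator's smoothing bias grows with curvature relative to
voxel size, so very small lesions at coarse spacing read a few ASP
points low — the same partial-volume regime the eligibility rules
exclude clinically.
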