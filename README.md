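# epifat

Quantification of epicardial and abdominal adipose tissue on non-contrast
CT, with a morphological quality check for heart segmentations, a synthetic
phantom/cohort generator, and the statistical battery used to relate fat
depots to glucose tolerance.

## Who this is for

Researchers analysing cardiometabolic imaging cohorts: epicardial adipose
tissue — the fat inside the pericardial sac — expands and becomes more
lipid-rich (lower CT attenuation) as glucose metabolism deteriorates from
normal tolerance through pre-diabetes (IFG, IGT, CGI) to type-2 diabetes,
but it co-varies strongly with BMI, waist circumference and abdominal
visceral fat. Disentangling these requires exact voxel-level measurement,
trustworthy segmentations and careful covariate-adjusted regression. This
package implements all three stages, plus synthetic data so every stage is
testable without patient images.

## What it computes

**EAT quantification.** A voxel is epicardial fat when it lies inside the
pericardium mask, outside the heart-chamber mask, and its attenuation falls
in the closed adipose window [−190, −30] HU. Then

- EATV (ml) = voxel count × dx·dy·dz / 1000, where dz is the *slice
  increment* — 1.5 mm for 3 mm slices reconstructed at 50 % overlap, so
  overlapping slices are not double-counted;
- EATA (HU) = exact sample median attenuation of the selected voxels.

**Segmentation QC.** A heart segmentation is flagged as potentially failed
when part of it lies outside the mask obtained by eroding the heart 15 mm,
keeping the largest 26-connected component, and dilating 35 mm — all
metrically, by thresholding the Euclidean distance transform in physical
millimetres, so anisotropic grids behave correctly. The volume outside this
QC mask is tabulated; above a cut-off (default 1 ml) the segmentation is
flagged.

**Abdominal VAT/SAT.** On a single 5 mm slice at L4, fat is thresholded
with the same HU window and split by an inside-lean-tissue filter: fat
enclosed by the (morphologically closed) muscular wall is visceral, the
rest subcutaneous. Areas in cm², median attenuations in HU.

**Statistics.** Median/IQR group summaries with differences vs. the NGT
reference and Kruskal–Wallis/chi-square tests; Kendall tau-b trend across
the ordered groups NGT–IFG/IGT–CGI–T2D with a seeded bootstrap CI;
HOMA-IR = insulin × glucose / 22.5; confounder qualification (association
with EATV independent of VAT area at p < 0.10 in the NGT group); staged OLS
models (exposure alone; + BMI; + waist; + VAT area; + confounders; and for
attenuation outcomes additionally + EATV), all complete-case with analytic
95 % CIs.

**Synthetic data.** `epifat.phantom` builds cardiac/abdominal phantoms with
exactly known fat content and injects parameterised segmentation failures;
`epifat.cohort` draws five-group subject tables via a Gaussian copula whose
marginals (median/IQR) and dependence emulate the published cohort, with
attenuation tied to EATV at a slope of −0.082 HU/ml.

## Worked example

```python
from epifat.phantom import generate_cardiac_phantom
from epifat.eat import quantify_eat
from epifat.qc import qc_check
from epifat.cohort import generate_cohort
from epifat.stats import kendall_trend, pairwise_regressions

vol, truth = generate_cardiac_phantom(noise_sd_hu=10.0, seed=1)
m = quantify_eat(vol, truth.pericardium_mask, truth.chamber_mask)
print(f"EATV = {m.volume_ml:.1f} ml (truth {truth.true_eatv_ml:.1f}), "
      f"EATA = {m.median_hu:.1f} HU (truth {truth.true_eata_hu:.1f})")

report = qc_check(truth.pericardium_mask, None, vol.spacing)
print(f"QC: outside volume = {report.outside_volume_ml:.2f} ml, flagged = {report.flagged}")

table = generate_cohort(seed=1)
tau = kendall_trend(table, "eatv_ml", seed=1)
slope = pairwise_regressions(table)["eata_on_eatv"]
print(f"cohort n = {len(table)}; Kendall tau (EATV vs glucose groups) = "
      f"{tau.tau:.3f} [{tau.ci_low:.3f}, {tau.ci_high:.3f}]")
print(f"EATA-on-EATV slope = {slope.slope:.4f} HU/ml (R = {slope.r:.3f})")
```

prints

```
EATV = 103.7 ml (truth 103.7), EATA = -70.0 HU (truth -70.0)
QC: outside volume = 0.00 ml, flagged = False
cohort n = 1948; Kendall tau (EATV vs glucose groups) = 0.153 [0.121, 0.186]
EATA-on-EATV slope = -0.0822 HU/ml (R = -0.688)
```

The phantom's measured EATV/EATA match its painted ground truth; an intact
heart is never flagged; the synthetic cohort shows the expected positive
volume trend and negative attenuation trend across glucose groups, and the
attenuation–volume regression recovers the generator's built-in slope.

A command-line interface mirrors the library:

```bash
epifat synth-phantom --kind cardiac --seed 1 --out phantom/
epifat quantify-eat --volume phantom/volume.nii.gz \
    --pericardium phantom/pericardium.nii.gz --chambers phantom/chambers.nii.gz
epifat qc-check --segmentation phantom/pericardium.nii.gz
epifat synth-cohort --seed 1 --out cohort.csv
epifat run-stats --cohort cohort.csv --outcome eatv --out stats/
epifat run-all --seed 1 --out run/        # everything, with a manifest
```

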