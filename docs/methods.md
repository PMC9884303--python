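# Methods

This note documents the models and procedures implemented in `epifat`, the
parameters that matter, and what the synthetic data can and cannot show.

## EAT quantification

The depot is defined purely geometrically and radiometrically: voxels inside
the pericardium mask, outside the chamber mask, with attenuation in a closed
window [−190, −30] HU. Both endpoints are **inclusive**; a voxel at exactly
−30 HU counts as fat, one at −29 HU does not. The chamber mask is
intersected with the pericardium before subtraction, so chamber voxels
outside the sac are irrelevant by construction. Voxels are all-or-nothing —
no partial-volume weighting — and the median attenuation is the exact sample
median on the native grid (midpoint convention for even counts), computed
before any resampling. An empty selection raises rather than returning a
sentinel; `FatMeasurement.median_hu` is `None` in that case.

Volume uses the **slice increment**, not the slice thickness. The cardiac
protocol this models reconstructs 3 mm slices at 50 % overlap, so
consecutive slices are 1.5 mm apart; summing thicknesses would count every
piece of tissue twice. `VoxelVolume.spacing` therefore carries the
increment, and `volume_ml = count · dx · dy · dz_increment / 1000`. Stacks
with missing slices are not extrapolated; quantification operates on the
grid it is given.

## Segmentation quality check

A failed heart segmentation deviates conspicuously from a heart's compact
shape. The check builds a plausibility region from the segmentation itself:
erode 15 mm, keep the largest connected component, dilate 35 mm. Volume
outside that region is tabulated; above `cutoff_ml` the case is flagged for
review.

Numerical choices:

- **Metric morphology.** Erosion and dilation threshold the Euclidean
  distance transform computed with the physical voxel spacing
  (`scipy.ndimage.distance_transform_edt(..., sampling=spacing)`), so
  "15 mm in all dimensions" is honoured on anisotropic grids. Conventions:
  erosion keeps voxels whose distance to background **exceeds** e; dilation
  keeps voxels **within** d of the mask. An iterated-structuring-element
  implementation would make the distances lattice-dependent.
- **Connectivity** for component labelling is 26-neighbour (configurable);
  standard for solid organs.
- **Cut-off.** The method's cut-off is inherently a free parameter tuned to
  reviewer workload; the default of 1.0 ml flags every injected failure of
  ≥ 5 ml placed beyond the dilation reach while producing zero false flags
  on intact phantoms, which is the operating point the validation tests
  assert.
- **Degenerate geometry.** A segmentation that vanishes under 15 mm erosion
  cannot be a heart; it is flagged (`eroded_empty`) rather than raising.

For convex segmentations the erode-then-dilate mask (net +20 mm) always
contains the original up to voxel discretisation, which is why intact
phantoms are never flagged at any non-negative cut-off; this fails for
non-convex shapes with thin bridges, which is exactly the sensitivity the
check relies on.

## Abdominal VAT/SAT separation

Fat on the single 5 mm L4 slice is thresholded with the same adipose window
(whether the original abdominal analysis used a different window is
unknowable from the publication; the cardiac window is reused and
configurable). Lean tissue defaults to [−29, +150] HU — the floor abuts the
adipose ceiling. The inside-lean-tissue filter closes the lean wall
metrically (default radius 5 mm, sealing anatomical gaps up to roughly the
closing diameter), computes the strict enclosed interior by hole-filling
from the image border, and reattaches closing-added pixels connected to
that interior (so swallowed boundary pixels and sealed gap bridges count as
inside, while an unsealed wall yields no interior at all). Fat inside the
interior is VAT, all other fat is SAT; the two masks partition the fat mask
exactly. No volumetric abdominal measure exists — the protocol acquires one
slice.

## Phantoms

The cardiac phantom is a pair of concentric ellipsoids on a
128 × 128 × 96 grid at 1 × 1 × 1.5 mm: pericardium semi-axes
(45, 40, 34) mm, chambers (40, 35, 26) mm, giving a fat shell of ≈ 104 ml —
the adult scale of the depot. The HU palette (lung −800, blood +40, fat −70,
chest wall +30) straddles the adipose window on both sides so window-edge
behaviour is testable. Noise is additive Gaussian (default SD 10 HU for
cardiac, 5 for abdominal), clipped to [−1000, 1000]; it is the simplest
model that makes the median a non-trivial statistic. Ground truth is always
an exhaustive voxel count on the painted labels, never an analytic formula,
so truth and measurement share the grid and agree exactly in the noiseless
case. No attempt is made at anatomical realism, gating, dose modulation or
reconstruction kernels; the published HU distribution of real epicardial
fat is not known in enough detail to calibrate to, so the fat centre and
noise SD are free parameters, not claims.

Failure injection honours its magnitude to within one voxel by
construction: the blob/wedge is the exact number of voxels
(`round(magnitude_ml·1000 / voxel_mm3)`) nearest to the target site, with
deterministic tie-breaking. Three modes: a detached blob at a given offset
beyond the surface, a deleted wedge at the surface, and a connected finger
("leak") running outward. Real failure modes are only known qualitatively;
these three parameterise the include/omit errors the QC step must catch.

## Synthetic cohort

Five groups (NGT n=1012, IGT 321, IFG 414, CGI 128, T2D 73; total 1948)
with the published medians, IQRs and categorical rates. Continuous margins:
log-normal for EATV, VAT area and HOMA-IR (right-skewed, positive), normal
for BMI, waist, attenuations and glucose; each margin is solved in closed
form from its (median, IQR). Dependence between EATV, VAT, BMI, waist and
HOMA-IR comes from a Gaussian copula with Spearman targets converted to the
latent scale via 2·sin(πρ/6); the published pairwise extremes (0.581–0.739)
anchor the matrix and the remaining entries are an explicit, editable
assumption (`DEFAULT_RANK_CORR`).

EATA is generated structurally, `eata = med_a + b·(eatv − med_v) + ε` with
b = −0.082 HU/ml, the residual SD solved per group so the EATA IQR stays on
target; VAT attenuation likewise with slope −0.129; SAT attenuation is an
independent margin (its published behaviour is flat across groups). Group
medians for VAT/SAT attenuation outside NGT/IGT are interpolations, as the
publication prints only those two groups.

EATV carries small built-in confounder effects — age +1.0 ml/yr, male sex
+15 ml, smoking +12 ml, physical activity −15 ml — mean-centred per group
and compensated in the base scale so medians/IQRs stay calibrated. Their
sizes are chosen so the p < 0.10 qualification rule has comfortable power
at the NGT group size, making {age, sex, smoking, physical activity} the
expected qualified set. Season, education, alcohol and lipid-lowering
medication have no built-in effect.

Age is uniform on a 14-year window inside 50–64 centred near each group
median (the recruitment age band). Fasting glucose margins are invented at
physiologically sensible group levels; insulin is back-solved so
HOMA-IR = insulin·glucose/22.5 holds row for row.

**What passing tests do not show.** The generator reproduces marginal
location/scale and a plausible dependence structure, not the real joint
distribution: no measurement error model, no recruitment enrichment, no
within-subject physiology. Parameter-recovery results (slope −0.082
recovered to ±0.005 over 20 seeds; positive EATV and negative EATA trends)
demonstrate that the *pipeline* is unbiased under known conditions, not
that the published coefficients would be recovered from new patient data.

## Statistics

- Group-vs-reference tests are pairwise two-sample Kruskal–Wallis
  (equivalent to Mann–Whitney) per continuous variable, chi-square across
  all groups for categorical ones; no multiplicity correction is applied.
- The trend test is Kendall tau-b (tie-corrected) with the ordinal coding
  NGT=0, IFG/IGT=1 (shared rank — the ordering does not separate them),
  CGI=2, T2D=3; p-values from the tie-corrected normal approximation; CI by
  seeded percentile bootstrap (default 2000 resamples) with a
  normal-approximation alternative flagged in the result.
- Staged models are OLS with analytic 95 % CIs, complete-case. Models 2–4
  add BMI, waist and VAT area one at a time (non-cumulative). Model 5 is
  exposure + VAT area + qualified confounders (VAT being the strongest and
  final anthropometric adjustment; the anthropometric is a keyword
  argument). Model 6, defined for the attenuation outcome only, adds EATV.
  HOMA-IR enters untransformed; rank-deficient designs raise a
  `CollinearityError` naming the offending columns rather than silently
  pseudo-inverting.

## Problem sizes

Default test/analysis sizes are chosen for seconds-scale feedback: 128³-ish
phantom grids, ≤ 32³ fixtures for brute-force morphology oracles (pairwise
physical distances via KD-trees), 100 randomised ≤ 16³ grids for the
voxel-rule oracle, 20 seeded cohort replicates for calibration, 500
replicates at n=160 for type-I-error control, and a 256 × 256 × 160 grid
for blob-injection cases so a 20 ml blob at 65 mm offset fits in any
direction.

## Known limitations

- No partial-volume handling; attenuation medians are sensitive to the
  window at the voxel scale real scanners blur.
- The QC cut-off transfers to real data only after re-tuning; its default
  is validated against synthetic failures only.
- The abdominal filter is a behavioural reimplementation of the
  inside-lean-tissue idea, not a replication of any specific production
  filter's internals; L4 level selection is out of scope.
- Pericardium/chamber segmentation itself (a deep-learning problem) is out
  of scope; masks are inputs.
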