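# hepavol

Volumetric and density response assessment of diffuse liver metastases on
contrast-enhanced CT.

## The problem

Drug response in patients with diffuse neuroendocrine liver metastases is
conventionally graded with RECIST 1.1: the sum *S* of the longest axial
diameters of at most two target lesions per organ, with categories

- **PR** if ΔS ≤ −30 %,
- **PD** if ΔS ≥ +20 % *and* the absolute increase is ≥ 5 mm,
- **CR** if all targets disappear, **SD** otherwise.

With dozens of lesions per liver, two diameters are a poor surrogate for the
tumor burden. `hepavol` instead measures **every** lesion on the
portal-venous phase:

- **V** — total tumor volume (cm³), the sum over all segmented lesions;
- **D** — mean volumetric tumor density (HU), the voxel-weighted mean CT
  value over the union of all tumor voxels;
- the percent changes ΔV, ΔD, ΔS from the pre-treatment baseline and the
  combined statistic **Δ(V+D) = ΔV + ΔD**.

Segmentation is semi-automatic: the liver is thresholded from a
two-component Gaussian-mixture intensity model (liver vs non-liver) fitted
by EM on a radiologist-seeded axial slice, keeping the largest connected
component and closing holes; tumors inside the liver are then classified
voxel-by-voxel by a four-layer backpropagation network fed 10 statistical
and gray-level co-occurrence (Haralick) texture features from each voxel's
11×11×11 neighborhood, followed by morphological clean-up and optional
batch edits. Cohort-level analysis correlates each change statistic with
progression-free survival (Pearson *r*, complete-case).

A synthetic phantom generator (ellipsoidal liver, non-overlapping spherical
tumors with configured volume scalings and HU shifts, Gaussian noise)
provides exact analytic ground truth for end-to-end validation.

## Worked example

```bash
python examples/cohort_analysis.py
```

prints, from the packaged 25-patient cohort table:

```
cohort: 25 patients, 21 with recorded PFS

metric    r        P        interpretation
d(V+D)   -0.653   0.001    significant
dV       -0.617   0.003    significant
dD       -0.226   0.325    not significant
dS       -0.548   0.010    significant

group means (%):
  progression     n= 7  dV= +134.1  dD=  -8.7  dS= +75.0
  nonprogression  n=18  dV=  +36.6  dD=  +6.4  dS= -13.5
```

Increases in tumor burden correlate inversely with progression-free
survival, and the combined Δ(V+D) statistic (r = −0.653) tracks PFS more
strongly than the RECIST size change alone (r = −0.548); density change by
itself does not (P = 0.325). The other examples
(`phantom_end_to_end.py`, `liver_segmentation_demo.py`,
`recist_vs_volumetrics.py`) exercise the phantom generator, the GMM liver
segmentation and the RECIST rules the same way.

The `hepavol` CLI chains the stages on image files:
`segment-liver`, `train-tumor-clf`, `segment-tumors`, `measure`,
`cohort-stats`, `make-phantom` and `run` (YAML-configured full pipeline).

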