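# persipet

Semi-quantification of tau-PET brain volumes with a subject-specific
white-matter reference region (PERSI: parametric estimation of reference
signal intensity), for researchers analyzing tracer-uptake images of
cognitively normal, MCI and Alzheimer's-disease cohorts.

## The problem and the method

Regional tau burden is usually summarized as the standardized uptake value
ratio

```
SUVR(region) = mean uptake in region / mean uptake in reference region
```

The traditional reference, the whole cerebellum, is small, noisy and
truncation-prone, which inflates the variance of every SUVR computed
against it. White matter has negligible specific tau binding and is large,
but near tau-rich cortex its voxels are contaminated by spill-in (the
partial volume effect), so a naive whole-WM mean is biased upward in
patients.

PERSI resolves this with the WM intensity histogram. Voxels of a
thresholded WM mask (probability > 0.9) are binned, and the histogram is
fitted with a two-Gaussian model by bounded trust-region-reflective least
squares:

```
f(x) = a_low exp(-(x - mu_low)^2 / 2 sigma_low^2)
     + a_high exp(-(x - mu_high)^2 / 2 sigma_high^2)
```

In controls the histogram is effectively unimodal; in patients the
spill-in voxels form the higher mode. Voxels within the FWHM window of the
lower peak, `mu_low ± 0.5 · 2√(2 ln 2) · sigma_low`, are retained as a
subject-specific clean-WM reference; its mean normalizes the image, which
is then smoothed (8 mm FWHM Gaussian) and averaged over eight
AD-signature regions (frontal, parietal, temporal and occipital lobes,
anterior and posterior cingulate, precuneus, Braak I/II). Group
discrimination per region is summarized with the symmetric Cohen's d,
`(m_1 - m_2)/√((s_1² + s_2²)/2)`, and the rank-based (Mann–Whitney) ROC
AUC.

Because real tau-PET cohorts cannot be redistributed, the package includes
a seeded digital-phantom generator that reproduces the statistical
structure the method relies on — unimodal control WM histograms, bimodal
patient histograms from spill-in placed against the cortical boundary,
programmed regional uptake ratios (true SUVRs), a nuisance-prone
cerebellum and per-subject global intensity scales — so every stage can be
validated against ground truth.

## Worked example

```python
from persipet import (PhantomSpec, generate_subject, build_atlas,
                      binarize_segmentation, build_histogram, fit_bimodal,
                      select_reference_voxels, quantify_subject)

spec = PhantomSpec()                      # default phantom conditions
pet, gm, wm, csf, truth = generate_subject(spec, "AD", seed=42)
atlas = build_atlas(spec)

mask = binarize_segmentation(wm, 0.9)     # binary WM image
fit = fit_bimodal(build_histogram(pet, mask, n_bins=128))
print(f"mu_low={fit.mu_low:.4f}  mu_high={fit.mu_high:.4f}  "
      f"bimodal={not fit.unimodal_fallback}")
ref = select_reference_voxels(pet, mask, fit)
print(f"reference: {ref.n_voxels} voxels, mean {ref.mean_intensity:.4f} "
      f"(true clean-WM mean {truth.clean_wm_mean_true:.4f})")

suvrs, _, _ = quantify_subject(pet, wm, atlas)
print(f"temporal SUVR (PERSI-WM): {suvrs['PERSI_WM']['temporal_lobe']:.3f} "
      f"(programmed ratio {truth.regional_ratios['temporal_lobe']:.3f})")
```

prints

```
mu_low=1.0317  mu_high=1.4424  bimodal=True
reference: 4583 voxels, mean 1.0324 (true clean-WM mean 1.0305)
temporal SUVR (PERSI-WM): 1.087 (programmed ratio 1.105)
```

The fitted lower peak sits on the clean-WM mean despite 30% of WM voxels
being contaminated at +40% intensity; the retained reference mean is
within 0.2% of truth, and the regional SUVR recovers the programmed
uptake ratio (the small shortfall is boundary blur from the 8 mm
smoothing).

The same pipeline runs from the shell:

```
persipet all --out results/run1 --seed 7
```

which simulates a 65 HC / 60 MCI / 12 AD cohort, writes `suvr_long.csv`,
`group_summary.csv`, `comparisons.csv` (Cohen's d and AUC per region,
method and group pair) and `persi_fit.json` (per-subject fit
diagnostics).

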