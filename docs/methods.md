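# Methods

## The quantification model

The package computes regional standardized uptake value ratios (SUVRs)
for tau-PET volumes that are already co-registered to a common template
space together with probabilistic tissue segmentations and an
integer-labelled ROI atlas. Registration, segmentation and reconstruction
are upstream concerns and are deliberately out of scope: volumes of one
subject must share a grid, and resampling is refused rather than
performed silently.

Two reference regions are supported:

* **PERSI-WM** (the method of interest). The white-matter probability map
  is binarized at a strict threshold (`prob > 0.9`; strict so boundary
  voxels at exactly the threshold are excluded). Masked PET intensities
  are histogrammed into 128 equal-width bins spanning their range and the
  histogram is fitted with the sum of two Gaussians by bounded
  trust-region-reflective least squares. Components are relabelled so
  `mu_low <= mu_high`. Voxels inside the intensity window of full width
  `2√(2 ln 2)·sigma_low` centered at `mu_low` form the reference; its
  arithmetic mean is the normalization denominator. The window is an
  *intensity* interval (not a spatial neighborhood): the lower mode is
  the uncontaminated WM signal, and the FWHM window keeps its central
  mass while excluding the spill-in mode.
* **Whole cerebellum** (the conventional comparator): the arithmetic mean
  over the atlas's `whole_cerebellum` label set, computed on the raw
  volume.

Normalization divides every voxel by the reference mean; an 8 mm-FWHM
separable Gaussian smooth (per-axis sigma `fwhm / (2√(2 ln 2)·voxel)`,
nearest-edge replication so brain-edge voxels are not darkened by zero
padding) is applied *after* normalization, and the eight analysis regions
are averaged on the smoothed volume. Smoothing order and the smoothing
step itself are configurable; both reference derivations always use the
raw (unsmoothed, unnormalized) volume. Identical smoothing is applied to
both reference arms so they remain comparable. Regions are unions of
atlas labels, so a composite region such as Braak I/II (entorhinal +
hippocampus) is a single pooled mean over all its labels; no
gray-matter-probability weighting is applied.

## Fitting details

* **Scale handling.** Bin centers are affinely mapped onto [0, 1] before
  fitting, and fitted parameters are mapped back exactly. The optimizer
  therefore sees a bit-identical problem when the input PET is globally
  rescaled, which makes the derived reference — and hence every SUVR —
  invariant under global intensity rescaling to floating-point precision.
* **Initialization.** Two deterministic starts: centers at the 25th/75th
  and at the 50th/95th count-weighted percentiles (the second start finds
  minor contamination components whose mass lies entirely above the 75th
  percentile); sigmas start at a quarter of the intensity range,
  amplitudes at the local histogram maxima near each starting center. The
  lower of the two converged costs wins. Up to 4 jittered restarts from a
  fixed internal seed run only if the optimizer reports failure.
* **Bounds.** Centers within the observed range, sigmas in
  [bin width, range], amplitudes in [0, 2·max count] — preventing
  component collapse and escape.
* **Objective.** Unweighted residuals on the counts by default; Poisson
  (inverse-√count) weighting is available behind a flag.
* **Unimodal fallback.** Control-like histograms have no spill-in mode,
  and a two-component fit of such data is ill-posed. The second component
  is rejected — and a dedicated single-Gaussian refit fills both
  parameter slots, with `unimodal_fallback` set — when any of the
  following holds:
  1. centers closer than `1·max(sigma_low, sigma_high)`;
  2. minor amplitude below 1% of the major;
  3. minor component area (`amp·sigma`) below 5% of the total — a
     least-squares fit will happily spend a component on a single noisy
     bin, which passes the amplitude test but carries no mass;
  4. BIC of the two-component fit no better than that of a
     single-Gaussian refit (the decisive test: splitting one peak into
     two overlapping components buys almost no residual reduction for
     three extra parameters, while a genuine spill-in component reduces
     the residual severalfold).
  Criteria 3 and 4 exist because 1 and 2 alone miss two failure modes
  observed on generated data: a unimodal peak split into two components
  ~1.2σ apart, and a spurious narrow "lower peak" fitted to a noise
  spike (which would corrupt the reference by >10%). The refit (rather
  than copying the dominant component of the split) keeps `mu_low`
  accurate to ~0.1% on unimodal data, since the dominant half of a split
  peak is off-center.
* **Degenerate inputs.** A constant-intensity WM region (possible only on
  idealized synthetic inputs) cannot be histogrammed; the full WM mask
  then serves as the reference, which is exact in that case. A reference
  window retaining fewer than 100 voxels (configurable) is an error; per
  cohort, failed subjects are excluded and logged (optionally demoted to
  cerebellum-only records), and a cohort with >20% failures is rejected.

## Group statistics

Cohen's d uses the symmetric two-group form
`(m_1 - m_2)/√((s_1² + s_2²)/2)` with sample SDs (ddof = 1), reported
signed and oriented patient − control. The AUC is the Mann–Whitney
probability `P(patient > control) + ½P(tie)` computed from midranks,
identical to the trapezoidal area under the empirical ROC; ties get half
credit. Point estimates only; a seeded percentile bootstrap CI is
available as an opt-in helper. Group labels are the fixed strings
HC/MCI/AD, and the patient group is always the ROC positive class.

## The phantom generator

The phantom is parametric — nested ellipsoids on a 64³ grid at 2 mm
isotropic (a ~100-subject cohort generates in seconds) — because ground
truth and speed outrank anatomical realism for validating an estimator.
A cerebrum ellipsoid holds a WM core (~8,400 voxels) and a cortical
shell split into octants for the eight analysis regions (Braak I/II is
two pooled labels, exercising multi-label aggregation); a separate
cerebellum ellipsoid (~6,600 voxels) sits below; a thin CSF gap separates
core and shell. Tissue probability maps are 1 inside each core and decay
as a Gaussian of distance outside, so thresholding at 0.9 recovers the
painted core exactly.

Per subject, given a seed:

* clean WM voxels ~ N(1.0, 0.10) (arbitrary units; the clean-WM mean is
  the intensity anchor);
* in patient groups a contamination fraction of WM voxels — those
  nearest the cortical boundary, mimicking the spatial structure of
  spill-in — is drawn instead from N(1.4, 0.15) (defaults: fraction 0.30
  in AD, 0.15 in MCI, 0 in HC; +40% intensity);
* each cortical region is painted at `ratio · (clean WM mean)` plus voxel
  noise (SD 0.15), where the subject's ratio is the group's programmed
  uptake ratio plus between-subject variation (SD 0.10). Default HC
  ratios are 0.95–1.05 (sub-unity SUVRs in controls are expected for
  these tracers); AD ratios add region-specific elevations of 0.18–0.30,
  giving designed effect sizes of ~1.8–3; MCI sits at 40% of the AD
  elevation;
* the cerebellum is painted at the clean-WM mean times a per-subject
  nuisance factor ~ N(1, 0.08), representing the noise-, size- and
  truncation-related variability that makes the cerebellum an inferior
  reference — this is the mechanism by which the phantom reproduces the
  discrimination advantage of PERSI-WM;
* the whole volume is multiplied by a per-subject global scale
  ~ N(1, 0.10), which any valid ratio method must cancel.

Atlas labels are the painted regions eroded 3 voxels away from tissue
boundaries (the painted anatomy is full-size). With the 8 mm kernel this
keeps the smoothing-induced boundary-blur bias of regional means at or
below ~3%; without the erosion, leakage into the near-zero background
would bias shell-region means by >10% and no smoothed readout would be
interpretable against ground truth. References are computed on raw
volumes and are unaffected.

Cohort generation derives per-subject seeds from a master seed via
`numpy.random.SeedSequence`, writes float32 NIfTI volumes, a CSV
manifest and a ground-truth JSON, and is bit-reproducible. Default group
sizes are 65 HC / 60 MCI / 12 AD.

What the phantom does **not** emulate: scanner physics (PSF, scatter,
randoms), anatomical shape, spatially correlated noise, registration and
segmentation error, and tracer kinetics. Passing tests therefore
demonstrate the estimator's statistical correctness under the assumed
mixture structure, not robustness to real-world acquisition artifacts.

## Validation benchmarks

`persipet.benchmarks` (driven by `scripts/acceptance.py` and the
validation tests) regenerates everything from a seed and measures:
fit recovery on 20 mixture histograms of 5·10⁴ draws with ≥3σ component
separation (median `mu_low`/`sigma_low` error, fallback rate on matched
unimodal histograms); contamination leakage into the retained reference
versus the analytic overlap of the true mixture inside the fitted FWHM
window (±2 Monte-Carlo SE); noiseless-phantom SUVR recovery (exact
without smoothing, ≤5% with it); SUVR invariance under a ×3.7 global
rescale; rank-AUC agreement with brute-force pairwise counting and
designed-effect recovery on a 50/50 cohort built for temporal d* = 1.5
(binormal target Φ(d*/√2) ≈ 0.856, Hanley–McNeil SE); per-region wins of
PERSI-WM over the cerebellum arm on the default cohort (HC vs AD, the
central comparison); and byte-identical CSVs across repeated CLI runs.
Problem sizes (20 histograms, single subjects, 100- and 137-subject
cohorts on the 64³ grid) were chosen so the full suite completes in about
a minute while keeping Monte-Carlo errors well inside the stated bands.

## Known limitations

* The fit assumes at most two intensity components; mixed pathologies
  producing three-mode histograms would fold into the nearest two.
* The fallback's BIC test assumes homoscedastic residuals across bins;
  with Poisson weighting enabled the comparison is still performed on the
  weighted residuals.
* Whether smoothing should also precede cerebellum-arm normalization is
  untestable from first principles here; both arms are treated
  identically for comparability.
* WM voxels adjacent to cortex are not excluded before fitting; the
  intensity-only model absorbs them into the higher mode.
* Effect sizes are reported signed (patient − control); consumers wanting
  magnitude tables should take absolute values.
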