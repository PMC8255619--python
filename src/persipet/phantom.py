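"""Seeded digital phantoms with the statistical structure the pipeline assumes.

The phantom is deliberately parametric, not anatomical: a cerebrum
ellipsoid holding a white-matter core and a cortical shell split into the
eight analysis regions, plus a separate cerebellum ellipsoid. What it
reproduces faithfully is the *statistics* the method exploits:

* clean WM voxels drawn from one Gaussian, giving controls a unimodal
  WM histogram;
* in patient groups, a fraction of WM voxels — those nearest the cortical
  boundary, mimicking spill-in — drawn from a second, higher-intensity
  Gaussian, making the histogram bimodal;
* cortical regions painted at per-subject uptake ratios relative to the
  clean WM mean (the programmed "true SUVRs"), with between-subject
  variability setting the group effect sizes;
* a cerebellum with per-subject multiplicative nuisance variability,
  emulating the small, noise- and truncation-prone reference the
  whole-cerebellum method depends on;
* a per-subject global intensity scale that any valid ratio method must
  cancel.

Atlas labels are the eroded cores of the painted regions (3 voxels in
from every tissue boundary) so that region means remain interpretable
after the 8 mm smoothing step; the painted anatomy itself is full-size.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_io import (
    ANALYSIS_REGIONS,
    CohortManifest,
    ManifestRow,
    RoiAtlas,
    Volume3D,
    load_atlas,
    write_volume,
)

#: default cohort composition (subjects per diagnostic group)
DEFAULT_COHORT_SIZES = {"HC": 65, "MCI": 60, "AD": 12}

_DEF_HC_RATIOS = {
    "frontal_lobe": 0.95,
    "parietal_lobe": 0.95,
    "temporal_lobe": 1.00,
    "occipital_lobe": 1.00,
    "anterior_cingulate": 1.00,
    "posterior_cingulate": 1.00,
    "precuneus": 1.00,
    "braak_i_ii": 1.05,
}
_DEF_AD_DELTAS = {
    "frontal_lobe": 0.20,
    "parietal_lobe": 0.22,
    "temporal_lobe": 0.30,
    "occipital_lobe": 0.25,
    "anterior_cingulate": 0.18,
    "posterior_cingulate": 0.25,
    "precuneus": 0.28,
    "braak_i_ii": 0.30,
}


def _default_uptake_ratios() -> dict[str, dict[str, float]]:
    hc = dict(_DEF_HC_RATIOS)
    ad = {r: hc[r] + _DEF_AD_DELTAS[r] for r in hc}
    mci = {r: hc[r] + 0.4 * _DEF_AD_DELTAS[r] for r in hc}
    return {"HC": hc, "MCI": mci, "AD": ad}


@dataclass
class PhantomSpec:
    """All knobs of the phantom cohort generator.

    Intensities are in arbitrary image units with the clean-WM mean as the
    anchor (default 1.0); SDs are in the same units. ``uptake_ratios`` are
    the programmed regional target-to-clean-WM ratios, i.e. the ground-truth
    SUVRs a perfect PERSI pipeline should recover.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0

    wm_mean: float = 1.0
    wm_sd: float = 0.10

    #: fraction of WM voxels receiving spill-in, per group
    contamination_fraction: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "MCI": 0.15, "AD": 0.30}
    )
    #: contaminated-component mean is wm_mean * (1 + contamination_delta)
    contamination_delta: float = 0.40
    contamination_sd: float = 0.15

    uptake_ratios: dict[str, dict[str, float]] = field(default_factory=_default_uptake_ratios)
    #: between-subject SD of each regional uptake ratio
    ratio_sd: float = 0.10
    #: within-region voxel noise SD
    roi_voxel_sd: float = 0.15

    cereb_ratio: float = 1.0
    #: SD of the per-subject multiplicative cerebellar nuisance factor
    cereb_nuisance_sd: float = 0.08
    cereb_voxel_sd: float = 0.15

    csf_value: float = 0.30
    csf_sd: float = 0.02
    background_value: float = 0.05
    background_sd: float = 0.02

    #: SD of the per-subject global multiplicative intensity scale
    global_scale_sd: float = 0.10

    seed: int = 0

    def __post_init__(self):
        for name in (
            "wm_sd",
            "contamination_sd",
            "ratio_sd",
            "roi_voxel_sd",
            "cereb_nuisance_sd",
            "cereb_voxel_sd",
            "csf_sd",
            "background_sd",
            "global_scale_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for g, f in self.contamination_fraction.items():
            if not 0.0 <= f < 1.0:
                raise ValidationError(f"contamination fraction for {g} must be in [0, 1)")
        for g, ratios in self.uptake_ratios.items():
            for r, v in ratios.items():
                if v <= 0:
                    raise ValidationError(f"uptake ratio {g}/{r} must be positive")

    @classmethod
    def noiseless(cls, **overrides) -> "PhantomSpec":
        """A spec with every noise source silenced; regional values are exact."""
        zeroed = dict(
            wm_sd=0.0,
            contamination_sd=0.0,
            ratio_sd=0.0,
            roi_voxel_sd=0.0,
            cereb_nuisance_sd=0.0,
            cereb_voxel_sd=0.0,
            csf_sd=0.0,
            background_sd=0.0,
            global_scale_sd=0.0,
        )
        zeroed.update(overrides)
        return cls(**zeroed)

    def replace(self, **changes) -> "PhantomSpec":
        return dataclasses.replace(self, **changes)


@dataclass
class PhantomGeometry:
    """Voxel masks of the painted anatomy plus the (eroded) atlas labels."""

    wm_core: np.ndarray
    csf_gap: np.ndarray
    shell_regions: dict[str, np.ndarray]  # full-size painted cortical regions
    cerebellum: np.ndarray
    atlas_labels: np.ndarray  # eroded cores, 0 = background
    region_spec: dict[str, list[int]]
    affine: np.ndarray
    #: WM voxel order by distance to the WM boundary, outermost first;
    #: contamination fills this list from the front
    wm_boundary_order: np.ndarray


_EROSION_VOXELS = 3.0  # atlas labels sit >= this far from any tissue boundary


def build_geometry(spec: PhantomSpec) -> PhantomGeometry:
    """Deterministic phantom anatomy for a given grid."""
    nx, ny, nz = spec.shape
    ix, iy, iz = np.indices(spec.shape)

    # cerebrum ellipsoid in the upper part of the grid
    cx, cy, cz = nx / 2.0, ny / 2.0, 0.625 * nz
    rx, ry, rz = 0.375 * nx, 0.375 * ny, 0.28 * nz
    rho = np.sqrt(((ix - cx) / rx) ** 2 + ((iy - cy) / ry) ** 2 + ((iz - cz) / rz) ** 2)
    wm_core = rho <= 0.58
    csf_gap = (rho > 0.58) & (rho <= 0.62)
    shell = (rho > 0.62) & (rho <= 1.0)

    # cerebellum ellipsoid below the cerebrum
    kx, ky, kz = nx / 2.0, ny / 2.0, 0.17 * nz
    sx, sy, sz = 0.22 * nx, 0.22 * ny, 0.125 * nz
    rho_c = np.sqrt(((ix - kx) / sx) ** 2 + ((iy - ky) / sy) ** 2 + ((iz - kz) / sz) ** 2)
    cerebellum = rho_c <= 1.0

    # split the cortical shell into octants -> the 8 analysis regions
    octant = (
        ((ix >= cx).astype(int) << 2) | ((iy >= cy).astype(int) << 1) | (iz >= cz).astype(int)
    )
    shell_regions = {name: shell & (octant == i) for i, name in enumerate(ANALYSIS_REGIONS)}

    # atlas labels: erode every painted region away from tissue boundaries
    shell_depth = ndimage.distance_transform_edt(shell)
    shell_core = shell_depth >= _EROSION_VOXELS
    cereb_depth = ndimage.distance_transform_edt(cerebellum)
    cereb_core = cereb_depth >= _EROSION_VOXELS

    labels = np.zeros(spec.shape, dtype=np.int16)
    region_spec: dict[str, list[int]] = {}
    for i, name in enumerate(ANALYSIS_REGIONS):
        region_core = shell_regions[name] & shell_core
        if not region_core.any():
            raise ValidationError(f"phantom geometry leaves region {name!r} empty")
        lab = i + 1
        if name == "braak_i_ii":
            # two anatomical labels (entorhinal-like / hippocampal-like halves)
            # pooled into one region, exercising multi-label aggregation
            lower = region_core & (iz < cz + 0.5 * rz * 0.5)
            upper = region_core & ~lower
            if lower.any() and upper.any():
                labels[lower] = lab
                labels[upper] = 10
                region_spec[name] = [lab, 10]
            else:
                labels[region_core] = lab
                region_spec[name] = [lab]
        else:
            labels[region_core] = lab
            region_spec[name] = [lab]
    if not cereb_core.any():
        raise ValidationError("phantom geometry leaves the cerebellum empty")
    labels[cereb_core] = 9
    region_spec["whole_cerebellum"] = [9]

    # WM voxels ordered outermost-first (spill-in sits against the cortex)
    wm_depth = ndimage.distance_transform_edt(wm_core)
    flat_idx = np.flatnonzero(wm_core)
    order = np.lexsort((flat_idx, wm_depth.ravel()[flat_idx]))
    wm_boundary_order = flat_idx[order]

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    return PhantomGeometry(
        wm_core=wm_core,
        csf_gap=csf_gap,
        shell_regions=shell_regions,
        cerebellum=cerebellum,
        atlas_labels=labels,
        region_spec=region_spec,
        affine=affine,
        wm_boundary_order=wm_boundary_order,
    )


@dataclass
class PhantomTruth:
    """Ground truth recorded while generating one subject."""

    subject_id: str
    group: str
    global_scale: float
    cereb_nuisance: float
    clean_wm_mean_true: float  # population mean of the clean WM component, scaled
    clean_wm_mean_empirical: float  # realized mean of the clean WM voxels
    cereb_mean_true: float
    cereb_mean_empirical: float
    regional_ratios: dict[str, float]  # per-subject programmed SUVR targets
    regional_means_true: dict[str, float]
    contamination_fraction: float
    n_wm_voxels: int
    n_contaminated: int
    contamination_labels: np.ndarray | None  # bool over the grid, WM voxels only
    pet_global_mean: float
    region_voxel_counts: dict[str, int]
    wm_prob_above_threshold: int  # voxels with WM probability > 0.9

    def to_jsonable(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "contamination_labels"}
        return d


def _prob_map(core: np.ndarray, affine: np.ndarray) -> Volume3D:
    """Probability 1 inside the tissue core, Gaussian decay with distance outside.

    The decay constant (1 voxel) guarantees p < 0.7 one voxel out, so
    thresholding at 0.9 recovers the core exactly.
    """
    dist = ndimage.distance_transform_edt(~core)
    p = np.exp(-(dist**2) / 2.0)
    p[core] = 1.0
    return Volume3D(data=p.astype(np.float64), affine=affine)


def generate_subject(
    spec: PhantomSpec,
    group: str,
    seed: int,
    subject_id: str = "sub",
    geometry: PhantomGeometry | None = None,
) -> tuple[Volume3D, Volume3D, Volume3D, Volume3D, PhantomTruth]:
    """One phantom subject: ``(pet, gm_prob, wm_prob, csf_prob, truth)``.

    Deterministic given ``(spec, group, seed)``.
    """
    if group not in spec.uptake_ratios:
        raise ValidationError(f"no uptake ratios defined for group {group!r}")
    geom = geometry or build_geometry(spec)
    rng = np.random.default_rng(seed)

    scale = max(1.0 + rng.normal() * spec.global_scale_sd, 0.5)
    cereb_nuisance = max(1.0 + rng.normal() * spec.cereb_nuisance_sd, 0.5)
    base_ratios = spec.uptake_ratios[group]
    ratios = {
        r: max(base_ratios[r] + rng.normal() * spec.ratio_sd, 0.05) for r in ANALYSIS_REGIONS
    }

    shape = spec.shape
    pet = spec.background_value + rng.normal(size=shape) * spec.background_sd

    pet[geom.csf_gap] = spec.csf_value + rng.normal(size=int(geom.csf_gap.sum())) * spec.csf_sd

    for region, mask in geom.shell_regions.items():
        n = int(mask.sum())
        pet[mask] = ratios[region] * spec.wm_mean + rng.normal(size=n) * spec.roi_voxel_sd

    n_cereb = int(geom.cerebellum.sum())
    cereb_mean = spec.cereb_ratio * cereb_nuisance * spec.wm_mean
    pet[geom.cerebellum] = cereb_mean + rng.normal(size=n_cereb) * spec.cereb_voxel_sd

    # white matter: clean component everywhere, spill-in component in the
    # contaminated fraction of voxels nearest the cortical boundary
    n_wm = int(geom.wm_core.sum())
    wm_vals = spec.wm_mean + rng.normal(size=n_wm) * spec.wm_sd
    frac = spec.contamination_fraction.get(group, 0.0)
    n_cont = int(round(frac * n_wm))
    contam_flat = geom.wm_boundary_order[:n_cont]
    flat = pet.ravel()
    flat[geom.wm_boundary_order] = wm_vals  # outermost-first order; values iid so order-free
    contam_vals = spec.wm_mean * (1.0 + spec.contamination_delta) + rng.normal(
        size=n_cont
    ) * spec.contamination_sd
    flat[contam_flat] = contam_vals

    pet *= scale

    contamination_labels = np.zeros(shape, dtype=bool)
    contamination_labels.ravel()[contam_flat] = True

    clean_flat = geom.wm_boundary_order[n_cont:]
    clean_emp = float(flat[clean_flat].mean()) if n_cont < n_wm else float("nan")
    cereb_emp = float(pet[geom.cerebellum].mean())

    wm_prob = _prob_map(geom.wm_core, geom.affine)
    gm_core = np.logical_or.reduce(list(geom.shell_regions.values())) | geom.cerebellum
    gm_prob = _prob_map(gm_core, geom.affine)
    csf_prob = _prob_map(geom.csf_gap, geom.affine)

    atlas = load_atlas(
        Volume3D(geom.atlas_labels.astype(np.int32), geom.affine), geom.region_spec
    )
    region_counts = {r: atlas.region_voxel_count(r) for r in geom.region_spec}

    truth = PhantomTruth(
        subject_id=subject_id,
        group=group,
        global_scale=scale,
        cereb_nuisance=cereb_nuisance,
        clean_wm_mean_true=spec.wm_mean * scale,
        clean_wm_mean_empirical=clean_emp,
        cereb_mean_true=cereb_mean * scale,
        cereb_mean_empirical=cereb_emp,
        regional_ratios=ratios,
        regional_means_true={r: ratios[r] * spec.wm_mean * scale for r in ratios},
        contamination_fraction=frac,
        n_wm_voxels=n_wm,
        n_contaminated=n_cont,
        contamination_labels=contamination_labels,
        pet_global_mean=float(pet.mean()),
        region_voxel_counts=region_counts,
        wm_prob_above_threshold=int((wm_prob.data > 0.9).sum()),
    )
    pet_vol = Volume3D(data=pet, affine=geom.affine)
    return pet_vol, gm_prob, wm_prob, csf_prob, truth


def build_atlas(spec: PhantomSpec, geometry: PhantomGeometry | None = None) -> RoiAtlas:
    geom = geometry or build_geometry(spec)
    return load_atlas(
        Volume3D(geom.atlas_labels.astype(np.int32), geom.affine), geom.region_spec
    )


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed below 2**31."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def generate_cohort(
    spec: PhantomSpec,
    n_per_group: dict[str, int] | None = None,
    master_seed: int | None = None,
    out_dir: str | os.PathLike | None = None,
) -> tuple[CohortManifest, RoiAtlas, dict[str, PhantomTruth]]:
    """Generate a whole cohort; optionally materialize it as NIfTI + CSV + JSON.

    Subject seeds derive deterministically from ``master_seed`` (default:
    ``spec.seed``). When ``out_dir`` is given, per-subject volumes, the
    atlas, the manifest and a ground-truth JSON are written there and the
    manifest carries the file paths; otherwise truths keep everything
    in memory and the manifest paths point at the (unwritten) file names.
    """
    n_per_group = dict(n_per_group or DEFAULT_COHORT_SIZES)
    for g, n in n_per_group.items():
        if n < 2:
            raise ValidationError(f"need at least 2 subjects per group, got {g}: {n}")
    master_seed = spec.seed if master_seed is None else master_seed
    geom = build_geometry(spec)
    atlas = build_atlas(spec, geom)

    write = out_dir is not None
    if write:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_volume(
            Volume3D(geom.atlas_labels.astype(np.int32), geom.affine), out_dir / "atlas.nii.gz"
        )
        with open(out_dir / "regions.json", "w") as fh:
            json.dump(geom.region_spec, fh, indent=2)

    rows: list[ManifestRow] = []
    truths: dict[str, PhantomTruth] = {}
    idx = 0
    for group in ("HC", "MCI", "AD"):
        for j in range(n_per_group.get(group, 0)):
            sid = f"{group}_{j:03d}"
            seed = subject_seed(master_seed, idx)
            pet, gm, wm, csf, truth = generate_subject(
                spec, group, seed, subject_id=sid, geometry=geom
            )
            paths = {
                kind: f"{sid}_{kind}.nii.gz" for kind in ("pet", "gm", "wm", "csf")
            }
            if write:
                write_volume(pet, out_dir / paths["pet"])
                write_volume(gm, out_dir / paths["gm"])
                write_volume(wm, out_dir / paths["wm"])
                write_volume(csf, out_dir / paths["csf"])
            rows.append(
                ManifestRow(
                    subject_id=sid,
                    group=group,
                    pet_path=paths["pet"],
                    gm_path=paths["gm"],
                    wm_path=paths["wm"],
                    csf_path=paths["csf"],
                )
            )
            truths[sid] = truth
            idx += 1

    manifest = CohortManifest(rows=rows)
    if write:
        manifest.write_csv(out_dir / "manifest.csv")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump({sid: t.to_jsonable() for sid, t in truths.items()}, fh, indent=2)
        # re-read so manifest paths resolve against the output directory
        from .image_io import read_manifest

        manifest = read_manifest(out_dir / "manifest.csv")
    return manifest, atlas, truths
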