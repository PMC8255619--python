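"""Regional SUVR computation for a cohort against two reference methods.

For each subject the PET volume is normalized by a reference mean
(PERSI-derived white matter, and the whole cerebellum for comparison),
smoothed, and averaged over each analysis region. SUVR is the ratio of
mean activity in the target region to mean activity in the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortError, RegionLookupError, ValidationError
from .image_io import (
    ANALYSIS_REGIONS,
    CohortManifest,
    RoiAtlas,
    Volume3D,
    binarize_segmentation,
    read_volume,
)
from .persi import (
    BimodalFit,
    FitConfig,
    ReferenceRegion,
    derive_persi_reference,
    gaussian_smooth,
    normalize_volume,
)

log = logging.getLogger(__name__)

METHOD_PERSI = "PERSI_WM"
METHOD_CEREBELLUM = "whole_cerebellum"


@dataclass
class QuantConfig:
    """Tunable parameters of the quantification pipeline."""

    wm_threshold: float = 0.9
    n_bins: int = 128
    fwhm_mm: float = 8.0
    smooth: bool = True
    min_ref_voxels: int = 100
    methods: tuple[str, ...] = (METHOD_PERSI, METHOD_CEREBELLUM)
    regions: tuple[str, ...] = ANALYSIS_REGIONS
    #: what to do when PERSI fails for a subject: drop the subject entirely
    #: ("exclude") or keep the cerebellum-arm records ("cerebellum_only")
    persi_failure_policy: str = "exclude"
    max_failure_rate: float = 0.2
    fit: FitConfig = field(default_factory=FitConfig)


@dataclass
class SuvrTable:
    """Long-format per-subject regional SUVRs plus per-subject diagnostics."""

    records: pd.DataFrame  # columns: subject_id, group, region, method, suvr
    fit_diagnostics: dict[str, dict] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def group_summary(self) -> pd.DataFrame:
        """Mean and SD of SUVR per (group, region, method)."""
        g = self.records.groupby(["group", "region", "method"], sort=False)["suvr"]
        out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
        return out

    def subject_values(self, group: str, region: str, method: str) -> np.ndarray:
        sel = (
            (self.records["group"] == group)
            & (self.records["region"] == region)
            & (self.records["method"] == method)
        )
        return self.records.loc[sel, "suvr"].to_numpy()

    def write_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def roi_mean(vol: Volume3D, atlas: RoiAtlas, region: str) -> float:
    """Arithmetic mean intensity over the region's label set."""
    mask = atlas.region_mask(region)
    if mask.n_voxels == 0:
        raise RegionLookupError(f"region {region!r} has no voxels")
    return float(vol.data[mask.data].mean())


def cerebellum_reference(vol: Volume3D, atlas: RoiAtlas) -> ReferenceRegion:
    """Whole-cerebellum reference: the traditional normalization denominator."""
    mask = atlas.region_mask("whole_cerebellum")
    return ReferenceRegion(
        mask=mask,
        mean_intensity=float(vol.data[mask.data].mean()),
        n_voxels=mask.n_voxels,
        method=METHOD_CEREBELLUM,
    )


def quantify_subject(
    pet: Volume3D,
    wm_prob: Volume3D,
    atlas: RoiAtlas,
    config: QuantConfig | None = None,
) -> tuple[dict[str, dict[str, float]], BimodalFit | None, dict[str, ReferenceRegion]]:
    """Regional SUVRs of one subject for every configured method.

    Returns ``(suvrs[method][region], persi_fit, references)``. References
    are always derived on the raw PET; smoothing (if enabled) is applied to
    the normalized volume before the target-region means are taken.
    """
    config = config or QuantConfig()
    refs: dict[str, ReferenceRegion] = {}
    fit: BimodalFit | None = None
    if METHOD_PERSI in config.methods:
        wm_mask = binarize_segmentation(wm_prob, config.wm_threshold)
        refs[METHOD_PERSI], fit = derive_persi_reference(
            pet,
            wm_mask,
            n_bins=config.n_bins,
            min_voxels=config.min_ref_voxels,
            fit_config=config.fit,
        )
    if METHOD_CEREBELLUM in config.methods:
        refs[METHOD_CEREBELLUM] = cerebellum_reference(pet, atlas)

    suvrs: dict[str, dict[str, float]] = {}
    for method, ref in refs.items():
        norm = normalize_volume(pet, ref)
        if config.smooth:
            norm = gaussian_smooth(norm, config.fwhm_mm)
        suvrs[method] = {r: roi_mean(norm, atlas, r) for r in config.regions}
    return suvrs, fit, refs


def compute_suvr_table(
    cohort: CohortManifest,
    atlas: RoiAtlas,
    config: QuantConfig | None = None,
) -> SuvrTable:
    """SUVR table for a whole cohort; per-subject failures are logged, not fatal.

    A subject whose PERSI derivation fails is excluded (or demoted to
    cerebellum-only records, per config). If more than
    ``config.max_failure_rate`` of subjects fail entirely, the cohort as a
    whole is rejected.
    """
    config = config or QuantConfig()
    rows = []
    diagnostics: dict[str, dict] = {}
    failures: dict[str, str] = {}
    for row in cohort.rows:
        try:
            pet = read_volume(row.pet_path)
            wm = read_volume(row.wm_path)
            if pet.shape != tuple(atlas.labels.shape) or wm.shape != pet.shape:
                raise ValidationError(
                    f"{row.subject_id}: volume shapes {pet.shape}/{wm.shape} "
                    f"do not match atlas {atlas.labels.shape}"
                )
            suvrs, fit, refs = quantify_subject(pet, wm, atlas, config)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation is the contract
            if (
                config.persi_failure_policy == "cerebellum_only"
                and METHOD_CEREBELLUM in config.methods
            ):
                try:
                    pet = read_volume(row.pet_path)
                    cereb_cfg = QuantConfig(**{**vars(config), "methods": (METHOD_CEREBELLUM,)})
                    suvrs, fit, refs = quantify_subject(pet, pet, atlas, cereb_cfg)
                    log.warning("subject %s: PERSI failed (%s); cerebellum-only", row.subject_id, exc)
                except Exception as exc2:  # noqa: BLE001
                    failures[row.subject_id] = f"{exc2!r}"
                    log.warning("subject %s failed: %r", row.subject_id, exc2)
                    continue
            else:
                failures[row.subject_id] = f"{exc!r}"
                log.warning("subject %s excluded: %r", row.subject_id, exc)
                continue
        diagnostics[row.subject_id] = {
            "fit": fit.to_dict() if fit is not None else None,
            "references": {
                m: {"mean_intensity": r.mean_intensity, "n_voxels": r.n_voxels}
                for m, r in refs.items()
            },
        }
        for method, per_region in suvrs.items():
            for region, suvr in per_region.items():
                rows.append(
                    {
                        "subject_id": row.subject_id,
                        "group": row.group,
                        "region": region,
                        "method": method,
                        "suvr": suvr,
                    }
                )
        log.info("subject %s: ok (%d records)", row.subject_id, len(config.regions) * len(suvrs))

    if len(cohort) and len(failures) / len(cohort) > config.max_failure_rate:
        raise CohortError(
            f"{len(failures)}/{len(cohort)} subjects failed "
            f"(limit {config.max_failure_rate:.0%}): {failures}"
        )
    records = pd.DataFrame(rows, columns=["subject_id", "group", "region", "method", "suvr"])
    return SuvrTable(records=records, fit_diagnostics=diagnostics, failures=failures)
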