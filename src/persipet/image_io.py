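"""Volumetric I/O, mask construction and atlas/manifest handling.

All volumes are carried as :class:`Volume3D`: a plain float array plus the
NIfTI affine. Volumes belonging to one subject must share grid shape; no
resampling is ever performed here — co-registration is assumed to have
happened upstream, in template space.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import AtlasError, CohortError, DegenerateMaskError, RegionLookupError, ValidationError

#: The eight cortical analysis regions, in reporting order.
ANALYSIS_REGIONS = (
    "frontal_lobe",
    "parietal_lobe",
    "temporal_lobe",
    "occipital_lobe",
    "anterior_cingulate",
    "posterior_cingulate",
    "precuneus",
    "braak_i_ii",
)

#: Regions every atlas must define: the analysis ROIs plus the reference.
REQUIRED_REGIONS = ANALYSIS_REGIONS + ("whole_cerebellum",)

GROUPS = ("HC", "MCI", "AD")


@dataclass
class Volume3D:
    """A 3D scalar image in a common template space.

    Parameters
    ----------
    data
        3D array of voxel intensities (arbitrary units).
    affine
        4x4 map from 0-based voxel indices to template-space mm coordinates.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3D volume, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValidationError(f"degenerate volume shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine), strictly positive."""
        vs = np.linalg.norm(self.affine[:3, :3], axis=0)
        if np.any(vs <= 0):
            raise ValidationError("voxel size must be strictly positive")
        return vs

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """A new volume with the same geometry but different voxel data."""
        return Volume3D(data=data, affine=self.affine.copy())


@dataclass
class BinaryMask:
    """A boolean voxel mask sharing geometry with a paired :class:`Volume3D`."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValidationError("mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class RoiAtlas:
    """Integer label volume plus the mapping from region names to label sets.

    A region may aggregate several anatomical labels (e.g. Braak I/II pools
    entorhinal and hippocampal labels into one region).
    """

    labels: np.ndarray
    region_map: dict[str, frozenset[int]]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def region_mask(self, region: str) -> BinaryMask:
        if region not in self.region_map:
            raise RegionLookupError(f"unknown region {region!r}")
        return BinaryMask(np.isin(self.labels, sorted(self.region_map[region])))

    def region_voxel_count(self, region: str) -> int:
        return self.region_mask(region).n_voxels


@dataclass
class ManifestRow:
    subject_id: str
    group: str
    pet_path: str
    gm_path: str
    wm_path: str
    csf_path: str


@dataclass
class CohortManifest:
    """Per-subject file table for one cohort."""

    rows: list[ManifestRow]

    def __post_init__(self):
        ids = [r.subject_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")
        bad = sorted({r.group for r in self.rows} - set(GROUPS))
        if bad:
            raise ValidationError(f"unknown diagnostic groups: {bad}; expected one of {GROUPS}")

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def write_csv(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Load a NIfTI-1 volume, honoring scaling slope/intercept.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValidationError
        If the image is not 3D or contains NaN voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValidationError(f"{path}: expected a 3D image, got shape {img.shape}")
    data = np.asarray(img.get_fdata(dtype=np.float64))
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        raise ValidationError(f"{path}: {n_nan} NaN voxel(s); refusing to load")
    return Volume3D(data=data, affine=np.asarray(img.affine))


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as float32 NIfTI-1 with identity scaling."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_slope_inter(1.0, 0.0)
    nib.save(img, str(path))


def binarize_segmentation(prob: Volume3D, threshold: float = 0.9) -> BinaryMask:
    """Threshold a probabilistic tissue map into a binary mask.

    The comparison is strict (``prob > threshold``) so boundary voxels at
    exactly the threshold are excluded. Default threshold 0.9, the value
    used to derive the binary white-matter image.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must lie in (0, 1), got {threshold}")
    lo, hi = float(np.min(prob.data)), float(np.max(prob.data))
    if lo < -1e-6 or hi > 1 + 1e-6:
        raise ValidationError(f"probability map has values outside [0, 1]: range [{lo}, {hi}]")
    mask = BinaryMask(prob.data > threshold)
    if mask.n_voxels == 0:
        raise DegenerateMaskError(
            f"no voxels exceed threshold {threshold}; no reference region derivable"
        )
    return mask


def load_atlas(label_volume: Volume3D, region_spec: dict[str, list[int] | set[int]]) -> RoiAtlas:
    """Validate a label volume against a region specification.

    ``region_spec`` maps region names to the integer labels they aggregate.
    It must cover the eight analysis ROIs plus ``whole_cerebellum``; every
    region must own at least one voxel. Labels shared across regions are
    legal but reported as a warning.
    """
    labels = label_volume.data
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded, atol=1e-6):
            raise AtlasError("atlas volume is not integer-valued")
        labels = rounded.astype(np.int32)
    if labels.min() < 0:
        raise AtlasError("atlas labels must be non-negative (0 = background)")

    missing = [r for r in REQUIRED_REGIONS if r not in region_spec]
    if missing:
        raise AtlasError(f"region_spec missing required regions: {missing}")

    region_map = {name: frozenset(int(v) for v in vals) for name, vals in region_spec.items()}
    atlas = RoiAtlas(labels=labels, region_map=region_map, affine=label_volume.affine)

    empty = [r for r in region_map if atlas.region_voxel_count(r) == 0]
    if empty:
        raise AtlasError(f"regions with zero voxels: {sorted(empty)}")

    seen: dict[int, str] = {}
    for name, vals in region_map.items():
        for lab in vals:
            if lab in seen and seen[lab] != name:
                warnings.warn(
                    f"label {lab} shared by regions {seen[lab]!r} and {name!r}",
                    stacklevel=2,
                )
            seen.setdefault(lab, name)
    return atlas


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read a cohort manifest CSV; relative file paths resolve against the CSV's directory."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = ["subject_id", "group", "pet_path", "gm_path", "wm_path", "csf_path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    base = path.parent
    rows = []
    for rec in df.itertuples(index=False):
        kwargs = {c: getattr(rec, c) for c in required}
        for key in ("pet_path", "gm_path", "wm_path", "csf_path"):
            p = Path(kwargs[key])
            kwargs[key] = str(p if p.is_absolute() else base / p)
        rows.append(ManifestRow(**kwargs))
    return CohortManifest(rows=rows)


def validate_manifest_files(manifest: CohortManifest, atlas: RoiAtlas | None = None) -> None:
    """Check every referenced file exists (and matches the atlas grid if given)."""
    problems = []
    for row in manifest.rows:
        for key in ("pet_path", "gm_path", "wm_path", "csf_path"):
            p = Path(getattr(row, key))
            if not p.exists():
                problems.append(f"{row.subject_id}: missing {key} {p}")
            elif atlas is not None:
                shape = nib.load(str(p)).shape
                if tuple(shape) != tuple(atlas.labels.shape):
                    problems.append(
                        f"{row.subject_id}: {key} shape {tuple(shape)} != atlas {atlas.labels.shape}"
                    )
    if problems:
        raise CohortError("manifest validation failed:\n" + "\n".join(problems))
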