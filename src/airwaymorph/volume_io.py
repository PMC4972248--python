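"""Volumes, masks, feature tables, and the canonical object/feature catalog.

The study analyses 14 objects in the upper-airway region.  Ten are *base*
objects delineated directly (sk, mn, np, op, fp, tR, tL, tg, sp, ad); four
are *composite* objects obtained as voxelwise unions (pm, ph, tn, at).
Every subject contributes a fixed-length vector of 159 features:

* 5 object-specific features per object — size ``S_lambda``, volume ``S_V``,
  surface area ``S_A``, sphericity ``S_P``, mean standardized intensity
  ``H_I`` — for the 14 objects, except that ``H_I`` is not computed for the
  tongue (tg) and soft palate (sp), and
* 91 = C(14, 2) normalized inter-object centroid distances ``d(A,B)``.

All geometry lives in physical millimetres.  Voxel indices are 0-based and
the physical position of a voxel is ``origin + (index + 0.5) * spacing``
(voxel-centre convention).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

# --- object catalog -------------------------------------------------------

#: Base objects that must be supplied as binary masks, in canonical order.
BASE_OBJECTS: tuple[str, ...] = (
    "sk", "mn", "np", "op", "fp", "tR", "tL", "tg", "sp", "ad",
)

#: All 14 analysed objects in canonical (table) order.
ALL_OBJECTS: tuple[str, ...] = (
    "sk", "pm", "mn", "ph", "np", "op", "fp", "at", "tn", "tR", "tL", "tg", "sp", "ad",
)

#: Composite objects and their components.  ``ph`` and ``tn`` are unions of
#: base objects; ``at`` and ``pm`` are unions involving other composites.
COMPOSITE_OBJECTS: dict[str, tuple[str, str]] = {
    "ph": ("np", "op"),
    "tn": ("tR", "tL"),
    "at": ("tn", "ad"),
    "pm": ("mn", "ph"),
}

#: Objects for which the mean standardized intensity H_I is not computed
#: (segmented on a different imaging sequence in the source protocol).
INTENSITY_EXCLUDED: tuple[str, ...] = ("tg", "sp")

#: Objects carrying an H_I feature, in canonical order.
INTENSITY_OBJECTS: tuple[str, ...] = tuple(
    o for o in ALL_OBJECTS if o not in INTENSITY_EXCLUDED
)

GEOMETRY_TOL_MM = 1e-3  # spacing/origin agreement tolerance across a subject


class GeometryMismatchError(ValueError):
    """Grids of a subject's volumes/masks disagree beyond tolerance."""


# --- domain types ---------------------------------------------------------

@dataclass
class IntensityVolume:
    """A 3D scalar grid with anisotropic voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
    spacing : mm per axis, strictly positive.
    origin : physical position (mm) of the corner of voxel (0, 0, 0);
        the voxel centre sits at ``origin + 0.5 * spacing``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.3)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity volume contains non-finite values")


@dataclass
class ObjectMask:
    """A binary segmentation mask on the same grid as its intensity volume."""

    object_code: str
    values: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.3)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.object_code not in ALL_OBJECTS:
            raise ValueError(f"unknown object code {self.object_code!r}")
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class SubjectRecord:
    """One subject: intensity volume, base-object masks, and group label.

    ``group`` is 0 for controls and 1 for cases (OSAS in the source study).
    """

    subject_id: str
    group: int
    intensity: IntensityVolume
    masks: dict[str, ObjectMask]

    def __post_init__(self) -> None:
        if self.group not in (0, 1):
            raise ValueError(f"group label must be 0 or 1, got {self.group}")
        missing = [o for o in BASE_OBJECTS if o not in self.masks]
        if missing:
            raise ValueError(
                f"subject {self.subject_id!r} is missing base-object masks: "
                + ", ".join(missing)
            )
        for code, mask in self.masks.items():
            _check_same_grid(self.intensity, mask, self.subject_id, code)
            if code in BASE_OBJECTS and mask.voxel_count == 0:
                raise ValueError(
                    f"subject {self.subject_id!r}: mask {code!r} is empty"
                )


def _check_same_grid(vol: IntensityVolume, mask: ObjectMask,
                     subject_id: str, code: str) -> None:
    if vol.values.shape != mask.values.shape:
        raise GeometryMismatchError(
            f"subject {subject_id!r}, object {code!r}: grid shape "
            f"{mask.values.shape} != intensity shape {vol.values.shape}"
        )
    for name, a, b in (("spacing", vol.spacing, mask.spacing),
                       ("origin", vol.origin, mask.origin)):
        if max(abs(x - y) for x, y in zip(a, b)) > GEOMETRY_TOL_MM:
            raise GeometryMismatchError(
                f"subject {subject_id!r}, object {code!r}: {name} {b} "
                f"differs from intensity {name} {a} beyond {GEOMETRY_TOL_MM} mm"
            )


@dataclass
class Cohort:
    """An ordered collection of labelled subjects."""

    subjects: list[SubjectRecord]

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects], dtype=int)


# --- feature catalog ------------------------------------------------------

def feature_id(kind: str, *objects: str) -> str:
    """Canonical identifier for a feature, e.g. ``S_P(op)`` or ``d(fp,tg)``."""
    if kind == "d":
        a, b = objects
        return f"d({a},{b})"
    (o,) = objects
    return f"{kind}({o})"


def build_catalog() -> list[str]:
    """The ordered list of all 159 feature identifiers.

    Block order: S_lambda, S_V, S_A, S_P over the 14 objects, H_I over the
    12 intensity-bearing objects, then the 91 unordered pairwise distances
    in canonical object order.  Deterministic across calls.
    """
    catalog: list[str] = []
    for kind in ("S_lambda", "S_V", "S_A", "S_P"):
        catalog.extend(feature_id(kind, o) for o in ALL_OBJECTS)
    catalog.extend(feature_id("H_I", o) for o in INTENSITY_OBJECTS)
    for a, b in itertools.combinations(ALL_OBJECTS, 2):
        catalog.append(feature_id("d", a, b))
    assert len(catalog) == 159
    return catalog


#: Module-level catalog instance; order-stable across runs.
CATALOG: tuple[str, ...] = tuple(build_catalog())


# --- feature tables -------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects x features with a binary group label per subject.

    ``data`` is indexed by subject id; ``groups`` is aligned to the same
    index.  For the full pipeline the columns are exactly :data:`CATALOG`;
    simulated tables may carry their own column set.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        if not self.data.index.equals(self.groups.index):
            raise ValueError("groups index must match the data index")
        if len(self.data) and self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in features: {bad}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values_for(self, feature_ids: Sequence[str]) -> np.ndarray:
        return self.data.loc[:, list(feature_ids)].to_numpy(dtype=float)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Serialize to CSV: ``subject_id, group, <feature columns...>``.

    Floats are written with 17 significant digits so the round trip is
    lossless to 1e-12 relative.
    """
    df = table.data.copy()
    df.insert(0, "group", table.groups.astype(int))
    df.index.name = "subject_id"
    df.to_csv(path, float_format="%.17g")


def read_feature_table(path: str | Path,
                       catalog: Sequence[str] | None = None) -> FeatureTable:
    """Read a feature-table CSV; optionally validate columns against a catalog."""
    df = pd.read_csv(path, index_col="subject_id")
    df.index = df.index.astype(str)
    if "group" not in df.columns:
        raise ValueError("feature table is missing the 'group' column")
    groups = df.pop("group").astype(int)
    if catalog is not None:
        unknown = [c for c in df.columns if c not in set(catalog)]
        if unknown:
            raise ValueError(f"unknown feature columns: {unknown}")
        missing = [c for c in catalog if c not in df.columns]
        if missing:
            raise ValueError(f"feature columns missing from file: {missing}")
        df = df.loc[:, list(catalog)]
    return FeatureTable(data=df, groups=groups)


# --- NIfTI subject I/O ----------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _grid_from_affine(aff: np.ndarray) -> tuple[tuple, tuple]:
    spacing = tuple(float(s) for s in np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
    origin = tuple(float(o) for o in aff[:3, 3])
    return spacing, origin


def write_subject(subject: SubjectRecord, out_dir: str | Path) -> None:
    """Write one subject as NIfTI files plus a small JSON sidecar.

    Layout: ``<dir>/<id>_intensity.nii.gz``, ``<dir>/<id>_mask_<code>.nii.gz``
    and ``<dir>/<id>.json`` holding the group label and the object->file map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    aff = _affine(subject.intensity.spacing, subject.intensity.origin)
    ipath = out_dir / f"{sid}_intensity.nii.gz"
    nib.save(nib.Nifti1Image(subject.intensity.values.astype(np.float32), aff), ipath)
    object_map = {}
    for code, mask in subject.masks.items():
        mpath = out_dir / f"{sid}_mask_{code}.nii.gz"
        nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), aff), mpath)
        object_map[code] = mpath.name
    meta = {"subject_id": sid, "group": int(subject.group),
            "intensity": ipath.name, "masks": object_map}
    (out_dir / f"{sid}.json").write_text(json.dumps(meta, indent=1))


def read_subject(intensity_path: str | Path,
                 mask_paths: Mapping[str, str | Path],
                 subject_id: str, group: int) -> SubjectRecord:
    """Load a subject from NIfTI files.

    ``mask_paths`` maps object codes to files and must cover all 10 base
    objects; grids must agree to :data:`GEOMETRY_TOL_MM`.
    """
    img = nib.load(str(intensity_path))
    spacing, origin = _grid_from_affine(img.affine)
    vol = IntensityVolume(np.asarray(img.dataobj, dtype=np.float64),
                          spacing=spacing, origin=origin)
    missing = [o for o in BASE_OBJECTS if o not in mask_paths]
    if missing:
        raise ValueError("missing base-object masks: " + ", ".join(missing))
    masks = {}
    for code, path in mask_paths.items():
        mimg = nib.load(str(path))
        mspacing, morigin = _grid_from_affine(mimg.affine)
        masks[code] = ObjectMask(code, np.asarray(mimg.dataobj) > 0,
                                 spacing=mspacing, origin=morigin)
    return SubjectRecord(subject_id=str(subject_id), group=int(group),
                         intensity=vol, masks=masks)


def read_subject_dir(subject_dir: str | Path, subject_id: str) -> SubjectRecord:
    """Load a subject written by :func:`write_subject`."""
    subject_dir = Path(subject_dir)
    meta = json.loads((subject_dir / f"{subject_id}.json").read_text())
    mask_paths = {c: subject_dir / f for c, f in meta["masks"].items()}
    return read_subject(subject_dir / meta["intensity"], mask_paths,
                        meta["subject_id"], meta["group"])


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in cohort:
        write_subject(s, out_dir)
    labels = pd.DataFrame({"subject_id": [s.subject_id for s in cohort],
                           "group": [s.group for s in cohort]})
    labels.to_csv(out_dir / "labels.csv", index=False)


def read_cohort(in_dir: str | Path) -> Cohort:
    in_dir = Path(in_dir)
    labels = pd.read_csv(in_dir / "labels.csv", dtype={"subject_id": str})
    return Cohort([read_subject_dir(in_dir, sid) for sid in labels["subject_id"]])
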