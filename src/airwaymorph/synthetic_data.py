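"""Synthetic surrogate inputs with the statistical structure the analysis assumes.

Two generators are provided:

* :func:`generate_phantom_cohort` — desk-scale 3D phantom cohorts: each
  subject is an assembly of ten ellipsoidal objects (the base objects of the
  upper-airway catalog: skin/neck body, mandible, naso- and oropharyngeal
  airway tubes, fat pad, paired tonsils, tongue, soft palate, adenoid)
  digitized on an anisotropic grid, plus an intensity volume with per-object
  mean intensities, voxel noise, and a per-subject affine (gain/offset)
  intensity distortion that the standardization step must remove.  Group-1
  subjects are drawn from the group-0 distributions shifted by configurable
  effects on object size/shape, position, and tissue intensity.

* :func:`generate_feature_table` — direct feature tables: correlated
  Gaussian features with a planted discriminative subset (standardized
  between-group mean difference Delta per planted feature).

Default group effects follow the directionality reported for obstructive
sleep apnea (larger adenoid and fat pad, less spherical oropharyngeal
airway, fat pad displaced toward the tongue, tissue-intensity shifts), but
are schematic: they do not claim to reproduce the source study's measured
feature distributions.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import (
    BASE_OBJECTS,
    CATALOG,
    COMPOSITE_OBJECTS,
    Cohort,
    FeatureTable,
    INTENSITY_OBJECTS,
    IntensityVolume,
    ObjectMask,
    SubjectRecord,
    feature_id,
)


class PhantomFitError(ValueError):
    """An object escapes the image grid after jitter/displacement."""


# --- phantom configuration ------------------------------------------------

@dataclass
class ObjectSpec:
    """Base geometry of one ellipsoidal phantom object (all mm)."""

    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float]
    intensity: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")


@dataclass
class GroupEffect:
    """Group-1 deviation for one object: multiplicative size factors (scalar
    or per-axis), a centre displacement (mm), and an additive intensity
    shift (arbitrary units)."""

    size_factor: float | tuple[float, float, float] = 1.0
    center_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_shift: float = 0.0

    @property
    def size_factors(self) -> np.ndarray:
        f = np.asarray(self.size_factor, dtype=float)
        return np.broadcast_to(f, (3,)).copy()

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.size_factors, 1.0)
                and not any(self.center_shift)
                and self.intensity_shift == 0.0)


#: Schematic anatomically inspired arrangement on an 80 x 80 x 118.8 mm grid:
#: x lateral, y anterior->posterior, z inferior->superior.  Airway tubes on
#: the midline, paired tonsils lateral, fat pad posterolateral, adenoid
#: posterosuperior.  Intensities are T2-like (air dark, fat bright).
DEFAULT_OBJECTS: dict[str, ObjectSpec] = {
    "sk": ObjectSpec((32.0, 31.0, 47.0), (40.0, 40.0, 59.0), 1100.0),
    "mn": ObjectSpec((24.0, 12.0, 10.0), (40.0, 24.0, 35.0), 400.0),
    "tg": ObjectSpec((18.0, 15.0, 15.0), (40.0, 30.0, 50.0), 1500.0),
    "sp": ObjectSpec((9.0, 6.0, 5.0), (40.0, 42.0, 62.0), 1400.0),
    "fp": ObjectSpec((15.0, 9.0, 10.0), (40.0, 58.0, 52.0), 2400.0),
    "tR": ObjectSpec((7.0, 6.0, 8.0), (24.0, 46.0, 52.0), 1550.0),
    "tL": ObjectSpec((7.0, 6.0, 8.0), (56.0, 46.0, 52.0), 1550.0),
    "ad": ObjectSpec((9.0, 7.0, 6.0), (40.0, 58.0, 84.0), 1600.0),
    "np": ObjectSpec((5.0, 5.0, 14.0), (40.0, 48.0, 76.0), 300.0),
    "op": ObjectSpec((4.5, 4.5, 13.0), (40.0, 49.0, 48.0), 300.0),
}

#: Painting order for the intensity volume (later objects overwrite
#: earlier ones; airway tubes last so they stay dark).
PAINT_ORDER: tuple[str, ...] = ("sk", "mn", "tg", "sp", "fp", "tR", "tL", "ad", "np", "op")

#: Default group-1 effects: larger adenoid and fat pad, fat pad displaced
#: toward the tongue (anteriorly), elongated/narrowed oropharyngeal airway
#: (lower sphericity), and tissue-intensity shifts on adenoid and right
#: tonsil.  Intensity effects are deliberately planted on objects occupying
#: a small fraction of the body histogram, so cohort-level histogram
#: standardization does not absorb them.
DEFAULT_GROUP_EFFECTS: dict[str, GroupEffect] = {
    "ad": GroupEffect(size_factor=1.06, intensity_shift=120.0),
    "fp": GroupEffect(size_factor=1.06, center_shift=(0.0, -3.5, 0.0)),
    "op": GroupEffect(size_factor=(0.96, 0.96, 1.10)),
    "tR": GroupEffect(intensity_shift=-100.0),
}


@dataclass
class PhantomConfig:
    """Study conditions for the phantom cohort generator."""

    subjects_per_group: int = 15
    grid_shape: tuple[int, int, int] = (160, 160, 36)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 3.3)
    objects: dict[str, ObjectSpec] = field(
        default_factory=lambda: dict(DEFAULT_OBJECTS))
    group_effects: dict[str, GroupEffect] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    axis_cv: float = 0.04           # between-subject CV of semi-axes
    center_sd: float = 1.5          # mm jitter per axis of object centres
    intensity_cv: float = 0.03      # between-subject CV of object mean intensity
    intensity_noise_sd: float = 60.0
    background_intensity: float = 150.0
    gain_range: tuple[float, float] = (0.85, 1.25)
    offset_range: tuple[float, float] = (-80.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subjects_per_group < 1:
            raise ValueError("subjects_per_group must be >= 1")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        missing = [o for o in BASE_OBJECTS if o not in self.objects]
        if missing:
            raise ValueError(f"missing object specs: {missing}")
        for code in self.group_effects:
            if code not in BASE_OBJECTS:
                raise ValueError(f"group effect for unknown object {code!r}")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_spacing)


@dataclass
class SubjectTruth:
    """True generative parameters of one phantom subject."""

    subject_id: str
    group: int
    semi_axes: dict[str, np.ndarray]
    centers: dict[str, np.ndarray]
    intensities: dict[str, float]
    gain: float
    offset: float


@dataclass
class GroundTruth:
    """What was planted: per-subject parameters, labels, and the feature
    identifiers the group effects act on."""

    group_labels: np.ndarray
    subjects: list[SubjectTruth] = field(default_factory=list)
    target_features: list[str] = field(default_factory=list)
    affected_features: list[str] = field(default_factory=list)
    planted_deltas: dict[str, float] = field(default_factory=dict)


# --- feature bookkeeping for planted effects ------------------------------

def phantom_target_features(effects: dict[str, GroupEffect]) -> list[str]:
    """One headline feature per planted effect component, in catalog order.

    Size -> S_lambda, anisotropic shape -> S_P, centre shift -> the distance
    to the nearest affected partner is not well defined generically, so the
    conventional targets for the default effects are returned by
    :data:`DEFAULT_TARGET_FEATURES`; for custom effects use
    :func:`phantom_affected_features`.
    """
    return [f for f in DEFAULT_TARGET_FEATURES if f in set(CATALOG)]


#: Headline features for :data:`DEFAULT_GROUP_EFFECTS`.
DEFAULT_TARGET_FEATURES: tuple[str, ...] = (
    "S_lambda(ad)", "S_A(fp)", "S_P(op)", "d(fp,tg)", "H_I(ad)", "H_I(tR)",
)


def _with_composites(objs: set[str]) -> set[str]:
    """Close a set of object codes under composite membership."""
    out = set(objs)
    changed = True
    while changed:
        changed = False
        for comp, (a, b) in COMPOSITE_OBJECTS.items():
            if comp not in out and (a in out or b in out):
                out.add(comp)
                changed = True
    return out


def phantom_affected_features(effects: dict[str, GroupEffect]) -> list[str]:
    """Feature identifiers causally downstream of a set of group effects.

    For each object with an effect: size/shape factors touch its
    S_lambda/S_V/S_A (plus S_P when anisotropic); an intensity shift touches
    its H_I (where defined); a centre displacement touches every distance
    involving it.  Effects propagate into the composite objects containing
    an affected component: their geometry features, their (diluted) H_I for
    intensity shifts, and their distances — a composite's centroid drifts
    whenever a component's size or position changes the union's mass
    weighting.
    """
    geom: set[str] = set()
    aniso: set[str] = set()
    inten: set[str] = set()
    shifted: set[str] = set()
    for code, e in effects.items():
        f = e.size_factors
        if not np.allclose(f, 1.0):
            geom.add(code)
            if not np.allclose(f, f[0]):
                aniso.add(code)
        if e.intensity_shift != 0.0:
            inten.add(code)
        if any(e.center_shift):
            shifted.add(code)
    geom_all = _with_composites(geom)
    composite_geom = geom_all - geom
    sp_objs = aniso | composite_geom
    inten_all = _with_composites(inten)
    dist_objs = _with_composites(shifted) | composite_geom

    out: list[str] = []
    for o in geom_all:
        out += [feature_id("S_lambda", o), feature_id("S_V", o),
                feature_id("S_A", o)]
    out += [feature_id("S_P", o) for o in sp_objs]
    out += [feature_id("H_I", o) for o in inten_all if o in INTENSITY_OBJECTS]
    cat = set(CATALOG)
    for code in dist_objs:
        out += [f for f in cat if f.startswith("d(")
                and (f"({code}," in f or f",{code})" in f)]
    order = {f: i for i, f in enumerate(CATALOG)}
    return sorted(set(out) & cat, key=order.get)


# --- phantom generation ---------------------------------------------------

def ellipsoid_mask(grid_shape, spacing, center, axes) -> np.ndarray:
    """Voxel-centre digitization of an axis-aligned ellipsoid (full grid)."""
    spacing = np.asarray(spacing, dtype=float)
    center = np.asarray(center, dtype=float)
    axes = np.asarray(axes, dtype=float)
    lo = np.maximum(np.ceil((center - axes) / spacing - 0.5).astype(int), 0)
    hi = np.minimum(np.floor((center + axes) / spacing - 0.5).astype(int) + 1,
                    np.asarray(grid_shape))
    mask = np.zeros(grid_shape, dtype=bool)
    if np.any(hi <= lo):
        return mask
    coords = [((np.arange(lo[k], hi[k]) + 0.5) * spacing[k] - center[k]) / axes[k]
              for k in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij", sparse=True)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = X * X + Y * Y + Z * Z <= 1.0
    return mask


#: Between-subject jitter is truncated at this many SDs so that the default
#: arrangement provably fits the default grid for every subject.
JITTER_TRUNCATION_SD = 2.5


def _jitter(rng: np.random.Generator, size=None) -> np.ndarray:
    z = rng.standard_normal(size)
    return np.clip(z, -JITTER_TRUNCATION_SD, JITTER_TRUNCATION_SD)


def _draw_subject_truth(config: PhantomConfig, group: int, index: int
                        ) -> SubjectTruth:
    rng = np.random.default_rng([config.seed, group, index])
    sid = f"g{group}s{index:02d}"
    axes, centers, intensities = {}, {}, {}
    for code in BASE_OBJECTS:
        spec = config.objects[code]
        a = np.asarray(spec.semi_axes) * (1.0 + config.axis_cv * _jitter(rng, 3))
        c = np.asarray(spec.center) + config.center_sd * _jitter(rng, 3)
        v = spec.intensity * (1.0 + config.intensity_cv * _jitter(rng))
        if group == 1 and code in config.group_effects:
            e = config.group_effects[code]
            a = a * e.size_factors
            c = c + np.asarray(e.center_shift)
            v = v + e.intensity_shift
        if np.any(a <= 0):
            raise PhantomFitError(
                f"subject {sid!r}, object {code!r}: non-positive semi-axis {a}")
        margin = np.asarray(config.voxel_spacing)
        if np.any(c - a < margin) or np.any(c + a > config.extent_mm - margin):
            raise PhantomFitError(
                f"subject {sid!r}, object {code!r} escapes the grid: "
                f"centre {np.round(c, 2)} mm, semi-axes {np.round(a, 2)} mm, "
                f"grid extent {np.round(config.extent_mm, 2)} mm")
        axes[code], centers[code], intensities[code] = a, c, float(v)
    gain = rng.uniform(*config.gain_range)
    offset = rng.uniform(*config.offset_range)
    return SubjectTruth(sid, group, axes, centers, intensities,
                        float(gain), float(offset))


def _render_subject(config: PhantomConfig, truth: SubjectTruth,
                    rng: np.random.Generator) -> SubjectRecord:
    spacing = config.voxel_spacing
    masks = {
        code: ObjectMask(code, ellipsoid_mask(
            config.grid_shape, spacing, truth.centers[code],
            truth.semi_axes[code]), spacing=spacing)
        for code in BASE_OBJECTS
    }
    vol = np.full(config.grid_shape, config.background_intensity, dtype=np.float64)
    for code in PAINT_ORDER:
        vol[masks[code].values] = truth.intensities[code]
    vol += rng.normal(0.0, config.intensity_noise_sd, size=config.grid_shape)
    vol = truth.gain * vol + truth.offset
    return SubjectRecord(
        subject_id=truth.subject_id, group=truth.group,
        intensity=IntensityVolume(vol, spacing=spacing), masks=masks)


def generate_phantom_cohort(config: PhantomConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a two-group phantom cohort and its generative ground truth.

    Deterministic given ``config.seed``: each subject's parameters and voxel
    noise derive from a per-subject seed stream keyed by (seed, group,
    index), so group-0 subjects are unchanged by group-effect settings.
    """
    subjects: list[SubjectRecord] = []
    truths: list[SubjectTruth] = []
    for group in (0, 1):
        for i in range(config.subjects_per_group):
            truth = _draw_subject_truth(config, group, i)
            rng = np.random.default_rng([config.seed, group, i, 7])
            subjects.append(_render_subject(config, truth, rng))
            truths.append(truth)
    effects = config.group_effects
    gt = GroundTruth(
        group_labels=np.array([t.group for t in truths], dtype=int),
        subjects=truths,
        target_features=(list(DEFAULT_TARGET_FEATURES)
                         if effects == DEFAULT_GROUP_EFFECTS
                         else phantom_affected_features(effects)),
        affected_features=phantom_affected_features(effects),
    )
    return Cohort(subjects), gt


# --- direct feature-table simulation --------------------------------------

@dataclass
class FeatureSimConfig:
    """Conditions for the correlated-Gaussian feature-table simulator.

    ``correlation_blocks`` is a list of (block size, within-block
    correlation) pairs occupying the leading features; the remaining
    features are independent.  ``planted`` maps feature indices to the
    standardized group mean difference Delta (group 1 minus group 0; unit
    marginal variance throughout).
    """

    n_per_group: int = 15
    n_features: int = 159
    correlation_blocks: list[tuple[int, float]] = field(default_factory=list)
    planted: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        total = sum(s for s, _ in self.correlation_blocks)
        if total > self.n_features:
            raise ValueError("correlation blocks exceed n_features")
        for s, rho in self.correlation_blocks:
            if s < 1 or not -1.0 < rho < 1.0:
                raise ValueError(
                    f"invalid correlation block (size {s}, rho {rho})")
        for i, d in self.planted.items():
            if not 0 <= i < self.n_features:
                raise ValueError(f"planted feature index {i} out of range")
            if not np.isfinite(d):
                raise ValueError(f"planted delta for feature {i} is not finite")


def _sim_correlation(config: FeatureSimConfig) -> np.ndarray:
    p = config.n_features
    corr = np.eye(p)
    start = 0
    for size, rho in config.correlation_blocks:
        block = np.full((size, size), rho)
        np.fill_diagonal(block, 1.0)
        corr[start:start + size, start:start + size] = block
        start += size
    return corr


def generate_feature_table(config: FeatureSimConfig
                           ) -> tuple[FeatureTable, GroundTruth]:
    """Simulate a feature table with planted group structure.

    Rows: ``n_per_group`` group-0 then ``n_per_group`` group-1 subjects.
    Features are multivariate Gaussian with the block correlation structure
    and unit marginal variance; planted features get +Delta added for group
    1.  Columns carry the canonical catalog names when ``n_features`` is
    159, generic names otherwise.  Deterministic given ``config.seed``.
    """
    corr = _sim_correlation(config)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "correlation blocks yield a non-positive-definite covariance"
        ) from err
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_group
    X = rng.standard_normal((n, config.n_features)) @ chol.T
    groups = np.repeat([0, 1], config.n_per_group)
    for i, delta in config.planted.items():
        X[groups == 1, i] += delta
    if config.n_features == len(CATALOG):
        columns = list(CATALOG)
    else:
        columns = [f"f{i:03d}" for i in range(config.n_features)]
    index = pd.Index([f"s{i:03d}" for i in range(n)], name="subject_id")
    table = FeatureTable(
        data=pd.DataFrame(X, index=index, columns=columns),
        groups=pd.Series(groups, index=index, name="group"),
    )
    planted_ids = {columns[i]: float(d) for i, d in config.planted.items()}
    gt = GroundTruth(group_labels=groups,
                     target_features=sorted(planted_ids,
                                            key=columns.index),
                     affected_features=sorted(planted_ids,
                                              key=columns.index),
                     planted_deltas=planted_ids)
    return table, gt
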