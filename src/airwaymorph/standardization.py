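"""Landmark-based MR intensity standardization onto a fixed scale.

MR intensities carry no tissue-specific numeric meaning: the same tissue in
the same subject can map to different grey values across acquisitions.  The
classical two-stage remedy learns a set of histogram *landmarks* (percentiles
of the foreground intensity distribution) from a training cohort, maps each
training volume's [p1, p99] linearly onto a fixed standard scale, and
averages the mapped landmarks.  A new volume is then standardized by
piecewise-linear interpolation that sends its own landmarks onto the learned
standard landmarks.  The standard scale here is the closed interval
[0, 4095].

The transform is monotone non-decreasing, removes per-subject affine
(gain/offset) intensity distortions exactly, and is idempotent up to
interpolation tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volume_io import IntensityVolume, ObjectMask

STANDARD_SCALE: tuple[float, float] = (0.0, 4095.0)

#: Decile landmarks anchored at the 1st and 99th percentiles.
DEFAULT_PERCENTILES: tuple[float, ...] = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)


class DegenerateHistogramError(ValueError):
    """Foreground histogram has no spread (p1 == p99)."""


@dataclass
class StandardizationMap:
    """Learned piecewise-linear landmark mapping onto [0, 4095]."""

    standard_landmarks: np.ndarray
    landmark_percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    standard_scale: tuple[float, float] = STANDARD_SCALE
    foreground_rule: str = "sk"

    def __post_init__(self) -> None:
        self.standard_landmarks = np.asarray(self.standard_landmarks, dtype=float)
        pct = np.asarray(self.landmark_percentiles, dtype=float)
        if not np.all(np.diff(pct) > 0) or pct[0] <= 0 or pct[-1] >= 100:
            raise ValueError("landmark percentiles must be strictly increasing in (0, 100)")
        lm = self.standard_landmarks
        if lm.shape != pct.shape:
            raise ValueError("one standard landmark required per percentile")
        lo, hi = self.standard_scale
        if not np.all(np.diff(lm) > 0) or lm[0] < lo or lm[-1] > hi:
            raise ValueError(
                "standard landmarks must be strictly increasing within the standard scale"
            )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "standard_landmarks": self.standard_landmarks.tolist(),
            "landmark_percentiles": list(self.landmark_percentiles),
            "standard_scale": list(self.standard_scale),
            "foreground_rule": self.foreground_rule,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationMap":
        d = json.loads(Path(path).read_text())
        return cls(
            standard_landmarks=np.asarray(d["standard_landmarks"], dtype=float),
            landmark_percentiles=tuple(d["landmark_percentiles"]),
            standard_scale=tuple(d["standard_scale"]),
            foreground_rule=d.get("foreground_rule", "sk"),
        )


def _foreground_landmarks(volume: IntensityVolume, body_mask: ObjectMask,
                          percentiles) -> np.ndarray:
    vals = volume.values[body_mask.values]
    if vals.size == 0:
        raise ValueError("body mask is empty")
    lm = np.percentile(vals, percentiles)
    if lm[-1] <= lm[0]:
        raise DegenerateHistogramError(
            f"degenerate foreground histogram: p{percentiles[0]} == p{percentiles[-1]}"
        )
    return lm


def train_standardizer(volumes: list[IntensityVolume],
                       body_masks: list[ObjectMask],
                       percentiles=DEFAULT_PERCENTILES) -> StandardizationMap:
    """Learn standard landmarks from a training cohort.

    For each training volume the landmark intensities at ``percentiles`` are
    computed over the foreground (body-mask voxels), the volume's [p_first,
    p_last] interval is mapped linearly onto the standard scale, and the
    standard landmarks are the per-percentile means of the mapped values,
    nudged if necessary so they remain strictly increasing.
    """
    if len(volumes) < 2:
        raise ValueError(f"need at least 2 training volumes, got {len(volumes)}")
    if len(volumes) != len(body_masks):
        raise ValueError("one body mask required per training volume")
    lo, hi = STANDARD_SCALE
    mapped = []
    for vol, mask in zip(volumes, body_masks):
        lm = _foreground_landmarks(vol, mask, percentiles)
        mapped.append(lo + (lm - lm[0]) * (hi - lo) / (lm[-1] - lm[0]))
    standard = np.mean(mapped, axis=0)
    # clamp to strict monotonicity (ties can arise from averaging)
    eps = 1e-9 * (hi - lo)
    for i in range(1, standard.size):
        if standard[i] <= standard[i - 1]:
            standard[i] = standard[i - 1] + eps
    standard = np.clip(standard, lo, hi)
    return StandardizationMap(standard_landmarks=standard,
                              landmark_percentiles=tuple(percentiles))


def standardize_volume(volume: IntensityVolume, body_mask: ObjectMask,
                       smap: StandardizationMap) -> IntensityVolume:
    """Apply a trained landmark map to one volume.

    Piecewise-linear between the subject's landmarks and the standard
    landmarks; linear continuation with the end-segment slopes outside
    [p_first, p_last]; output clipped to the standard scale.  Monotone
    non-decreasing in the input intensity.
    """
    subj = _foreground_landmarks(volume, body_mask, smap.landmark_percentiles)
    std = smap.standard_landmarks
    # enforce strictly increasing subject landmarks for a well-posed interp
    eps = 1e-9 * max(subj[-1] - subj[0], 1.0)
    for i in range(1, subj.size):
        if subj[i] <= subj[i - 1]:
            subj[i] = subj[i - 1] + eps
    x = volume.values
    out = np.interp(x, subj, std)
    # linear extension beyond the anchor landmarks, then clip to scale
    lo_slope = (std[1] - std[0]) / (subj[1] - subj[0])
    hi_slope = (std[-1] - std[-2]) / (subj[-1] - subj[-2])
    below = x < subj[0]
    above = x > subj[-1]
    if np.any(below):
        out = np.where(below, std[0] + (x - subj[0]) * lo_slope, out)
    if np.any(above):
        out = np.where(above, std[-1] + (x - subj[-1]) * hi_slope, out)
    out = np.clip(out, *smap.standard_scale)
    return IntensityVolume(out, spacing=volume.spacing, origin=volume.origin)
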