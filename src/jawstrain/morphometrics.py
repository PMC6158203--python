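"""Jaw, joint and cell-shape measurements.

The measurement suite mirrors what is quantified on 3D renders of the larval
lower jaw: the width of the Meckel's cartilage neck and head at the jaw joint,
the joint space between Meckel's cartilage (MC) and palatoquadrate (PQ), cell
circularity (4*pi*A/P^2) from outlined chondrocytes, and counts of protruding
chondrocytes (exostosis-like cells outside the main cartilage elements).

Distances are voxel-centre Euclidean; a voxel is treated as a cube of material,
so the empty gap between two voxelized surfaces is the minimal centre-to-centre
distance minus one voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LinearRing

from .errors import MeasurementError, ValidationError
from .volume import (
    CARTILAGE_LABELS,
    ELEMENT_LABELS,
    EXOSTOSIS,
    INTERZONE,
    MC_LEFT,
    MC_RIGHT,
    PQ_LEFT,
    PQ_RIGHT,
    LabelVolume,
)

__all__ = [
    "ClosedPolygon",
    "JointMorphometrics",
    "circularity",
    "measure_joint",
    "count_protrusions",
    "summarize_groups",
]

#: 26-connectivity structuring element for component analysis.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class ClosedPolygon:
    """Simple closed polygon in the plane, vertices in micrometres."""

    vertices: np.ndarray  # (n, 2), implicitly closed

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError("polygon needs an (n, 2) vertex array with n >= 3")
        if not np.all(np.isfinite(v)):
            raise ValidationError("polygon vertices must be finite")
        object.__setattr__(self, "vertices", v)

    @cached_property
    def _ring(self) -> LinearRing:
        return LinearRing(self.vertices)

    @property
    def is_simple(self) -> bool:
        return bool(shapely.is_simple(self._ring))

    @property
    def area(self) -> float:
        """Enclosed area by the shoelace formula (um^2)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    @property
    def perimeter(self) -> float:
        """Closed perimeter length (um)."""
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    @property
    def circularity(self) -> float:
        return circularity(self)


def circularity(poly: ClosedPolygon) -> float:
    """Shape descriptor ``4 pi A / P^2``: 1 for a circle, <1 otherwise.

    Raises :class:`ValidationError` on self-intersecting outlines, matching the
    behaviour of interactive freehand measurement tools that reject them.
    """
    if not poly.is_simple:
        raise ValidationError("self-intersecting polygon has no defined circularity")
    p = poly.perimeter
    if p <= 0:
        raise ValidationError("degenerate polygon with zero perimeter")
    return 4.0 * np.pi * poly.area / p**2


@dataclass(frozen=True)
class JointMorphometrics:
    """Joint-level shape summary (all in micrometres)."""

    neck_width: float
    head_width: float
    joint_space: float
    jaw_length: float
    jaw_width: float


def _width_at_plane(vol: LabelVolume, label: int, plane_x: float, axis: int = 1) -> float:
    """Maximal label extent along ``axis`` in the one-voxel slab at ``plane_x``."""
    h = vol.voxel_size
    xs = (np.arange(vol.shape[0]) + 0.5) * h
    sel = np.abs(xs - plane_x) <= h / 2 + 1e-9
    if not sel.any():
        raise MeasurementError(f"landmark plane x={plane_x} outside the volume")
    slab = vol.labels[sel] == label
    if not slab.any():
        raise MeasurementError(
            f"label {label} absent in the slab at x={plane_x}"
        )
    idx = np.argwhere(slab)[:, axis]
    return float((idx.max() - idx.min() + 1) * h)


def surface_gap(vol: LabelVolume, labels_a: tuple[int, ...], labels_b: tuple[int, ...]) -> float:
    """Minimal surface-to-surface distance between two label sets (um).

    Computed as the minimum voxel-centre distance minus one voxel size (each
    voxel contributes half a voxel of material on either side of its centre),
    floored at zero.
    """
    a = vol.mask(*labels_a)
    b = vol.mask(*labels_b)
    if not a.any():
        raise MeasurementError(f"labels {labels_a} missing from volume")
    if not b.any():
        raise MeasurementError(f"labels {labels_b} missing from volume")
    # distance from every voxel to the nearest A voxel centre, sampled at B
    d = ndimage.distance_transform_edt(~a, sampling=vol.voxel_size)
    gap = float(d[b].min()) - vol.voxel_size
    return max(gap, 0.0)


def measure_joint(vol: LabelVolume, landmarks: dict[str, float] | None = None) -> JointMorphometrics:
    """Measure the Fig.-2-style joint morphometrics on a labelled jaw volume.

    ``landmarks`` carries the measurement-plane x positions (``neck_x``,
    ``head_x``); the generator stores them in ``vol.meta['landmarks']`` so a
    synthetic volume measures itself without manual placement.
    """
    if landmarks is None:
        landmarks = vol.meta.get("landmarks")
    if not landmarks or "neck_x" not in landmarks or "head_x" not in landmarks:
        raise MeasurementError("no landmark planes supplied (need neck_x, head_x)")
    for lab, name in [(MC_LEFT, "meckels_left"), (PQ_LEFT, "palatoquadrate_left")]:
        if not vol.mask(lab).any():
            raise MeasurementError(f"required label '{name}' missing from volume")

    h = vol.voxel_size
    necks, heads = [], []
    for mc in (MC_LEFT, MC_RIGHT):
        if vol.mask(mc).any():
            necks.append(_width_at_plane(vol, mc, landmarks["neck_x"]))
            heads.append(_width_at_plane(vol, mc, landmarks["head_x"]))
    joint_space = surface_gap(vol, (MC_LEFT, MC_RIGHT), (PQ_LEFT, PQ_RIGHT))

    jaw = vol.mask(MC_LEFT, MC_RIGHT, PQ_LEFT, PQ_RIGHT)
    xi = np.argwhere(jaw)
    jaw_length = float((xi[:, 0].max() - xi[:, 0].min() + 1) * h)
    all_el = vol.mask(*ELEMENT_LABELS)
    yi = np.argwhere(all_el)
    jaw_width = float((yi[:, 1].max() - yi[:, 1].min() + 1) * h)

    return JointMorphometrics(
        neck_width=float(np.mean(necks)),
        head_width=float(np.mean(heads)),
        joint_space=joint_space,
        jaw_length=jaw_length,
        jaw_width=jaw_width,
    )


def count_protrusions(vol: LabelVolume, min_size: int = 5) -> int:
    """Count cartilage components outside the main elements.

    A protrusion is a 26-connected component of cartilage-lineage voxels with at
    least ``min_size`` voxels that shares no voxel with the main skeletal
    elements (a component that merges with an element is, by definition, part of
    it). The size floor suppresses single-voxel segmentation noise.
    """
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    tissue = vol.mask(*CARTILAGE_LABELS, INTERZONE, EXOSTOSIS)
    main = vol.mask(*CARTILAGE_LABELS, INTERZONE)
    comp, n = ndimage.label(tissue, structure=_CONN26)
    if n == 0:
        return 0
    sizes = np.bincount(comp.ravel(), minlength=n + 1)
    touches_main = np.zeros(n + 1, dtype=bool)
    touches_main[np.unique(comp[main])] = True
    keep = (sizes >= min_size) & ~touches_main
    keep[0] = False
    return int(keep.sum())


def summarize_groups(df: pd.DataFrame, group: str = "group") -> pd.DataFrame:
    """Per-group mean and standard error for every numeric measurement column.

    Returns a frame indexed by group with a (metric, statistic) column
    hierarchy; SEM is NaN for singleton groups (flagged, not fabricated). No
    inferential statistics are computed.
    """
    if group not in df.columns:
        raise ValidationError(f"grouping column '{group}' not in frame")
    if df.empty:
        raise ValidationError("no specimens to summarize")
    counts = df.groupby(group).size()
    if (counts < 1).any():
        raise ValidationError("empty group")
    numeric = df.select_dtypes("number").columns
    if numeric.empty:
        raise ValidationError("no numeric measurement columns")
    agg = df.groupby(group)[list(numeric)].agg(["mean", "sem", "count"])
    return agg
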