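"""Labelled voxel volumes — the geometric substrate shared by all stages.

Axis convention: axis 0 = x (anterior -> posterior), axis 1 = y (lateral,
midline near the centre), axis 2 = z (ventral -> dorsal). Voxels are isotropic;
the centre of voxel ``(i, j, k)`` sits at ``((i + 0.5) h, (j + 0.5) h,
(k + 0.5) h)`` in micrometres, where ``h`` is the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "LabelVolume",
    "BACKGROUND",
    "MC_LEFT",
    "MC_RIGHT",
    "PQ_LEFT",
    "PQ_RIGHT",
    "CERATOHYAL",
    "INTERZONE",
    "EXOSTOSIS",
    "IMMATURE",
    "HYPERTROPHIC",
    "LABEL_NAMES",
    "ELEMENT_LABELS",
    "CARTILAGE_LABELS",
]

# Label dictionary (closed: any other value in a LabelVolume is an error).
BACKGROUND = 0
MC_LEFT = 1        # Meckel's cartilage, left
MC_RIGHT = 2       # Meckel's cartilage, right
PQ_LEFT = 3        # palatoquadrate, left
PQ_RIGHT = 4       # palatoquadrate, right
CERATOHYAL = 5
INTERZONE = 6      # joint interzone tissue bridging articulating elements
EXOSTOSIS = 7      # protruding chondrocytes outside the main elements
IMMATURE = 8       # near-joint cartilage (duplicate-mesh region)
HYPERTROPHIC = 9   # main-body cartilage after the joint split

LABEL_NAMES = {
    BACKGROUND: "background",
    MC_LEFT: "meckels_left",
    MC_RIGHT: "meckels_right",
    PQ_LEFT: "palatoquadrate_left",
    PQ_RIGHT: "palatoquadrate_right",
    CERATOHYAL: "ceratohyal",
    INTERZONE: "interzone",
    EXOSTOSIS: "exostosis",
    IMMATURE: "cartilage_immature",
    HYPERTROPHIC: "cartilage_hypertrophic",
}

#: Skeletal elements proper (what Otsu would segment as cartilage rods).
ELEMENT_LABELS = (MC_LEFT, MC_RIGHT, PQ_LEFT, PQ_RIGHT, CERATOHYAL)
#: Everything that is cartilage tissue for meshing/partitioning purposes.
CARTILAGE_LABELS = ELEMENT_LABELS + (IMMATURE, HYPERTROPHIC)


@dataclass
class LabelVolume:
    """3D integer label grid with isotropic voxel size in micrometres.

    ``meta`` carries generator-side landmarks (joint plane positions, muscle
    attachment points) so downstream stages never re-derive them by eye.
    """

    labels: np.ndarray
    voxel_size: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        bad = np.setdiff1d(np.unique(self.labels), list(LABEL_NAMES))
        if bad.size:
            raise ValueError(f"undeclared label values present: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, *label_ids: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        return np.isin(self.labels, label_ids)

    def centers(self, mask: np.ndarray) -> np.ndarray:
        """Voxel-centre coordinates (um) of masked voxels, shape (n, 3)."""
        idx = np.argwhere(mask)
        return (idx + 0.5) * self.voxel_size

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.labels.copy(), self.voxel_size, dict(self.meta))
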