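"""Core data containers shared across the pipeline.

The raw unit of analysis is a 3-channel 2D fluorescence tile (Hoechst for
nuclei, TMRM for mitochondria / membrane potential, CellMask deep red for
the plasma membrane).  Segmentation stages produce integer label masks on
the same pixel grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

#: Channel order used everywhere in the package.
CHANNELS = ("hoechst", "tmrm", "cellmask")

Condition = Literal["baseline", "FCCP"]
MaskKind = Literal["nuclei", "cell", "mito"]


@dataclass
class ImageTile:
    """One 3-channel 2D image tile.

    All three channels share a pixel grid; intensities are non-negative
    (16-bit unsigned in files, but float arrays are accepted in memory).
    """

    hoechst: np.ndarray
    tmrm: np.ndarray
    cellmask: np.ndarray
    subject_id: str = ""
    well_id: str = ""
    tile_id: int = 0
    condition: Condition = "baseline"
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        shapes = {self.hoechst.shape, self.tmrm.shape, self.cellmask.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.hoechst.ndim != 2:
            raise ValueError("channels must be 2D arrays")
        for name in CHANNELS:
            arr = getattr(self, name)
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"negative intensities in channel {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hoechst.shape

    @property
    def channels(self) -> np.ndarray:
        """Channels stacked (hoechst, tmrm, cellmask) as a (3, H, W) array."""
        return np.stack([self.hoechst, self.tmrm, self.cellmask])


@dataclass
class LabelMask:
    """Integer-labelled segmentation sharing the tile's pixel grid.

    Background is 0; labels are contiguous 1..K after any filtering
    operation.  Components are connected under 8-connectivity.
    """

    labels: np.ndarray
    kind: MaskKind = "mito"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def is_contiguous(self) -> bool:
        """True if the label set is exactly {1..K} with no gaps."""
        present = np.unique(self.labels)
        present = present[present > 0]
        return bool(len(present) == 0 or
                    (present[0] == 1 and present[-1] == len(present)))


@dataclass
class GroundTruth:
    """Simulator ground truth for one tile.

    ``per_mito_truth`` columns: cell_id, mito_id, area_px, skeleton_px,
    branch_count, endpoint_count, width_px.
    ``per_cell_truth`` columns: cell_id, mito_count, total_mito_area_px,
    mean_tmrm.
    """

    nuclei_mask: LabelMask
    cell_mask: LabelMask
    mito_mask: LabelMask
    per_mito_truth: "object" = None  # pandas.DataFrame
    per_cell_truth: "object" = None  # pandas.DataFrame
    mito_to_cell: dict = field(default_factory=dict)
    #: cell-label pairs rendered as touching cells
    touching_pairs: list = field(default_factory=list)
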