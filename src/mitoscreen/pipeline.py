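"""End-to-end tile processing: segmentation -> features -> QC.

Glue between the segmentation and morphometrics stages, parameterized by
:class:`mitoscreen.io.PipelineConfig`.  Group labels are never read at
these stages (segmentation and feature extraction are blind to sample
status by construction).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import morphometrics, segment
from .io import PipelineConfig
from .types import ImageTile

__all__ = ["segment_tile", "tile_features", "cohort_features"]


def segment_tile(tile: ImageTile, config: PipelineConfig | None = None):
    """Run the three segmentation stages on one tile.

    Returns ``(nuclei, cells, mito, qc)`` where qc is the cell-splitting
    QC table plus per-tile counts.
    """
    cfg = config or PipelineConfig()
    nuclei = segment.detect_nuclei(
        tile.hoechst, gaussian_size=cfg.nucleus_gaussian_size,
        gaussian_sd=cfg.nucleus_gaussian_sd,
        threshold=cfg.nucleus_threshold, min_size=cfg.nucleus_min_size)
    cell_area = segment.segment_cell_area(
        tile.cellmask, dog_sigma_narrow=cfg.cell_dog_sigma_narrow,
        dog_sigma_wide=cfg.cell_dog_sigma_wide,
        threshold=cfg.cell_dog_threshold, min_size=cfg.cell_min_size)
    cells, qc = segment.split_cells(
        cell_area, nuclei, tile.cellmask,
        threshold=cfg.split_threshold,
        erosion_radius=cfg.split_erosion_radius,
        max_iterations=cfg.split_max_iterations)
    mito = segment.segment_mitochondria(
        tile.tmrm, dog_sigma_narrow=cfg.mito_dog_sigma_narrow,
        dog_sigma_wide=cfg.mito_dog_sigma_wide,
        threshold=cfg.mito_dog_threshold, min_size=cfg.mito_min_size)
    return nuclei, cells, mito, qc


def tile_features(tile: ImageTile,
                  config: PipelineConfig | None = None) -> pd.DataFrame:
    """Segment one tile and compute its per-cell feature table."""
    nuclei, cells, mito, qc = segment_tile(tile, config)
    feats = morphometrics.compute_cell_features(
        cells, mito, np.asarray(tile.tmrm, dtype=np.float64))
    feats.insert(0, "subject_id", tile.subject_id)
    feats.insert(1, "condition", tile.condition)
    feats.insert(2, "tile_id", tile.tile_id)
    return feats


def cohort_features(tiles: dict, config: PipelineConfig | None = None,
                    metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell features for a rendered cohort (as from simulate_cohort).

    ``tiles`` maps (subject_id, condition, tile_index) -> (tile, truth);
    metadata columns (group, age, gender, doubling_time) are merged in
    when provided.
    """
    frames = []
    for (sid, cond, t), (tile, _truth) in sorted(tiles.items()):
        tile.subject_id, tile.condition, tile.tile_id = sid, cond, t
        frames.append(tile_features(tile, config))
    cells = pd.concat(frames, ignore_index=True)
    if metadata is not None:
        cells = cells.merge(
            metadata[["subject_id", "condition", "group", "age", "gender",
                      "doubling_time"]],
            on=["subject_id", "condition"], how="left")
    return cells
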