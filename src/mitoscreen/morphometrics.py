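"""Per-mitochondrion morphometrics and per-cell / per-subject aggregation.

Feature definitions (computer-vision / graph-theory terminology):

* ``MitoVolume`` — pixel count of the mitochondrial component ("volume"
  is the assay's historical name for 2D pixel area; units are pixels).
* ``MitoPerimeter`` / ``MitoErosionBodies`` — the component is eroded
  with a radius-1 disk; the surviving pixels are the "bodies" (their
  connected-component count is the erosion-body count) and the removed
  rim, component AND NOT bodies, is the perimeter (pixel count).  By
  construction perimeter + body pixel counts equal the area exactly.
* ``MitoSkel`` — pixel count of the homotopic-thinning skeleton.
* ``MitoNodes`` / ``MitoEndpoints`` — skeleton pixels with >=3 /
  exactly 1 skeleton neighbours (8-connectivity); ``MitoNodeDegree`` is
  the mean neighbour count over node pixels (0 for node-free skeletons).
* ``MitoFormFactor`` — perimeter^2 / (4*pi*area), with the
  subtraction-defined pixel-count perimeter; rises with boundary
  complexity and elongation.  Because the perimeter is a pixel count
  rather than a contour-length estimate, the form-factor-of-a-disk = 1
  ideal holds only approximately.
* ``MitoAspectRatio`` — major/minor axis length of the moments-fitted
  ellipse; the minor axis is floored at 1 px (a digital object is at
  least one pixel wide), so a 1-px component has aspect ratio 1.

Per-mito features are averaged per cell as unweighted means; cells are
averaged per subject as unweighted means.  Cells with zero mitochondria
keep their cell-shape features but are excluded from per-mito feature
means (logged).  Subjects with fewer than ``min_cells`` analysed cells
(default 175) are flagged.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, skeletonize as _sk_skeletonize

from .types import LabelMask

logger = logging.getLogger(__name__)

__all__ = [
    "skeletonize",
    "nodes_and_endpoints",
    "perimeter_and_bodies",
    "shape_factors",
    "compute_mito_features",
    "compute_cell_record",
    "compute_cell_features",
    "aggregate_subject",
    "aggregate_subjects",
    "MITO_FEATURES",
    "CELL_FEATURES",
]

#: Per-cell feature columns, named as in the screening assay's readouts.
MITO_FEATURES = [
    "MitoCount", "MitoVolumeMean", "MitoVolumeTotal", "MitoPerimeter",
    "MitoFormFactor", "MitoErosionBodies", "MitoNodeDegree", "MitoSkel",
    "MitoNodes", "MitoEndpoints", "MitoAspectRatio", "TMRM_MitoMask",
]
CELL_FEATURES = ["TMRM_Cell", "AspectRatioCell", "FormFactorCell"]

_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def skeletonize(component: np.ndarray) -> np.ndarray:
    """1-px-wide skeleton via homotopic thinning.

    Preserves topology: the skeleton has the same number of connected
    components and holes (cycles) as the input.  Idempotent on sets that
    are already 1 px wide.
    """
    component = np.asarray(component).astype(bool)
    if not component.any():
        raise ValueError("cannot skeletonize an empty component")
    return _sk_skeletonize(component)


def nodes_and_endpoints(skeleton: np.ndarray):
    """Classify skeleton pixels by 8-neighbour count.

    Returns ``(node_mask, endpoint_mask, node_degree)``: endpoints have
    exactly 1 skeleton neighbour, nodes have >=3; node_degree is the mean
    neighbour count over node pixels (0.0 when there are no nodes).
    """
    skel = np.asarray(skeleton).astype(bool)
    nb = ndi.convolve(skel.astype(np.uint8), _NEIGH, mode="constant")
    nb = np.where(skel, nb, 0)
    endpoints = skel & (nb == 1)
    nodes = skel & (nb >= 3)
    node_degree = float(nb[nodes].mean()) if nodes.any() else 0.0
    return nodes, endpoints, node_degree


def perimeter_and_bodies(component: np.ndarray, erosion_radius: int = 1):
    """Erosion bodies and subtraction-defined perimeter.

    ``bodies`` is the binary erosion of the component with a disk of
    ``erosion_radius``; ``perimeter`` is component AND NOT bodies.
    Returns ``(perimeter_mask, bodies_mask, n_bodies, perimeter_px)``.
    """
    component = np.asarray(component).astype(bool)
    if not component.any():
        raise ValueError("empty component")
    bodies = ndi.binary_erosion(component, structure=disk(erosion_radius),
                                border_value=0)
    perimeter = component & ~bodies
    n_bodies = int(cc_label(bodies, connectivity=2).max())
    return perimeter, bodies, n_bodies, int(perimeter.sum())


def shape_factors(component: np.ndarray,
                  perimeter_px: float) -> tuple[float, float]:
    """Form factor and aspect ratio of one component.

    ``form_factor = perimeter^2 / (4 pi area)`` using the
    subtraction-defined perimeter pixel count; ``aspect_ratio`` is the
    major/minor axis length ratio of the moments-fitted ellipse, with
    the minor axis floored at 1 px (so a single pixel has ratio 1).
    """
    component = np.asarray(component).astype(bool)
    area = int(component.sum())
    if area == 0:
        raise ValueError("empty component")
    form_factor = float(perimeter_px) ** 2 / (4.0 * np.pi * area)
    if area == 1:
        return form_factor, 1.0
    props = regionprops(component.astype(np.uint8))[0]
    minor = max(props.axis_minor_length, 1.0)
    major = max(props.axis_major_length, minor)
    return form_factor, float(major / minor)


def compute_mito_features(mito: LabelMask, tmrm: np.ndarray,
                          assignment: pd.DataFrame | None = None,
                          ) -> pd.DataFrame:
    """Per-mitochondrion feature table (one row per mito label).

    Columns: mito_id, cell_id (if ``assignment`` given), area, perimeter,
    erosion_bodies, form_factor, aspect_ratio, skeleton_size, nodes,
    endpoints, node_degree, tmrm_mean.
    """
    tmrm = np.asarray(tmrm, dtype=np.float64)
    if tmrm.shape != mito.labels.shape:
        raise ValueError("tmrm and mito mask differ in shape")
    cell_of = ({int(r.mito_id): int(r.cell_id)
                for r in assignment.itertuples()}
               if assignment is not None else {})
    rows = []
    for props in regionprops(mito.labels.astype(np.int32)):
        comp = props.image  # bounding-box binary
        area = int(props.area)
        skel = skeletonize(comp)
        node_mask, end_mask, node_degree = nodes_and_endpoints(skel)
        _, _, n_bodies, perim = perimeter_and_bodies(comp)
        form_factor, aspect = shape_factors(comp, perim)
        sl = props.slice
        tmrm_mean = float(tmrm[sl][comp].mean())
        rows.append(dict(
            mito_id=int(props.label),
            cell_id=cell_of.get(int(props.label), 0),
            area=area, perimeter=perim, erosion_bodies=n_bodies,
            form_factor=form_factor, aspect_ratio=aspect,
            skeleton_size=int(skel.sum()), nodes=int(node_mask.sum()),
            endpoints=int(end_mask.sum()), node_degree=node_degree,
            tmrm_mean=tmrm_mean))
    return pd.DataFrame(rows, columns=[
        "mito_id", "cell_id", "area", "perimeter", "erosion_bodies",
        "form_factor", "aspect_ratio", "skeleton_size", "nodes",
        "endpoints", "node_degree", "tmrm_mean"])


_PER_MITO_MEANS = {
    "MitoVolumeMean": "area",
    "MitoPerimeter": "perimeter",
    "MitoFormFactor": "form_factor",
    "MitoErosionBodies": "erosion_bodies",
    "MitoNodeDegree": "node_degree",
    "MitoSkel": "skeleton_size",
    "MitoNodes": "nodes",
    "MitoEndpoints": "endpoints",
    "MitoAspectRatio": "aspect_ratio",
}


def compute_cell_record(cell_mask: np.ndarray, mitos: pd.DataFrame,
                        tmrm: np.ndarray) -> dict:
    """Aggregate one cell: per-mito feature means, TMRM readouts and
    cell-shape factors.

    ``TMRM_MitoMask`` is the mean TMRM intensity over the union of the
    cell's mitochondrial pixels; ``TMRM_Cell`` the mean over the whole
    cell area.  MitoVolumeTotal = sum of mito areas and MitoVolumeMean =
    MitoVolumeTotal / MitoCount hold exactly.
    """
    cell_mask = np.asarray(cell_mask).astype(bool)
    tmrm = np.asarray(tmrm, dtype=np.float64)
    n = len(mitos)
    rec: dict = {"MitoCount": n}
    rec["MitoVolumeTotal"] = float(mitos["area"].sum()) if n else 0.0
    for out_col, in_col in _PER_MITO_MEANS.items():
        rec[out_col] = float(mitos[in_col].mean()) if n else np.nan
    rec["TMRM_Cell"] = float(tmrm[cell_mask].mean())
    _, _, _, cell_perim = perimeter_and_bodies(cell_mask)
    ff, ar = shape_factors(cell_mask, cell_perim)
    rec["FormFactorCell"] = ff
    rec["AspectRatioCell"] = ar
    rec["cell_area"] = int(cell_mask.sum())
    return rec


def compute_cell_features(cells: LabelMask, mito: LabelMask,
                          tmrm: np.ndarray,
                          mito_features: pd.DataFrame | None = None,
                          assignment: pd.DataFrame | None = None,
                          ) -> pd.DataFrame:
    """Per-cell feature table for one tile.

    Computes (or reuses) per-mito features and their cell assignment,
    then aggregates one record per cell label.  Cells with zero
    mitochondria are retained with NaN per-mito means and logged.
    """
    from .segment import assign_mitochondria_to_cells

    if assignment is None:
        assignment = assign_mitochondria_to_cells(mito, cells)
    if mito_features is None:
        mito_features = compute_mito_features(mito, tmrm, assignment)
    else:
        mito_features = mito_features.copy()
        cell_of = {int(r.mito_id): int(r.cell_id)
                   for r in assignment.itertuples()}
        mito_features["cell_id"] = [
            cell_of.get(int(m), 0) for m in mito_features["mito_id"]]
    rows = []
    n_empty = 0
    for props in regionprops(cells.labels.astype(np.int32)):
        cid = int(props.label)
        sub = mito_features[mito_features["cell_id"] == cid]
        comp = np.zeros(cells.labels.shape, dtype=bool)
        comp[props.slice] = props.image
        rec = compute_cell_record(comp, sub, tmrm)
        rec["cell_id"] = cid
        if rec["MitoCount"] == 0:
            n_empty += 1
        rows.append(rec)
    if n_empty:
        logger.info("%d cells without mitochondria (per-mito means NaN)",
                    n_empty)
    df = pd.DataFrame(rows)
    cols = ["cell_id"] + MITO_FEATURES[:-1] + ["TMRM_MitoMask"]
    # TMRM_MitoMask: mean TMRM over the union of the cell's mito pixels
    tmrm_arr = np.asarray(tmrm, dtype=np.float64)
    mm = []
    for cid in df["cell_id"]:
        mids = assignment.loc[assignment["cell_id"] == cid, "mito_id"]
        sel = np.isin(mito.labels, mids.to_numpy()) if len(mids) else None
        mm.append(float(tmrm_arr[sel].mean()) if sel is not None
                  and sel.any() else np.nan)
    df["TMRM_MitoMask"] = mm
    ordered = (["cell_id"] + MITO_FEATURES + CELL_FEATURES + ["cell_area"])
    return df[ordered]


def aggregate_subject(cells: pd.DataFrame, min_cells: int = 175) -> dict:
    """Unweighted per-subject mean over cell records.

    Cells with zero mitochondria are excluded from per-mito feature
    means but still counted in ``n_cells`` and cell-shape means.
    Subjects with ``n_cells < min_cells`` are flagged (``low_cell_count``).
    """
    if len(cells) == 0:
        raise ValueError("empty cell record list")
    rec: dict = {"n_cells": int(len(cells)),
                 "low_cell_count": bool(len(cells) < min_cells)}
    with_mito = cells[cells["MitoCount"] > 0]
    for col in MITO_FEATURES:
        rec[col] = float(with_mito[col].mean()) if len(with_mito) else np.nan
    rec["MitoCount"] = float(cells["MitoCount"].mean())
    for col in CELL_FEATURES:
        if col in cells:
            rec[col] = float(cells[col].mean())
    return rec


def aggregate_subjects(cells: pd.DataFrame, min_cells: int = 175,
                       meta_cols: tuple[str, ...] = ("group", "age",
                                                     "gender",
                                                     "doubling_time"),
                       ) -> pd.DataFrame:
    """Aggregate a long per-cell table to one row per subject x condition.

    ``cells`` must carry subject_id and condition columns; metadata
    columns listed in ``meta_cols`` are carried through unchanged.
    """
    rows = []
    for (sid, cond), sub in cells.groupby(["subject_id", "condition"],
                                          sort=True):
        rec = aggregate_subject(sub, min_cells=min_cells)
        rec["subject_id"] = sid
        rec["condition"] = cond
        for col in meta_cols:
            if col in sub:
                rec[col] = sub[col].iloc[0]
        rows.append(rec)
    df = pd.DataFrame(rows)
    front = ["subject_id", "condition"] + [c for c in meta_cols if c in df]
    return df[front + [c for c in df.columns if c not in front]]
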