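"""Three-channel segmentation: nuclei, cell area, nucleus-guided cell
splitting, and mitochondria.

Nuclei are detected on the Hoechst channel by Gaussian low-pass filtering
(10x10 kernel, sigma 2) and a fixed intensity threshold (>100); cell area
and mitochondria come from difference-of-Gaussians (DoG) band-pass
filtering of the CellMask and TMRM channels.  Size filters are strict
"fewer than N pixels removed": a component of exactly N pixels survives.

Touching cells are split with a bespoke grey-tone-erosion algorithm: the
CellMask intensity image is eroded repeatedly with a disk-shaped
structuring element until re-thresholding separates a multi-nucleus
component into parts containing one nucleus each; all original foreground
pixels are then re-attached to the nearest part, geodesically within the
component, so foreground area is conserved.  Splitting success is
validated by nucleus counting.

All operations are deterministic: identical inputs and parameters yield
bit-identical label masks.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .types import LabelMask

logger = logging.getLogger(__name__)

__all__ = [
    "gaussian_lowpass",
    "detect_nuclei",
    "segment_cell_area",
    "split_cells",
    "segment_mitochondria",
    "assign_mitochondria_to_cells",
    "filter_small_objects",
]

#: 8-connectivity structure used for all component labelling.
_CONN8 = np.ones((3, 3), dtype=bool)


def _check_2d(image: np.ndarray, name: str = "image") -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 2D array")
    return arr


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Truncated ``size x size`` Gaussian kernel, normalized to unit sum.

    ``size`` may be even (the classic 10x10 / sigma 2 low-pass); samples
    are taken at offsets symmetric about the kernel center.
    """
    if size < 1 or sigma <= 0:
        raise ValueError("size and sigma must be positive")
    offsets = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(offsets ** 2) / (2.0 * sigma ** 2))
    kernel = np.outer(g, g)
    return kernel / kernel.sum()


def gaussian_lowpass(image: np.ndarray, size: int = 10,
                     sigma: float = 2.0) -> np.ndarray:
    """Low-pass filter with a truncated, unit-sum Gaussian kernel.

    Border handled by edge replication.
    """
    arr = _check_2d(image)
    return ndi.correlate(arr, gaussian_kernel(size, sigma), mode="nearest")


def filter_small_objects(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Remove components with *fewer than* ``min_size`` pixels and
    relabel contiguously (1..K).  A component of exactly ``min_size``
    pixels survives."""
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels.astype(np.int32)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    mapping = np.zeros(len(sizes), dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    return mapping[labels]


def _threshold_and_label(filtered: np.ndarray, threshold: float,
                         min_size: int) -> np.ndarray:
    mask = filtered > threshold  # strict, as in ">100"
    labels = cc_label(mask, connectivity=2)
    return filter_small_objects(labels, min_size)


def detect_nuclei(hoechst: np.ndarray, gaussian_size: int = 10,
                  gaussian_sd: float = 2.0, threshold: float = 100.0,
                  min_size: int = 500) -> LabelMask:
    """Detect nuclei on the Hoechst channel.

    Gaussian low-pass (``gaussian_size`` x ``gaussian_size`` kernel,
    sigma ``gaussian_sd``), strict threshold, 8-connected labelling, and
    removal of components with fewer than ``min_size`` pixels.
    """
    if gaussian_size <= 0 or gaussian_sd <= 0 or min_size < 0:
        raise ValueError("parameters must be positive")
    filtered = gaussian_lowpass(hoechst, gaussian_size, gaussian_sd)
    return LabelMask(_threshold_and_label(filtered, threshold, min_size),
                     "nuclei")


def difference_of_gaussians(image: np.ndarray, sigma_narrow: float,
                            sigma_wide: float) -> np.ndarray:
    """Band-pass DoG: G(sigma_narrow)*I - G(sigma_wide)*I."""
    arr = _check_2d(image)
    if sigma_narrow >= sigma_wide:
        raise ValueError("sigma_narrow must be < sigma_wide")
    return (ndi.gaussian_filter(arr, sigma_narrow, mode="nearest")
            - ndi.gaussian_filter(arr, sigma_wide, mode="nearest"))


def segment_cell_area(cellmask_channel: np.ndarray,
                      dog_sigma_narrow: float = 4.0,
                      dog_sigma_wide: float = 40.0,
                      threshold: float = 60.0,
                      min_size: int = 200) -> np.ndarray:
    """Binary cell-area mask from the CellMask deep red channel.

    DoG band-pass, strict threshold, removal of components with fewer
    than ``min_size`` pixels.  Sigma/threshold defaults were chosen on
    the built-in simulator; the size filter (200) is fixed.
    """
    dog = difference_of_gaussians(cellmask_channel, dog_sigma_narrow,
                                  dog_sigma_wide)
    return _threshold_and_label(dog, threshold, min_size) > 0


def auto_dog_threshold(dog: np.ndarray, fraction: float = 0.5,
                       percentile: float = 99.5,
                       noise_mult: float = 6.0) -> float:
    """Per-tile robust threshold for a DoG response.

    ``fraction`` of a high percentile of the response (which lands inside
    the foreground intensity range when foreground occupies <~1% of the
    tile), floored at ``noise_mult`` robust-sigma of the response (MAD
    estimate) so an empty tile yields an empty mask.
    """
    flat = np.asarray(dog).ravel()
    med = np.median(flat)
    mad_sigma = 1.4826 * np.median(np.abs(flat - med))
    return float(max(fraction * np.percentile(flat, percentile),
                     noise_mult * mad_sigma, 1e-6))


def segment_mitochondria(tmrm: np.ndarray, dog_sigma_narrow: float = 1.0,
                         dog_sigma_wide: float = 4.0,
                         threshold: float | str = "auto",
                         min_size: int = 6) -> LabelMask:
    """MitoMask: labelled mitochondria from the TMRM channel.

    DoG band-pass, strict threshold, removal of components with fewer
    than 6 pixels.  ``threshold`` may be a fixed intensity (plate-wide
    convention) or ``"auto"`` for a per-tile robust threshold
    (:func:`auto_dog_threshold`), which tracks the global TMRM dimming
    under FCCP.
    """
    dog = difference_of_gaussians(tmrm, dog_sigma_narrow, dog_sigma_wide)
    if threshold == "auto":
        threshold = auto_dog_threshold(dog)
    return LabelMask(_threshold_and_label(dog, float(threshold), min_size),
                     "mito")


def _nuclei_per_part(parts: np.ndarray, nuclei: np.ndarray) -> dict[int, int]:
    """Map part label -> number of nuclei whose majority pixels fall in
    that part (nuclei entirely outside all parts count for part 0)."""
    counts: dict[int, int] = {}
    for nid in np.unique(nuclei):
        if nid == 0:
            continue
        owner_parts = parts[nuclei == nid]
        owner_parts = owner_parts[owner_parts > 0]
        if len(owner_parts) == 0:
            counts[0] = counts.get(0, 0) + 1
            continue
        owner = int(np.bincount(owner_parts).argmax())
        counts[owner] = counts.get(owner, 0) + 1
    return counts


def _geodesic_assign(component: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Assign every pixel of ``component`` to the geodesically nearest
    seed label (chebyshev steps within the component)."""
    out = np.where(component, seeds, 0).astype(np.int32)
    foot = np.ones((3, 3), dtype=np.int32)
    # iterative label propagation; components are small
    for _ in range(max(component.shape) * 2):
        unfilled = component & (out == 0)
        if not unfilled.any():
            break
        grown = ndi.grey_dilation(out, footprint=foot)
        out[unfilled] = grown[unfilled]
    return out


def split_cells(cell_area: np.ndarray, nuclei: LabelMask,
                intensity: np.ndarray, threshold: float = 300.0,
                erosion_radius: int = 12,
                max_iterations: int = 20) -> tuple[LabelMask, pd.DataFrame]:
    """Split multi-nucleus components of the cell-area mask into cells.

    For each connected component of ``cell_area`` the number of contained
    nuclei is counted.  Components with 0 nuclei are discarded; with 1
    nucleus they pass through unchanged.  Components with 2+ nuclei are
    iteratively grey-tone eroded on the CellMask ``intensity`` image
    (disk-shaped structuring element, ``erosion_radius``); after each
    pass the eroded intensity is re-thresholded and re-labelled, and when
    the parts' nuclei counts are all at most one and every nucleus is
    recovered, the parts are used as seeds and all original component
    pixels are re-attached to the geodesically nearest seed (foreground
    area is conserved).  Components that do not separate within
    ``max_iterations`` are flagged in the QC table and kept as one label.

    Returns ``(cell LabelMask, QC DataFrame)`` with QC columns
    cell_label, n_nuclei, split_success, border, source_component.
    """
    cell_area = np.asarray(cell_area).astype(bool)
    if cell_area.shape != nuclei.labels.shape:
        raise ValueError("cell_area and nuclei masks differ in shape")
    intensity = _check_2d(intensity, "intensity")
    if intensity.shape != cell_area.shape:
        raise ValueError("intensity and cell_area differ in shape")

    comps = cc_label(cell_area, connectivity=2)
    selem = disk(erosion_radius)
    out = np.zeros_like(comps, dtype=np.int32)
    qc_rows = []
    next_label = 1
    h, w = cell_area.shape
    objects = ndi.find_objects(comps)
    for comp_id, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        # pad bounding box so erosion sees the surroundings
        pad = erosion_radius + 1
        rs = slice(max(0, sl[0].start - pad), min(h, sl[0].stop + pad))
        cs = slice(max(0, sl[1].start - pad), min(w, sl[1].stop + pad))
        comp = comps[rs, cs] == comp_id
        nuc = np.where(comp, nuclei.labels[rs, cs], 0)
        nuc_ids = np.unique(nuc)
        nuc_ids = nuc_ids[nuc_ids > 0]
        n_nuc = len(nuc_ids)
        border = bool(sl[0].start == 0 or sl[1].start == 0
                      or sl[0].stop == h or sl[1].stop == w)
        if n_nuc == 0:
            continue  # discarded
        if n_nuc == 1:
            out[rs, cs][comp] = next_label
            qc_rows.append(dict(cell_label=next_label, n_nuclei=1,
                                split_success=True, border=border,
                                source_component=comp_id))
            next_label += 1
            continue
        # smooth before grey erosion: the min filter is extremely
        # sensitive to shot noise (it tracks local minima)
        eroded = ndi.gaussian_filter(intensity[rs, cs], 2.0, mode="nearest")
        success = False
        for _ in range(max_iterations):
            eroded = ndi.grey_erosion(eroded, footprint=selem)
            if not np.any((eroded > threshold) & comp):
                break  # everything eroded away; give up
            # escalating re-threshold schedule: necks shadowed by a
            # brighter neighbour separate at a higher cut
            for thr in (threshold * (1 + 0.25 * j) for j in range(5)):
                parts = cc_label((eroded > thr) & comp, connectivity=2)
                if parts.max() < 2:
                    continue
                per_part = _nuclei_per_part(parts, nuc)
                seeded = {p: c for p, c in per_part.items() if p > 0}
                if (per_part.get(0, 0) == 0 and len(seeded) == n_nuc
                        and all(c == 1 for c in seeded.values())):
                    success = True
                    break
            if success:
                seeds = np.where(np.isin(parts, list(seeded)), parts, 0)
                assigned = _geodesic_assign(comp, seeds)
                for p in sorted(seeded):
                    out[rs, cs][assigned == p] = next_label
                    qc_rows.append(dict(cell_label=next_label, n_nuclei=1,
                                        split_success=True, border=border,
                                        source_component=comp_id))
                    next_label += 1
                break
        if not success:
            out[rs, cs][comp] = next_label
            qc_rows.append(dict(cell_label=next_label, n_nuclei=n_nuc,
                                split_success=False, border=border,
                                source_component=comp_id))
            next_label += 1
            logger.warning("component %d with %d nuclei not split within "
                           "%d iterations", comp_id, n_nuc, max_iterations)
    qc = pd.DataFrame(qc_rows, columns=["cell_label", "n_nuclei",
                                        "split_success", "border",
                                        "source_component"])
    return LabelMask(out, "cell"), qc


def assign_mitochondria_to_cells(mito: LabelMask,
                                 cells: LabelMask) -> pd.DataFrame:
    """Assign each mitochondrion to the cell containing the majority of
    its pixels; mitochondria outside all cells are dropped (logged).

    Returns a DataFrame with columns mito_id, cell_id.
    """
    if mito.labels.shape != cells.labels.shape:
        raise ValueError("masks differ in shape")
    m = mito.labels.ravel()
    c = cells.labels.ravel()
    sel = m > 0
    if not sel.any():
        return pd.DataFrame(columns=["mito_id", "cell_id"])
    n_cells = int(cells.labels.max())
    pair = m[sel].astype(np.int64) * (n_cells + 1) + c[sel]
    counts = np.bincount(
        pair, minlength=(int(m[sel].max()) + 1) * (n_cells + 1))
    rows = []
    dropped = 0
    for mid in np.unique(m[sel]):
        segm = counts[mid * (n_cells + 1): (mid + 1) * (n_cells + 1)]
        owner = int(segm.argmax())
        if owner == 0:  # plurality of pixels outside all cells
            dropped += 1
            continue
        rows.append(dict(mito_id=int(mid), cell_id=owner))
    if dropped:
        logger.info("dropped %d mitochondria outside all cells", dropped)
    return pd.DataFrame(rows, columns=["mito_id", "cell_id"])
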