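"""Seeded synthetic 3-channel fluorescence microscopy simulator.

Generates tiles that emulate a high-content fibroblast screen: nuclei as
filled ellipses (Hoechst channel), cells as disks with a radially decaying
plasma-membrane / cytoplasm signal (CellMask channel), and mitochondria as
random trees rasterized as thin polylines carrying a TMRM intensity that
reports membrane potential.  Every tile comes with pixel-exact ground-truth
label masks and truth tables, so each downstream stage (segmentation,
skeleton morphometrics, statistics, classification) can be validated
without any external data.

Two-group cohorts carry a configurable "case" effect: more but smaller
mitochondria (fragmentation with conserved total mass), reduced branching,
and elevated TMRM retention under the protonophore FCCP.

Mitochondrial trees are grown as Galton-Watson processes: each segment end
branches into two children with probability ``branch_probability`` (up to
``max_segments`` segments per tree).  Rendered trees use 8-compass-direction
segments and reject any geometry that would violate clean 8-connected
topology, so the generative branch/endpoint counts are exact pixel-level
truth for skeleton analysis.  A second, structure-level sampler draws
per-cell feature records from the same generative law without
rasterization; it is used for cohort-scale statistical experiments.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .types import GroundTruth, ImageTile, LabelMask

__all__ = [
    "GroupEffect",
    "SimulationConfig",
    "OvercrowdingError",
    "simulate_tile",
    "simulate_cohort",
    "evaluate_pair_splitting",
    "sample_cell_features",
    "simulate_cohort_features",
    "expected_segments_per_tree",
]


class OvercrowdingError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""


# 8 compass directions in 45-degree steps (row, col), index 0 = east.
_DIRS = np.array(
    [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
)


def _chebyshev(a, b) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def _valid_child_pairs() -> dict[int, list[tuple[int, int]]]:
    """For each parent direction, child-direction pairs giving a clean
    degree-3 junction: the two child first-pixels and the parent's previous
    pixel must be pairwise non-adjacent (8-connectivity)."""
    pairs: dict[int, list[tuple[int, int]]] = {}
    for d in range(8):
        prev = tuple(-_DIRS[d])
        ok = []
        for i in range(8):
            for j in range(i + 1, 8):
                pts = [tuple(_DIRS[i]), tuple(_DIRS[j])]
                if any(p == prev for p in pts):
                    continue
                if _chebyshev(pts[0], pts[1]) < 2:
                    continue
                if _chebyshev(pts[0], prev) < 2 or _chebyshev(pts[1], prev) < 2:
                    continue
                ok.append((i, j))
        pairs[d] = ok
    return pairs


_CHILD_PAIRS = _valid_child_pairs()


@dataclass
class GroupEffect:
    """Multipliers applied to the generative law for "case" subjects only.

    Defaults implement the disease signature: increased mitochondrial
    count, decreased per-mitochondrion size, reduced branching, elevated
    TMRM retention under FCCP.  ``mean_size`` defaults to the value that
    keeps the expected total mitochondrial mass per cell group-invariant
    given ``mito_count`` and ``branch_probability`` (fragmentation without
    a change in total mass); pass a float to override.
    """

    mito_count: float = 1.4
    mean_size: float | None = None  # None -> mass-conserving compensation
    branch_probability: float = 0.6
    tmrm_retention: float = 1.5
    # modest basal hyperpolarization: strongly detectable in pooled
    # single-cell analysis, marginal at the subject level
    tmrm_baseline: float = 1.03

    def validate(self) -> None:
        for name in ("mito_count", "branch_probability", "tmrm_retention"):
            if getattr(self, name) < 0:
                raise ValueError(f"group_effect.{name} must be >= 0")
        if self.mean_size is not None and self.mean_size < 0:
            raise ValueError("group_effect.mean_size must be >= 0")


@dataclass
class MorphCoupling:
    """Linear coupling of per-cell TMRM level to mitochondrial morphology
    (membrane potential rises with mitochondrial volume and endpoints and
    falls with skeleton size and node degree)."""

    volume_mean: float = 6.0
    skeleton: float = -9.0
    endpoints: float = 30.0
    node_degree: float = -60.0


@dataclass
class SimulationConfig:
    """All generative parameters for tiles and cohorts.

    Intensities are arbitrary 16-bit units; lengths/areas are pixels.
    Fixing ``seed`` makes every output bit-identical across runs.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    mosaic_layout: tuple[int, int] = (5, 5)
    cells_per_tile: int = 20
    nucleus_radius: tuple[float, float] = (15.0, 2.0)  # (mean, sd) px
    cell_radius: tuple[float, float] = (52.0, 4.0)  # (mean, sd) px
    mito_count_per_cell: tuple[float, float] = (14.0, 3.0)
    mito_segment_length: tuple[float, float] = (10.0, 3.0)  # px per segment
    branch_probability: float = 0.30
    max_segments: int = 7
    mito_width: int = 3  # rendered width in px (1 or 3)
    tmrm_base_intensity: float = 1000.0
    tmrm_fccp_retention: float = 0.35  # residual TMRM multiplier under FCCP
    noise_sd: float = 20.0
    # just below the fixed nucleus threshold (>100), as in the assay:
    # background must not cross the threshold after low-pass filtering
    background_level: float = 80.0
    hoechst_intensity: float = 3000.0
    cellmask_core_intensity: float = 800.0
    cellmask_edge_intensity: float = 200.0
    group_effect: GroupEffect = field(default_factory=GroupEffect)
    morph_coupling: MorphCoupling = field(default_factory=MorphCoupling)
    subject_sd: float = 0.05  # lognormal sd of per-subject random effects
    touching_pairs: int = 0  # pairs of deliberately touching cells
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.branch_probability <= 1.0):
            raise ValueError("branch_probability must lie in [0, 1]")
        if not (0.0 <= self.tmrm_fccp_retention <= 1.0):
            raise ValueError("tmrm_fccp_retention must lie in [0, 1]")
        if self.cells_per_tile < 0 or self.touching_pairs < 0:
            raise ValueError("counts must be >= 0")
        if self.mito_width not in (1, 3):
            raise ValueError("mito_width must be 1 or 3")
        if min(self.image_shape) < 64:
            raise ValueError("image too small")
        self.group_effect.validate()

    # -- JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        raw["group_effect"] = GroupEffect(**raw.get("group_effect", {}))
        raw["morph_coupling"] = MorphCoupling(**raw.get("morph_coupling", {}))
        for key in ("image_shape", "mosaic_layout", "nucleus_radius",
                    "cell_radius", "mito_count_per_cell",
                    "mito_segment_length"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Generative law helpers
# ---------------------------------------------------------------------------

def expected_segments_per_tree(p: float, max_segments: int) -> float:
    """Expected segment count of the capped binary Galton-Watson tree.

    Each active tip branches into two with probability ``p`` provided the
    running segment total stays within ``max_segments``; otherwise it
    terminates.  Computed by exact enumeration over the (small) state
    space of (segments, tips) reachable under the cap.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def mean_added(segments: int, tips: int) -> float:
        if tips == 0:
            return 0.0
        # each tip decides independently; process one tip at a time
        added = 0.0
        if segments + 2 <= max_segments:
            added += p * (2 + mean_added(segments + 2, tips - 1 + 2))
            added += (1 - p) * mean_added(segments, tips - 1)
        return added

    return 1.0 + mean_added(1, 1)


def _effective(config: SimulationConfig, group: str):
    """Per-group effective generative parameters (count mean, segment-length
    mean, branch probability, FCCP retention)."""
    ge = config.group_effect
    count_mu, count_sd = config.mito_count_per_cell
    len_mu, len_sd = config.mito_segment_length
    p = config.branch_probability
    retention = config.tmrm_fccp_retention
    base_mult = 1.0
    if group == "case":
        count_mu *= ge.mito_count
        base_mult = ge.tmrm_baseline
        p = min(1.0, p * ge.branch_probability)
        if ge.mean_size is None:
            # conserve expected total mitochondrial mass per cell:
            # count_mult * size_mult * E[S](p_case)/E[S](p_ctrl) == 1
            s_ratio = (expected_segments_per_tree(p, config.max_segments)
                       / expected_segments_per_tree(
                           config.branch_probability, config.max_segments))
            size_mult = 1.0 / (ge.mito_count * s_ratio)
        else:
            size_mult = ge.mean_size
        len_mu *= size_mult
        retention = min(1.0, retention * ge.tmrm_retention)
    elif group != "control":
        raise ValueError(f"unknown group {group!r}")
    return (count_mu, count_sd), (len_mu, len_sd), p, retention, base_mult


def _tmrm_level(config, rng, retention_factor, vol_mean, skel_mean,
                endp_mean, deg_mean, subject_factor=1.0):
    """Noise-free per-cell TMRM intensity from base level, condition
    retention, subject effect and the morphology coupling."""
    mc = config.morph_coupling
    level = (config.tmrm_base_intensity * retention_factor * subject_factor
             * float(np.exp(rng.normal(0.0, 0.05)))
             + mc.volume_mean * vol_mean + mc.skeleton * skel_mean
             + mc.endpoints * endp_mean + mc.node_degree * deg_mean)
    return max(level, config.background_level + 50.0)


# ---------------------------------------------------------------------------
# Rendered tree growth (pixel-exact topology)
# ---------------------------------------------------------------------------

def _grow_tree(rng, origin, allowed, forbidden, p_branch, len_mu, len_sd,
               max_segments):
    """Grow one mitochondrial tree of 1-px-wide compass segments.

    Returns (pixel list in lay order, branch_count, endpoint_count) or
    None if the tree could not reach 2 pixels.  Geometry that would break
    the clean-junction topology (every pixel's neighbours are exactly its
    predecessors/successors) is rejected, so the returned counts are exact
    topological truth for the rendered component.
    """
    r0, c0 = origin
    if not allowed[r0, c0] or forbidden[r0, c0]:
        return None
    px: set[tuple[int, int]] = {origin}
    order = [origin]

    def can_place(q, ok_neighbors):
        r, c = q
        if r < 0 or c < 0 or r >= allowed.shape[0] or c >= allowed.shape[1]:
            return False
        if not allowed[r, c] or forbidden[r, c] or q in px:
            return False
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                n = (r + dr, c + dc)
                if n != q and n in px and n not in ok_neighbors:
                    return False
        return True

    def lay(start, d, length):
        laid = []
        prev = start
        dr, dc = _DIRS[d]
        for _ in range(length):
            q = (prev[0] + dr, prev[1] + dc)
            if not can_place(q, {prev}):
                break
            px.add(q)
            order.append(q)
            laid.append(q)
            prev = q
        return laid

    branch_count = 0
    terminated = 0
    n_segments = 1
    stack = [(origin, int(rng.integers(8)), True)]  # (start, dir, is_root)
    while stack:
        start, d, fresh = stack.pop()
        length = max(2, int(round(rng.normal(len_mu, len_sd))))
        laid = lay(start, d, length if fresh else length - 1)
        end = laid[-1] if laid else start
        # a bare root (no laid pixel) must not branch: its "junction"
        # would have no predecessor and end up degree 2, not a node
        can_branch = ((laid or not fresh)
                      and n_segments + 2 <= max_segments
                      and rng.random() < p_branch)
        branched = False
        if can_branch:
            pairs = _CHILD_PAIRS[d]
            for idx in rng.permutation(len(pairs)):
                d1, d2 = pairs[idx]
                p1 = (end[0] + _DIRS[d1][0], end[1] + _DIRS[d1][1])
                if not can_place(p1, {end}):
                    continue
                px.add(p1)
                order.append(p1)
                p2 = (end[0] + _DIRS[d2][0], end[1] + _DIRS[d2][1])
                if not can_place(p2, {end}):
                    px.discard(p1)
                    order.pop()
                    continue
                px.add(p2)
                order.append(p2)
                branch_count += 1
                n_segments += 2
                stack.append((p1, d1, False))
                stack.append((p2, d2, False))
                branched = True
                break
        if not branched:
            terminated += 1
    if len(px) < 2:
        return None
    endpoints = terminated + 1  # tips plus the root pixel
    return order, branch_count, endpoints


# ---------------------------------------------------------------------------
# Tile rendering
# ---------------------------------------------------------------------------

def _radial_profile(shape, center, radius, core, edge):
    """CellMask-like intensity: bright near the nucleus, decaying to the
    cell edge."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dist = np.hypot(rr - center[0], cc - center[1])
    inside = dist <= radius
    prof = np.where(inside, edge + (core - edge) * (1.0 - dist / radius), 0.0)
    return prof, inside


def _place_cell_centers(config: SimulationConfig, rng):
    """Jittered-grid placement; returns (centers, radii, pair_partner).

    ``touching_pairs`` pairs are produced by placing two cells in one grid
    slot at a center distance slightly below the sum of radii.
    """
    h, w = config.image_shape
    r_mu, r_sd = config.cell_radius
    r_max = r_mu + 3 * r_sd
    # a touching pair spans nearly 4 radii; widen the grid when present
    pairs = config.touching_pairs > 0
    spacing = int((4.4 if pairs else 2.0) * r_max + 10)
    margin = int(r_max + 6)
    xs = np.arange(margin, w - margin, spacing)
    ys = np.arange(margin, h - margin, spacing)
    slots = [(int(y), int(x)) for y in ys for x in xs]
    n_single = config.cells_per_tile - 2 * config.touching_pairs
    n_slots_needed = n_single + config.touching_pairs
    if n_single < 0:
        raise ValueError("touching_pairs exceeds cells_per_tile / 2")
    if n_slots_needed > len(slots):
        raise OvercrowdingError(
            f"cannot place {config.cells_per_tile} cells "
            f"({n_slots_needed} slots needed, {len(slots)} available) in "
            f"a {h}x{w} tile without overlap")
    chosen = rng.permutation(len(slots))[:n_slots_needed]
    jit = spacing // 2 - int((2.0 if pairs else 1.0) * r_max) - 4
    centers, radii, partner = [], [], []
    idx = 0
    for k, si in enumerate(chosen):
        cy, cx = slots[si]
        cy += int(rng.integers(-jit, jit + 1)) if jit > 0 else 0
        cx += int(rng.integers(-jit, jit + 1)) if jit > 0 else 0
        if k < config.touching_pairs:
            # two touching cells sharing the slot, horizontal contact
            r1 = float(np.clip(rng.normal(r_mu, r_sd), r_mu - 2 * r_sd, r_max))
            r2 = float(np.clip(rng.normal(r_mu, r_sd), r_mu - 2 * r_sd, r_max))
            overlap = 0.45 * min(r1, r2)  # deep enough that the DoG
            half = (r1 + r2 - overlap) / 2.0  # cell-area mask merges
            centers.append((cy, cx - half))
            centers.append((cy, cx + half))
            radii.extend([r1, r2])
            partner.extend([idx + 1, idx])
            idx += 2
        else:
            r1 = float(np.clip(rng.normal(r_mu, r_sd), r_mu - 2 * r_sd, r_max))
            centers.append((float(cy), float(cx)))
            radii.append(r1)
            partner.append(-1)
            idx += 1
    return centers, radii, partner


def simulate_tile(config: SimulationConfig, group: str = "control",
                  condition: str = "baseline",
                  rng: np.random.Generator | None = None,
                  subject_factors: dict | None = None,
                  ) -> tuple[ImageTile, GroundTruth]:
    """Render one 3-channel tile plus pixel-exact ground truth.

    ``subject_factors`` optionally carries per-subject lognormal random
    effects (keys: count, size, tmrm) so tiles of one subject share them.
    """
    config.validate()
    if condition not in ("baseline", "FCCP"):
        raise ValueError(f"unknown condition {condition!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sf = subject_factors or {"count": 1.0, "size": 1.0, "tmrm": 1.0}

    (count_mu, count_sd), (len_mu, len_sd), p_branch, retention, base_mult \
        = _effective(config, group)
    count_mu *= sf["count"]
    len_mu *= sf["size"]
    ret_factor = base_mult * (retention if condition == "FCCP" else 1.0)

    h, w = config.image_shape
    hoechst = np.full((h, w), config.background_level, dtype=np.float64)
    tmrm = np.full((h, w), config.background_level, dtype=np.float64)
    cellmask = np.full((h, w), config.background_level, dtype=np.float64)
    nuclei_lbl = np.zeros((h, w), dtype=np.uint16)
    cell_lbl = np.zeros((h, w), dtype=np.uint16)
    mito_lbl = np.zeros((h, w), dtype=np.uint16)

    centers, radii, partner = _place_cell_centers(config, rng)
    pairs = [(i + 1, j + 1) for i, j in enumerate(partner) if 0 <= i < j]

    # cell truth labels: nearest center among overlapping disks
    rr, cc = np.mgrid[:h, :w]
    dist_best = np.full((h, w), np.inf)
    for ci, ((cy, cx), R) in enumerate(zip(centers, radii), start=1):
        dist = np.hypot(rr - cy, cc - cx)
        inside = dist <= R
        closer = inside & (dist < dist_best)
        cell_lbl[closer] = ci
        dist_best[closer] = dist[closer]
        prof = np.where(
            dist <= R,
            config.cellmask_edge_intensity
            + (config.cellmask_core_intensity
               - config.cellmask_edge_intensity) * (1.0 - dist / R),
            0.0)
        cellmask = np.maximum(cellmask, config.background_level + prof)

    from skimage.draw import ellipse as _ellipse
    from skimage.morphology import disk as _disk

    dil_r = (config.mito_width - 1) // 2
    sep = 3 + dil_r  # centerline separation keeps rendered mitos apart
    sep_foot = np.ones((2 * sep + 1, 2 * sep + 1), dtype=bool)
    mito_rows = []
    cell_rows = []
    mito_to_cell: dict[int, int] = {}
    next_mito = 1
    n_rad_mu, n_rad_sd = config.nucleus_radius

    for ci, ((cy, cx), R) in enumerate(zip(centers, radii), start=1):
        # nucleus: filled ellipse at the cell center
        a = max(8.0, rng.normal(n_rad_mu, n_rad_sd))
        b = a * rng.uniform(0.8, 1.0)
        theta = rng.uniform(0, np.pi)
        err, ecc = _ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        nuclei_lbl[err, ecc] = ci
        hoechst[err, ecc] = config.hoechst_intensity * rng.uniform(0.9, 1.1)

        # work in a local window around the cell for speed
        pad = int(R) + sep + 2
        rs = slice(max(0, int(cy) - pad), min(h, int(cy) + pad))
        cs = slice(max(0, int(cx) - pad), min(w, int(cx) + pad))
        lrr, lcc = np.mgrid[rs, cs]
        dist = np.hypot(lrr - cy, lcc - cx)
        # mitochondria zone: annulus between nucleus and inner cell area
        own = ndi.binary_erosion(cell_lbl[rs, cs] == ci, iterations=2,
                                 border_value=0)
        allowed = (dist > a + 4) & (dist < 0.80 * R) & own
        forbidden = np.zeros(allowed.shape, dtype=bool)
        lh, lw = allowed.shape

        n_target = max(0, int(round(rng.normal(count_mu, count_sd))))
        placed = 0
        attempts = 0
        cell_mitos = []
        while placed < n_target and attempts < n_target * 30:
            attempts += 1
            free = np.nonzero(allowed & ~forbidden)
            if len(free[0]) == 0:
                break
            k = int(rng.integers(len(free[0])))
            origin = (int(free[0][k]), int(free[1][k]))
            res = _grow_tree(rng, origin, allowed, forbidden, p_branch,
                             len_mu, len_sd, config.max_segments)
            if res is None:
                continue
            pts = np.array(res[0])
            center = np.zeros((lh, lw), dtype=bool)
            center[pts[:, 0], pts[:, 1]] = True
            comp = (ndi.binary_dilation(center, structure=_disk(dil_r))
                    if dil_r > 0 else center)
            forbidden |= ndi.binary_dilation(comp, structure=sep_foot)
            area = int(comp.sum())
            if area < 6:
                continue  # would be removed by the mito size filter
            cell_mitos.append((res[1], res[2], len(pts), area, comp, center))
            placed += 1

        skels = [m[2] for m in cell_mitos]
        vols = [m[3] for m in cell_mitos]
        endps = [m[1] for m in cell_mitos]
        degs = [3.0 if m[0] > 0 else 0.0 for m in cell_mitos]
        level = _tmrm_level(
            config, rng, ret_factor,
            float(np.mean(vols)) if vols else 0.0,
            float(np.mean(skels)) if skels else 0.0,
            float(np.mean(endps)) if endps else 0.0,
            float(np.mean(degs)) if degs else 0.0,
            subject_factor=sf["tmrm"])
        cell_mito_union = np.zeros(allowed.shape, dtype=bool)
        for branches, endpoints, skel, area, comp, center in cell_mitos:
            mito_lbl[rs, cs][comp] = next_mito
            mito_to_cell[next_mito] = ci
            # bright centerline with a dimmer flank: keeps the DoG
            # response sharp so the mask edge is well defined
            flank = comp & ~center
            tmrm[rs, cs][center] = level
            tmrm[rs, cs][flank] = (config.background_level
                                   + 0.55 * (level - config.background_level))
            cell_mito_union |= comp
            mito_rows.append(dict(cell_id=ci, mito_id=next_mito,
                                  area_px=area, skeleton_px=skel,
                                  branch_count=branches,
                                  endpoint_count=endpoints,
                                  width_px=config.mito_width))
            next_mito += 1
        mean_tmrm = (float(tmrm[rs, cs][cell_mito_union].mean())
                     if cell_mito_union.any() else float("nan"))
        cell_rows.append(dict(cell_id=ci, mito_count=placed,
                              total_mito_area_px=int(np.sum(vols)),
                              mean_tmrm=mean_tmrm))

    if config.noise_sd > 0:
        hoechst = hoechst + rng.normal(0, config.noise_sd, (h, w))
        tmrm = tmrm + rng.normal(0, config.noise_sd, (h, w))
        cellmask = cellmask + rng.normal(0, config.noise_sd, (h, w))

    def to_u16(arr):
        return np.clip(np.rint(arr), 0, 65535).astype(np.uint16)

    tile = ImageTile(hoechst=to_u16(hoechst), tmrm=to_u16(tmrm),
                     cellmask=to_u16(cellmask), condition=condition)
    truth = GroundTruth(
        nuclei_mask=LabelMask(nuclei_lbl, "nuclei"),
        cell_mask=LabelMask(cell_lbl, "cell"),
        mito_mask=LabelMask(mito_lbl, "mito"),
        per_mito_truth=pd.DataFrame(
            mito_rows, columns=["cell_id", "mito_id", "area_px",
                                "skeleton_px", "branch_count",
                                "endpoint_count", "width_px"]),
        per_cell_truth=pd.DataFrame(
            cell_rows, columns=["cell_id", "mito_count",
                                "total_mito_area_px", "mean_tmrm"]),
        mito_to_cell=mito_to_cell,
        touching_pairs=pairs,
    )
    return tile, truth


def evaluate_pair_splitting(truth: GroundTruth, cells: LabelMask,
                            nuclei: LabelMask) -> tuple[int, int]:
    """Score touching-pair recovery against ground truth.

    A seeded pair counts as successfully split when its two truth cells
    map (by majority pixel overlap) onto two *distinct* detected cell
    labels, each containing exactly one nucleus.  Returns
    ``(n_success, n_pairs)``.
    """
    n_ok = 0
    for c1, c2 in truth.touching_pairs:
        labs = []
        good = True
        for cid in (c1, c2):
            region = cells.labels[truth.cell_mask.labels == cid]
            region = region[region > 0]
            if len(region) == 0:
                good = False
                break
            labs.append(int(np.bincount(region).argmax()))
        if not good or labs[0] == labs[1]:
            continue
        for lab in labs:
            inside = cells.labels == lab
            nuc = np.unique(nuclei.labels[inside])
            nuc = nuc[nuc > 0]
            counts = [int(np.sum(nuclei.labels[inside] == nid)
                          > (nuclei.labels == nid).sum() / 2)
                      for nid in nuc]
            if sum(counts) != 1:
                good = False
                break
        n_ok += bool(good)
    return n_ok, len(truth.touching_pairs)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _subject_metadata(rng, group: str):
    """Age / gender / doubling-time draws emulating the study cohort
    (cases: older-male-skewed gender split, slower growth)."""
    age = float(np.clip(rng.normal(66.0, 6.0), 40, 90))
    p_male = 25 / 41 if group == "case" else 4 / 21
    gender = "M" if rng.random() < p_male else "F"
    if group == "case":
        doubling = float(np.exp(rng.normal(np.log(16.0), 0.5)))
    else:
        doubling = float(np.exp(rng.normal(np.log(4.9), 0.5)))
    return age, gender, doubling


def _subject_factors(rng, sd):
    return {k: float(np.exp(rng.normal(0.0, sd)))
            for k in ("count", "size", "tmrm")}


def simulate_cohort(config: SimulationConfig, n_case: int, n_control: int,
                    tiles_per_subject: int = 1,
                    conditions: tuple[str, ...] = ("baseline", "FCCP"),
                    outdir: str | Path | None = None):
    """Simulate a rendered two-group cohort.

    Returns (metadata DataFrame, dict mapping (subject_id, condition,
    tile_index) -> (ImageTile, GroundTruth)).  With ``outdir`` set, writes
    multi-page TIFF tiles, 16-bit label-mask TIFFs, truth/metadata CSVs and
    the config JSON.
    """
    config.validate()
    if n_case < 1 or n_control < 1:
        raise ValueError("n_case and n_control must be >= 1")
    if tiles_per_subject < 1:
        raise ValueError("tiles_per_subject must be >= 1")
    root = np.random.SeedSequence(config.seed)
    meta_rows = []
    tiles = {}
    subjects = ([("case", i) for i in range(n_case)]
                + [("control", i) for i in range(n_control)])
    seeds = root.spawn(len(subjects))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(config.to_json())
    for (group, i), ss in zip(subjects, seeds):
        rng = np.random.default_rng(ss)
        sid = f"{'IPD' if group == 'case' else 'CTRL'}{i + 1:03d}"
        age, gender, doubling = _subject_metadata(rng, group)
        sf = _subject_factors(rng, config.subject_sd)
        for condition in conditions:
            for t in range(tiles_per_subject):
                tile, truth = simulate_tile(config, group, condition,
                                            rng=rng, subject_factors=sf)
                tile.subject_id = sid
                tile.tile_id = t
                tiles[(sid, condition, t)] = (tile, truth)
                if out is not None:
                    _write_tile(out, sid, condition, t, tile, truth)
            meta_rows.append(dict(subject_id=sid, group=group,
                                  condition=condition, age=age,
                                  gender=gender, doubling_time=doubling,
                                  n_tiles=tiles_per_subject))
    metadata = pd.DataFrame(meta_rows)
    if out is not None:
        metadata.to_csv(out / "metadata.csv", index=False)
    return metadata, tiles


def _write_tile(out: Path, sid, condition, t, tile: ImageTile,
                truth: GroundTruth) -> None:
    import tifffile

    stem = f"{sid}_{condition}_t{t:02d}"
    tifffile.imwrite(out / f"{stem}.tif", tile.channels,
                     photometric="minisblack")
    for kind, mask in (("nuclei", truth.nuclei_mask),
                       ("cell", truth.cell_mask),
                       ("mito", truth.mito_mask)):
        tifffile.imwrite(out / f"{stem}_{kind}_truth.tif",
                         mask.labels.astype(np.uint16))
    truth.per_mito_truth.to_csv(out / f"{stem}_per_mito_truth.csv",
                                index=False)
    truth.per_cell_truth.to_csv(out / f"{stem}_per_cell_truth.csv",
                                index=False)


# ---------------------------------------------------------------------------
# Structure-level cohort sampler (no rasterization)
# ---------------------------------------------------------------------------

_W3_AREA_FACTOR = 2.6  # mean rendered area per skeleton pixel at width 3


def _sample_trees(rng, n, p_branch, max_segments):
    """Vectorized capped Galton-Watson branching: returns (segments,
    branch events) for ``n`` trees."""
    segments = np.ones(n, dtype=np.int64)
    branches = np.zeros(n, dtype=np.int64)
    tips = np.ones(n, dtype=np.int64)
    while tips.sum() > 0:
        room = np.maximum(0, (max_segments - segments) // 2)
        br = rng.binomial(tips, p_branch)
        br = np.minimum(br, room)
        branches += br
        segments += 2 * br
        tips = 2 * br
    return segments, branches


def sample_cell_features(config: SimulationConfig, n_cells: int, group: str,
                         condition: str, rng: np.random.Generator,
                         subject_factors: dict | None = None) -> pd.DataFrame:
    """Draw per-cell feature records directly from the generative law.

    Returns one row per cell with the standard per-cell feature columns
    (MitoCount, MitoVolumeMean, ..., TMRM_MitoMask, TMRM_Cell,
    AspectRatioCell, FormFactorCell).  Statistically equivalent to
    rendering tiles and measuring them, but fast enough for cohort-scale
    simulation experiments.
    """
    config.validate()
    sf = subject_factors or {"count": 1.0, "size": 1.0, "tmrm": 1.0}
    (count_mu, count_sd), (len_mu, len_sd), p_branch, retention, base_mult \
        = _effective(config, group)
    count_mu *= sf["count"]
    len_mu *= sf["size"]
    ret_factor = base_mult * (retention if condition == "FCCP" else 1.0)

    counts = np.maximum(
        1, np.rint(rng.normal(count_mu, count_sd, n_cells))).astype(int)
    total = int(counts.sum())
    segments, branches = _sample_trees(rng, total, p_branch,
                                       config.max_segments)
    skel = np.maximum(
        2 * segments,
        np.rint(rng.normal(segments * len_mu,
                           np.sqrt(segments) * len_sd))).astype(np.int64)
    width3 = rng.random(total) < 0.5
    vol = np.rint(skel * np.where(width3, _W3_AREA_FACTOR, 1.0)).astype(int)
    vol = np.maximum(vol, 6)
    endpoints = branches + 2
    nodes = branches
    degree = np.where(branches > 0, 3.0, 0.0)
    bodies_px = np.where(width3, skel, 0)
    perim = vol - bodies_px
    bodies = np.where(width3, 1, 0)
    form = perim.astype(float) ** 2 / (4 * np.pi * vol)
    aspect = np.exp(rng.normal(1.0, 0.25, total))

    cell_idx = np.repeat(np.arange(n_cells), counts)

    def cmean(x):
        return np.bincount(cell_idx, weights=x, minlength=n_cells) / counts

    vol_total = np.bincount(cell_idx, weights=vol, minlength=n_cells)
    rec = pd.DataFrame({
        "MitoCount": counts,
        "MitoVolumeTotal": vol_total,
        "MitoVolumeMean": vol_total / counts,
        "MitoPerimeter": cmean(perim),
        "MitoFormFactor": cmean(form),
        "MitoErosionBodies": cmean(bodies),
        "MitoSkel": cmean(skel),
        "MitoNodes": cmean(nodes),
        "MitoEndpoints": cmean(endpoints),
        "MitoNodeDegree": cmean(degree),
        "MitoAspectRatio": cmean(aspect),
    })
    mc = config.morph_coupling
    base = (config.tmrm_base_intensity * ret_factor * sf["tmrm"]
            * np.exp(rng.normal(0.0, 0.05, n_cells)))
    level = (base + mc.volume_mean * rec["MitoVolumeMean"]
             + mc.skeleton * rec["MitoSkel"]
             + mc.endpoints * rec["MitoEndpoints"]
             + mc.node_degree * rec["MitoNodeDegree"]
             + rng.normal(0.0, 30.0, n_cells))
    level = np.maximum(level, config.background_level)
    cell_r = np.clip(rng.normal(*config.cell_radius, n_cells), 30, None)
    cell_area = np.pi * cell_r ** 2
    rec["TMRM_MitoMask"] = level
    rec["TMRM_Cell"] = (config.background_level
                        + (level - config.background_level)
                        * rec["MitoVolumeTotal"] / cell_area)
    rec["AspectRatioCell"] = np.exp(rng.normal(np.log(1.8), 0.2, n_cells))
    rec["FormFactorCell"] = np.exp(rng.normal(np.log(2.5), 0.2, n_cells))
    rec["cell_area"] = cell_area
    rec.insert(0, "cell_id", np.arange(1, n_cells + 1))
    return rec


def simulate_cohort_features(config: SimulationConfig, n_case: int,
                             n_control: int, cells_per_subject: int = 200,
                             conditions: tuple[str, ...] = ("baseline",
                                                            "FCCP"),
                             seed: int | None = None) -> pd.DataFrame:
    """Structure-level cohort: per-cell feature records for every subject
    and condition, with subject metadata columns attached.

    The "case" group carries ``config.group_effect``.  Returns a long
    DataFrame with columns subject_id, group, condition, age, gender,
    doubling_time plus the per-cell feature columns.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("n_case and n_control must be >= 1")
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    subjects = ([("case", i) for i in range(n_case)]
                + [("control", i) for i in range(n_control)])
    frames = []
    for (group, i), ss in zip(subjects, root.spawn(len(subjects))):
        rng = np.random.default_rng(ss)
        sid = f"{'IPD' if group == 'case' else 'CTRL'}{i + 1:03d}"
        age, gender, doubling = _subject_metadata(rng, group)
        sf = _subject_factors(rng, config.subject_sd)
        for condition in conditions:
            rec = sample_cell_features(config, cells_per_subject, group,
                                       condition, rng, subject_factors=sf)
            rec.insert(0, "subject_id", sid)
            rec.insert(1, "group", group)
            rec.insert(2, "condition", condition)
            rec["age"] = age
            rec["gender"] = gender
            rec["doubling_time"] = doubling
            frames.append(rec)
    return pd.concat(frames, ignore_index=True)
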