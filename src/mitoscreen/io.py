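"""File I/O and pipeline configuration.

Interchange formats: multi-page 16-bit TIFF for images and label masks,
CSV (UTF-8, header row) for feature tables and metadata, JSON for
configuration and reports.  Every run writes a manifest (config hash,
seed, package version) next to its outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import CHANNELS, ImageTile, LabelMask

__all__ = ["PipelineConfig", "read_tile", "write_tile", "read_label_mask",
           "write_label_mask", "write_manifest"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips losslessly through JSON.

    Segmentation defaults carry the assay's fixed values: Gaussian
    low-pass 10x10 / sigma 2, nucleus threshold 100, size filters
    500/200/6 px, erosion radii 12 (cell splitting) and 1 (perimeter).
    """

    # channel mapping: page index of each channel in input TIFFs
    channel_order: tuple[str, str, str] = CHANNELS
    # nuclei
    nucleus_gaussian_size: int = 10
    nucleus_gaussian_sd: float = 2.0
    nucleus_threshold: float = 100.0
    nucleus_min_size: int = 500
    # cell area
    cell_dog_sigma_narrow: float = 4.0
    cell_dog_sigma_wide: float = 40.0
    cell_dog_threshold: float = 60.0
    cell_min_size: int = 200
    # splitting
    split_threshold: float = 300.0
    split_erosion_radius: int = 12
    split_max_iterations: int = 20
    # mitochondria
    mito_dog_sigma_narrow: float = 1.0
    mito_dog_sigma_wide: float = 4.0
    mito_dog_threshold: float | str = "auto"  # intensity or per-tile "auto"
    mito_min_size: int = 6
    # morphometrics / aggregation
    body_erosion_radius: int = 1
    min_cells_per_subject: int = 175
    # statistics
    alpha: float = 0.05
    n_permutations: int = 100_000
    # classification
    svm_C: float = 1.0
    svm_kernel: str = "linear"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        raw["channel_order"] = tuple(raw.get("channel_order", CHANNELS))
        return cls(**raw)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def write_tile(path: str | Path, tile: ImageTile) -> None:
    """Write a 3-page 16-bit TIFF in (hoechst, tmrm, cellmask) order."""
    tifffile.imwrite(path, tile.channels.astype(np.uint16),
                     photometric="minisblack")


def read_tile(path: str | Path,
              channel_order: tuple[str, str, str] = CHANNELS,
              **meta) -> ImageTile:
    """Read a multi-page TIFF as an ImageTile.

    ``channel_order`` maps page index to channel role, allowing inputs
    with a different channel arrangement.
    """
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - error text only
        raise ValueError(f"could not read TIFF {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        raise ValueError(f"{path} has one page; 3 channels required")
    if pages.shape[0] != 3:
        raise ValueError(f"{path}: expected 3 pages, got {pages.shape[0]}")
    by_role = {role: pages[i] for i, role in enumerate(channel_order)}
    return ImageTile(hoechst=by_role["hoechst"], tmrm=by_role["tmrm"],
                     cellmask=by_role["cellmask"], **meta)


def write_label_mask(path: str | Path, mask: LabelMask) -> None:
    if mask.labels.max() > 65535:
        raise ValueError("more than 65535 labels; cannot store as uint16")
    tifffile.imwrite(path, mask.labels.astype(np.uint16))


def read_label_mask(path: str | Path, kind: str = "mito") -> LabelMask:
    return LabelMask(tifffile.imread(path).astype(np.int32), kind)


def write_manifest(outdir: str | Path, config: PipelineConfig,
                   extra: dict | None = None) -> Path:
    """Write run manifest (config + hash + seed + version) as JSON."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mitoscreen_version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV output (stable column order, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
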