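"""Readers, writers and configuration for batch runs.

Cell images travel as multi-page TIFF stacks (one page per channel, in
the canonical order brightfield, DNA, BV421/ɣH2AX, AF488/pH3, PE/p53)
with a ``channels.json`` sidecar documenting the order; tabular outputs
are plain CSV with JSON schema sidecars; configuration is a single YAML
file with one section per pipeline stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .analysis import ClassificationThresholds
from .core import CHANNELS, CellImage
from .segmentation import SegmentationConfig, SpotParams
from .synthgen import SyntheticExperiment

log = logging.getLogger("ismn")

#: default channel_map: role -> page index in the TIFF stack
DEFAULT_CHANNEL_MAP = {name: i for i, name in enumerate(CHANNELS)}


# ---------------------------------------------------------------------------
# cell stacks
# ---------------------------------------------------------------------------


def write_cell_stack(cell: CellImage, path: str | Path) -> None:
    """Write one cell as a multi-page float32 TIFF."""
    tifffile.imwrite(str(path), cell.stack().astype(np.float32))


def read_cell_stack(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    pixel_size_um: float = 0.5,
    cell_id: str = "",
    sample_id: str = "",
) -> CellImage:
    """Read a cell stack, selecting the five channel roles.

    ``channel_map`` maps each role name to its page index, so stacks
    with extra channels (a 12-channel instrument export, say) can be
    ingested.  A missing or out-of-range role raises an error naming
    the role.
    """
    channel_map = dict(channel_map or DEFAULT_CHANNEL_MAP)
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    kwargs = {}
    for role in CHANNELS:
        if role not in channel_map:
            raise ValueError(f"channel_map is missing the {role!r} role")
        idx = channel_map[role]
        if not 0 <= idx < pages.shape[0]:
            raise ValueError(
                f"channel_map points role {role!r} at page {idx}, "
                f"but the stack has {pages.shape[0]} pages"
            )
        kwargs[role] = np.asarray(pages[idx], dtype=np.float64)
    return CellImage(
        pixel_size_um=pixel_size_um,
        cell_id=cell_id or Path(path).stem,
        sample_id=sample_id,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# experiments on disk
# ---------------------------------------------------------------------------


def write_experiment(exp: SyntheticExperiment, outdir: str | Path) -> Path:
    """Write a synthetic experiment: per-sample TIFF directories, a
    sample manifest, per-cell ground truth and the channel sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "channels.json").write_text(
        json.dumps({"channel_order": list(CHANNELS)}, indent=2)
    )
    manifest = exp.manifest
    manifest["image_dir"] = [s.sample_id for s in exp.samples]
    centers = []
    for sample in exp.samples:
        sdir = outdir / sample.sample_id
        sdir.mkdir(exist_ok=True)
        for cell, tr in sample.cells():
            write_cell_stack(cell, sdir / f"{cell.cell_id}.tiff")
            centers.append(
                ";".join(f"{r:.2f}:{c:.2f}" for r, c in tr.mn_centers_px)
            )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    truth = exp.truth()  # iterates samples/cells in the same order
    truth["mn_centers"] = centers
    truth.to_csv(outdir / "truth.csv", index=False)
    return outdir


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "dose", "replicate", "is_vehicle", "is_stained"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df


def iter_sample_cells(
    directory: str | Path,
    sample_id: str,
    channel_map: Mapping[str, int] | None = None,
    pixel_size_um: float = 0.5,
):
    """Yield CellImages for every TIFF in a sample directory."""
    sdir = Path(directory)
    for path in sorted(sdir.glob("*.tif*")):
        yield read_cell_stack(
            path,
            channel_map,
            pixel_size_um=pixel_size_um,
            cell_id=path.stem,
            sample_id=sample_id,
        )


# ---------------------------------------------------------------------------
# schemas
# ---------------------------------------------------------------------------

FEATURE_SCHEMA = {
    "cell_id": "unique cell identifier",
    "sample_id": "acquisition/sample identifier",
    "bf_aspect_ratio": "minor/major axis ratio of the brightfield cell mask",
    "bf_area_um2": "brightfield cell area, um^2",
    "gradient_rms": "brightfield gradient RMS (focus measure)",
    "cytoplasm_contrast": "normalized brightfield variation over the inner cytoplasm",
    "nuclear_area_um2": "segmented nucleus area, um^2",
    "dna_intensity": "integrated DNA intensity over nucleus + MN masks",
    "dna_gradient_rms": "DNA-channel gradient RMS over the nucleus",
    "h2ax_whole": "integrated BV421 intensity over the cell",
    "h2ax_nuclear": "integrated BV421 intensity over the nucleus",
    "ph3_whole": "integrated AF488 intensity over the cell",
    "ph3_nuclear": "integrated AF488 intensity over the nucleus",
    "p53_whole": "integrated PE intensity over the cell",
    "p53_nuclear": "integrated PE intensity over the nucleus",
    "similarity_h2ax": "Fisher-z Pearson similarity of BV421 vs DNA",
    "similarity_ph3": "Fisher-z Pearson similarity of AF488 vs DNA",
    "similarity_p53": "Fisher-z Pearson similarity of PE vs DNA",
    "mn_count": "number of CFM spot-count components",
    "n_nuclei": "number of parent-nucleus components",
    "mn_centroids": "semicolon-separated row:col centroids of CFM components",
    "flag": "non-empty when segmentation failed for this cell",
}


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    features.to_csv(path, index=False)
    schema = {c: FEATURE_SCHEMA.get(c, "") for c in features.columns}
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

CONFIG_SCHEMA_ID = "ismn-config/1"


def default_config() -> dict:
    return {
        "schema": CONFIG_SCHEMA_ID,
        "segmentation": dataclasses.asdict(SegmentationConfig()),
        "gating": {
            "g2_shift": 1.9,
            "dna_content_min": 1.0e5,
            "similarity_min": 0.0,
            "refit_cycle_per_sample": True,
            "min_cells_cycle": 500,
        },
        "analysis": dataclasses.asdict(ClassificationThresholds()),
        "qc_minimums": {"min_cells_biomarkers": 13000, "min_cells_mn": 10000},
    }


def load_config(path: str | Path | None) -> dict:
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def segmentation_config_from_dict(d: Mapping) -> SegmentationConfig:
    d = dict(d)
    d.pop("iterations", None)  # derived from `spot` unless set programmatically
    spot = d.pop("spot", None)
    kwargs = dict(d)
    if spot is not None:
        spot = {k: tuple(v) if isinstance(v, list) else v for k, v in spot.items()}
        kwargs["spot"] = SpotParams(**spot)
    return SegmentationConfig(**kwargs)
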