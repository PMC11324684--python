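"""Batch driver chaining simulate -> segment -> features -> gate -> analyze.

Used both by the CLI and by in-memory runs on synthetic experiments.
Samples are processed one at a time so a full dose-response study never
holds more than one sample's images in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .analysis import (
    ClassificationThresholds,
    DoseGroupResult,
    MoAProfile,
    results_frame,
    summarize_experiment,
)
from .core import CellImage
from .evaluation import MaskBenchResult, benchmark_mask, records_from_tables
from .features import extract_features, features_frame
from .gating import GateSet, classify_table, fit_gates
from .segmentation import SegmentationConfig
from .synthgen import SyntheticExperiment

log = logging.getLogger("ismn")


def extract_sample_features(
    cells: Iterable[CellImage | tuple], cfg: SegmentationConfig | None = None
) -> pd.DataFrame:
    """Feature rows for one sample's cells (accepts bare images or
    (image, ground-truth) pairs)."""
    feats = []
    for item in cells:
        cell = item[0] if isinstance(item, tuple) else item
        feats.append(extract_features(cell, cfg=cfg))
    return features_frame(feats)


@dataclass
class BatchResult:
    features: pd.DataFrame
    classified: pd.DataFrame
    gates: GateSet
    results: list[DoseGroupResult]
    profile: MoAProfile
    bench: MaskBenchResult | None = None

    @property
    def results_table(self) -> pd.DataFrame:
        return results_frame(self.results)


def run_experiment(
    experiment: SyntheticExperiment,
    seg_cfg: SegmentationConfig | None = None,
    thresholds: ClassificationThresholds | None = None,
    min_cells_biomarkers: int = 0,
    min_cells_mn: int = 0,
    benchmark: bool = False,
    min_cells_cycle: int = 500,
) -> BatchResult:
    """Run the full scoring pipeline on an in-memory synthetic study.

    ``min_cells_*`` default to 0 (no warnings) because desk-scale
    simulations are far below the instrument-scale scored-cell
    minimums.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    frames = []
    truth_centers: list[dict] = []
    for sample in experiment.samples:
        feats = []
        for cell, truth in sample.cells():
            feats.append(extract_features(cell, cfg=seg_cfg))
            if benchmark:
                truth_centers.append(
                    {
                        "cell_id": cell.cell_id,
                        "mn_centers": ";".join(
                            f"{r:.2f}:{c:.2f}" for r, c in truth.mn_centers_px
                        ),
                    }
                )
        frame = features_frame(feats)
        log.info("sample %s: %d cells featurized", sample.sample_id, len(frame))
        frames.append(frame)
    features = pd.concat(frames, ignore_index=True)

    manifest = experiment.manifest
    gates = fit_gates(features, manifest, min_cells_cycle=min_cells_cycle)
    classified = classify_table(features, gates)
    results, profile = summarize_experiment(
        classified,
        manifest,
        thresholds=thresholds,
        min_cells_biomarkers=min_cells_biomarkers,
        min_cells_mn=min_cells_mn,
    )
    bench = None
    if benchmark:
        truth_df = pd.DataFrame(truth_centers)
        stained_ids = set(manifest.loc[manifest.is_stained, "sample_id"])
        feat_sub = classified[
            classified.sample_id.isin(stained_ids) & classified.mononucleated
        ]
        records = records_from_tables(feat_sub, truth_df)
        bench = benchmark_mask(records)
    return BatchResult(
        features=features,
        classified=classified,
        gates=gates,
        results=results,
        profile=profile,
        bench=bench,
    )
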