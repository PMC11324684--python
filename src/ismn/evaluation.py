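"""Micronucleus-mask performance metrics against known truth.

Two printed-formula metrics quantify mask quality: %Accuracy (of the
cells the mask flags as MN-containing, the percentage that truly are)
and %Miss Rate, whose published formula — detected true MN over
manually identified true MN, x100 — actually computes a detection
proportion; both that as-printed value and its complement (the share of
true MN the mask failed to find) are therefore reported under explicit
labels.  Benchmarking runs on the "DNA Focus" subpopulation: cells
whose DNA-channel gradient RMS lies above the population median, i.e.
the crisply stained nuclei that give the mask its best chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: a mask component counts as a true MN when its centroid lies within
#: this many pixels of a ground-truth MN centre
MATCH_TOLERANCE_PX = 2.0


def pct_accuracy(true_mn_by_mask: int, cells_flagged_by_mask: int) -> float:
    """100 x true MN-containing cells / cells flagged by the mask.

    Undefined (NaN) when no cell was flagged.
    """
    if cells_flagged_by_mask < 0 or true_mn_by_mask < 0:
        raise ValueError("counts must be non-negative")
    if true_mn_by_mask > cells_flagged_by_mask:
        raise ValueError("true positives cannot exceed flagged cells")
    if cells_flagged_by_mask == 0:
        return float("nan")
    return 100.0 * true_mn_by_mask / cells_flagged_by_mask


def pct_miss_rate(true_mn_by_mask: int, true_mn_manual: int) -> tuple[float, float]:
    """(as_printed, complement) of the published miss-rate formula.

    ``as_printed`` = 100 x mask-detected true MN / manually identified
    true MN (a detection proportion); ``complement`` = 100 - as_printed,
    the fraction of true MN the mask missed.  The two always sum to 100.
    """
    if true_mn_manual <= 0:
        raise ValueError("manual MN total must be positive")
    if true_mn_by_mask < 0:
        raise ValueError("counts must be non-negative")
    as_printed = 100.0 * true_mn_by_mask / true_mn_manual
    return as_printed, 100.0 - as_printed


@dataclass
class CellBenchRecord:
    """Per-cell inputs for mask benchmarking."""

    cell_id: str
    dna_gradient_rms: float
    predicted_centers: Sequence[tuple[float, float]]
    true_centers: Sequence[tuple[float, float]]


@dataclass
class MaskBenchResult:
    n_cells_assessed: int
    flagged_cells: int
    true_positives: int
    manual_mn_total: int
    matched_mn_total: int
    pct_accuracy: float
    pct_miss_as_printed: float
    pct_miss_complement: float
    notes: list[str] = field(default_factory=list)


def focus_subpopulation(features: pd.DataFrame, column: str = "dna_gradient_rms") -> pd.DataFrame:
    """Cells with DNA gradient RMS strictly above the population median.

    With an all-equal column the strict rule selects nothing; the
    caller receives the empty frame (flagged degenerate).
    """
    vals = features[column].to_numpy(dtype=float)
    med = np.nanmedian(vals)
    return features[vals > med]


def _match_centers(
    predicted: Sequence[tuple[float, float]],
    truth: Sequence[tuple[float, float]],
    tol: float = MATCH_TOLERANCE_PX,
) -> int:
    """Greedy one-to-one matching of predicted to true centres."""
    remaining = list(truth)
    matched = 0
    for pr, pc in predicted:
        best, best_d = None, tol
        for i, (tr, tc) in enumerate(remaining):
            d = math.hypot(pr - tr, pc - tc)
            if d <= best_d:
                best, best_d = i, d
        if best is not None:
            remaining.pop(best)
            matched += 1
    return matched


def benchmark_mask(
    records: Sequence[CellBenchRecord],
    apply_focus_gate: bool = True,
) -> MaskBenchResult:
    """Score the mask's MN calls against truth (synthetic ground truth
    or a manual-call table converted to centres).

    A flagged cell counts as a true positive when at least one of its
    mask components matches a true MN centre within
    ``MATCH_TOLERANCE_PX``; the miss rate is computed event-wise over
    all true MN in the assessed subpopulation.
    """
    notes: list[str] = []
    if apply_focus_gate:
        grms = np.array([r.dna_gradient_rms for r in records], dtype=float)
        med = np.nanmedian(grms) if len(records) else float("nan")
        subset = [r for r, v in zip(records, grms) if v > med]
        if not subset:
            notes.append("degenerate focus distribution; gate disabled")
            subset = list(records)
    else:
        subset = list(records)

    flagged = 0
    true_pos = 0
    manual_total = 0
    matched_total = 0
    for r in subset:
        manual_total += len(r.true_centers)
        matched = _match_centers(r.predicted_centers, r.true_centers)
        matched_total += matched
        if len(r.predicted_centers) > 0:
            flagged += 1
            if matched > 0:
                true_pos += 1
    acc = pct_accuracy(true_pos, flagged)
    if manual_total > 0:
        as_printed, complement = pct_miss_rate(matched_total, manual_total)
    else:
        as_printed, complement = float("nan"), float("nan")
        notes.append("no true MN in assessed population")
    return MaskBenchResult(
        n_cells_assessed=len(subset),
        flagged_cells=flagged,
        true_positives=true_pos,
        manual_mn_total=manual_total,
        matched_mn_total=matched_total,
        pct_accuracy=acc,
        pct_miss_as_printed=as_printed,
        pct_miss_complement=complement,
        notes=notes,
    )


def records_from_tables(
    features: pd.DataFrame, truth: pd.DataFrame
) -> list[CellBenchRecord]:
    """Build benchmark records from a features table (with
    ``mn_centroids`` encoded as ``r:c;r:c``) and a truth table with
    matching ``cell_id`` and ``mn_centers`` columns."""

    def parse(text) -> list[tuple[float, float]]:
        if not isinstance(text, str) or not text:
            return []
        out = []
        for part in text.split(";"):
            r, c = part.split(":")
            out.append((float(r), float(c)))
        return out

    truth_map = {
        row.cell_id: parse(getattr(row, "mn_centers", ""))
        for row in truth.itertuples(index=False)
    }
    records = []
    for row in features.itertuples(index=False):
        records.append(
            CellBenchRecord(
                cell_id=row.cell_id,
                dna_gradient_rms=float(row.dna_gradient_rms),
                predicted_centers=parse(row.mn_centroids)
                if isinstance(row.mn_centroids, str)
                else list(row.mn_centroids),
                true_centers=truth_map.get(row.cell_id, []),
            )
        )
    return records
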