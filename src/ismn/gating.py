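"""Template gating: QC, health, DNA content, cell cycle and biomarkers.

The gating chain reproduces a template-based imaging-flow-cytometry
analysis: focused/single cells are kept by aspect-ratio, brightfield
area and gradient-RMS criteria; healthy cells by high nuclear area and
low cytoplasmic contrast; DNA-positive cells by an integrated-DNA floor.
Cell-cycle gates are placed around the dominant (G1) DNA-intensity mode
and its ~1.8-2x (G2/M) image, guided by the pH3 mitotic marker.
Biomarker gates are built per channel from unstained samples: an
"unstained peak" (UP) interval, the UP shifted tenfold, a stained-peak
(SP) interval from stained samples, and their coordinate average (the
"combined average" gate).  Final per-cell populations additionally
require nuclear localization via the similarity-of-morphology score.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BIOMARKERS

Interval = tuple[float, float]


# ---------------------------------------------------------------------------
# density helpers
# ---------------------------------------------------------------------------


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    sd = float(np.std(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])) * -1)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(sd, 1e-12)
    return 0.9 * scale * x.size ** (-0.2)


def _kde_on_grid(x: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    z = (grid[:, None] - x[None, :]) / bw
    return np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))


def _kde_mode_interval(
    x: np.ndarray, bw: float | None = None, n_grid: int = 512
) -> tuple[float, Interval]:
    """Dominant KDE mode and its half-maximum interval.

    Returns ``(mode, (lo, hi))`` where lo/hi are the nearest points
    around the mode at which the density falls to half its modal value.
    """
    x = np.asarray(x, dtype=float)
    bw = bw if bw is not None else _silverman_bandwidth(x)
    lo, hi = x.min() - 3 * bw, x.max() + 3 * bw
    grid = np.linspace(lo, hi, n_grid)
    dens = _kde_on_grid(x, grid, bw)
    imode = int(np.argmax(dens))
    if imode == 0 or imode == n_grid - 1:
        raise ValueError("cycle fit failed: no interior density mode")
    half = dens[imode] / 2.0
    below = dens < half
    left = imode
    while left > 0 and not below[left]:
        left -= 1
    right = imode
    while right < n_grid - 1 and not below[right]:
        right += 1
    return float(grid[imode]), (float(grid[left]), float(grid[right]))


# ---------------------------------------------------------------------------
# gate containers
# ---------------------------------------------------------------------------


@dataclass
class QcGates:
    """Single/in-focus criteria (strict inequalities at every bound)."""

    aspect_ratio_min: float = 0.6
    bf_area_min: float = 70.0
    bf_area_max: float = 450.0
    gradient_rms_min: float = 50.0


@dataclass
class HealthGates:
    """Thresholds fitted from the vehicle sample's percentiles."""

    nuclear_area_min_um2: float = 0.0
    cytoplasm_contrast_max: float = float("inf")


@dataclass
class CycleGates:
    g1: Interval = (0.0, 0.0)
    s: Interval = (0.0, 0.0)
    g2m: Interval = (0.0, 0.0)
    g2_shift: float = 1.9


@dataclass
class BiomarkerGates:
    """Fitted interval chain for one fluorescence channel."""

    unstained_peak: Interval = (0.0, 0.0)
    tenfold: Interval = (0.0, 0.0)
    stained_peak: Interval = (0.0, 0.0)
    combined_average: Interval = (0.0, 0.0)
    #: boundary between background-level (+) and induced (++) staining
    plusplus_bound: float = float("inf")


@dataclass
class GateSet:
    """Fitted population boundaries, serializable as the template analog."""

    qc: QcGates = field(default_factory=QcGates)
    health: HealthGates = field(default_factory=HealthGates)
    dna_content_min: float = 1.0e5
    cycle: CycleGates = field(default_factory=CycleGates)
    per_sample_cycle: dict[str, CycleGates] = field(default_factory=dict)
    biomarkers: dict[str, BiomarkerGates] = field(default_factory=dict)
    similarity_min: float = 0.0

    def cycle_for(self, sample_id: str | None) -> CycleGates:
        if sample_id is not None and sample_id in self.per_sample_cycle:
            return self.per_sample_cycle[sample_id]
        return self.cycle

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "GateSet":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        gs = cls(
            qc=QcGates(**payload["qc"]),
            health=HealthGates(**payload["health"]),
            dna_content_min=payload["dna_content_min"],
            cycle=CycleGates(**_tupled(payload["cycle"])),
            per_sample_cycle={
                k: CycleGates(**_tupled(v))
                for k, v in payload.get("per_sample_cycle", {}).items()
            },
            biomarkers={
                k: BiomarkerGates(**_tupled(v))
                for k, v in payload.get("biomarkers", {}).items()
            },
            similarity_min=payload.get("similarity_min", 0.0),
        )
        return gs


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


# ---------------------------------------------------------------------------
# per-cell gates
# ---------------------------------------------------------------------------


def qc_gate(f, gates: GateSet | QcGates) -> tuple[bool, bool]:
    """(focused, single) flags; all comparisons strict as stated."""
    q = gates.qc if isinstance(gates, GateSet) else gates
    focused = bool(f.gradient_rms > q.gradient_rms_min)
    single = bool(
        f.bf_aspect_ratio > q.aspect_ratio_min
        and q.bf_area_min < f.bf_area_um2 < q.bf_area_max
    )
    return focused, single


def healthy_gate(f, gates: GateSet | HealthGates) -> bool:
    """High nuclear area and low cytoplasmic contrast (inclusive at the
    fitted percentile thresholds so a degenerate all-identical
    population stays healthy)."""
    h = gates.health if isinstance(gates, GateSet) else gates
    return bool(
        f.nuclear_area_um2 >= h.nuclear_area_min_um2
        and f.cytoplasm_contrast <= h.cytoplasm_contrast_max
    )


def fit_healthy_thresholds(
    nuclear_area: Sequence[float],
    cytoplasm_contrast: Sequence[float],
    area_percentile: float = 10.0,
    contrast_percentile: float = 90.0,
) -> HealthGates:
    """Percentile thresholds from the vehicle population.

    Defaults keep cells above the 10th nuclear-area percentile and
    below the 90th cytoplasmic-contrast percentile: the gate is meant
    to drop the distressed tail (pyknotic/apoptotic morphologies), not
    to halve an overwhelmingly healthy population.
    """
    area = np.asarray(nuclear_area, dtype=float)
    ctr = np.asarray(cytoplasm_contrast, dtype=float)
    return HealthGates(
        nuclear_area_min_um2=float(np.nanpercentile(area, area_percentile)),
        cytoplasm_contrast_max=float(np.nanpercentile(ctr, contrast_percentile)),
    )


# ---------------------------------------------------------------------------
# cycle gates
# ---------------------------------------------------------------------------


def fit_cycle_gates(
    dna_intensities: Sequence[float],
    ph3_flags: Sequence[bool] | None = None,
    g2_shift: float = 1.9,
    min_cells: int = 500,
    widen_factor: float = 2.0,
) -> CycleGates:
    """Place G1/S/G2M gates on the DNA-intensity axis.

    The G1 gate is centred on the dominant density mode (Gaussian KDE
    with Silverman bandwidth, computed on the log scale where both
    cycle peaks have equal width); its half-width is ``widen_factor``
    times the mode's half-maximum half-width.  The G2/M gate is the G1
    gate scaled by ``g2_shift`` (~1.8-2x), with its lower bound
    extended to cover the pH3-positive (mitotic) cells when provided;
    S is the open interval between.
    """
    x = np.asarray(dna_intensities, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < min_cells:
        raise ValueError(f"cycle fit requires >= {min_cells} cells, got {x.size}")
    logx = np.log(x)
    try:
        mode, (lo_h, hi_h) = _kde_mode_interval(logx)
    except ValueError as err:
        raise ValueError("cycle fit failed") from err
    half_lo = mode - widen_factor * (mode - lo_h)
    half_hi = mode + widen_factor * (hi_h - mode)
    g1 = (float(np.exp(half_lo)), float(np.exp(half_hi)))
    g2m = (g1[0] * g2_shift, g1[1] * g2_shift)
    if ph3_flags is not None:
        flags = np.asarray(list(ph3_flags), dtype=bool)
        pos = np.asarray(dna_intensities, dtype=float)[flags]
        pos = pos[np.isfinite(pos) & (pos > 0)]
        if pos.size >= 5:
            g2m = (min(g2m[0], float(np.percentile(pos, 1))), g2m[1])
    s = (g1[1], g2m[0])
    return CycleGates(g1=g1, s=s, g2m=g2m, g2_shift=g2_shift)


def assign_cycle_stage(dna_intensity: float, cycle: CycleGates) -> str:
    """G1 / S / G2M / unassigned for one cell."""
    v = float(dna_intensity)
    if cycle.g1[0] <= v <= cycle.g1[1]:
        return "G1"
    if cycle.g2m[0] <= v <= cycle.g2m[1]:
        return "G2M"
    if cycle.s[0] < v < cycle.s[1]:
        return "S"
    return "unassigned"


# ---------------------------------------------------------------------------
# biomarker gates
# ---------------------------------------------------------------------------


def fit_unstained_peak(intensities) -> Interval:
    """Unstained-peak gate: the central 99% of the unstained sample.

    When several unstained samples are given (a sequence of sequences)
    the per-sample intervals are coordinate-averaged, mirroring the
    repeated-positioning-then-average procedure.
    """
    first = intensities[0] if len(intensities) else None
    if first is not None and np.ndim(first) > 0:
        ivs = [fit_unstained_peak(np.asarray(s)) for s in intensities]
        lo = float(np.mean([iv[0] for iv in ivs]))
        hi = float(np.mean([iv[1] for iv in ivs]))
        return (lo, hi)
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError("unstained-peak fit requires >= 100 cells")
    lo, hi = np.percentile(x, [0.5, 99.5])
    return (float(lo), float(hi))


def tenfold_gate(up: Interval, p53_variant: bool = False) -> Interval:
    """Shift the unstained-peak gate up by a factor of 10.

    The p53 variant additionally lowers the gate's lower boundary to
    10% below the maximum autofluorescence (0.9 x the UP upper bound),
    because constitutive p53 expression sits just above background.
    """
    lo, hi = 10.0 * up[0], 10.0 * up[1]
    if p53_variant:
        lo = min(lo, 0.9 * up[1])
    return (lo, hi)


def fit_stained_peak(
    intensities: Sequence[float], tenfold: Interval, min_cells: int = 20
) -> Interval:
    """Stained-peak (SP) gate: half-maximum interval around the KDE
    mode (log scale) of the stained cells above the tenfold gate's
    lower bound.  Falls back to the tenfold gate itself when too few
    stained cells exist."""
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x) & (x >= max(tenfold[0], 1e-12))]
    if x.size < min_cells or np.ptp(x) == 0:
        return tenfold
    logx = np.log(x)
    try:
        mode, (lo, hi) = _kde_mode_interval(logx)
    except ValueError:
        return tenfold
    return (float(np.exp(lo)), float(np.exp(hi)))


def combined_average_gate(tenfold: Interval, stained_peak: Interval) -> Interval:
    """Element-wise mean of the tenfold and stained-peak gates."""
    return (
        (tenfold[0] + stained_peak[0]) / 2.0,
        (tenfold[1] + stained_peak[1]) / 2.0,
    )


def fit_plusplus_bound(
    vehicle_stained: Sequence[float],
    treated_stained: Sequence[float],
    tenfold: Interval,
    sp_vehicle: Interval | None = None,
) -> float:
    """Boundary between background (+) and induced (++) staining.

    The geometric mean of the vehicle-stained secondary-peak mode and
    the treated-stained secondary-peak mode (the latter searched above
    the vehicle SP interval so the constitutive background peak does
    not dominate); infinity when no induced peak is discernible.
    """
    sp_v = sp_vehicle or fit_stained_peak(vehicle_stained, tenfold)
    v = np.asarray(vehicle_stained, dtype=float)
    v = v[np.isfinite(v) & (v >= max(tenfold[0], 1e-12))]
    if v.size < 20:
        return float("inf")
    mode_v = float(np.exp(_kde_mode_interval(np.log(v))[0]))
    t = np.asarray(treated_stained, dtype=float)
    t = t[np.isfinite(t) & (t > sp_v[1])]
    if t.size < 20:
        return float("inf")
    mode_t = float(np.exp(_kde_mode_interval(np.log(t))[0]))
    return float(np.sqrt(mode_v * mode_t))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class PopulationFlags:
    focused: bool = False
    single: bool = False
    healthy: bool = False
    dna_positive: bool = False
    mononucleated: bool = False
    ph3_pos: bool = False
    ph3_neg: bool = False
    h2ax_plus: bool = False
    h2ax_plusplus: bool = False
    p53_overall: bool = False
    true_nuclear_ph3: bool = False
    true_nuclear_h2ax: bool = False
    cycle_stage: str = "unassigned"


def classify_cell(f, gates: GateSet, sample_id: str | None = None) -> PopulationFlags:
    """Apply the fitted gate chain to one cell's features.

    Missing features (NaN) yield False flags rather than errors.
    pH3-positive and ɣH2AX-positive calls use the nuclear channel
    intensity; p53 uses the whole-cell intensity.  ``true_nuclear_*``
    additionally requires a similarity score above ``similarity_min``
    (intermediate 0-1 scores are deliberately included).  The
    MN-eligible (mononucleated) population is healthy, pH3-negative
    and has exactly one parent nucleus.
    """
    out = PopulationFlags()
    out.focused, out.single = qc_gate(f, gates)
    out.healthy = healthy_gate(f, gates)
    dna = f.dna_intensity
    out.dna_positive = bool(np.isfinite(dna) and dna > gates.dna_content_min)
    out.cycle_stage = (
        assign_cycle_stage(dna, gates.cycle_for(sample_id))
        if out.dna_positive
        else "unassigned"
    )

    def above(value: float, lo: float) -> bool:
        return bool(np.isfinite(value) and value >= lo)

    if "ph3" in gates.biomarkers:
        g = gates.biomarkers["ph3"]
        out.ph3_pos = out.dna_positive and above(
            f.ph3_nuclear, g.combined_average[0]
        )
        out.ph3_neg = out.dna_positive and not out.ph3_pos
        out.true_nuclear_ph3 = out.ph3_pos and bool(
            np.isfinite(f.similarity_ph3) and f.similarity_ph3 > gates.similarity_min
        )
    if "h2ax" in gates.biomarkers:
        g = gates.biomarkers["h2ax"]
        nuc = f.h2ax_nuclear
        out.h2ax_plusplus = out.dna_positive and above(nuc, g.plusplus_bound)
        out.h2ax_plus = (
            out.dna_positive
            and above(nuc, g.combined_average[0])
            and not out.h2ax_plusplus
        )
        out.true_nuclear_h2ax = out.h2ax_plusplus and bool(
            np.isfinite(f.similarity_h2ax)
            and f.similarity_h2ax > gates.similarity_min
        )
    if "p53" in gates.biomarkers:
        g = gates.biomarkers["p53"]
        out.p53_overall = out.dna_positive and above(
            f.p53_whole, g.combined_average[0]
        )
    out.mononucleated = (
        out.healthy and out.ph3_neg and getattr(f, "n_nuclei", 0) == 1
    )
    return out


_MARKER_VALUE_COLUMN = {
    "h2ax": "h2ax_nuclear",
    "ph3": "ph3_nuclear",
    "p53": "p53_whole",
}
#: whole-cell intensity columns used when fitting gates from histograms
_MARKER_WHOLE_COLUMN = {
    "h2ax": "h2ax_whole",
    "ph3": "ph3_whole",
    "p53": "p53_whole",
}


def fit_gates(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    g2_shift: float = 1.9,
    dna_content_min: float = 1.0e5,
    similarity_min: float = 0.0,
    refit_cycle_per_sample: bool = True,
    min_cells_cycle: int = 500,
) -> GateSet:
    """Fit the full gate template from a batch of per-cell features.

    ``manifest`` must mark unstained and vehicle samples.  Unstained
    samples provide the per-channel autofluorescence (UP) intervals;
    stained vehicle samples the SP gates and health thresholds; the
    pooled stained samples the cell-cycle gates (refit per sample when
    enough cells are present, since the DNA histogram drifts slightly
    between acquisitions).
    """
    gates = GateSet(dna_content_min=dna_content_min, similarity_min=similarity_min)
    meta = manifest.set_index("sample_id")
    df = features.merge(
        manifest[["sample_id", "dose", "is_vehicle", "is_stained"]], on="sample_id"
    )
    focused, single = _qc_vec(df, gates.qc)
    df = df[focused & single]
    if df.empty:
        raise ValueError("no cells pass QC; cannot fit gates")
    unstained = df[~df.is_stained]
    stained = df[df.is_stained]
    if unstained.empty:
        raise ValueError("gate fitting requires unstained samples in the batch")
    if stained.empty:
        raise ValueError("gate fitting requires stained samples in the batch")
    vehicle = stained[stained.is_vehicle]
    if vehicle.empty:
        raise ValueError("gate fitting requires a stained vehicle sample")

    # health thresholds from the stained vehicle population
    gates.health = fit_healthy_thresholds(
        vehicle.nuclear_area_um2.to_numpy(), vehicle.cytoplasm_contrast.to_numpy()
    )

    # biomarker chains; the +/++ boundary is informed by exposed and
    # unexposed samples together, so it can be placed even when the
    # treatment suppresses the induced population
    treated = stained
    for marker in BIOMARKERS:
        whole = _MARKER_WHOLE_COLUMN[marker]
        groups = [
            g[whole].dropna().to_numpy()
            for _, g in unstained.groupby("sample_id")
        ]
        up = fit_unstained_peak(groups if len(groups) > 1 else groups[0])
        tf = tenfold_gate(up, p53_variant=(marker == "p53"))
        value_col = _MARKER_VALUE_COLUMN[marker]
        sp = fit_stained_peak(vehicle[value_col].dropna().to_numpy(), tf)
        bg = BiomarkerGates(
            unstained_peak=up,
            tenfold=tf,
            stained_peak=sp,
            combined_average=combined_average_gate(tf, sp),
        )
        if marker == "h2ax":
            bg.plusplus_bound = fit_plusplus_bound(
                vehicle[value_col].dropna().to_numpy(),
                treated[value_col].dropna().to_numpy(),
                tf,
                sp_vehicle=sp,
            )
        gates.biomarkers[marker] = bg

    # cycle gates: preliminary pH3 calls guide the G2/M lower bound
    ph3_lo = gates.biomarkers["ph3"].combined_average[0]
    dna = stained.dna_intensity.to_numpy()
    keep = np.isfinite(dna) & (dna > dna_content_min)
    pooled = stained[keep]
    ph3_flags = pooled.ph3_nuclear.to_numpy() >= ph3_lo
    gates.cycle = fit_cycle_gates(
        pooled.dna_intensity.to_numpy(), ph3_flags, g2_shift, min_cells=min_cells_cycle
    )
    if refit_cycle_per_sample:
        for sid, g in pooled.groupby("sample_id"):
            if len(g) >= min_cells_cycle:
                try:
                    gates.per_sample_cycle[str(sid)] = fit_cycle_gates(
                        g.dna_intensity.to_numpy(),
                        g.ph3_nuclear.to_numpy() >= ph3_lo,
                        g2_shift,
                        min_cells=min_cells_cycle,
                    )
                except ValueError:
                    pass  # keep the pooled gates for this sample
    return gates


def _qc_vec(df: pd.DataFrame, qc: QcGates) -> tuple[np.ndarray, np.ndarray]:
    focused = df.gradient_rms.to_numpy() > qc.gradient_rms_min
    single = (
        (df.bf_aspect_ratio.to_numpy() > qc.aspect_ratio_min)
        & (df.bf_area_um2.to_numpy() > qc.bf_area_min)
        & (df.bf_area_um2.to_numpy() < qc.bf_area_max)
    )
    return np.nan_to_num(focused), np.nan_to_num(single)


def classify_table(features: pd.DataFrame, gates: GateSet) -> pd.DataFrame:
    """Classify every cell; returns the features joined with flag columns."""
    rows = []
    for f in features.itertuples(index=False):
        flags = classify_cell(f, gates, sample_id=getattr(f, "sample_id", None))
        rows.append(vars(flags))
    flags_df = pd.DataFrame(rows, index=features.index)
    return pd.concat([features, flags_df], axis=1)
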