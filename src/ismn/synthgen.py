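"""Synthetic single-cell image generator with complete ground truth.

Emulates per-cell multi-channel crops from an imaging flow cytometer
running a multiplexed micronucleus assay on a TK6-like suspension cell
line: a round cell on a bright fluid background (brightfield), one round
DNA-stained nucleus whose integrated intensity scales with cell-cycle
stage (G2/M at about twice G1, controlled through nuclear area at a
fixed per-pixel amplitude), zero or more small DNA-positive micronuclei
in the cytoplasm, and three antibody channels (BV421/ɣH2AX, AF488/pH3,
PE/p53) painted with nuclear, cytoplasmic or mixed localization on top
of a lognormal per-cell autofluorescence background.  Focus blur and
additive camera noise complete the image.  Every generated quantity is
recorded as ground truth so all downstream stages can be scored against
known labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import BIOMARKERS, CellImage

CYCLE_STAGES = ("G1", "S", "G2", "M")
LEVELS = ("negative", "background", "induced")
LOCALIZATIONS = ("nuclear", "cytoplasmic", "mixed")


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth phenotype of one synthetic cell."""

    cycle_stage: str = "G1"
    mn_count: int = 0
    mn_diameters_um: tuple[float, ...] = ()
    h2ax_level: str = "background"
    ph3_positive: bool = False
    p53_level: str = "negative"
    biomarker_localization: str = "nuclear"
    focus_sigma_px: float = 0.8
    noise_sd: float = 10.0
    stained: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_stage not in CYCLE_STAGES:
            raise ValueError(f"unknown cycle stage {self.cycle_stage!r}")
        if self.h2ax_level not in LEVELS or self.p53_level not in LEVELS:
            raise ValueError("biomarker levels must be negative/background/induced")
        if self.biomarker_localization not in LOCALIZATIONS:
            raise ValueError(f"unknown localization {self.biomarker_localization!r}")
        if self.mn_count < 0 or self.mn_count != len(self.mn_diameters_um):
            raise ValueError("mn_count must equal len(mn_diameters_um)")
        if any(d <= 0 for d in self.mn_diameters_um):
            raise ValueError("MN diameters must be positive")
        if self.ph3_positive and self.cycle_stage not in ("G2", "M"):
            raise ValueError("pH3-positive cells must be in G2 or M")
        if self.focus_sigma_px < 0 or self.noise_sd < 0:
            raise ValueError("focus_sigma_px and noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline on one synthetic cell."""

    spec: CellSpec
    mn_centers_px: list[tuple[float, float]]
    nucleus_mask_true: np.ndarray
    nucleus_center_px: tuple[float, float]
    cell_radius_px: float
    true_intensities: dict[str, float]


@dataclass(frozen=True)
class ImagingModel:
    """Free parameters of the synthetic image formation.

    The instrument gives no published quantitative image model, so these
    amplitudes are package choices, fixed once: they place the G1 DNA
    peak at ~2e5 integrated counts (comfortably above the 1e5
    DNA-content gate), stained-antibody populations a decade above the
    lognormal autofluorescence "unstained peak", and brightfield edge
    gradients high enough that an in-focus cell passes a gradient-RMS
    gate of 50.
    """

    image_size_px: int = 64
    pixel_size_um: float = 0.5
    cell_radius_px: float = 15.0
    nucleus_radius_g1_px: float = 6.0
    g2_area_factor: float = 1.9
    dna_amplitude: float = 1770.0
    cell_cv: float = 0.05
    bf_background: float = 1000.0
    bf_cell_depth: float = 700.0
    autofluor_median: float = 1000.0
    lognorm_sigma: float = 0.25
    #: integrated biomarker signal (median) per expression level
    level_medians: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "h2ax": {"background": 3.5e4, "induced": 3.0e5},
            "ph3": {"induced": 2.5e5},
            "p53": {"background": 3.0e4, "induced": 1.5e5},
        }
    )
    mn_clearance_px: float = 3.0
    mn_separation_px: float = 4.0


DEFAULT_IMAGING = ImagingModel()


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _stage_area_factor(spec: CellSpec, rng: np.random.Generator, model: ImagingModel) -> float:
    if spec.cycle_stage == "G1":
        return 1.0
    if spec.cycle_stage == "S":
        lo, hi = 1.1, model.g2_area_factor - 0.1
        return float(rng.uniform(lo, hi))
    return model.g2_area_factor


def generate_cell(
    spec: CellSpec,
    image_size_px: int | None = None,
    pixel_size_um: float | None = None,
    model: ImagingModel | None = None,
    cell_id: str = "",
    sample_id: str = "",
) -> tuple[CellImage, GroundTruth]:
    """Render one synthetic cell and its ground truth.

    Deterministic for a fixed ``spec`` (the spec carries its own seed).
    Raises ``ValueError`` for infeasible specs, e.g. a micronucleus
    wider than the nucleus.
    """
    model = model or DEFAULT_IMAGING
    size = int(image_size_px or model.image_size_px)
    px = float(pixel_size_um or model.pixel_size_um)
    if size < 32:
        raise ValueError("image_size_px must be >= 32")
    rng = np.random.default_rng(spec.seed)

    area_factor = _stage_area_factor(spec, rng, model)
    nuc_r = model.nucleus_radius_g1_px * math.sqrt(area_factor)
    mn_radii = np.asarray(spec.mn_diameters_um, dtype=float) / 2.0 / px
    if mn_radii.size and mn_radii.max() * 2 > nuc_r * 2:
        raise ValueError("MN diameter exceeds nucleus diameter; spec rejected")
    max_mn_r = float(mn_radii.max()) if mn_radii.size else 0.0
    cell_r = max(
        model.cell_radius_px, nuc_r + model.mn_clearance_px + 2.0 * max_mn_r + 3.0
    )
    if cell_r > size / 2 - 3:
        raise ValueError("cell does not fit in the requested image size")

    center = (
        size / 2 + float(rng.uniform(-2, 2)),
        size / 2 + float(rng.uniform(-2, 2)),
    )
    shape = (size, size)
    cell_mask = _disc(shape, center, cell_r)
    nucleus_mask = _disc(shape, center, nuc_r)
    cyto_mask = cell_mask & ~_disc(shape, center, nuc_r + 1.0)

    # --- place micronuclei in the cytoplasm annulus ---
    mn_centers: list[tuple[float, float]] = []
    for r_mn in mn_radii:
        lo = nuc_r + model.mn_clearance_px + r_mn
        hi = cell_r - r_mn - 1.0
        if hi <= lo:
            raise ValueError("no room for micronucleus in cytoplasm annulus")
        placed = False
        for _ in range(200):
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(lo, hi)
            cand = (center[0] + rad * math.sin(ang), center[1] + rad * math.cos(ang))
            ok = all(
                math.hypot(cand[0] - p[0], cand[1] - p[1])
                >= r_mn + q + model.mn_separation_px
                for p, q in zip(mn_centers, mn_radii)
            )
            if ok:
                mn_centers.append(cand)
                placed = True
                break
        if not placed:
            raise ValueError("could not place micronuclei without overlap")

    # --- DNA channel: fixed per-pixel amplitude, area sets total ---
    amp = model.dna_amplitude * float(rng.lognormal(0.0, model.cell_cv))
    dna = np.zeros(shape)
    dna[nucleus_mask] = amp
    for (cy, cx), r_mn in zip(mn_centers, mn_radii):
        dna[_disc(shape, (cy, cx), r_mn)] = amp

    # --- brightfield: dark cell on bright fluid background ---
    bf = np.full(shape, model.bf_background)
    bf[cell_mask] -= model.bf_cell_depth

    # --- biomarker channels ---
    def paint(total: float, localization: str) -> np.ndarray:
        img = np.zeros(shape)
        if total <= 0:
            return img
        if localization == "nuclear":
            region = nucleus_mask
        elif localization == "cytoplasmic":
            region = cyto_mask
        else:  # mixed
            img[nucleus_mask] += 0.5 * total / max(nucleus_mask.sum(), 1)
            img[cyto_mask] += 0.5 * total / max(cyto_mask.sum(), 1)
            return img
        img[region] += total / max(region.sum(), 1)
        return img

    marker_level = {
        "h2ax": spec.h2ax_level,
        "ph3": "induced" if spec.ph3_positive else "negative",
        "p53": spec.p53_level,
    }
    true_int: dict[str, float] = {"dna": float(dna.sum())}
    channels: dict[str, np.ndarray] = {}
    for marker in BIOMARKERS:
        auto = model.autofluor_median * float(rng.lognormal(0.0, model.lognorm_sigma))
        img = np.zeros(shape)
        img[cell_mask] += auto / cell_mask.sum()
        signal = 0.0
        level = marker_level[marker]
        if spec.stained and level != "negative":
            median = model.level_medians[marker][level]
            signal = median * float(rng.lognormal(0.0, model.lognorm_sigma))
            img += paint(signal, spec.biomarker_localization)
        channels[marker] = img
        true_int[marker] = signal + auto

    # --- optics and camera ---
    def finish(img: np.ndarray) -> np.ndarray:
        if spec.focus_sigma_px > 0:
            img = ndi.gaussian_filter(img, spec.focus_sigma_px)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, shape)
        return np.clip(img, 0.0, None)

    cell = CellImage(
        brightfield=finish(bf),
        dna=finish(dna),
        h2ax_bv421=finish(channels["h2ax"]),
        ph3_af488=finish(channels["ph3"]),
        p53_pe=finish(channels["p53"]),
        pixel_size_um=px,
        cell_id=cell_id,
        sample_id=sample_id,
    )
    truth = GroundTruth(
        spec=spec,
        mn_centers_px=mn_centers,
        nucleus_mask_true=nucleus_mask,
        nucleus_center_px=center,
        cell_radius_px=cell_r,
        true_intensities=true_int,
    )
    return cell, truth


# ---------------------------------------------------------------------------
# experiment-level generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSizes:
    """Multiplicative shifts applied at one dose (1.0 = no effect).

    ``rcg`` is the relative cell growth (%) the dose produces; the
    other entries scale the baseline rates in ``PopulationModel``.
    """

    mn_rate: float = 1.0
    h2ax_shift: float = 1.0
    ph3_shift: float = 1.0
    p53_shift: float = 1.0
    rcg: float = 100.0


@dataclass(frozen=True)
class PopulationModel:
    """Baseline (vehicle) composition of the simulated cell population.

    Defaults describe an asynchronously cycling TK6-like culture: ~55%
    G1, 25% S, 14% G2 and a 6% mitotic (pH3-positive) fraction; 8% of
    cells with induced-level ɣH2AX on a 40% constitutive-background
    tier; 15% p53-positive; 3% of cells carrying at least one
    micronucleus.  A small fraction of positive cells carry their
    signal in the cytoplasm (off-target staining) and should be removed
    by the similarity refinement.
    """

    g1: float = 0.55
    s: float = 0.25
    g2: float = 0.14
    m: float = 0.06
    h2ax_induced: float = 0.08
    h2ax_background: float = 0.40
    p53_positive: float = 0.15
    p53_induced_share: float = 0.20
    mn_prob: float = 0.03
    mn_count_probs: tuple[float, ...] = (0.85, 0.13, 0.02)  # 1, 2, 3 MN
    mn_diameter_um: tuple[float, float] = (1.25, 3.0)
    offtarget_fraction: float = 0.05
    focus_sigma_px: float = 0.8
    noise_sd: float = 10.0


@dataclass
class SyntheticSample:
    """One acquisition file: metadata plus lazily rendered cells."""

    sample_id: str
    compound: str
    dose: float
    replicate: int
    is_vehicle: bool
    is_stained: bool
    cells_per_ml: float
    specs: list[CellSpec]
    model: ImagingModel

    def cells(self) -> Iterator[tuple[CellImage, GroundTruth]]:
        for i, spec in enumerate(self.specs):
            yield generate_cell(
                spec,
                model=self.model,
                cell_id=f"{self.sample_id}_c{i:05d}",
                sample_id=self.sample_id,
            )


@dataclass
class SyntheticExperiment:
    samples: list[SyntheticSample]
    seed: int

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "compound": s.compound,
                "dose": s.dose,
                "replicate": s.replicate,
                "is_vehicle": s.is_vehicle,
                "is_stained": s.is_stained,
                "cells_per_ml": s.cells_per_ml,
                "n_cells": len(s.specs),
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows)

    def truth(self) -> pd.DataFrame:
        """Per-cell ground-truth labels (no image rendering needed)."""
        rows = []
        for s in self.samples:
            for i, spec in enumerate(s.specs):
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "cell_id": f"{s.sample_id}_c{i:05d}",
                        "dose": s.dose,
                        "replicate": s.replicate,
                        "is_stained": s.is_stained,
                        "cycle_stage": spec.cycle_stage,
                        "mn_count": spec.mn_count,
                        "h2ax_level": spec.h2ax_level,
                        "ph3_positive": spec.ph3_positive,
                        "p53_level": spec.p53_level,
                        "localization": spec.biomarker_localization,
                    }
                )
        return pd.DataFrame(rows)


def make_effect_model(
    doses: Sequence[float],
    *,
    mn_top: float = 1.0,
    h2ax_top: float = 1.0,
    ph3_top: float = 1.0,
    p53_top: float = 1.0,
    rcg_top: float = 100.0,
) -> dict[float, EffectSizes]:
    """Linear-in-dose interpolation from no effect at dose 0 to the
    stated shifts at the top dose."""
    top = max(doses)
    if top <= 0:
        return {d: EffectSizes() for d in doses}

    def interp(lo: float, hi: float, d: float) -> float:
        return lo + (hi - lo) * d / top

    return {
        d: EffectSizes(
            mn_rate=interp(1.0, mn_top, d),
            h2ax_shift=interp(1.0, h2ax_top, d),
            ph3_shift=interp(1.0, ph3_top, d),
            p53_shift=interp(1.0, p53_top, d),
            rcg=interp(100.0, rcg_top, d),
        )
        for d in doses
    }


#: Effect sizes at the top dose for the three study designs.
MOA_EFFECTS: dict[str, dict[str, float]] = {
    "clastogen": dict(mn_top=2.5, h2ax_top=2.5, ph3_top=0.5, p53_top=2.0, rcg_top=50.0),
    "aneugen": dict(mn_top=2.5, h2ax_top=0.5, ph3_top=2.5, p53_top=2.0, rcg_top=50.0),
    "negative": dict(),
}


def _sample_spec(
    rng: np.random.Generator,
    pop: PopulationModel,
    eff: EffectSizes,
    stained: bool,
) -> CellSpec:
    m = min(pop.m * eff.ph3_shift, 0.5)
    g2 = pop.g2
    scale = (1.0 - m - g2) / (pop.g1 + pop.s)
    probs = np.array([pop.g1 * scale, pop.s * scale, g2, m])
    stage = CYCLE_STAGES[int(rng.choice(4, p=probs / probs.sum()))]
    ph3_positive = stage == "M"

    induced = min(pop.h2ax_induced * eff.h2ax_shift, 0.8)
    background = min(pop.h2ax_background, 0.95 - induced)
    u = rng.uniform()
    if u < induced:
        h2ax = "induced"
    elif u < induced + background:
        h2ax = "background"
    else:
        h2ax = "negative"

    p_pos = min(pop.p53_positive * eff.p53_shift, 0.9)
    if rng.uniform() < p_pos:
        p53 = "induced" if rng.uniform() < pop.p53_induced_share else "background"
    else:
        p53 = "negative"

    mn_p = min(pop.mn_prob * eff.mn_rate, 0.6)
    if rng.uniform() < mn_p:
        k = 1 + int(rng.choice(len(pop.mn_count_probs), p=pop.mn_count_probs))
        lo, hi = pop.mn_diameter_um
        if k > 1:
            hi = min(hi, 2.2)  # keep multi-MN placements feasible
        diameters = tuple(float(x) for x in rng.uniform(lo, hi, size=k))
    else:
        k, diameters = 0, ()

    localization = (
        "cytoplasmic" if rng.uniform() < pop.offtarget_fraction else "nuclear"
    )
    return CellSpec(
        cycle_stage=stage,
        mn_count=k,
        mn_diameters_um=diameters,
        h2ax_level=h2ax,
        ph3_positive=ph3_positive,
        p53_level=p53,
        biomarker_localization=localization,
        focus_sigma_px=pop.focus_sigma_px,
        noise_sd=pop.noise_sd,
        stained=stained,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_experiment(
    moa: str,
    doses: Sequence[float],
    cells_per_dose: int,
    effect_model: Mapping[float, EffectSizes] | None = None,
    seed: int = 0,
    replicates: int = 3,
    unstained_cells: int = 150,
    population: PopulationModel | None = None,
    model: ImagingModel | None = None,
    compound: str | None = None,
    vehicle_cells_per_ml: float = 1.0e6,
) -> SyntheticExperiment:
    """Simulate a full dose-response study.

    ``cells_per_dose`` cells are generated per dose *per replicate*.
    Matched unstained samples (vehicle and top dose) are included for
    biomarker gate calibration.  A single master seed drives everything;
    per-sample and per-cell seeds are derived deterministically.
    """
    doses = list(doses)
    if not doses:
        raise ValueError("dose list is empty")
    if 0.0 not in [float(d) for d in doses]:
        raise ValueError("doses must include 0 (vehicle)")
    if cells_per_dose < 50:
        raise ValueError("cells_per_dose must be >= 50")
    if moa not in MOA_EFFECTS:
        raise ValueError(f"unknown mode of action {moa!r}")
    pop = population or PopulationModel()
    model = model or DEFAULT_IMAGING
    compound = compound or moa
    if effect_model is None:
        effect_model = make_effect_model(doses, **MOA_EFFECTS[moa])

    master = np.random.SeedSequence(seed)
    samples: list[SyntheticSample] = []

    def build_sample(
        sid: str, dose: float, rep: int, stained: bool, n: int, ss: np.random.SeedSequence
    ) -> SyntheticSample:
        rng = np.random.default_rng(ss)
        eff = effect_model[dose]
        rcg = eff.rcg if stained or dose > 0 else 100.0
        cells_per_ml = (
            vehicle_cells_per_ml * eff.rcg / 100.0 * float(rng.lognormal(0.0, 0.03))
        )
        specs = [_sample_spec(rng, pop, eff, stained) for _ in range(n)]
        return SyntheticSample(
            sample_id=sid,
            compound=compound,
            dose=float(dose),
            replicate=rep,
            is_vehicle=dose == 0,
            is_stained=stained,
            cells_per_ml=cells_per_ml,
            specs=specs,
            model=model,
        )

    children = iter(master.spawn(len(doses) * replicates + 2))
    for dose in doses:
        for rep in range(1, replicates + 1):
            sid = f"{compound}_d{dose:g}_r{rep}"
            samples.append(
                build_sample(sid, dose, rep, True, cells_per_dose, next(children))
            )
    top = max(doses)
    samples.append(
        build_sample(f"{compound}_unstained_d0", 0.0, 1, False, unstained_cells, next(children))
    )
    samples.append(
        build_sample(
            f"{compound}_unstained_d{top:g}", top, 1, False, unstained_cells, next(children)
        )
    )
    return SyntheticExperiment(samples=samples, seed=seed)
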