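"""Stacked Boolean-mask segmentation of nuclei and micronuclei.

The detection strategy mirrors template-based imaging-flow-cytometry
scoring: an intensity threshold keeps the stained part of the image, a
spot mask extracts small bright blobs, a range filter keeps blobs with
micronucleus-like size and roundness, and the parent nucleus (found with
an Otsu seed refined by a morphological active contour, then dilated) is
Boolean-subtracted so only extra-nuclear spots survive.  Three such
mask iterations with different size/roundness settings are OR-combined
and intersected with the cytoplasm region to give the Complete Final MN
(CFM) mask, within which spots are counted per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import morphological_chan_vese

from .core import CellImage, as_bool_mask

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structure


@dataclass(frozen=True)
class SpotParams:
    """Spot-detection settings for one MN-mask iteration.

    ``spot_diameter_px`` bounds the equivalent diameter of a detected
    blob's half-maximum support; ``area_bounds_um2`` and
    ``aspect_ratio_bounds`` are the range-filter limits applied to the
    resulting connected components.  All bounds are inclusive.
    """

    spot_diameter_px: tuple[float, float] = (1.0, 6.0)
    spot_to_background_ratio: float = 1.5
    area_bounds_um2: tuple[float, float] = (1.25, 25.0)
    aspect_ratio_bounds: tuple[float, float] = (0.4, 1.0)

    def __post_init__(self) -> None:
        for lo, hi in (
            self.spot_diameter_px,
            self.area_bounds_um2,
            self.aspect_ratio_bounds,
        ):
            if not lo < hi:
                raise ValueError("bounds must satisfy min < max")


def default_iterations(base: SpotParams) -> tuple[SpotParams, SpotParams, SpotParams]:
    """The three MN-mask iterations.

    Iteration 1 uses the base settings, iteration 2 relaxes the
    roundness criterion and iteration 3 widens the admissible spot
    diameter, so that irregular or blur-spread micronuclei missed by the
    strict first pass are still captured.
    """
    return (
        base,
        replace(base, aspect_ratio_bounds=(0.3, 1.0)),
        replace(base, spot_diameter_px=(1.0, 8.0)),
    )


@dataclass
class SegmentationConfig:
    """Every numeric knob of the mask stack.

    Defaults: drop the lowest 10% of pixel intensities, detect bright
    spots 1-6 px across at a low (1.5x) spot-to-background ratio, keep
    components of 1.25-25 um^2 with aspect ratio 0.4-1, fit the nucleus
    with contour detail level 3 and dilate it by 1 px.  The pixel scale
    defaults to 0.5 um/px (x40 magnification convention).
    """

    lower_intensity_percent: float = 10.0
    spot: SpotParams = field(default_factory=SpotParams)
    iterations: tuple[SpotParams, ...] | None = None
    nucleus_contour_detail: int = 3
    nucleus_dilate_px: int = 1
    levelset_iterations: int = 4
    min_peak_snr: float = 6.0
    #: extra clearance (px) around the nucleus mask inside which spot
    #: peaks are ignored; suppresses nuclear-rim blur residuals
    nucleus_exclusion_pad_px: int = 2
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.lower_intensity_percent < 100:
            raise ValueError("lower_intensity_percent must be in (0, 100)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def iteration_params(self) -> tuple[SpotParams, ...]:
        if self.iterations is not None:
            return tuple(self.iterations)
        return default_iterations(self.spot)

    @property
    def mn_area_max_um2(self) -> float:
        return max(p.area_bounds_um2[1] for p in self.iteration_params())

    @property
    def max_spot_diameter_px(self) -> float:
        return max(p.spot_diameter_px[1] for p in self.iteration_params())


@dataclass
class NucleusResult:
    mask: np.ndarray
    found: bool


@dataclass
class CfmResult:
    """All masks produced for one cell."""

    cfm: np.ndarray
    nucleus: np.ndarray
    cytoplasm: np.ndarray
    cell: np.ndarray
    mn_masks: tuple[np.ndarray, ...] = ()
    no_nucleus: bool = False


def threshold_lower_percent(image: np.ndarray, percent: float) -> np.ndarray:
    """Mask retaining pixels strictly above the ``percent``-th intensity
    percentile of the image.

    A constant image has every pixel tied at the percentile, in which
    case all pixels are retained (documented tie rule).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("image is empty")
    if not 0 < percent < 100:
        raise ValueError("percent must be in (0, 100)")
    cut = np.percentile(image, percent)
    mask = image > cut
    if not mask.any() and np.all(image == image.flat[0]):
        return np.ones_like(image, dtype=bool)
    return mask


def boolean_subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """``a AND NOT b``; shapes must match."""
    a = as_bool_mask(a)
    b = as_bool_mask(b, shape=a.shape)
    return a & ~b


def spot_count(cfm: np.ndarray) -> int:
    """Number of 8-connected components in the mask."""
    cfm = as_bool_mask(cfm)
    _, n = ndi.label(cfm, structure=_EIGHT)
    return int(n)


def _component_aspect_ratio(rows: np.ndarray, cols: np.ndarray) -> float:
    """Minor/major axis-length ratio from the pixel-coordinate covariance."""
    if rows.size <= 2:
        return 1.0  # too few pixels to define an ellipse; treat as round
    coords = np.stack([rows.astype(float), cols.astype(float)])
    cov = np.cov(coords, bias=True)
    evals = np.linalg.eigvalsh(cov)
    lo, hi = max(evals[0], 0.0), max(evals[1], 0.0)
    if hi <= 0:
        return 1.0
    return float(np.sqrt(lo / hi))


def range_filter(
    mask: np.ndarray,
    area_bounds_um2: tuple[float, float],
    aspect_ratio_bounds: tuple[float, float],
    pixel_size_um: float,
) -> np.ndarray:
    """Keep components whose physical area and roundness fall within the
    given inclusive bounds.

    Area is the pixel count scaled by ``pixel_size_um**2``; roundness is
    the minor/major axis ratio of the component's equivalent ellipse.
    """
    mask = as_bool_mask(mask)
    lab, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return np.zeros_like(mask)
    out = np.zeros_like(mask)
    px_area = pixel_size_um**2
    lo_a, hi_a = area_bounds_um2
    lo_r, hi_r = aspect_ratio_bounds
    objs = ndi.find_objects(lab)
    for i, sl in enumerate(objs, start=1):
        comp = lab[sl] == i
        area = comp.sum() * px_area
        if not lo_a <= area <= hi_a:
            continue
        rows, cols = np.nonzero(comp)
        ratio = _component_aspect_ratio(rows, cols)
        if not lo_r <= ratio <= hi_r:
            continue
        out[sl] |= comp
    return out


def _tophat(image: np.ndarray, max_diameter_px: float) -> np.ndarray:
    """White top-hat with a structuring element just larger than the
    largest admissible spot, so spots survive and flat nuclei vanish.

    A square window is used (separable, hence fast); side = largest
    admissible spot diameter + 1 px.
    """
    image = np.asarray(image, dtype=np.float64)
    side = int(np.ceil(max_diameter_px)) + 1
    return image - ndi.grey_opening(image, size=(side, side))


@dataclass
class SpotCandidates:
    """Bright-blob candidates shared by the three MN-mask iterations.

    Each candidate is one flood-grown half-maximum support around a
    top-hat local maximum, with the quantities the per-iteration
    filters need (equivalent diameter and peak-to-background ratio).
    """

    shape: tuple[int, int]
    slices: list[tuple[slice, slice]]
    supports: list[np.ndarray]
    diameters: np.ndarray
    ratios: np.ndarray


def detect_spots(
    image: np.ndarray,
    base: np.ndarray,
    *,
    max_diameter_px: float = 8.0,
    min_peak_snr: float = 5.0,
    tophat: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
) -> SpotCandidates:
    """Find candidate bright spots within ``base``.

    A candidate peak is a local maximum of the white-top-hat residual
    whose amplitude clears a robust (MAD-based) noise floor.  Its
    support is the 8-connected region above half the peak residual,
    grown inside a local window; its background is the
    morphological-opening value at the peak floored by the whole-image
    median.  ``exclude`` (typically the parent-nucleus mask) removes
    peaks inside it and stops support growth at its boundary, so rim
    residuals of large objects cannot masquerade as, or bridge into,
    spots.
    """
    image = np.asarray(image, dtype=np.float64)
    base = as_bool_mask(base, shape=image.shape)
    if exclude is not None:
        base = base & ~as_bool_mask(exclude, shape=image.shape)
    empty = SpotCandidates(image.shape, [], [], np.empty(0), np.empty(0))
    if not base.any():
        return empty
    th = _tophat(image, max_diameter_px) if tophat is None else tophat
    opened = image - th

    maxf = ndi.maximum_filter(th, size=3)
    med = np.median(th[base])
    sigma = 1.4826 * np.median(np.abs(th[base] - med))
    floor = max(min_peak_snr * sigma, 1e-12)
    peaks = (th >= maxf) & base & (th > floor)
    if not peaks.any():
        return empty

    bg_med = float(np.median(image))
    win = int(np.ceil(max_diameter_px)) + 4
    claimed = np.zeros_like(base)
    slices: list[tuple[slice, slice]] = []
    supports: list[np.ndarray] = []
    diameters: list[float] = []
    ratios: list[float] = []
    for r, c in zip(*np.nonzero(peaks)):
        if claimed[r, c]:
            continue
        sl = (
            slice(max(r - win, 0), min(r + win + 1, image.shape[0])),
            slice(max(c - win, 0), min(c + win + 1, image.shape[1])),
        )
        local = (th[sl] >= 0.5 * th[r, c]) & base[sl]
        lab, _ = ndi.label(local, structure=_EIGHT)
        comp = lab == lab[r - sl[0].start, c - sl[1].start]
        claimed[sl] |= comp
        # a genuine spot is a local structure: its support boundary must
        # be dimmer than its peak (rejects rim residues of large flat
        # objects whose plateau continues past the support)
        boundary = ndi.binary_dilation(comp, structure=_EIGHT) & ~comp
        if boundary.any() and image[sl][boundary].max() >= image[r, c]:
            continue
        local_bg = max(opened[r, c], bg_med, 1e-12)
        slices.append(sl)
        supports.append(comp)
        diameters.append(float(np.sqrt(4.0 * comp.sum() / np.pi)))
        ratios.append(float(image[r, c] / local_bg))
    return SpotCandidates(
        image.shape, slices, supports, np.asarray(diameters), np.asarray(ratios)
    )


def spot_mask(
    image: np.ndarray,
    base: np.ndarray,
    params: SpotParams,
    *,
    candidates: SpotCandidates | None = None,
    tophat: np.ndarray | None = None,
    min_peak_snr: float = 5.0,
) -> np.ndarray:
    """Union of compact bright blobs within ``base``.

    Detection is white-top-hat residual -> local maxima -> flood-grown
    half-maximum support (see :func:`detect_spots`); a blob is kept when
    its peak-to-background ratio is at least
    ``spot_to_background_ratio`` and its support's equivalent diameter
    lies within ``spot_diameter_px`` (inclusive).
    """
    base = as_bool_mask(base)
    if candidates is None:
        candidates = detect_spots(
            image,
            base,
            max_diameter_px=params.spot_diameter_px[1],
            min_peak_snr=min_peak_snr,
            tophat=tophat,
        )
    out = np.zeros(candidates.shape, dtype=bool)
    lo_d, hi_d = params.spot_diameter_px
    for sl, comp, dia, ratio in zip(
        candidates.slices, candidates.supports, candidates.diameters, candidates.ratios
    ):
        if ratio >= params.spot_to_background_ratio and lo_d <= dia <= hi_d:
            out[sl] |= comp
    return out


def nucleus_mask(
    dna_image: np.ndarray, cfg: SegmentationConfig | None = None
) -> NucleusResult:
    """Segment the parent nucleus (or nuclei) from the DNA channel.

    An Otsu threshold on the lightly smoothed image seeds a
    morphological active contour (smoothing mapped from the contour
    detail level) which is run on a padded bounding box for speed; the
    result is dilated by ``nucleus_dilate_px`` and size-filtered so that
    only components larger than any admissible micronucleus remain.
    """
    cfg = cfg or SegmentationConfig()
    image = np.asarray(dna_image, dtype=np.float64)
    empty = NucleusResult(np.zeros(image.shape, dtype=bool), False)
    if image.size == 0 or np.ptp(image) == 0:
        return empty
    sm = ndi.gaussian_filter(image, 1.0)
    fg = sm > threshold_otsu(sm)
    if not fg.any():
        return empty
    # cut thin blur bridges between the nucleus and nearby micronuclei
    # so the size filter can tell them apart
    fg = ndi.binary_opening(fg, structure=disk(2))

    min_px = cfg.mn_area_max_um2 / cfg.pixel_size_um**2
    lab, n = ndi.label(fg, structure=_EIGHT)
    sizes = ndi.sum_labels(fg, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes > min_px) + 1
    if keep.size == 0:
        return empty
    seed = np.isin(lab, keep)

    rows, cols = np.nonzero(seed)
    pad = 5
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, image.shape[0])
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, image.shape[1])
    box = (slice(r0, r1), slice(c0, c1))
    smoothing = max(0, 4 - cfg.nucleus_contour_detail)
    refined_box = morphological_chan_vese(
        sm[box],
        num_iter=cfg.levelset_iterations,
        init_level_set=seed[box],
        smoothing=smoothing,
    ).astype(bool)
    refined = np.zeros_like(seed)
    refined[box] = refined_box
    # the active contour refines the seed boundary; restrict its growth
    # to a narrow band so nearby bright spots (micronuclei) are not annexed
    refined &= ndi.binary_dilation(seed, structure=disk(1), iterations=2)

    if cfg.nucleus_dilate_px > 0:
        refined = ndi.binary_dilation(refined, structure=disk(cfg.nucleus_dilate_px))

    lab, n = ndi.label(refined, structure=_EIGHT)
    if n == 0:
        return empty
    sizes = ndi.sum_labels(refined, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes > min_px) + 1
    if keep.size == 0:
        return empty
    return NucleusResult(np.isin(lab, keep), True)


def cell_extent_mask(brightfield: np.ndarray) -> np.ndarray:
    """Cell footprint from the brightfield channel.

    Cells image darker than the fluid background; the largest
    below-Otsu component, hole-filled, is taken as the cell extent.
    Falls back to the full frame when no credible dark object exists.
    """
    image = np.asarray(brightfield, dtype=np.float64)
    full = np.ones(image.shape, dtype=bool)
    if np.ptp(image) == 0:
        return full
    sm = ndi.gaussian_filter(image, 1.0)
    dark = sm < threshold_otsu(sm)
    lab, n = ndi.label(dark, structure=_EIGHT)
    if n == 0:
        return full
    sizes = ndi.sum_labels(dark, lab, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < 30:
        return full
    return ndi.binary_fill_holes(lab == biggest)


def _drop_border_components(mask: np.ndarray) -> np.ndarray:
    """Remove components touching the image border (likely crop artifacts)."""
    lab, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return mask
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    bad = np.unique(lab[border & mask])
    bad = bad[bad > 0]
    if bad.size == 0:
        return mask
    return mask & ~np.isin(lab, bad)


def build_cfm(cell: CellImage, cfg: SegmentationConfig | None = None) -> CfmResult:
    """Run the full mask stack for one cell.

    Three MN-mask iterations (spot mask -> range filter -> nucleus
    subtraction) are OR-combined, intersected with the cytoplasm region
    (cell extent minus nucleus) and cleaned of border-touching
    components.  When no parent nucleus is found the result is flagged
    and the CFM left empty.
    """
    cfg = cfg or SegmentationConfig()
    dna = cell.dna
    base = threshold_lower_percent(dna, cfg.lower_intensity_percent)
    nuc = nucleus_mask(dna, cfg)
    cellmask = cell_extent_mask(cell.brightfield)
    cyto = cellmask & ~nuc.mask
    if not nuc.found:
        return CfmResult(
            cfm=np.zeros(dna.shape, dtype=bool),
            nucleus=nuc.mask,
            cytoplasm=cyto,
            cell=cellmask,
            no_nucleus=True,
        )

    exclusion = nuc.mask
    if cfg.nucleus_exclusion_pad_px > 0:
        exclusion = ndi.binary_dilation(
            exclusion, structure=disk(1), iterations=cfg.nucleus_exclusion_pad_px
        )
    candidates = detect_spots(
        dna,
        base,
        max_diameter_px=cfg.max_spot_diameter_px,
        min_peak_snr=cfg.min_peak_snr,
        exclude=exclusion,
    )
    mn_masks = []
    for params in cfg.iteration_params():
        sm_ = spot_mask(dna, base, params, candidates=candidates)
        rf = range_filter(
            sm_, params.area_bounds_um2, params.aspect_ratio_bounds, cfg.pixel_size_um
        )
        mn_masks.append(boolean_subtract(rf, nuc.mask))
    combined = mn_masks[0] | mn_masks[1] | mn_masks[2]
    cfm = _drop_border_components(combined & cyto)
    return CfmResult(
        cfm=cfm,
        nucleus=nuc.mask,
        cytoplasm=cyto,
        cell=cellmask,
        mn_masks=tuple(mn_masks),
        no_nucleus=False,
    )


def mn_centroids(cfm: np.ndarray) -> list[tuple[float, float]]:
    """(row, col) centroids of each CFM component."""
    lab, n = ndi.label(as_bool_mask(cfm), structure=_EIGHT)
    if n == 0:
        return []
    return [(float(r), float(c)) for r, c in ndi.center_of_mass(cfm, lab, range(1, n + 1))]
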