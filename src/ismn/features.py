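"""Per-cell scalar features used by every gate.

Each cell contributes morphology features from the brightfield channel
(aspect ratio, area, gradient RMS as a focus measure, cytoplasmic
contrast), DNA-content and nuclear-area features from the segmentation
masks, integrated whole-cell and nuclear intensities per biomarker
channel, a similarity-of-morphology score per biomarker (Fisher
z-transformed Pearson correlation with the DNA channel over the cell
footprint, the standard nuclear-localization score: > 1 predominantly
nuclear, < 0 predominantly cytoplasmic), and the CFM spot count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import BIOMARKERS, CellImage, as_bool_mask
from .segmentation import (
    CfmResult,
    SegmentationConfig,
    _EIGHT,
    build_cfm,
    mn_centroids,
    spot_count,
)

_R_CLIP = 1.0 - 1e-6


def aspect_ratio(mask: np.ndarray) -> float:
    """Minor/major axis-length ratio of the mask's equivalent ellipse.

    Computed from the eigenvalues of the pixel-coordinate covariance;
    always in (0, 1].
    """
    mask = as_bool_mask(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("aspect_ratio of an empty mask is undefined")
    if rows.size == 1:
        return 1.0
    cov = np.cov(np.stack([rows.astype(float), cols.astype(float)]), bias=True)
    evals = np.linalg.eigvalsh(cov)
    lo, hi = max(evals[0], 0.0), max(evals[1], 0.0)
    if hi <= 0:
        return 1.0
    return float(np.sqrt(lo / hi))


def gradient_rms(image: np.ndarray, mask: np.ndarray) -> float:
    """Root mean square of the first-difference gradient magnitude over
    the masked pixels, on the raw intensity scale (a focus measure)."""
    image = np.asarray(image, dtype=np.float64)
    mask = as_bool_mask(mask, shape=image.shape)
    if not mask.any():
        raise ValueError("gradient_rms of an empty mask is undefined")
    gy, gx = np.gradient(image)
    mag2 = gy**2 + gx**2
    return float(np.sqrt(mag2[mask].mean()))


def contrast(image: np.ndarray, mask: np.ndarray) -> float:
    """Normalized intensity variation over the masked pixels
    (coefficient of variation); 0 for a constant region."""
    image = np.asarray(image, dtype=np.float64)
    mask = as_bool_mask(mask, shape=image.shape)
    if not mask.any():
        raise ValueError("contrast of an empty mask is undefined")
    vals = image[mask]
    mean = vals.mean()
    if mean == 0:
        return 0.0
    return float(vals.std() / abs(mean))


def similarity_of_morphology(
    signal_image: np.ndarray,
    dna_image: np.ndarray,
    region: np.ndarray,
) -> float:
    """Fisher z (atanh) of the Pearson correlation between the two
    channels' pixel intensities over ``region``.

    Scores > 1 indicate predominantly nuclear signal, < 0 predominantly
    cytoplasmic, 0-1 intermediate.  The correlation is clipped to
    +/-(1 - 1e-6) before the transform.  Returns NaN (flagged
    undefined) when the region has fewer than 3 pixels or either
    channel has zero variance there.
    """
    signal_image = np.asarray(signal_image, dtype=np.float64)
    dna_image = np.asarray(dna_image, dtype=np.float64)
    region = as_bool_mask(region, shape=signal_image.shape)
    a = signal_image[region]
    b = dna_image[region]
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    r = float(np.clip(r, -_R_CLIP, _R_CLIP))
    return float(np.arctanh(r))


@dataclass
class CellFeatures:
    """The per-cell scalar feature set used by all gating."""

    cell_id: str = ""
    sample_id: str = ""
    bf_aspect_ratio: float = float("nan")
    bf_area_um2: float = float("nan")
    gradient_rms: float = float("nan")
    cytoplasm_contrast: float = float("nan")
    nuclear_area_um2: float = float("nan")
    dna_intensity: float = float("nan")
    dna_gradient_rms: float = float("nan")
    h2ax_whole: float = float("nan")
    h2ax_nuclear: float = float("nan")
    ph3_whole: float = float("nan")
    ph3_nuclear: float = float("nan")
    p53_whole: float = float("nan")
    p53_nuclear: float = float("nan")
    similarity_h2ax: float = float("nan")
    similarity_ph3: float = float("nan")
    similarity_p53: float = float("nan")
    mn_count: int = 0
    n_nuclei: int = 0
    mn_centroids: tuple[tuple[float, float], ...] = ()
    flag: str = ""

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["mn_centroids"] = ";".join(f"{r:.2f}:{c:.2f}" for r, c in self.mn_centroids)
        return d


def extract_features(
    cell: CellImage,
    masks: CfmResult | None = None,
    cfg: SegmentationConfig | None = None,
) -> CellFeatures:
    """Compute all per-cell features.

    Segmentation failures (no parent nucleus) produce a flagged record
    with NaN nuclear features rather than an exception, so that batch
    runs continue and the affected cells fall out at the QC/DNA gates.
    """
    if masks is None:
        masks = build_cfm(cell, cfg)
    px2 = cell.pixel_size_um**2
    f = CellFeatures(cell_id=cell.cell_id, sample_id=cell.sample_id)

    cellmask = masks.cell
    if cellmask.any():
        f.bf_aspect_ratio = aspect_ratio(cellmask)
        f.bf_area_um2 = float(cellmask.sum() * px2)
        f.gradient_rms = gradient_rms(cell.brightfield, cellmask)
    # contrast is measured inside the cell boundary (2-px rim eroded) so
    # the focus-dependent edge gradient does not masquerade as texture
    # and penalize large-nucleus (G2/M) cells with thin cytoplasm
    inner_cyto = masks.cytoplasm & ndi.binary_erosion(cellmask, iterations=2)
    if inner_cyto.any():
        f.cytoplasm_contrast = contrast(cell.brightfield, inner_cyto)
    elif masks.cytoplasm.any():
        f.cytoplasm_contrast = contrast(cell.brightfield, masks.cytoplasm)

    if masks.no_nucleus:
        f.flag = "no_nucleus"
        return f

    nucleus = masks.nucleus
    f.nuclear_area_um2 = float(nucleus.sum() * px2)
    f.dna_gradient_rms = gradient_rms(cell.dna, nucleus)
    dna_region = nucleus | masks.cfm
    f.dna_intensity = float(cell.dna[dna_region].sum())
    _, f.n_nuclei = ndi.label(nucleus, structure=_EIGHT)

    whole_support = cellmask | nucleus  # guarantees nuclear <= whole
    for marker in BIOMARKERS:
        img = cell.channel(marker)
        setattr(f, f"{marker}_whole", float(img[whole_support].sum()))
        setattr(f, f"{marker}_nuclear", float(img[nucleus].sum()))
        setattr(
            f,
            f"similarity_{marker}",
            similarity_of_morphology(img, cell.dna, whole_support),
        )

    f.mn_count = spot_count(masks.cfm)
    f.mn_centroids = tuple(mn_centroids(masks.cfm))
    return f


def features_frame(feature_list: Iterable[CellFeatures]) -> pd.DataFrame:
    """Stack per-cell features into a tidy DataFrame (one row per cell)."""
    return pd.DataFrame([f.as_dict() for f in feature_list])
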