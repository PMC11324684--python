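"""Shared container types for per-cell imaging-flow-cytometry data.

A "cell image" is a small multi-channel crop centred on one cell, as
exported from an imaging flow cytometer after compensation.  Channel
roles follow the assay's staining panel: brightfield, DRAQ5 DNA stain,
BV421 anti-ɣH2AX, AF488 anti-pH3 and PE anti-p53.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical channel order used throughout the package (and in TIFF stacks).
CHANNELS = ("brightfield", "dna", "h2ax_bv421", "ph3_af488", "p53_pe")

#: Short biomarker keys used for per-channel features and gates.
BIOMARKERS = ("h2ax", "ph3", "p53")

#: Biomarker key -> CellImage attribute with that channel's pixels.
BIOMARKER_CHANNEL = {
    "h2ax": "h2ax_bv421",
    "ph3": "ph3_af488",
    "p53": "p53_pe",
}


@dataclass
class CellImage:
    """One cell's aligned multi-channel intensity arrays plus pixel scale.

    All channels must share a single shape and hold non-negative
    intensities on the instrument's raw scale.
    """

    brightfield: np.ndarray
    dna: np.ndarray
    h2ax_bv421: np.ndarray
    ph3_af488: np.ndarray
    p53_pe: np.ndarray
    pixel_size_um: float = 0.5
    cell_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        shape = np.asarray(self.brightfield).shape
        for name in CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} must be a 2-D array")
            if arr.shape != shape:
                raise ValueError(
                    f"channel {name!r} has shape {arr.shape}, expected {shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            setattr(self, name, arr)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightfield.shape

    def channel(self, name: str) -> np.ndarray:
        """Return a channel by canonical name or biomarker key."""
        if name in BIOMARKER_CHANNEL:
            name = BIOMARKER_CHANNEL[name]
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def stack(self) -> np.ndarray:
        """All channels as a (5, rows, cols) array in canonical order."""
        return np.stack([getattr(self, name) for name in CHANNELS])


def as_bool_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate and coerce a 2-D boolean mask."""
    out = np.asarray(mask, dtype=bool)
    if out.ndim != 2:
        raise ValueError("mask must be 2-D")
    if shape is not None and out.shape != shape:
        raise ValueError(f"mask shape {out.shape} does not match image shape {shape}")
    return out
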