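"""Foreground masking of plant segments on the plate and per-sample spectra.

Plates carry dried plant segments arranged in a grid on a bright Teflon
background.  Tissue reflects far less than the plate in the NIR, so a single
band near 850 nm separates the two populations; Otsu's threshold on that band,
a small binary opening, and connected-component labeling yield one label per
segment.  Per-sample spectra are arithmetic means over masked pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .hsi_core import HyperspectralCube

__all__ = ["SegmentMask", "SampleRecord", "build_mask", "mean_spectrum"]

DEFAULT_BAND_NM = 850.0
DEFAULT_MIN_AREA = 50

#: default analyte panel (four marker metabolites + moisture, mass fractions)
ANALYTE_NAMES = (
    "salvianolic_acid_B",
    "dihydrotanshinone_I",
    "cryptotanshinone",
    "tanshinone_IIA",
    "moisture",
)


@dataclass
class SegmentMask:
    """Labeled foreground regions; 0 = background, k = segment k."""

    labels: np.ndarray
    n_segments: int
    band_used_nm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size != self.n_segments or (
            present.size and (present.min() != 1 or present.max() != self.n_segments)
        ):
            raise ValueError("labels must be contiguous 1..n_segments")

    def segment_pixels(self, segment: int) -> np.ndarray:
        """Boolean image of one segment."""
        return self.labels == segment

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class SampleRecord:
    """One sample: mean spectrum, optional image patch, reference values."""

    sample_id: str
    mean_spectrum: np.ndarray
    concentrations: np.ndarray | None = None
    patch: np.ndarray | None = None
    analyte_names: tuple[str, ...] = ANALYTE_NAMES

    def __post_init__(self) -> None:
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=float)
        if self.concentrations is not None:
            self.concentrations = np.asarray(self.concentrations, dtype=float)
            if self.concentrations.shape != (len(self.analyte_names),):
                raise ValueError(
                    f"expected {len(self.analyte_names)} concentrations, "
                    f"got shape {self.concentrations.shape}"
                )
            if np.any(self.concentrations < 0):
                raise ValueError("concentrations must be >= 0")


def build_mask(
    cube: HyperspectralCube,
    band_nm: float = DEFAULT_BAND_NM,
    min_area: int = DEFAULT_MIN_AREA,
    threshold: float | None = None,
    foreground_is_dark: bool = True,
) -> SegmentMask:
    """Threshold one band, clean up, and label connected segments.

    Otsu's threshold on the band nearest ``band_nm`` unless a fixed
    ``threshold`` is given; plant tissue is the *dark* class on a bright plate
    (``foreground_is_dark``).  A 3x3 binary opening suppresses speckle and
    components below ``min_area`` pixels are dropped before row-major
    relabeling.
    """
    if cube.mode != "reflectance":
        raise ValueError("build_mask expects a reflectance-mode cube")
    image = cube.band_image(band_nm)
    if threshold is None:
        if np.ptp(image) == 0:
            # uniform frame: everything is one class; treat as all-foreground
            binary = np.ones_like(image, dtype=bool)
        else:
            t = threshold_otsu(image)
            binary = image < t if foreground_is_dark else image > t
    else:
        binary = image < threshold if foreground_is_dark else image > threshold

    # opening with a closed border: erode treating outside as foreground so a
    # frame-filling region survives, dilate with the usual open border
    struct = np.ones((3, 3), dtype=bool)
    binary = ndimage.binary_dilation(
        ndimage.binary_erosion(binary, structure=struct, border_value=1),
        structure=struct,
    )
    labels, n = ndimage.label(binary)
    if n:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= min_area) + 1
        # relabel kept components 1..k in row-major order of first appearance
        remap = np.zeros(n + 1, dtype=int)
        order = sorted(keep, key=lambda lab: int(np.argmax(labels.ravel() == lab)))
        for new, lab in enumerate(order, start=1):
            remap[lab] = new
        labels = remap[labels]
        n = len(order)
    if n == 0:
        warnings.warn("empty mask: no foreground segments found", stacklevel=2)
    actual_nm = float(cube.bands.wavelengths_nm[cube.bands.nearest_band(band_nm)])
    return SegmentMask(labels=labels, n_segments=n, band_used_nm=actual_nm)


def mean_spectrum(
    cube: HyperspectralCube,
    mask: SegmentMask,
    segment: int | str = "all",
) -> np.ndarray:
    """Arithmetic mean spectrum over the pixels of one segment or of the whole
    foreground (``segment="all"``)."""
    if segment == "all":
        if mask.n_segments < 1:
            raise ValueError("mask has no foreground segments")
        sel = mask.foreground
    else:
        if not (1 <= int(segment) <= mask.n_segments):
            raise ValueError(f"segment {segment} not in mask (1..{mask.n_segments})")
        sel = mask.segment_pixels(int(segment))
    if not sel.any():
        raise ValueError("empty pixel selection")
    return cube.data[sel].mean(axis=0)


def records_to_table(records: list[SampleRecord], wavelengths_nm: np.ndarray):
    """Sample table: id, analyte columns, one column per wavelength-named band."""
    import pandas as pd

    rows = {}
    for rec in records:
        row: dict = {}
        if rec.concentrations is not None:
            row.update(dict(zip(rec.analyte_names, rec.concentrations)))
        row.update(
            {f"R_{wl:.2f}nm": v for wl, v in zip(wavelengths_nm, rec.mean_spectrum)}
        )
        rows[rec.sample_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return table
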