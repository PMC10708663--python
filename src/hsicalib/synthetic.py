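"""Synthetic hyperspectral plates with known concentration ground truth.

The generator emulates the statistical structure a plate-scanning VIS/NIR
instrument produces when imaging dried plant segments whose reflectance
depends on a handful of constituent concentrations:

* five analyte concentrations drawn from a truncated multivariate normal
  whose per-analyte bounds and means follow the reference panel (four marker
  metabolites of *Salvia miltiorrhiza* plus moisture, mass fractions), with a
  configurable cross-correlation (default 0.64) between the two tanshinones;
* a Beer-Lambert-style forward model: per-pixel absorbance is a linear mix of
  synthetic endmember absorptivity curves (sums of Gaussian peaks between 450
  and 1000 nm — structural stand-ins, not measured spectra), modulated by a
  smooth spatial field; reflectance is ``10**(-A)``;
* segments laid out as a 6-per-row x 5-per-column disc grid on a bright
  plate, plus white/dark reference frames and Gaussian detector noise, so the
  raw cubes exercise the full calibration -> segmentation -> spectra path.

Everything is seeded and bit-reproducible.  An optional multiplicative
scattering term (off by default) curves the reflectance-concentration
relation the way real plate data does.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .hsi_core import (
    BandAxis, HyperspectralCube, ReferenceFrames, calibrate_reflectance,
    default_band_axis, write_cube,
)
from .segmentation import ANALYTE_NAMES, SampleRecord, SegmentMask, build_mask, mean_spectrum

__all__ = [
    "ComponentSpectrum", "SyntheticConfig", "GroundTruth",
    "default_concentration_bounds", "make_endmembers",
    "sample_concentrations", "render_cube", "generate_dataset",
]

#: (min, max, mean) mass fractions of the calibration panel
DEFAULT_BOUNDS = {
    "salvianolic_acid_B": (0.223, 2.064, 1.231),
    "dihydrotanshinone_I": (0.001, 0.064, 0.007),
    "cryptotanshinone": (0.005, 0.184, 0.031),
    "tanshinone_IIA": (0.009, 0.136, 0.053),
    "moisture": (0.057, 0.085, 0.071),
}

#: the two tanshinones carry the embedded cross-correlation
DEFAULT_CORR_PAIR = (2, 3)
DEFAULT_CORRELATION = 0.64

#: fraction of the distance from the mean to the nearest bound used as the
#: marginal sd; keeps truncation mild so the embedded correlation survives
SD_BOUND_FRACTION = 0.35


def default_concentration_bounds() -> dict[str, tuple[float, float, float]]:
    return dict(DEFAULT_BOUNDS)


@dataclass(frozen=True)
class ComponentSpectrum:
    """Synthetic absorptivity curve of one analyte (a.u. per unit mass
    fraction); a sum of Gaussian peaks, non-negative by construction."""

    analyte_name: str
    absorptivity: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.absorptivity, dtype=float)
        if np.any(a < 0):
            raise ValueError("absorptivity must be non-negative")
        object.__setattr__(self, "absorptivity", a)


@dataclass
class SyntheticConfig:
    """Generator parameters.

    The spatial geometry defaults to a compact 100x120-pixel plate (6 x 5 disc
    grid, radius 8) so a full dataset renders in seconds; pass
    ``instrument_geometry=True`` for the full 703x800 frame.
    """

    n_samples: int = 187
    concentration_bounds: dict = field(default_factory=default_concentration_bounds)
    cross_correlation: float = DEFAULT_CORRELATION
    correlated_pair: tuple[int, int] = DEFAULT_CORR_PAIR
    noise_sd: float = 0.01
    spatial_field_sd: float = 0.03
    baseline_absorbance: float = 0.15
    plate_reflectance: float = 0.92
    grid_rows: int = 5
    grid_cols: int = 6
    segment_radius_px: int = 8
    cell_px: int = 20
    patch_px: int = 8
    n_bands: int = 128
    patch_mode: str = "absorbance"  # network input mode; or "reflectance"
    scattering: float = 0.0  # multiplicative non-bilinear term, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 5:
            raise ValueError("n_samples must be >= 5")
        if not -1.0 < self.cross_correlation < 1.0:
            raise ValueError("|cross_correlation| must be < 1")
        for name, (lo, hi, mean) in self.concentration_bounds.items():
            if not lo < hi:
                raise ValueError(f"{name}: bound min must be < max")
            if not lo <= mean <= hi:
                raise ValueError(f"{name}: mean must lie within bounds")

    @property
    def analyte_names(self) -> tuple[str, ...]:
        return tuple(self.concentration_bounds)

    @property
    def plate_shape(self) -> tuple[int, int]:
        return (self.grid_rows * self.cell_px, self.grid_cols * self.cell_px)

    def band_axis(self) -> BandAxis:
        return default_band_axis(self.n_bands)

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["concentration_bounds"] = {
            k: list(v) for k, v in self.concentration_bounds.items()
        }
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticConfig":
        payload = dict(payload)
        if "concentration_bounds" in payload:
            payload["concentration_bounds"] = {
                k: tuple(v) for k, v in payload["concentration_bounds"].items()
            }
        if "correlated_pair" in payload:
            payload["correlated_pair"] = tuple(payload["correlated_pair"])
        return cls(**payload)


@dataclass
class GroundTruth:
    """What the generator knows: the table, masks, and endmembers used."""

    concentrations: pd.DataFrame
    endmembers: list[ComponentSpectrum]
    segment_masks: list[np.ndarray] = field(default_factory=list)


# ---------------------------------------------------------------------------
# endmembers
# ---------------------------------------------------------------------------

def make_endmembers(config: SyntheticConfig) -> list[ComponentSpectrum]:
    """Seeded library of 5 absorptivity curves, 2-4 Gaussian peaks each.

    Peak amplitudes are scaled inversely to the analyte's mean concentration
    so every analyte contributes a comparable (~0.25 a.u.) absorbance at its
    mean — without this the trace constituents would be spectroscopically
    invisible.
    """
    rng = np.random.default_rng(config.seed + 104729)  # decoupled from sampling
    wl = config.band_axis().wavelengths_nm
    out = []
    for name, (lo, hi, mean) in config.concentration_bounds.items():
        n_peaks = int(rng.integers(2, 5))
        curve = np.zeros_like(wl)
        for _ in range(n_peaks):
            center = rng.uniform(450.0, 1000.0)
            width = rng.uniform(20.0, 60.0)
            amp = rng.uniform(0.6, 1.4)
            curve += amp * np.exp(-((wl - center) ** 2) / (2 * width**2))
        curve *= 0.25 / (mean * curve.max())
        out.append(ComponentSpectrum(analyte_name=name, absorptivity=curve))
    return out


# ---------------------------------------------------------------------------
# concentrations
# ---------------------------------------------------------------------------

def _covariance(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    bounds = list(config.concentration_bounds.values())
    means = np.array([m for _, _, m in bounds])
    sds = np.array(
        [SD_BOUND_FRACTION * min(m - lo, hi - m) for lo, hi, m in bounds]
    )
    corr = np.eye(len(bounds))
    i, j = config.correlated_pair
    corr[i, j] = corr[j, i] = config.cross_correlation
    cov = corr * np.outer(sds, sds)
    return means, cov


def sample_concentrations(
    config: SyntheticConfig, n_samples: int | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Truncated multivariate normal concentration table (samples x 5).

    Rejection sampling against the per-analyte bounds; the marginal sds are a
    fixed fraction of the distance from the mean to the nearest bound, so
    rejection is rare and the embedded correlation survives truncation.
    """
    n = n_samples if n_samples is not None else config.n_samples
    rng = np.random.default_rng(config.seed if seed is None else seed)
    means, cov = _covariance(config)
    lows = np.array([lo for lo, _, _ in config.concentration_bounds.values()])
    highs = np.array([hi for _, hi, _ in config.concentration_bounds.values()])

    rows = []
    attempts = 0
    while sum(len(r) for r in rows) < n:
        if attempts > 1000:
            raise RuntimeError(
                "rejection sampling cap reached: bounds and correlation are "
                "jointly infeasible"
            )
        draw = rng.multivariate_normal(means, cov, size=n, method="cholesky")
        ok = np.all((draw >= lows) & (draw <= highs), axis=1)
        rows.append(draw[ok])
        attempts += 1
    table = np.vstack(rows)[:n]
    return pd.DataFrame(table, columns=list(config.analyte_names))


# ---------------------------------------------------------------------------
# forward optical model
# ---------------------------------------------------------------------------

def _grid_centers(config: SyntheticConfig) -> list[tuple[int, int]]:
    half = config.cell_px // 2
    return [
        (r * config.cell_px + half, c * config.cell_px + half)
        for r in range(config.grid_rows)
        for c in range(config.grid_cols)
    ]


def _truth_mask(config: SyntheticConfig) -> np.ndarray:
    h, w = config.plate_shape
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros((h, w), dtype=int)
    for k, (cy, cx) in enumerate(_grid_centers(config), start=1):
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= config.segment_radius_px**2
        labels[inside] = k
    return labels


def _white_dark(config: SyntheticConfig) -> ReferenceFrames:
    wl = config.band_axis().wavelengths_nm
    envelope = 0.65 + 0.35 * np.exp(-((wl - 700.0) ** 2) / (2 * 250.0**2))
    white = 40000.0 * envelope
    dark = 600.0 + 2.0 * np.arange(config.n_bands)
    return ReferenceFrames(white=white, dark=dark)


def render_cube(
    concentrations: np.ndarray,
    endmembers: list[ComponentSpectrum],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[HyperspectralCube, ReferenceFrames, np.ndarray]:
    """Render one plate: raw-count cube, reference frames, truth mask.

    Tissue pixels follow ``A(lambda) = sum_k conc_k * eps_k(lambda) *
    (1 + field) + baseline`` with a smooth zero-mean spatial field;
    ``R = 10**(-A)``; raw counts are ``dark + R * (white - dark)`` plus
    Gaussian noise of sd ``noise_sd * (white - dark)``.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    rng = rng or np.random.default_rng(config.seed)
    axis = config.band_axis()
    h, w = config.plate_shape
    truth = _truth_mask(config)
    refs = _white_dark(config)

    eps = np.stack([e.absorptivity for e in endmembers])          # (5, B)
    mix = conc @ eps                                              # (B,)
    reflectance = np.empty((h, w, config.n_bands), dtype=float)
    reflectance[...] = config.plate_reflectance

    if config.spatial_field_sd > 0:
        coarse = rng.normal(0.0, config.spatial_field_sd, size=(h // 10 + 2, w // 10 + 2))
        from scipy.ndimage import zoom

        fld = zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)[:h, :w]
    else:
        fld = np.zeros((h, w))

    tissue = truth > 0
    A = mix[None, :] * (1.0 + fld[tissue][:, None]) + config.baseline_absorbance
    R = 10.0 ** (-A)
    if config.scattering > 0:
        # multiplicative scatter: per-pixel gain curving the linear mix
        gain = 1.0 + config.scattering * rng.normal(size=(int(tissue.sum()), 1))
        R = np.clip(R * gain, 1e-4, 1.4)
    reflectance[tissue] = R

    span = refs.white - refs.dark
    raw = refs.dark + reflectance * span
    if config.noise_sd > 0:
        raw = raw + rng.normal(0.0, config.noise_sd, size=raw.shape) * span
    raw = np.clip(raw, 0.0, 65535.0)
    cube = HyperspectralCube(raw, axis, mode="raw")
    return cube, refs, truth


def _extract_patch(refl: HyperspectralCube, size: int, mode: str = "absorbance") -> np.ndarray:
    """Whole-plate view block-averaged to ``size x size`` (bands preserved).

    Feeding the resized full plate, rather than a crop of one segment, lets
    the smooth illumination/scatter field average out across segments exactly
    as it does in the plate-mean spectrum.  ``mode="absorbance"`` applies the
    Beer-Lambert linearizing log transform, the recommended input space for
    calibration models on this kind of data.
    """
    from .hsi_core import ABSORBANCE_REFLECTANCE_FLOOR

    data = refl.data
    if mode == "absorbance":
        data = np.log10(1.0 / np.maximum(data, ABSORBANCE_REFLECTANCE_FLOOR))
    elif mode != "reflectance":
        raise ValueError(f"unknown patch mode {mode!r}")
    h, w, b = data.shape
    fr, fc = h // size, w // size
    if fr < 1 or fc < 1:
        raise ValueError(f"plate {h}x{w} is smaller than the patch size {size}")
    trim_r, trim_c = (h - fr * size) // 2, (w - fc * size) // 2
    core = data[trim_r:trim_r + fr * size, trim_c:trim_c + fc * size, :]
    return core.reshape(size, fr, size, fc, b).mean(axis=(1, 3))


def generate_dataset(
    config: SyntheticConfig,
    out_dir: str | None = None,
    with_patches: bool = True,
    use_truth_mask: bool = False,
) -> tuple[list[SampleRecord], GroundTruth]:
    """End-to-end dataset: concentrations -> raw cubes -> reflectance ->
    masks -> mean spectra (+ a patch around a central segment).

    By default the pipeline's own mask (Otsu + opening + labeling) supplies
    the foreground; ``use_truth_mask`` short-circuits it with the generator's
    disc layout.  With ``out_dir`` set, an HDF5 container per sample, the
    reference CSV and a ground-truth JSON sidecar are written.
    """
    table = sample_concentrations(config)
    endmembers = make_endmembers(config)
    rng = np.random.default_rng(config.seed + 1)
    names = tuple(config.analyte_names)

    records: list[SampleRecord] = []
    masks: list[np.ndarray] = []
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)

    for i in range(config.n_samples):
        conc = table.iloc[i].to_numpy()
        raw, refs, truth = render_cube(conc, endmembers, config, rng=rng)
        refl = calibrate_reflectance(raw, refs)
        if use_truth_mask:
            mask = SegmentMask(truth, int(truth.max()), band_used_nm=850.0)
        else:
            mask = build_mask(refl)
        spectrum = mean_spectrum(refl, mask, "all")
        patch = (
            _extract_patch(refl, config.patch_px, config.patch_mode)
            if with_patches else None
        )
        rec = SampleRecord(
            sample_id=f"sample_{i:04d}",
            mean_spectrum=spectrum,
            concentrations=conc,
            patch=patch,
            analyte_names=names,
        )
        records.append(rec)
        masks.append(truth)
        if out_dir:
            write_cube(os.path.join(out_dir, f"{rec.sample_id}.h5"), refl,
                       dialect="hdf5", refs=refs)

    truth_obj = GroundTruth(concentrations=table, endmembers=endmembers,
                            segment_masks=masks)
    if out_dir:
        table.to_csv(os.path.join(out_dir, "reference_concentrations.csv"),
                     index_label="sample_index")
        sidecar = {
            "config": config.to_dict(),
            "endmembers": {
                e.analyte_name: [float(v) for v in e.absorptivity]
                for e in endmembers
            },
        }
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)
    return records, truth_obj
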