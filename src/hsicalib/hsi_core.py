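"""Hyperspectral cube container, ENVI/HDF5 I/O, and radiometric calibration.

A hyperspectral cube is a 3-D array indexed ``(row, col, band)`` in which every
spatial pixel carries a full spectrum.  Cubes move through three modes:

``raw``
    detector counts straight off the camera (unsigned integers);
``reflectance``
    relative reflectance obtained from white/dark reference frames,
    ``R = (I - D) / (W - D)``;
``absorbance``
    ``A = log10(1 / R)``, which linearises concentration-signal relations
    under Beer-Lambert assumptions.

The default band axis matches a visible/NIR line-scan instrument: 128 bands
from 380 nm sampled every 5.38 nm (instrument spectral resolution 10 nm is
carried as metadata only; the data grid uses the sampling interval).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "BandAxis",
    "HyperspectralCube",
    "ReferenceFrames",
    "CalibrationError",
    "CubeFormatError",
    "CubeConsistencyError",
    "CubeModeError",
    "default_band_axis",
    "calibrate_reflectance",
    "to_absorbance",
    "read_cube",
    "write_cube",
]

#: nominal acquisition defaults
DEFAULT_N_BANDS = 128
DEFAULT_START_NM = 380.0
DEFAULT_SAMPLING_NM = 5.38
DEFAULT_RESOLUTION_NM = 10.0
DEFAULT_HEIGHT_PX = 703
DEFAULT_WIDTH_PX = 800

#: numerical floors (see docs/methods.md)
REFLECTANCE_DENOM_FLOOR = 1e-6
REFLECTANCE_CLIP_MAX = 1.5
ABSORBANCE_REFLECTANCE_FLOOR = 1e-4


class CubeFormatError(ValueError):
    """Malformed on-disk header or payload."""


class CubeConsistencyError(ValueError):
    """Header metadata contradicts the data payload."""


class CubeModeError(ValueError):
    """Operation applied to a cube in the wrong mode."""


class CalibrationError(ValueError):
    """White and dark references coincide where a pixel must be calibrated."""


@dataclass(frozen=True)
class BandAxis:
    """Band-center wavelengths of a cube, strictly increasing, in nm."""

    wavelengths_nm: np.ndarray
    sampling_interval_nm: float = DEFAULT_SAMPLING_NM
    resolution_nm: float = DEFAULT_RESOLUTION_NM

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("band axis needs at least 2 wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def nearest_band(self, wavelength_nm: float) -> int:
        """Index of the band center closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))


def default_band_axis(
    n_bands: int = DEFAULT_N_BANDS,
    start_nm: float = DEFAULT_START_NM,
    sampling_nm: float = DEFAULT_SAMPLING_NM,
    resolution_nm: float = DEFAULT_RESOLUTION_NM,
) -> BandAxis:
    """Linear axis ``start + i * sampling``, i = 0..n_bands-1 (380-1063.66 nm
    for the defaults, i.e. the nominal 380-1064 nm span)."""
    wl = start_nm + sampling_nm * np.arange(n_bands)
    return BandAxis(wl, sampling_interval_nm=sampling_nm, resolution_nm=resolution_nm)


@dataclass
class HyperspectralCube:
    """3-D spectral image, ``data[row, col, band]``."""

    data: np.ndarray
    bands: BandAxis
    mode: str = "raw"

    _MODES = ("raw", "reflectance", "absorbance")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (row, col, band)")
        if self.data.shape[2] != len(self.bands):
            raise CubeConsistencyError(
                f"cube has {self.data.shape[2]} band planes but the axis "
                f"lists {len(self.bands)} wavelengths"
            )
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}")
        if self.mode == "reflectance":
            if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
                raise ValueError("reflectance values must be finite and >= 0")

    @property
    def height_px(self) -> int:
        return self.data.shape[0]

    @property
    def width_px(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_image(self, wavelength_nm: float) -> np.ndarray:
        """2-D image of the band nearest to ``wavelength_nm``."""
        return self.data[:, :, self.bands.nearest_band(wavelength_nm)]


@dataclass(frozen=True)
class ReferenceFrames:
    """White and dark reference frames, broadcastable against a cube.

    Either full ``(H, W, B)`` frames or per-band ``(B,)`` vectors.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "white", np.asarray(self.white, dtype=float))
        object.__setattr__(self, "dark", np.asarray(self.dark, dtype=float))


def calibrate_reflectance(
    raw: HyperspectralCube,
    refs: ReferenceFrames,
    denom_floor: float = REFLECTANCE_DENOM_FLOOR,
    clip_max: float = REFLECTANCE_CLIP_MAX,
) -> HyperspectralCube:
    """Raw counts to relative reflectance, ``R = (I - D) / (W - D)``.

    The denominator is floored at ``denom_floor`` and the output clipped to
    ``[0, clip_max]`` to tolerate specular pixels.  Positions where white and
    dark coincide cannot be calibrated.
    """
    if raw.mode != "raw":
        raise CubeModeError(f"expected a raw-mode cube, got {raw.mode!r}")
    intensity = raw.data.astype(float)
    denom = np.broadcast_to(refs.white - refs.dark, intensity.shape)
    if np.any(denom <= 0):
        raise CalibrationError(
            "white reference does not exceed dark reference at every position"
        )
    refl = (intensity - refs.dark) / np.maximum(denom, denom_floor)
    refl = np.clip(refl, 0.0, clip_max)
    return HyperspectralCube(refl, raw.bands, mode="reflectance")


def to_absorbance(
    refl: HyperspectralCube, floor: float = ABSORBANCE_REFLECTANCE_FLOOR
) -> HyperspectralCube:
    """Reflectance to absorbance, ``A = log10(1 / max(R, floor))``."""
    if refl.mode != "reflectance":
        raise CubeModeError(f"expected a reflectance-mode cube, got {refl.mode!r}")
    absorb = np.log10(1.0 / np.maximum(refl.data, floor))
    return HyperspectralCube(absorb, refl.bands, mode="absorbance")


# ---------------------------------------------------------------------------
# on-disk dialects: ENVI header + BSQ raster, and an HDF5 container
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _write_envi(path: str, cube: HyperspectralCube) -> None:
    if cube.mode == "raw":
        dtype = np.uint16
    else:
        # keep the in-memory float width so round trips are bit exact
        dtype = np.float64 if cube.data.dtype == np.float64 else np.float32
    code = _ENVI_CODES[np.dtype(dtype)]
    hdr_path = path + ".hdr"
    wl = ", ".join(f"{w:.4f}" for w in cube.bands.wavelengths_nm)
    header = (
        "ENVI\n"
        f"samples = {cube.width_px}\n"
        f"lines = {cube.height_px}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"mode = {cube.mode}\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(hdr_path, "w") as fh:
        fh.write(header)
    # BSQ: band-sequential planes, little-endian
    planes = np.ascontiguousarray(np.moveaxis(cube.data, 2, 0)).astype(
        np.dtype(dtype).newbyteorder("<")
    )
    planes.tofile(path)


def _parse_envi_header(hdr_path: str) -> dict:
    with open(hdr_path) as fh:
        text = fh.read()
    if not text.lstrip().startswith("ENVI"):
        raise CubeFormatError(f"{hdr_path}: missing ENVI magic")
    fields: dict = {}
    # collapse brace-delimited multi-line values
    buf = text.replace("\n", " \n")
    i = 0
    for line in _iter_header_entries(buf):
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
        i += 1
    if i == 0:
        raise CubeFormatError(f"{hdr_path}: no key = value entries")
    return fields


def _iter_header_entries(text: str):
    entry = ""
    depth = 0
    for line in text.splitlines():
        entry += line
        depth += line.count("{") - line.count("}")
        if depth == 0:
            if entry.strip():
                yield entry
            entry = ""
        else:
            entry += " "
    if entry.strip():
        raise CubeFormatError("unterminated '{' block in header")


def _read_envi(path: str) -> HyperspectralCube:
    hdr_path = path + ".hdr"
    if not os.path.exists(hdr_path):
        raise FileNotFoundError(hdr_path)
    fields = _parse_envi_header(hdr_path)
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except (KeyError, ValueError) as exc:
        raise CubeFormatError(f"{hdr_path}: missing or invalid field ({exc})")
    if interleave != "bsq":
        raise CubeFormatError(f"only BSQ interleave is supported, got {interleave!r}")
    if code not in _ENVI_DTYPES:
        raise CubeFormatError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code]).newbyteorder("<")
    flat = np.fromfile(path, dtype=dtype)
    expected = samples * lines * bands
    if flat.size != expected:
        raise CubeConsistencyError(
            f"{path}: header declares {bands} bands of {lines}x{samples} "
            f"({expected} values) but file holds {flat.size}"
        )
    data = np.moveaxis(flat.reshape(bands, lines, samples), 0, 2)
    wl_text = fields.get("wavelength", "").strip().strip("{}").strip()
    if wl_text:
        wl = np.array([float(w) for w in wl_text.split(",")])
        if wl.size != bands:
            raise CubeConsistencyError(
                f"{hdr_path}: {wl.size} wavelengths for {bands} bands"
            )
    else:
        wl = default_band_axis(bands).wavelengths_nm
    axis = BandAxis(wl)
    mode = fields.get("mode", "raw")
    return HyperspectralCube(data.astype(float), axis, mode=mode)


def _write_hdf5(
    path: str, cube: HyperspectralCube, refs: ReferenceFrames | None = None
) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cube", data=cube.data)
        fh.create_dataset("wavelengths_nm", data=cube.bands.wavelengths_nm)
        fh.attrs["mode"] = cube.mode
        fh.attrs["sampling_interval_nm"] = cube.bands.sampling_interval_nm
        fh.attrs["resolution_nm"] = cube.bands.resolution_nm
        if refs is not None:
            fh.create_dataset("white", data=refs.white)
            fh.create_dataset("dark", data=refs.dark)


def _read_hdf5(path: str) -> tuple[HyperspectralCube, ReferenceFrames | None]:
    with h5py.File(path, "r") as fh:
        data = fh["cube"][...]
        wl = fh["wavelengths_nm"][...]
        mode = fh.attrs.get("mode", "raw")
        axis = BandAxis(
            wl,
            sampling_interval_nm=float(fh.attrs.get("sampling_interval_nm", DEFAULT_SAMPLING_NM)),
            resolution_nm=float(fh.attrs.get("resolution_nm", DEFAULT_RESOLUTION_NM)),
        )
        refs = None
        if "white" in fh and "dark" in fh:
            refs = ReferenceFrames(fh["white"][...], fh["dark"][...])
    return HyperspectralCube(data, axis, mode=str(mode)), refs


def write_cube(
    path: str,
    cube: HyperspectralCube,
    dialect: str = "envi",
    refs: ReferenceFrames | None = None,
) -> None:
    """Write a cube to disk.

    ``dialect="envi"``: text header at ``path + '.hdr'`` plus BSQ binary at
    ``path`` (float32 for calibrated modes, uint16 for raw).
    ``dialect="hdf5"``: portable container with datasets ``/cube``,
    ``/wavelengths_nm`` and optional ``/white``, ``/dark``.
    """
    if dialect == "envi":
        _write_envi(path, cube)
    elif dialect == "hdf5":
        _write_hdf5(path, cube, refs)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_cube(path: str, dialect: str = "envi") -> HyperspectralCube:
    """Read a cube written by :func:`write_cube`; mode defaults to raw if the
    header does not state one."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "envi":
        return _read_envi(path)
    if dialect == "hdf5":
        cube, _ = _read_hdf5(path)
        return cube
    raise ValueError(f"unknown dialect {dialect!r}")


def read_cube_with_refs(path: str) -> tuple[HyperspectralCube, ReferenceFrames | None]:
    """HDF5-only variant returning the stored reference frames as well."""
    return _read_hdf5(path)
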