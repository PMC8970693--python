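"""Hyperspectral scenes: containers, synthesis, and file I/O.

A scene is a hypercube ``H(x, y, lambda)`` of shape ``(N, M, Q)`` — two
spatial axes and one spectral axis.  Scenes may be measured directly or
synthesized from an abundance map ``A(x, y)`` of shape ``(N, M, L)`` and an
endmember matrix ``E`` of shape ``(Q, L)`` via the linear mixing model

    H(n, m, :) = E @ A(n, m) + noise

with optional i.i.d. Gaussian noise per (pixel, band).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SpectralAxis",
    "Hypercube",
    "EndmemberLibrary",
    "AbundanceMap",
    "hypercube_from_abundance",
    "synthesize_scene",
    "read_hypercube",
    "write_hypercube",
]


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing wavelength grid in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength axis must be 1-D with at least 2 points")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelength axis must be finite")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return (
            self.wavelengths.shape == other.wavelengths.shape
            and np.array_equal(self.wavelengths, other.wavelengths)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.wavelengths.size, self.wavelengths.tobytes()))

    @classmethod
    def regular(cls, start: float, stop: float, step: float) -> "SpectralAxis":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))


@dataclass
class Hypercube:
    """Radiance cube of shape ``(N, M, Q)`` on a :class:`SpectralAxis`.

    Layout is (row, col, band), origin top-left, 0-based.  Units are
    arbitrary; downstream merit functions compare abundances, which are
    unitless.
    """

    data: np.ndarray
    axis: SpectralAxis

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("hypercube data must be 3-D (rows, cols, bands)")
        if self.data.shape[2] != self.axis.n_bands:
            raise ValueError(
                f"band axis ({self.data.shape[2]}) does not match the "
                f"wavelength axis ({self.axis.n_bands})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("hypercube data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class EndmemberLibrary:
    """Pure spectra as columns of a ``(Q, L)`` matrix, with names."""

    E: np.ndarray
    names: Sequence[str]
    axis: SpectralAxis

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.ndim != 2:
            raise ValueError("endmember matrix must be 2-D (bands, endmembers)")
        if self.E.shape[0] != self.axis.n_bands:
            raise ValueError("endmember matrix rows must match the wavelength axis")
        if self.E.shape[1] < 1:
            raise ValueError("need at least one endmember")
        if np.any(self.E < 0):
            raise ValueError("endmember spectra must be nonnegative")
        self.names = list(self.names)
        if len(self.names) != self.E.shape[1]:
            raise ValueError("one name per endmember required")

    @property
    def n_endmembers(self) -> int:
        return self.E.shape[1]


@dataclass
class AbundanceMap:
    """Per-pixel nonnegative endmember coefficients, shape ``(N, M, L)``."""

    A: np.ndarray
    names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 3:
            raise ValueError("abundance map must be 3-D (rows, cols, endmembers)")
        if np.any(self.A < 0):
            raise ValueError("abundances must be nonnegative")
        self.names = list(self.names) or [f"em{i}" for i in range(self.A.shape[2])]

    @property
    def n_endmembers(self) -> int:
        return self.A.shape[2]


def hypercube_from_abundance(
    abundance: AbundanceMap,
    library: EndmemberLibrary,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    clip_negative: bool = True,
) -> Hypercube:
    """Synthesize a hypercube from the linear mixing model.

    Parameters
    ----------
    abundance, library
        Map ``A`` of shape (N, M, L) and endmembers ``E`` of shape (Q, L);
        the pixel spectrum is ``E @ A(n, m)``.
    noise_sigma
        Standard deviation of additive i.i.d. Gaussian noise per
        (pixel, band); 0 gives the exact product.
    clip_negative
        Clip noise-induced negative radiance at 0 (on by default to keep
        the cube physical).
    """
    if abundance.n_endmembers != library.n_endmembers:
        raise ValueError(
            f"abundance map has {abundance.n_endmembers} endmembers but the "
            f"library has {library.n_endmembers}"
        )
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    data = np.einsum("ql,nml->nmq", library.E, abundance.A)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
        if clip_negative:
            data = np.clip(data, 0.0, None)
    return Hypercube(data, library.axis)


def _smooth_field(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """Smooth nonnegative random field in [0, 1] via low-order cosines."""
    yy, xx = np.meshgrid(
        np.linspace(0, 1, n), np.linspace(0, 1, m), indexing="ij"
    )
    f = np.zeros((n, m))
    for _ in range(4):
        fy, fx = rng.uniform(0.3, 1.2, size=2)
        py, px = rng.uniform(0, 2 * np.pi, size=2)
        f += rng.uniform(0.3, 1.0) * np.cos(2 * np.pi * fy * yy + py) * np.cos(
            2 * np.pi * fx * xx + px
        )
    f -= f.min()
    peak = f.max()
    if peak > 0:
        f /= peak
    return f


def _gaussian(wl: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((wl - center) / s) ** 2)


def synthesize_scene(
    n_rows: int,
    n_cols: int,
    axis: SpectralAxis,
    n_endmembers: int,
    scene_kind: str = "reflectance",
    seed: int | None = None,
) -> tuple[Hypercube, AbundanceMap, EndmemberLibrary]:
    """Generate a synthetic scene with known ground truth.

    ``reflectance`` scenes emulate remote-sensing cubes (Samson / Jasper
    Ridge style): a few spatially smooth abundance fields with per-pixel sum
    <= 1, and smooth broad-featured endmember spectra.  ``fluorescence``
    scenes emulate dye-emission imaging: narrowband single-peak endmembers
    (FWHM 20-50 nm) plus one broadband illumination endmember as the last
    column.  Deterministic for a fixed seed; noise is added separately via
    :func:`hypercube_from_abundance`.
    """
    if n_endmembers < 1:
        raise ValueError("n_endmembers must be >= 1")
    if scene_kind not in ("reflectance", "fluorescence"):
        raise ValueError(f"unknown scene_kind {scene_kind!r}")
    rng = np.random.default_rng(seed)
    wl = axis.wavelengths
    lo, hi = axis.range
    span = hi - lo

    if n_endmembers > axis.n_bands:
        warnings.warn(
            "more endmembers than spectral bands; they cannot all be "
            "spectrally separable",
            stacklevel=2,
        )

    names: list[str]
    if scene_kind == "reflectance":
        E = np.zeros((axis.n_bands, n_endmembers))
        for i in range(n_endmembers):
            n_lobes = rng.integers(2, 5)
            for _ in range(n_lobes):
                c = rng.uniform(lo, hi)
                w = rng.uniform(0.25 * span, 0.6 * span)
                E[:, i] += rng.uniform(0.2, 1.0) * _gaussian(wl, c, w)
            E[:, i] += 0.05
        names = [f"material{i}" for i in range(n_endmembers)]
    else:
        # emission peaks plus broadband illumination; real dye panels crowd
        # their peaks into the lower half of the detection window
        E = np.zeros((axis.n_bands, n_endmembers))
        n_dyes = max(n_endmembers - 1, 1)
        if n_dyes == 1:
            rel = np.array([0.35])
        else:
            rel = 0.1 + 0.5 * np.arange(n_dyes) / (n_dyes - 1)
        centers = lo + span * rel
        centers = centers + rng.uniform(-0.02 * span, 0.02 * span, size=n_dyes)
        for i in range(n_dyes):
            E[:, i] = _gaussian(wl, float(centers[i]), rng.uniform(20.0, 35.0))
        names = [f"dye{i}" for i in range(n_dyes)]
        if n_endmembers > 1:
            # multi-LED source reflectance: a comb of LED lines, one near
            # each dye's excitation/emission band plus a reference LED in
            # the dye-free long-wavelength region
            ill = np.zeros(axis.n_bands)
            for c in centers:
                ill += 0.8 * _gaussian(wl, float(c) - 0.02 * span, 0.08 * span)
            ill += _gaussian(wl, lo + 0.8 * span, 0.1 * span)
            E[:, -1] = ill / ill.max()
            names.append("illumination")

    if scene_kind == "reflectance":
        A = np.stack(
            [_smooth_field(rng, n_rows, n_cols) for _ in range(n_endmembers)],
            axis=-1,
        )
        total = A.sum(axis=-1, keepdims=True)
        A /= np.maximum(total.max(), 1.0)  # per-pixel sums <= 1
    else:
        # well-plate geometry: flat dye wells on a dark background, with the
        # illumination endmember present uniformly across the field of view
        A = np.zeros((n_rows, n_cols, n_endmembers))
        n_dyes = max(n_endmembers - 1, 1)
        if n_endmembers > 1:
            A[..., -1] = 0.3
        yy, xx = np.mgrid[0:n_rows, 0:n_cols]
        radius = max(min(n_rows, n_cols) / 6.0, 2.0)
        n_wells = n_dyes + (1 if n_dyes > 1 else 0)  # one per dye + a mixture
        for s in range(n_wells):
            ang = 2 * np.pi * s / n_wells + rng.uniform(-0.2, 0.2)
            cy = n_rows / 2 + 0.3 * n_rows * np.sin(ang)
            cx = n_cols / 2 + 0.3 * n_cols * np.cos(ang)
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            if s < n_dyes:
                A[disk, s] += rng.uniform(0.3, 0.6)
            else:
                A[disk, :n_dyes] += 0.5 / n_dyes
        # imaging-system PSF: real well edges are blurred over ~a pixel
        from scipy.ndimage import gaussian_filter

        A = gaussian_filter(A, sigma=(1.2, 1.2, 0))
        total = A.sum(axis=-1, keepdims=True)
        A *= np.where(total > 1.0, 1.0 / total, 1.0)

    library = EndmemberLibrary(E, names, axis)
    amap = AbundanceMap(A, names)
    cube = hypercube_from_abundance(amap, library, noise_sigma=0.0)
    return cube, amap, library


# ---------------------------------------------------------------------------
# File I/O: ENVI (.hdr + raw binary), HDF5 (/cube, /wavelengths), NumPy .npz
# ---------------------------------------------------------------------------

_ENVI_INTERLEAVES = {"bsq", "bil", "bip"}


def _envi_header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr") if path.suffix != ".hdr" else path


def write_hypercube(
    cube: Hypercube,
    path: str | Path,
    format: str | None = None,
    interleave: str = "bsq",
) -> None:
    """Write a hypercube to ENVI, HDF5, or ``.npz``.

    The format is inferred from the suffix (``.img`` -> ENVI, ``.h5``/
    ``.hdf5`` -> HDF5, ``.npz`` -> NumPy) unless given explicitly.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "envi":
        _write_envi(cube, path, interleave)
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("cube", data=cube.data)
            f.create_dataset("wavelengths", data=cube.axis.wavelengths)
    elif fmt == "npz":
        np.savez(path, cube=cube.data, wavelengths=cube.axis.wavelengths)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_hypercube(path: str | Path, format: str | None = None) -> Hypercube:
    """Read a hypercube, normalizing any interleave to (rows, cols, bands).

    Raises a ``KeyError`` naming the missing key when the file declares no
    wavelength axis.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "envi":
        return _read_envi(path)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            if "wavelengths" not in f:
                raise KeyError(
                    f"{path}: HDF5 file lacks the required 'wavelengths' dataset"
                )
            return Hypercube(f["cube"][...], SpectralAxis(f["wavelengths"][...]))
    if fmt == "npz":
        with np.load(path) as z:
            if "wavelengths" not in z:
                raise KeyError(
                    f"{path}: npz archive lacks the required 'wavelengths' key"
                )
            return Hypercube(z["cube"], SpectralAxis(z["wavelengths"]))
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".img", ".dat", ".hdr", ".envi"):
        return "envi"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix == ".npz":
        return "npz"
    raise ValueError(f"cannot infer hypercube format from {path.name!r}")


def _write_envi(cube: Hypercube, path: Path, interleave: str) -> None:
    interleave = interleave.lower()
    if interleave not in _ENVI_INTERLEAVES:
        raise ValueError(f"interleave must be one of {sorted(_ENVI_INTERLEAVES)}")
    n, m, q = cube.shape
    if interleave == "bsq":
        raw = np.transpose(cube.data, (2, 0, 1))
    elif interleave == "bil":
        raw = np.transpose(cube.data, (0, 2, 1))
    else:  # bip
        raw = cube.data
    raw.astype("<f8").tofile(path)
    wl = ", ".join(f"{w:.6f}" for w in cube.axis.wavelengths)
    header = (
        "ENVI\n"
        "description = {msfakit hypercube}\n"
        f"samples = {m}\n"
        f"lines = {n}\n"
        f"bands = {q}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 5\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    _envi_header_path(path).write_text(header)


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    key = None
    buf = ""
    for line in text.splitlines():
        if key is None:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip().lower()
            buf = value.strip()
        else:
            buf += " " + line.strip()
        if buf.startswith("{") and not buf.endswith("}"):
            continue  # multi-line braced value
        fields[key] = buf.strip("{} ")
        key = None
    return fields


_ENVI_DTYPES = {
    "1": "u1", "2": "<i2", "3": "<i4", "4": "<f4", "5": "<f8",
    "12": "<u2", "13": "<u4", "14": "<i8", "15": "<u8",
}


def _read_envi(path: Path) -> Hypercube:
    if path.suffix == ".hdr":
        hdr_path = path
        data_path = path.with_suffix("")
        if not data_path.exists():
            for ext in (".img", ".dat"):
                cand = path.with_suffix(ext)
                if cand.exists():
                    data_path = cand
                    break
    else:
        data_path = path
        hdr_path = _envi_header_path(path)
    fields = _parse_envi_header(hdr_path.read_text())
    if "wavelength" not in fields:
        raise KeyError(
            f"{hdr_path}: ENVI header lacks the required 'wavelength' field"
        )
    n = int(fields["lines"])
    m = int(fields["samples"])
    q = int(fields["bands"])
    interleave = fields.get("interleave", "bsq").lower()
    dtype = _ENVI_DTYPES[fields.get("data type", "5")]
    if fields.get("byte order", "0") == "1":
        dtype = dtype.replace("<", ">")
    offset = int(fields.get("header offset", "0"))
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    if interleave == "bsq":
        data = np.transpose(raw.reshape(q, n, m), (1, 2, 0))
    elif interleave == "bil":
        data = np.transpose(raw.reshape(n, q, m), (0, 2, 1))
    elif interleave == "bip":
        data = raw.reshape(n, m, q)
    else:
        raise ValueError(f"unknown ENVI interleave {interleave!r}")
    wl = np.array([float(v) for v in fields["wavelength"].split(",")])
    return Hypercube(np.ascontiguousarray(data, dtype=float), SpectralAxis(wl))


def save_scene_npz(
    path: str | Path,
    cube: Hypercube,
    abundance: AbundanceMap | None = None,
    library: EndmemberLibrary | None = None,
) -> None:
    """Write a full synthetic scene (cube + ground truth) to one ``.npz``."""
    arrays: dict[str, np.ndarray] = {
        "cube": cube.data,
        "wavelengths": cube.axis.wavelengths,
    }
    if abundance is not None:
        arrays["abundance"] = abundance.A
    if library is not None:
        arrays["endmembers"] = library.E
        arrays["names"] = np.array(library.names)
    np.savez(path, **arrays)
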