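"""Spectrum -> XYZ -> chromaticity -> sRGB conversion and RGB rendering.

Tristimulus values are trapezoidal quadratures of a spectrum against the
CIE 1931 2-degree observer color matching functions (bundled at 5 nm
spacing, linearly interpolated to the scene axis).  The RGB space is sRGB
with a D65 white point, specified by chromaticity coordinates; the
conversion matrix is the primary-chromaticity matrix with its columns
scaled so that the white point maps to R = G = B = 1.

All merit computations use linear-light RGB; the sRGB gamma transfer is
applied only when exporting images for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .demosaic import DemosaickedCube
from .hypercube import Hypercube, SpectralAxis

__all__ = [
    "CMFTable",
    "ChromaticityMatrix",
    "SRGB_D65",
    "load_cmf",
    "spectrum_to_xyz",
    "xyz_to_chromaticity",
    "xyz_to_rgb",
    "render_rgb",
    "srgb_gamma",
]


@dataclass(frozen=True)
class CMFTable:
    """Color matching functions sampled on a spectral axis."""

    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    axis: SpectralAxis

    def resampled(self, axis: SpectralAxis) -> "CMFTable":
        if axis == self.axis:
            return self
        src = self.axis.wavelengths
        dst = axis.wavelengths
        return CMFTable(
            np.interp(dst, src, self.xbar, left=0.0, right=0.0),
            np.interp(dst, src, self.ybar, left=0.0, right=0.0),
            np.interp(dst, src, self.zbar, left=0.0, right=0.0),
            axis,
        )

    @property
    def matrix(self) -> np.ndarray:
        """(3, Q) stack of xbar, ybar, zbar."""
        return np.stack([self.xbar, self.ybar, self.zbar])


def load_cmf(axis: SpectralAxis | None = None) -> CMFTable:
    """Load the bundled CIE 1931 2-degree CMFs, optionally resampled."""
    with resources.files("msfakit.data").joinpath("cie1931_cmf_5nm.csv").open() as f:
        table = np.loadtxt(f, delimiter=",")
    cmf = CMFTable(table[:, 1], table[:, 2], table[:, 3], SpectralAxis(table[:, 0]))
    return cmf.resampled(axis) if axis is not None else cmf


@dataclass(frozen=True)
class ChromaticityMatrix:
    """RGB primaries and white point as (x, y, z) chromaticity rows."""

    red: tuple[float, float, float]
    green: tuple[float, float, float]
    blue: tuple[float, float, float]
    white: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, row in (
            ("red", self.red), ("green", self.green),
            ("blue", self.blue), ("white", self.white),
        ):
            if abs(sum(row) - 1.0) > 1e-6:
                raise ValueError(f"{name} chromaticity must sum to 1, got {row}")

    @property
    def primary_matrix(self) -> np.ndarray:
        """3x3 matrix with primary chromaticities as columns."""
        return np.column_stack([self.red, self.green, self.blue])

    @property
    def white_xyz(self) -> np.ndarray:
        """White-point tristimulus scaled to Y = 1."""
        xw, yw, zw = self.white
        return np.array([xw / yw, 1.0, zw / yw])

    def rgb_from_xyz_matrix(self) -> np.ndarray:
        """Inverse of the white-point-scaled primary matrix.

        The primary chromaticity columns are scaled so that RGB = (1,1,1)
        reproduces the white-point tristimulus (Y = 1); the returned matrix
        maps XYZ to linear RGB.
        """
        C = self.primary_matrix
        scale = np.linalg.solve(C, self.white_xyz)
        return np.linalg.inv(C * scale)


#: sRGB primaries and CIE Illuminant D65 white point (chromaticities).
SRGB_D65 = ChromaticityMatrix(
    red=(0.640, 0.330, 0.030),
    green=(0.300, 0.600, 0.100),
    blue=(0.150, 0.060, 0.790),
    white=(0.313, 0.329, 0.358),
)


def _trapezoid_weights(axis: SpectralAxis) -> np.ndarray:
    wl = axis.wavelengths
    w = np.zeros_like(wl)
    dw = np.diff(wl)
    w[:-1] += 0.5 * dw
    w[1:] += 0.5 * dw
    return w


def spectrum_to_xyz(spectrum: np.ndarray, cmf: CMFTable) -> np.ndarray:
    """Tristimulus (X, Y, Z) of one spectrum (or a (..., Q) stack)."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[-1] != cmf.axis.n_bands:
        raise ValueError("spectrum length does not match the CMF axis")
    weights = cmf.matrix * _trapezoid_weights(cmf.axis)  # (3, Q)
    return spectrum @ weights.T


def xyz_to_chromaticity(
    xyz: np.ndarray, white: tuple[float, float, float] = SRGB_D65.white
) -> np.ndarray:
    """Normalize tristimulus to chromaticities (x, y, z), summing to 1.

    All-zero pixels (no light) are mapped to the white point chromaticity
    by convention.
    """
    xyz = np.asarray(xyz, dtype=float)
    total = xyz.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        chroma = xyz / total
    chroma = np.where(total > 0, chroma, np.asarray(white))
    return chroma


def xyz_to_rgb(
    xyz: np.ndarray,
    primaries: ChromaticityMatrix = SRGB_D65,
    clip: bool = True,
) -> np.ndarray:
    """Linear RGB from tristimulus via the white-point-scaled sRGB matrix.

    Out-of-gamut components are clipped to [0, 1] when ``clip`` is set.
    """
    M = primaries.rgb_from_xyz_matrix()
    rgb = np.asarray(xyz, dtype=float) @ M.T
    if clip:
        rgb = np.clip(rgb, 0.0, 1.0)
    return rgb


def srgb_gamma(linear: np.ndarray) -> np.ndarray:
    """Standard sRGB transfer function (display encoding only)."""
    linear = np.clip(linear, 0.0, 1.0)
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(linear, 1 / 2.4) - 0.055,
    )


def _spectra_to_image(
    spectra: np.ndarray, axis: SpectralAxis, primaries: ChromaticityMatrix
) -> np.ndarray:
    cmf = load_cmf(axis)
    if not np.any(cmf.ybar > 0):
        raise ValueError("scene wavelengths do not overlap the CMF support")
    xyz = spectrum_to_xyz(spectra, cmf)
    max_y = xyz[..., 1].max()
    if max_y > 0:
        xyz = xyz / max_y
    return xyz_to_rgb(xyz, primaries)


def render_rgb(
    source: Hypercube | DemosaickedCube,
    bank=None,
    primaries: ChromaticityMatrix = SRGB_D65,
) -> np.ndarray:
    """Render a scene or an MSFA result to a linear-RGB (N, M, 3) image.

    For a raw hypercube each pixel spectrum is converted directly.  For a
    demosaicked MSFA result the per-pixel spectrum is reconstructed as
    sum_j I_hat_j(n, m) * F_j(lambda) from the filter bank before
    conversion.  Intensity is normalized by the scene's maximum luminance
    Y, and components are clipped to [0, 1].
    """
    if isinstance(source, Hypercube):
        return _spectra_to_image(source.data, source.axis, primaries)
    if bank is None:
        raise ValueError("rendering an MSFA result requires the filter bank")
    spectra = np.einsum("nmj,jq->nmq", source.planes, bank.responses)
    return _spectra_to_image(spectra, bank.axis, primaries)
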