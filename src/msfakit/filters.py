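"""Spectral filter responses and per-channel signal integration.

Each MSFA channel j carries a normalized spectral response F_j(lambda)
(peak = 1).  The channel signal at a pixel is the integral of
F_j(lambda) * H(n, m, lambda) over the axis, evaluated by trapezoidal
quadrature on the cube's native wavelength grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .hypercube import EndmemberLibrary, Hypercube, SpectralAxis

__all__ = [
    "GaussianFilter",
    "TabulatedFilter",
    "FilterBank",
    "gaussian_response",
    "channel_signal",
    "channel_signals",
    "effective_endmembers",
    "bank_to_config",
    "bank_from_config",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_response(
    center: float,
    bandwidth: float,
    convention: str,
    axis: SpectralAxis,
) -> np.ndarray:
    """Sampled Gaussian response exp(-(l-c)^2 / 2 s^2), peak-normalized.

    ``convention`` selects how ``bandwidth`` parameterizes the width:
    ``"fwhm"`` gives s = bandwidth / (2 sqrt(2 ln 2)); ``"sigma"`` uses the
    bandwidth directly as the Gaussian standard deviation.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    lo, hi = axis.range
    if not (lo <= center <= hi):
        raise ValueError(
            f"filter center {center} nm outside axis range [{lo}, {hi}] nm"
        )
    if convention == "fwhm":
        s = bandwidth * _FWHM_TO_SIGMA
    elif convention == "sigma":
        s = bandwidth
    else:
        raise ValueError("convention must be 'fwhm' or 'sigma'")
    return np.exp(-0.5 * ((axis.wavelengths - center) / s) ** 2)


@dataclass(frozen=True)
class GaussianFilter:
    """Gaussian bandpass filter with center and bandwidth in nm."""

    center: float
    bandwidth: float
    convention: str = "fwhm"

    def response(self, axis: SpectralAxis) -> np.ndarray:
        return gaussian_response(self.center, self.bandwidth, self.convention, axis)


@dataclass(frozen=True)
class TabulatedFilter:
    """User-supplied response vector sampled on a known axis."""

    values: np.ndarray
    axis: SpectralAxis
    name: str = "custom"

    def response(self, axis: SpectralAxis) -> np.ndarray:
        v = np.asarray(self.values, dtype=float)
        if axis == self.axis:
            return v
        return np.interp(axis.wavelengths, self.axis.wavelengths, v, left=0.0, right=0.0)


@dataclass
class FilterBank:
    """Ordered set of J filters sharing one spectral axis."""

    filters: Sequence[GaussianFilter | TabulatedFilter]
    axis: SpectralAxis
    _responses: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.filters = list(self.filters)
        if len(self.filters) < 1:
            raise ValueError("a filter bank needs at least one filter")

    @property
    def n_channels(self) -> int:
        return len(self.filters)

    @property
    def responses(self) -> np.ndarray:
        """(J, Q) matrix of sampled responses (cached)."""
        if self._responses is None:
            self._responses = np.stack(
                [f.response(self.axis) for f in self.filters]
            )
        return self._responses

    @property
    def centers(self) -> np.ndarray:
        return np.array(
            [getattr(f, "center", np.nan) for f in self.filters], dtype=float
        )

    @property
    def bandwidths(self) -> np.ndarray:
        return np.array(
            [getattr(f, "bandwidth", np.nan) for f in self.filters], dtype=float
        )

    @classmethod
    def gaussian(
        cls,
        centers: Iterable[float],
        bandwidths: Iterable[float],
        axis: SpectralAxis,
        convention: str = "fwhm",
    ) -> "FilterBank":
        filters = [
            GaussianFilter(float(c), float(b), convention)
            for c, b in zip(centers, bandwidths, strict=True)
        ]
        return cls(filters, axis)


def channel_signal(
    cube: Hypercube, filt: GaussianFilter | TabulatedFilter | np.ndarray
) -> np.ndarray:
    """Integrate one filter against every pixel spectrum -> (N, M) plane."""
    response = _as_response(filt, cube.axis)
    weights = _trapezoid_weights(cube.axis) * response
    return cube.data @ weights


def channel_signals(cube: Hypercube, bank: FilterBank) -> np.ndarray:
    """All J channel planes at once -> (N, M, J)."""
    if bank.axis != cube.axis:
        raise ValueError("filter bank and hypercube axes differ")
    weights = bank.responses * _trapezoid_weights(cube.axis)
    return np.einsum("nmq,jq->nmj", cube.data, weights)


def effective_endmembers(library: EndmemberLibrary, bank: FilterBank) -> np.ndarray:
    """(J, L) design matrix of filtered endmember signals.

    Entry (j, l) is the quadrature of F_j(lambda) * E_l(lambda): the pure
    endmember spectrum as seen through channel j.  This is the design
    matrix used to unmix MSFA signals.
    """
    if bank.axis != library.axis:
        raise ValueError("filter bank and endmember library axes differ")
    weights = bank.responses * _trapezoid_weights(library.axis)
    return weights @ library.E


def bank_to_config(bank: FilterBank) -> list[dict]:
    """Serialize a bank to a plain list of filter descriptions."""
    out: list[dict] = []
    for f in bank.filters:
        if isinstance(f, GaussianFilter):
            out.append(
                {
                    "center_nm": float(f.center),
                    "bandwidth_nm": float(f.bandwidth),
                    "convention": f.convention,
                }
            )
        else:
            out.append(
                {
                    "response": [float(v) for v in np.asarray(f.values)],
                    "name": f.name,
                }
            )
    return out


def bank_from_config(entries: Sequence[dict], axis: SpectralAxis) -> FilterBank:
    """Rebuild a bank from :func:`bank_to_config` output."""
    filters: list[GaussianFilter | TabulatedFilter] = []
    for entry in entries:
        if "response" in entry:
            filters.append(
                TabulatedFilter(
                    np.asarray(entry["response"], dtype=float),
                    axis,
                    entry.get("name", "custom"),
                )
            )
        else:
            filters.append(
                GaussianFilter(
                    float(entry["center_nm"]),
                    float(entry["bandwidth_nm"]),
                    entry.get("convention", "fwhm"),
                )
            )
    return FilterBank(filters, axis)


def _as_response(
    filt: GaussianFilter | TabulatedFilter | np.ndarray, axis: SpectralAxis
) -> np.ndarray:
    if isinstance(filt, np.ndarray):
        if filt.shape != (axis.n_bands,):
            raise ValueError("response vector length does not match the axis")
        return filt
    return filt.response(axis)


def _trapezoid_weights(axis: SpectralAxis) -> np.ndarray:
    """Quadrature weights w with trapz(f) == w @ f on the axis grid."""
    wl = axis.wavelengths
    w = np.zeros_like(wl)
    dw = np.diff(wl)
    w[:-1] += 0.5 * dw
    w[1:] += 0.5 * dw
    return w
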