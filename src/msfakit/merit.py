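"""Scalar merit functions scoring candidate MSFA designs.

All four objectives are RMS errors, zero iff the compared quantities are
identical:

* **spectral**: RMS abundance error of NNLS unmixing with every filter
  responsive at every pixel (no mosaic) — scores the filter set alone.
* **spatial**: per-pixel, per-channel RMS between demosaicked planes and
  the full-resolution channel signals — scores the mosaic arrangement.
* **total**: RMS abundance error after the full pipeline (mosaic,
  demosaic, unmix) — the end-to-end "unmixing error" of a design.
* **rgb**: RMS between RGB renderings of the scene and of the MSFA
  result — scores visual fidelity.

The spectral/total inner square over the endmember vector is the squared
Euclidean norm (summed over endmembers), averaged over the N*M pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .colorimetry import render_rgb
from .demosaic import DemosaickedCube, demosaic
from .filters import FilterBank, channel_signals, effective_endmembers
from .hypercube import AbundanceMap, EndmemberLibrary, Hypercube
from .mosaic import MosaicPattern, MSFASignal, apply_mosaic
from .unmix import nnls_unmix

__all__ = [
    "MeritReport",
    "spectral_merit",
    "spatial_merit",
    "total_merit",
    "rgb_merit",
    "evaluate_design",
]


@dataclass(frozen=True)
class MeritReport:
    value: float
    kind: str
    context: dict[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("merit values are nonnegative by construction")


def _abundance_rms(a_true: np.ndarray, a_est: np.ndarray) -> float:
    if a_true.shape != a_est.shape:
        raise ValueError("abundance maps have different shapes")
    n, m, _ = a_true.shape
    return float(np.sqrt(np.sum((a_true - a_est) ** 2) / (n * m)))


def spectral_merit(
    a_true: AbundanceMap,
    bank: FilterBank,
    cube: Hypercube,
    library: EndmemberLibrary,
) -> MeritReport:
    """RMS abundance error of the filter set with p == 1 everywhere."""
    signals = channel_signals(cube, bank)
    design = effective_endmembers(library, bank)
    est = nnls_unmix(signals, design).abundances
    value = _abundance_rms(a_true.A, est.A)
    return MeritReport(value, "spectral", {"n_channels": bank.n_channels})


def spatial_merit(
    sig: MSFASignal,
    truth_planes: np.ndarray,
    method: str = "wbi",
) -> MeritReport:
    """RMS demosaicking error against the unmosaicked channel planes.

    ``truth_planes`` is (N, M, J): the signal if every filter were
    responsive at every pixel.
    """
    est = demosaic(sig, method, full_res_planes=truth_planes)
    if est.planes.shape != truth_planes.shape:
        raise ValueError("truth planes shape does not match the signal")
    n, m, j = truth_planes.shape
    value = float(np.sqrt(np.sum((truth_planes - est.planes) ** 2) / (n * m * j)))
    return MeritReport(value, "spatial", {"method": method, "pattern": sig.pattern.cell})


def total_merit(
    a_true: AbundanceMap,
    demosaicked: DemosaickedCube,
    design: np.ndarray,
) -> MeritReport:
    """RMS abundance error after unmixing the demosaicked MSFA result."""
    est = nnls_unmix(demosaicked.planes, design).abundances
    value = _abundance_rms(a_true.A, est.A)
    return MeritReport(value, "total", {})


def rgb_merit(
    cube: Hypercube,
    demosaicked: DemosaickedCube,
    bank: FilterBank,
) -> MeritReport:
    """RMS between the RGB renderings of the scene and of the MSFA result."""
    h_rgb = render_rgb(cube)
    i_rgb = render_rgb(demosaicked, bank)
    n, m, _ = h_rgb.shape
    value = float(np.sqrt(np.sum((h_rgb - i_rgb) ** 2) / (3 * n * m)))
    return MeritReport(value, "rgb", {"n_channels": bank.n_channels})


def evaluate_design(
    cube: Hypercube,
    a_true: AbundanceMap,
    library: EndmemberLibrary,
    bank: FilterBank,
    pattern: MosaicPattern,
    method: str = "wbi",
    with_rgb: bool = False,
) -> dict[str, Any]:
    """Run the full pipeline for one fixed design and report every merit.

    Returns a dict with the spectral, spatial, and total merits, the
    demosaicked cube, and the recovered abundance map.
    """
    truth_planes = channel_signals(cube, bank)
    sig = apply_mosaic(truth_planes, pattern)
    est_cube = demosaic(sig, method, full_res_planes=truth_planes)
    design = effective_endmembers(library, bank)
    unmixed = nnls_unmix(est_cube.planes, design)
    report = {
        "spectral": spectral_merit(a_true, bank, cube, library),
        "spatial": spatial_merit(sig, truth_planes, method),
        "total": MeritReport(_abundance_rms(a_true.A, unmixed.abundances.A), "total", {}),
        "demosaicked": est_cube,
        "abundances": unmixed.abundances,
    }
    if with_rgb:
        report["rgb"] = rgb_merit(cube, est_cube, bank)
    return report
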