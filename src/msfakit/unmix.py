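"""Per-pixel nonnegative least-squares (NNLS) abundance recovery.

Each pixel's measured channel vector I(n, m) is regressed on the design
matrix of filtered endmember signatures, minimizing ||E_eff a - I|| subject
to a >= 0.  Pixels are independent; the active-set NNLS solver is
deterministic for fixed input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .hypercube import AbundanceMap

__all__ = ["UnmixResult", "nnls_unmix"]


@dataclass
class UnmixResult:
    abundances: AbundanceMap
    residuals: np.ndarray  # (N, M) Euclidean residual norm per pixel


def nnls_unmix(
    signal: np.ndarray,
    design: np.ndarray,
    sum_to_one: bool = False,
    sum_weight: float = 1e4,
) -> UnmixResult:
    """Unmix an (N, M, J) signal cube against a (J, L) design matrix.

    Parameters
    ----------
    signal
        Channel signals per pixel, shape (N, M, J).
    design
        Filtered endmember signatures (columns are endmembers).
    sum_to_one
        Additionally softly enforce sum(a) == 1 by augmenting the system
        with a heavily weighted row of ones (fully constrained variant;
        off by default — the reproduction pipeline only constrains
        nonnegativity).
    """
    signal = np.asarray(signal, dtype=float)
    design = np.asarray(design, dtype=float)
    if design.ndim != 2:
        raise ValueError("design matrix must be 2-D (channels, endmembers)")
    if not np.all(np.isfinite(design)):
        raise ValueError("design matrix must be finite")
    if signal.ndim != 3:
        raise ValueError("signal must be an (N, M, J) cube")
    if signal.shape[2] != design.shape[0]:
        raise ValueError("signal channel count does not match the design matrix")

    if design.shape[1] > 1:
        cond = np.linalg.cond(design)
        if not np.isfinite(cond) or cond > 1e12:
            warnings.warn(
                f"design matrix is (near) rank-deficient (condition number "
                f"{cond:.3g}); NNLS remains well-posed but abundances may "
                "not be unique",
                stacklevel=2,
            )

    A = design
    if sum_to_one:
        A = np.vstack([design, sum_weight * np.ones((1, design.shape[1]))])

    n, m, _ = signal.shape
    L = design.shape[1]
    abund = np.empty((n, m, L))
    resid = np.empty((n, m))
    for i in range(n):
        for k in range(m):
            b = signal[i, k]
            if sum_to_one:
                b = np.concatenate([b, [sum_weight]])
            a, _ = _scipy_nnls(A, b)
            abund[i, k] = a
            resid[i, k] = np.linalg.norm(design @ a - signal[i, k])
    return UnmixResult(AbundanceMap(abund), resid)
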