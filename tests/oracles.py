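"""Independent, literal, loop-based reference implementations.

These transcribe the pipeline's defining equations step by step with
explicit Python loops (no vectorization, no shared code with the package)
and serve as oracles for the fast implementations.  Boundary handling
mirrors symmetric reflection (a b c | c b a).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls as scipy_nnls


def reflect_index(i: int, n: int) -> int:
    """Symmetric-reflection index into [0, n)."""
    while i < 0 or i >= n:
        if i < 0:
            i = -1 - i
        else:
            i = 2 * n - 1 - i
    return i


def triangle_kernel(pitch: int) -> np.ndarray:
    return np.array([1.0 - abs(k) / pitch for k in range(-(pitch - 1), pitch)])


def conv2d_sep_reflect(img: np.ndarray, kr: np.ndarray, kc: np.ndarray) -> np.ndarray:
    """Separable 2-D convolution with reflect boundaries, by explicit loops."""
    n, m = img.shape
    hr = len(kr) // 2
    hc = len(kc) // 2
    tmp = np.zeros_like(img)
    for i in range(n):
        for j in range(m):
            acc = 0.0
            for t, w in enumerate(kr):
                acc += w * img[reflect_index(i + t - hr, n), j]
            tmp[i, j] = acc
    out = np.zeros_like(img)
    for i in range(n):
        for j in range(m):
            acc = 0.0
            for t, w in enumerate(kc):
                acc += w * tmp[i, reflect_index(j + t - hc, m)]
            out[i, j] = acc
    return out


def interp_masked_loops(values: np.ndarray, mask: np.ndarray, pitch: tuple[int, int]) -> np.ndarray:
    kr = triangle_kernel(pitch[0])
    kc = triangle_kernel(pitch[1])
    num = conv2d_sep_reflect(values, kr, kc)
    den = conv2d_sep_reflect(mask, kr, kc)
    out = np.zeros_like(values)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            out[i, j] = num[i, j] / den[i, j]
    return out


def wbi_loops(masked: np.ndarray, masks: np.ndarray, pitch: tuple[int, int]) -> np.ndarray:
    """(J, N, M) weighted bilinear demosaicking, measured pixels re-imposed."""
    J = masked.shape[0]
    out = np.zeros_like(masked)
    for j in range(J):
        est = interp_masked_loops(masked[j], masks[j], pitch)
        for a in range(masked.shape[1]):
            for b in range(masked.shape[2]):
                out[j, a, b] = masked[j, a, b] if masks[j, a, b] > 0 else est[a, b]
    return out


def specdiff_passes_loops(
    masked: np.ndarray, masks: np.ndarray, pitch: tuple[int, int], G: np.ndarray
) -> np.ndarray:
    """Spectral-differences demosaicking with per-pair pass counts."""
    J, n, m = masked.shape
    prev = wbi_loops(masked, masks, pitch)
    frozen: dict[tuple[int, int], np.ndarray] = {}
    for t in range(1, int(G.max()) + 1):
        new = np.zeros_like(prev)
        for j in range(J):
            acc = np.zeros((n, m))
            for k in range(J):
                if k == j:
                    continue
                if t <= G[k, j]:
                    delta = np.zeros((n, m))
                    for a in range(n):
                        for b in range(m):
                            delta[a, b] = prev[k, a, b] * masks[j, a, b] - masked[j, a, b]
                    delta_full = interp_masked_loops(delta, masks[j], pitch)
                    contrib = prev[k] - delta_full
                    frozen[(k, j)] = contrib
                else:
                    contrib = frozen[(k, j)]
                acc += contrib
            for a in range(n):
                for b in range(m):
                    est = acc[a, b] / (J - 1)
                    new[j, a, b] = masked[j, a, b] if masks[j, a, b] > 0 else est
        prev = new
    return prev


def channel_signal_loops(cube: np.ndarray, response: np.ndarray, wl: np.ndarray) -> np.ndarray:
    """Trapezoidal quadrature of response * spectrum, pixel by pixel."""
    n, m, q = cube.shape
    out = np.zeros((n, m))
    for a in range(n):
        for b in range(m):
            acc = 0.0
            for i in range(q - 1):
                f0 = response[i] * cube[a, b, i]
                f1 = response[i + 1] * cube[a, b, i + 1]
                acc += 0.5 * (f0 + f1) * (wl[i + 1] - wl[i])
            out[a, b] = acc
    return out


def nnls_image_loops(signal: np.ndarray, design: np.ndarray) -> np.ndarray:
    n, m, _ = signal.shape
    L = design.shape[1]
    out = np.zeros((n, m, L))
    for a in range(n):
        for b in range(m):
            out[a, b], _ = scipy_nnls(design, signal[a, b])
    return out


def abundance_rms_loops(a_true: np.ndarray, a_est: np.ndarray) -> float:
    n, m, L = a_true.shape
    acc = 0.0
    for a in range(n):
        for b in range(m):
            for l in range(L):
                acc += (a_true[a, b, l] - a_est[a, b, l]) ** 2
    return float(np.sqrt(acc / (n * m)))


def spatial_rms_loops(truth: np.ndarray, est: np.ndarray) -> float:
    n, m, J = truth.shape
    acc = 0.0
    for a in range(n):
        for b in range(m):
            for j in range(J):
                acc += (truth[a, b, j] - est[a, b, j]) ** 2
    return float(np.sqrt(acc / (n * m * J)))


def xyz_loops(spectrum: np.ndarray, cmf_matrix: np.ndarray, wl: np.ndarray) -> np.ndarray:
    out = np.zeros(3)
    for c in range(3):
        acc = 0.0
        for i in range(len(wl) - 1):
            f0 = spectrum[i] * cmf_matrix[c, i]
            f1 = spectrum[i + 1] * cmf_matrix[c, i + 1]
            acc += 0.5 * (f0 + f1) * (wl[i + 1] - wl[i])
        out[c] = acc
    return out


def rgb_image_loops(
    spectra: np.ndarray, cmf_matrix: np.ndarray, wl: np.ndarray, rgb_matrix: np.ndarray
) -> np.ndarray:
    """Per-pixel spectrum -> XYZ -> max-Y normalization -> clipped linear RGB."""
    n, m, _ = spectra.shape
    xyz = np.zeros((n, m, 3))
    for a in range(n):
        for b in range(m):
            xyz[a, b] = xyz_loops(spectra[a, b], cmf_matrix, wl)
    max_y = xyz[:, :, 1].max()
    if max_y > 0:
        xyz = xyz / max_y
    rgb = np.zeros((n, m, 3))
    for a in range(n):
        for b in range(m):
            v = rgb_matrix @ xyz[a, b]
            rgb[a, b] = np.minimum(np.maximum(v, 0.0), 1.0)
    return rgb


def projected_gradient_nnls(
    A: np.ndarray, b: np.ndarray, max_iters: int = 200_000, tol: float = 1e-14
) -> np.ndarray:
    """Accelerated projected gradient for min ||Ax - b||, x >= 0."""
    AtA = A.T @ A
    Atb = A.T @ b
    lip = np.linalg.norm(AtA, 2)
    if lip == 0:
        return np.zeros(A.shape[1])
    x = np.zeros(A.shape[1])
    y = x.copy()
    t = 1.0
    for _ in range(max_iters):
        x_new = np.maximum(y - (AtA @ y - Atb) / lip, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x_new + ((t - 1.0) / t_new) * (x_new - x)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x, t = x_new, t_new
    return x
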