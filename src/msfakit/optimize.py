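"""Spectral channel search, exhaustive spatial search, and the joint driver.

The spectral stage picks J filter centers/bandwidths minimizing the
spectral (unmixing) merit with no mosaic, by either greedy coordinate
descent from the best of many random starts, or simulated annealing with a
Metropolis acceptance rule.  The spatial stage exhaustively scores every
unit-cell arrangement of the chosen filters with the spatial
(demosaicking) merit.  The joint driver chains the two and reports the
end-to-end total merit of the winning design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .demosaic import demosaic
from .filters import FilterBank, channel_signals, effective_endmembers
from .hypercube import AbundanceMap, EndmemberLibrary, Hypercube
from .merit import MeritReport, spatial_merit, spectral_merit, total_merit
from .mosaic import MosaicPattern, apply_mosaic, enumerate_patterns

__all__ = [
    "SpectralSearchConfig",
    "AnnealConfig",
    "OptimizationTrace",
    "gradient_descent_spectral",
    "simulated_annealing_spectral",
    "exhaustive_spatial",
    "joint_optimize",
    "near_duplicate_pairs",
]


@dataclass
class SpectralSearchConfig:
    """Search space and schedule for the spectral stage.

    All wavelengths in nm.  ``center_step`` is the coordinate-descent
    perturbation for center wavelengths (+/- 2 nm by default);
    ``bandwidth_step`` mirrors it for bandwidths.
    """

    n_channels: int
    wavelength_range: tuple[float, float]
    bandwidth_range: tuple[float, float]
    convention: str = "fwhm"
    max_iters: int = 100
    n_random_starts: int = 50
    n_candidates_kept: int = 5
    center_step: float = 2.0
    bandwidth_step: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.wavelength_range
        bmin, bmax = self.bandwidth_range
        if not lo < hi:
            raise ValueError("wavelength_range must satisfy min < max")
        if not 0 < bmin <= bmax:
            raise ValueError("bandwidth_range must satisfy 0 < min <= max")
        if self.center_step <= 0 or self.bandwidth_step <= 0:
            raise ValueError("steps must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")

    @property
    def initial_bandwidth(self) -> float:
        return 0.5 * (self.bandwidth_range[0] + self.bandwidth_range[1])


@dataclass
class AnnealConfig:
    """Simulated-annealing schedule.

    The temperature decreases by ``T_step`` only when a worsening move is
    accepted (the literal Metropolis schedule); ``stall_guard`` > 0
    additionally decreases it after that many consecutive rejections, as
    an optional escape hatch for low-acceptance stalls (off by default).
    ``max_steps`` bounds the total proposal count.
    """

    T_initial: float
    T_final: float
    T_step: float
    neighbor_radius: float = 10.0
    seed: int | None = None
    max_steps: int = 200_000
    stall_guard: int = 0

    def __post_init__(self) -> None:
        if not self.T_final < self.T_initial:
            raise ValueError("T_final must be below T_initial")
        if self.T_step <= 0:
            raise ValueError("T_step must be positive")
        if self.neighbor_radius <= 0:
            raise ValueError("neighbor_radius must be positive")


@dataclass
class TraceRecord:
    iteration: int
    phase: str
    centers: tuple[float, ...]
    bandwidths: tuple[float, ...]
    merit: float


@dataclass
class OptimizationTrace:
    records: list[TraceRecord] = field(default_factory=list)

    def log(self, iteration: int, phase: str, centers, bandwidths, merit: float) -> None:
        self.records.append(
            TraceRecord(
                iteration, phase,
                tuple(float(c) for c in centers),
                tuple(float(b) for b in bandwidths),
                float(merit),
            )
        )

    def best(self) -> TraceRecord:
        return min(self.records, key=lambda r: r.merit)

    def __len__(self) -> int:
        return len(self.records)


class _MeritEvaluator:
    """Memoized spectral-merit evaluation for one scene."""

    def __init__(
        self,
        cfg: SpectralSearchConfig,
        cube: Hypercube,
        a_true: AbundanceMap,
        library: EndmemberLibrary,
    ):
        self.cfg = cfg
        self.cube = cube
        self.a_true = a_true
        self.library = library
        self.cache: dict[tuple, float] = {}
        self.n_evals = 0

    def bank(self, centers, bandwidths) -> FilterBank:
        return FilterBank.gaussian(centers, bandwidths, self.cube.axis, self.cfg.convention)

    def __call__(self, centers, bandwidths) -> float:
        key = tuple(np.round(centers, 9)) + tuple(np.round(bandwidths, 9))
        if key not in self.cache:
            # candidates with ill-conditioned designs are legal states that
            # simply score badly; silence the per-pixel solver warning here
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                merit = spectral_merit(
                    self.a_true, self.bank(centers, bandwidths), self.cube, self.library
                ).value
            self.cache[key] = merit
            self.n_evals += 1
        return self.cache[key]


def _search_grid(cfg: SpectralSearchConfig, axis) -> np.ndarray:
    lo, hi = cfg.wavelength_range
    wl = axis.wavelengths
    grid = wl[(wl >= lo) & (wl <= hi)]
    if grid.size < cfg.n_channels:
        raise ValueError(
            "channel count exceeds the number of distinct grid wavelengths "
            "in the search range"
        )
    return grid


def gradient_descent_spectral(
    cfg: SpectralSearchConfig,
    cube: Hypercube,
    a_true: AbundanceMap,
    library: EndmemberLibrary,
) -> tuple[FilterBank, OptimizationTrace]:
    """Random multi-start plus greedy coordinate descent.

    Bandwidths start at the midpoint of the allowed range; centers are
    drawn without replacement from the scene's wavelength grid inside the
    search range.  The best ``n_candidates_kept`` starts are refined by
    cycling center then bandwidth perturbations of +/- one step, keeping
    strict improvements, until a full cycle accepts nothing or
    ``max_iters`` cycles elapse.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = _search_grid(cfg, cube.axis)
    evaluate = _MeritEvaluator(cfg, cube, a_true, library)
    trace = OptimizationTrace()
    J = cfg.n_channels
    bw0 = np.full(J, cfg.initial_bandwidth)

    starts: list[tuple[float, np.ndarray]] = []
    for i in range(cfg.n_random_starts):
        centers = np.sort(rng.choice(grid, size=J, replace=False))
        merit = evaluate(centers, bw0)
        trace.log(i, "random-start", centers, bw0, merit)
        starts.append((merit, centers))
    starts.sort(key=lambda t: t[0])

    lo, hi = cfg.wavelength_range
    bmin, bmax = cfg.bandwidth_range
    best_merit = math.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    for rank, (_, centers0) in enumerate(starts[: cfg.n_candidates_kept]):
        centers = centers0.astype(float).copy()
        bw = bw0.copy()
        merit = evaluate(centers, bw)
        for cycle in range(cfg.max_iters):
            changed = False
            for arr, step, lim in (
                (centers, cfg.center_step, (lo, hi)),
                (bw, cfg.bandwidth_step, (bmin, bmax)),
            ):
                for idx in range(J):
                    current = arr[idx]
                    for cand in (current + step, current - step):
                        cand = min(max(cand, lim[0]), lim[1])
                        if cand == current:
                            continue
                        arr[idx] = cand
                        m = evaluate(centers, bw)
                        if m < merit:
                            merit = m
                            current = cand
                            changed = True
                        else:
                            arr[idx] = current
            trace.log(cycle, f"descent-{rank}", centers, bw, merit)
            if not changed:
                break
        if merit < best_merit:
            best_merit = merit
            best = (centers.copy(), bw.copy())

    assert best is not None
    bank = evaluate.bank(best[0], best[1])
    return bank, trace


def simulated_annealing_spectral(
    cfg: SpectralSearchConfig,
    anneal: AnnealConfig,
    cube: Hypercube,
    a_true: AbundanceMap,
    library: EndmemberLibrary,
) -> tuple[FilterBank, OptimizationTrace]:
    """Metropolis annealing over filter centers and bandwidths.

    Neighbors perturb every center and bandwidth by a uniform draw within
    +/- ``neighbor_radius`` nm, clipped to the search bounds.  Strictly
    improving neighbors are always accepted with the temperature
    unchanged; worsening (or equal) neighbors are accepted with
    probability exp(-(eps' - eps)/T), and each such acceptance cools the
    system by ``T_step``.  The best-visited state is returned.
    Deterministic for fixed seeds.
    """
    rng = np.random.default_rng(anneal.seed if anneal.seed is not None else cfg.seed)
    grid = _search_grid(cfg, cube.axis)
    evaluate = _MeritEvaluator(cfg, cube, a_true, library)
    trace = OptimizationTrace()
    J = cfg.n_channels
    lo, hi = cfg.wavelength_range
    bmin, bmax = cfg.bandwidth_range
    r = anneal.neighbor_radius

    centers = np.sort(rng.choice(grid, size=J, replace=False)).astype(float)
    bw = np.full(J, cfg.initial_bandwidth)
    merit = evaluate(centers, bw)
    trace.log(0, "anneal-init", centers, bw, merit)
    best = (merit, centers.copy(), bw.copy())

    T = anneal.T_initial
    stall = 0
    step = 0
    while T > anneal.T_final and step < anneal.max_steps:
        step += 1
        cand_c = np.clip(centers + rng.uniform(-r, r, size=J), lo, hi)
        cand_b = np.clip(bw + rng.uniform(-r, r, size=J), bmin, bmax)
        cand_merit = evaluate(cand_c, cand_b)
        if cand_merit < merit:
            centers, bw, merit = cand_c, cand_b, cand_merit
            stall = 0
        elif rng.random() < math.exp(-(cand_merit - merit) / T):
            centers, bw, merit = cand_c, cand_b, cand_merit
            T -= anneal.T_step
            stall = 0
        else:
            stall += 1
            if anneal.stall_guard and stall >= anneal.stall_guard:
                T -= anneal.T_step
                stall = 0
        trace.log(step, "anneal", centers, bw, merit)
        if merit < best[0]:
            best = (merit, centers.copy(), bw.copy())

    bank = evaluate.bank(best[1], best[2])
    return bank, trace


def exhaustive_spatial(
    bank: FilterBank,
    cell_shape: tuple[int, int],
    cube: Hypercube,
    method: str = "wbi",
    deduplicate_shifts: bool = False,
    budget: int = 100_000,
) -> tuple[MosaicPattern, MeritReport]:
    """Score every unit-cell arrangement; return the argmin pattern.

    Ties resolve to the first pattern in the deterministic enumeration
    order.  Raises if J! exceeds ``budget``.
    """
    J = bank.n_channels
    if math.factorial(J) > budget:
        raise ValueError(
            f"exhaustive search over {J}! = {math.factorial(J)} patterns "
            f"exceeds the budget ({budget}); use a smaller cell or raise it"
        )
    truth_planes = channel_signals(cube, bank)
    best_pattern = None
    best_report = None
    for pattern in enumerate_patterns(J, cell_shape, deduplicate_shifts):
        sig = apply_mosaic(truth_planes, pattern)
        report = spatial_merit(sig, truth_planes, method)
        if best_report is None or report.value < best_report.value:
            best_pattern, best_report = pattern, report
    assert best_pattern is not None and best_report is not None
    return best_pattern, best_report


def joint_optimize(
    cfg: SpectralSearchConfig,
    anneal: AnnealConfig | None,
    cell_shape: tuple[int, int],
    cube: Hypercube,
    a_true: AbundanceMap,
    library: EndmemberLibrary,
    method: str = "wbi",
) -> dict:
    """Spectral search, then exhaustive spatial search, then total merit.

    Uses gradient descent when ``anneal`` is None, simulated annealing
    otherwise.  Returns the winning filter bank and mosaic pattern with
    the spectral, spatial, and end-to-end total merit reports plus the
    search trace.
    """
    if anneal is None:
        bank, trace = gradient_descent_spectral(cfg, cube, a_true, library)
    else:
        bank, trace = simulated_annealing_spectral(cfg, anneal, cube, a_true, library)
    spectral = spectral_merit(a_true, bank, cube, library)

    if bank.n_channels == 1:
        pattern = MosaicPattern.trivial()
        truth_planes = channel_signals(cube, bank)
        sig = apply_mosaic(truth_planes, pattern)
        spatial = spatial_merit(sig, truth_planes, method)
    else:
        pattern, spatial = exhaustive_spatial(bank, cell_shape, cube, method)
        truth_planes = channel_signals(cube, bank)
        sig = apply_mosaic(truth_planes, pattern)

    est = demosaic(sig, method, full_res_planes=truth_planes)
    design = effective_endmembers(library, bank)
    total = total_merit(a_true, est, design)
    return {
        "bank": bank,
        "pattern": pattern,
        "spectral": spectral,
        "spatial": spatial,
        "total": total,
        "trace": trace,
        "demosaicked": est,
    }


def near_duplicate_pairs(
    bank: FilterBank, tol_nm: float | None = None
) -> list[tuple[int, int]]:
    """Channel pairs with nearly overlapping passbands.

    Duplicated channels are a signature of optimized designs with more
    channels than the scene has distinct spectral features: the surplus
    channels re-sample an informative band (buying noise averaging and
    denser spatial sampling) instead of opening a new one.  By default a
    pair is flagged when its full-width-at-half-maximum intervals
    intersect, i.e. center distance < (bw_i + bw_j) / 2; pass ``tol_nm``
    to flag on a fixed center distance instead (e.g. the emission
    linewidth of the features being sampled).
    """
    centers = bank.centers
    bandwidths = bank.bandwidths
    pairs = []
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            tol = tol_nm if tol_nm is not None else 0.5 * (bandwidths[i] + bandwidths[j])
            if abs(centers[i] - centers[j]) < tol:
                pairs.append((i, j))
    return pairs
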