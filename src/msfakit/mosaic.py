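"""Mosaic unit cells, binary sampling masks, and pattern enumeration.

A :class:`MosaicPattern` is a small (h, w) unit cell of channel indices
tiled periodically over the sensor.  Tiling yields one binary mask p_j per
channel; the masks partition the sensor (exactly one channel per pixel).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = ["MosaicPattern", "MSFASignal", "masks", "enumerate_patterns", "apply_mosaic"]


@dataclass(frozen=True)
class MosaicPattern:
    """Unit cell of channel indices, e.g. ``[[0, 1], [2, 3]]`` for a 2x2."""

    cell: tuple[tuple[int, ...], ...]
    n_channels: int

    def __post_init__(self) -> None:
        cell = tuple(tuple(int(v) for v in row) for row in self.cell)
        object.__setattr__(self, "cell", cell)
        arr = self.cell_array
        if arr.size < self.n_channels:
            raise ValueError("unit cell smaller than the channel count")
        present = np.unique(arr)
        if present.min() < 0 or present.max() >= self.n_channels:
            raise ValueError("cell entries must be channel indices in [0, J)")
        if present.size != self.n_channels:
            raise ValueError("every channel must appear at least once in the cell")

    @classmethod
    def from_array(cls, cell: np.ndarray, n_channels: int | None = None) -> "MosaicPattern":
        cell = np.asarray(cell, dtype=int)
        j = int(cell.max()) + 1 if n_channels is None else n_channels
        return cls(tuple(tuple(row) for row in cell), j)

    @property
    def cell_array(self) -> np.ndarray:
        return np.array(self.cell, dtype=int)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.cell), len(self.cell[0])

    @classmethod
    def trivial(cls) -> "MosaicPattern":
        """Single-channel 'mosaic' (p == 1 everywhere)."""
        return cls(((0,),), 1)


@dataclass
class MSFASignal:
    """Mosaicked measurement: masked per-channel planes plus their masks."""

    masked_planes: np.ndarray  # (J, N, M), zero off-mask
    masks: np.ndarray          # (J, N, M) binary
    pattern: MosaicPattern

    @property
    def n_channels(self) -> int:
        return self.masked_planes.shape[0]

    @property
    def sensor_image(self) -> np.ndarray:
        """The single-sensor raw image sum_j masked_plane_j."""
        return self.masked_planes.sum(axis=0)


def masks(pattern: MosaicPattern, n_rows: int, n_cols: int) -> np.ndarray:
    """Tile the unit cell and return (J, N, M) binary masks."""
    h, w = pattern.shape
    if n_rows < h or n_cols < w:
        raise ValueError("sensor smaller than the unit cell")
    cell = pattern.cell_array
    reps = (-(-n_rows // h), -(-n_cols // w))
    tiled = np.tile(cell, reps)[:n_rows, :n_cols]
    return (tiled[None, :, :] == np.arange(pattern.n_channels)[:, None, None]).astype(
        float
    )


def apply_mosaic(channel_planes: np.ndarray, pattern: MosaicPattern) -> MSFASignal:
    """Mask full-resolution channel planes onto the sensor.

    ``channel_planes`` may be (J, N, M) or (N, M, J); the result holds
    (J, N, M) masked planes with zeros where a channel is not sampled.
    """
    planes = np.asarray(channel_planes, dtype=float)
    if planes.ndim != 3:
        raise ValueError("channel planes must be 3-D")
    if planes.shape[0] != pattern.n_channels and planes.shape[2] == pattern.n_channels:
        planes = np.moveaxis(planes, 2, 0)
    if planes.shape[0] != pattern.n_channels:
        raise ValueError("plane count does not match the pattern's channel count")
    p = masks(pattern, planes.shape[1], planes.shape[2])
    return MSFASignal(planes * p, p, pattern)


def _canonical_shift(cell: np.ndarray) -> bytes:
    """Lexicographically smallest byte string over cyclic row/col shifts."""
    h, w = cell.shape
    best = None
    for dr in range(h):
        rolled_r = np.roll(cell, dr, axis=0)
        for dc in range(w):
            key = np.roll(rolled_r, dc, axis=1).tobytes()
            if best is None or key < best:
                best = key
    return best  # type: ignore[return-value]


def enumerate_patterns(
    n_channels: int,
    cell_shape: tuple[int, int],
    deduplicate_shifts: bool = False,
):
    """Yield every assignment of J channels to an h x w cell (h*w == J).

    Order is deterministic (itertools.permutations order).  With
    ``deduplicate_shifts`` one representative per cyclic row/column shift
    orbit is kept; note shifted cells tile to *translated* sensor
    patterns, which score differently against a fixed finite scene, so
    deduplication is a lossy search-space reduction and is off by default.
    """
    h, w = cell_shape
    if h * w < n_channels:
        raise ValueError("cell has fewer sites than channels")
    if h * w != n_channels:
        raise ValueError(
            "enumeration assumes one cell site per channel (h*w == J)"
        )
    seen: set[bytes] = set()
    for perm in itertools.permutations(range(n_channels)):
        cell = np.array(perm, dtype=int).reshape(h, w)
        if deduplicate_shifts:
            key = _canonical_shift(cell)
            if key in seen:
                continue
            seen.add(key)
        yield MosaicPattern(tuple(tuple(row) for row in cell), n_channels)
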