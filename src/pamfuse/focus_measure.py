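"""3D modified-Laplacian focus measure.

The per-voxel sharpness indicator is the discrete 3D modified Laplacian
(ML): the sum over the three axes of the absolute second difference,

    ML(x,y,z) = |2P(x,y,z) - P(x-1,y,z) - P(x+1,y,z)|
              + |2P(x,y,z) - P(x,y-1,z) - P(x,y+1,z)|
              + |2P(x,y,z) - P(x,y,z-1) - P(x,y,z+1)|.

Taking absolute values before summing prevents curvature of opposite sign
along orthogonal axes from cancelling.  The volume is then tiled into
non-overlapping cubic blocks of edge ``2N+1`` and the block focus measure is
the sum-modified Laplacian (SML): the sum of ML over the block.  A larger
SML means more high-frequency content, i.e. a better-focused block.

Step size is fixed at one voxel per axis even though dz differs from dx:
the operator is defined in voxel units and both inputs of a fusion share
the same anisotropy, so the comparison is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .volume_io import ValidationError, Volume

_PAD_MODES = {"replicate": "edge", "zero": "constant"}


def modified_laplacian(v: Volume | np.ndarray, boundary: str = "replicate") -> np.ndarray:
    """Per-voxel 3D modified Laplacian of a volume.

    Parameters
    ----------
    v
        Volume (or raw 3D array) with every dimension >= 3.
    boundary
        How the one-voxel neighbourhood is closed at the faces:
        ``"replicate"`` (default) repeats the edge voxel, ``"zero"`` pads
        with zeros.  Replication avoids artificial edges at the volume
        faces that would inflate SML in boundary blocks.

    Returns
    -------
    numpy.ndarray
        Non-negative ML field with the same shape as the input.
    """
    data = v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)
    if data.ndim != 3 or min(data.shape) < 3:
        raise ValidationError(
            f"modified Laplacian needs a 3D volume with all dims >= 3, got {data.shape}"
        )
    if boundary not in _PAD_MODES:
        raise ValidationError(f"boundary must be 'replicate' or 'zero', got {boundary!r}")
    p = np.pad(data.astype(np.float64, copy=False), 1, mode=_PAD_MODES[boundary])
    c = p[1:-1, 1:-1, 1:-1]
    ml = np.abs(2.0 * c - p[:-2, 1:-1, 1:-1] - p[2:, 1:-1, 1:-1])
    ml += np.abs(2.0 * c - p[1:-1, :-2, 1:-1] - p[1:-1, 2:, 1:-1])
    ml += np.abs(2.0 * c - p[1:-1, 1:-1, :-2] - p[1:-1, 1:-1, 2:])
    return ml


@dataclass(frozen=True)
class BlockGrid:
    """Non-overlapping tiling of a volume into cubic blocks of edge ``2N+1``.

    Tiling starts at index 0 on each axis with stride ``2N+1``; a final
    truncated block absorbs the remainder so every voxel belongs to exactly
    one block.  ``sml`` (if set) holds one focus-measure value per block,
    indexed ``sml[bi, bj, bk]``.
    """

    shape: tuple[int, int, int]
    n: int
    sml: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"block half-width N must be >= 1, got {self.n}")
        if self.edge > min(self.shape):
            raise ValidationError(
                f"block edge {self.edge} exceeds smallest volume dimension "
                f"of shape {self.shape}"
            )

    @property
    def edge(self) -> int:
        return 2 * self.n + 1

    @property
    def counts(self) -> tuple[int, int, int]:
        """Number of blocks along each axis."""
        return tuple(-(-s // self.edge) for s in self.shape)

    def starts(self, axis: int) -> np.ndarray:
        """Start index of each block along one axis."""
        return np.arange(0, self.shape[axis], self.edge)

    def sizes(self, axis: int) -> np.ndarray:
        """Edge length of each block along one axis (last may be truncated)."""
        starts = self.starts(axis)
        ends = np.minimum(starts + self.edge, self.shape[axis])
        return ends - starts

    def ranges(self):
        """Iterate ``(bi, bj, bk), (slice_x, slice_y, slice_z)`` over blocks."""
        sx, sy, sz = (self.starts(a) for a in range(3))
        e = self.edge
        for bi, x0 in enumerate(sx):
            for bj, y0 in enumerate(sy):
                for bk, z0 in enumerate(sz):
                    yield (bi, bj, bk), (
                        slice(x0, min(x0 + e, self.shape[0])),
                        slice(y0, min(y0 + e, self.shape[1])),
                        slice(z0, min(z0 + e, self.shape[2])),
                    )

    def same_tiling(self, other: "BlockGrid") -> bool:
        return self.shape == other.shape and self.n == other.n

    def expand(self, block_values: np.ndarray) -> np.ndarray:
        """Broadcast one value per block back onto the full voxel grid."""
        out = block_values
        for axis in range(3):
            out = np.repeat(out, self.sizes(axis), axis=axis)
        return out


def block_partition(shape: tuple[int, int, int], n: int) -> BlockGrid:
    """Partition ``shape`` into non-overlapping cubic blocks of edge ``2N+1``."""
    return BlockGrid(shape=tuple(int(s) for s in shape), n=int(n))


def sum_modified_laplacian(ml: np.ndarray, grid: BlockGrid) -> BlockGrid:
    """Per-block sum of the ML field (the SML focus measure).

    The total of all block values equals the sum of the whole ML field:
    the tiling is a disjoint cover.
    """
    ml = np.asarray(ml)
    if ml.shape != grid.shape:
        raise ValidationError(
            f"ML field shape {ml.shape} does not match block grid shape {grid.shape}"
        )
    sml = ml
    for axis in range(3):
        sml = np.add.reduceat(sml, grid.starts(axis), axis=axis)
    return replace(grid, sml=sml)


def volume_sml(v: Volume | np.ndarray, n: int = 3, boundary: str = "replicate") -> BlockGrid:
    """Convenience: ML then block SML in one call."""
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    grid = block_partition(data.shape, n)
    return sum_modified_laplacian(modified_laplacian(v, boundary=boundary), grid)
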