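"""Decision-map construction, consistency verification, and smoothing.

The initial decision map (IDM) compares the two inputs' block focus
measures: every voxel of block *i* receives

    1    if SML1_i > SML2_i   (input 1 in focus)
    0    if SML1_i < SML2_i   (input 2 in focus)
    0.5  if SML1_i = SML2_i   (tie; the fusion will average)

Noise can misclassify isolated blocks, so the IDM is refined by a
consistency-verification step: a block labelled 1 whose six face-adjacent
blocks are all labelled 0 is flipped to 0, and vice versa.  Tied (0.5)
blocks are never flipped and never count as agreeing neighbours, and blocks
at the volume boundary (fewer than six face neighbours) are left alone in
the default ``unanimous6`` mode.  A ``majority6`` variant (flip when at
least 4 of the 6 existing neighbours disagree) is available.

Finally the refined map is smoothed with a normalized, truncated 3D
Gaussian window to remove block seams, giving the final decision map (FDM)
with values in [0, 1]:

    FDM(x) = (1/W) * sum_{x' in S} G(x', x) * IDM(x'),   W = sum_{x' in S} G(x', x)

with G a Gaussian of standard deviation sigma in voxel units.  At the
volume faces the window is truncated and W recomputed over the surviving
voxels, so constants are preserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .focus_measure import BlockGrid
from .volume_io import ValidationError

STAGE_IDM = "IDM"
STAGE_REFINED = "refined_IDM"
STAGE_FDM = "FDM"


@dataclass(frozen=True)
class DecisionMap:
    """Per-voxel weight field selecting (or blending) the in-focus input.

    ``data`` holds the voxel weights; ``block_values`` (present before
    smoothing) holds one label per block on the tiling ``grid``.
    """

    data: np.ndarray
    stage: str
    grid: BlockGrid | None = None
    block_values: np.ndarray | None = None


@dataclass(frozen=True)
class GaussianSmoother:
    """Truncated Gaussian smoothing window.

    sigma is in voxels; the cubic window has half-width ``window_radius``
    voxels (default ``ceil(3*sigma)``, which bounds the truncated mass).
    """

    sigma: float = 2.0
    window_radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        radius = self.window_radius
        if radius is None:
            radius = math.ceil(3.0 * self.sigma)
            object.__setattr__(self, "window_radius", radius)
        if radius < 1:
            raise ValidationError(f"window_radius must be >= 1, got {radius}")

    def kernel1d(self) -> np.ndarray:
        """Unnormalized 1D Gaussian taps over the window (normalization is
        carried out jointly over the 3D window by the smoother)."""
        k = np.arange(-self.window_radius, self.window_radius + 1, dtype=np.float64)
        return np.exp(-(k**2) / (2.0 * self.sigma**2))


def build_idm(grid1: BlockGrid, grid2: BlockGrid) -> DecisionMap:
    """Initial decision map from paired block focus measures."""
    if grid1.sml is None or grid2.sml is None:
        raise ValidationError("both block grids must carry SML values")
    if not grid1.same_tiling(grid2):
        raise ValidationError(
            f"mismatched tilings: shape/N {grid1.shape}/{grid1.n} "
            f"vs {grid2.shape}/{grid2.n}"
        )
    bv = np.where(
        grid1.sml > grid2.sml, 1.0, np.where(grid1.sml < grid2.sml, 0.0, 0.5)
    )
    return DecisionMap(
        data=grid1.expand(bv), stage=STAGE_IDM, grid=grid1, block_values=bv
    )


def _neighbor_flags(bv: np.ndarray, value: float) -> tuple[np.ndarray, np.ndarray]:
    """Count face neighbours equal to ``value`` and how many exist.

    Returns ``(matches, existing)`` arrays of the block-grid shape.
    """
    matches = np.zeros(bv.shape, dtype=np.int64)
    existing = np.zeros(bv.shape, dtype=np.int64)
    for axis in range(3):
        for sign in (-1, 1):
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if sign < 0:
                src[axis], dst[axis] = slice(1, None), slice(None, -1)
            else:
                src[axis], dst[axis] = slice(None, -1), slice(1, None)
            matches[tuple(dst)] += bv[tuple(src)] == value
            existing[tuple(dst)] += 1
    return matches, existing


def consistency_verification(
    idm: DecisionMap, mode: str = "unanimous6", iterations: int = 1
) -> DecisionMap:
    """Refine the IDM by flipping isolated misclassified blocks.

    ``unanimous6`` (default, the stated rule): a 0/1 block is flipped only
    when all six face neighbours exist and carry the opposite label.
    ``majority6``: flipped when at least four of the existing face
    neighbours carry the opposite label.  Decisions are computed from the
    input map and applied simultaneously, once per iteration.
    """
    if idm.block_values is None or idm.grid is None:
        raise ValidationError("consistency verification needs a block-constant map")
    if mode not in ("unanimous6", "majority6"):
        raise ValidationError(f"mode must be 'unanimous6' or 'majority6', got {mode!r}")
    bv = idm.block_values.copy()
    for _ in range(max(1, int(iterations))):
        zeros, existing = _neighbor_flags(bv, 0.0)
        ones, _ = _neighbor_flags(bv, 1.0)
        if mode == "unanimous6":
            flip_to_zero = (bv == 1.0) & (existing == 6) & (zeros == 6)
            flip_to_one = (bv == 0.0) & (existing == 6) & (ones == 6)
        else:
            flip_to_zero = (bv == 1.0) & (zeros >= 4)
            flip_to_one = (bv == 0.0) & (ones >= 4)
        new = bv.copy()
        new[flip_to_zero] = 0.0
        new[flip_to_one] = 1.0
        if np.array_equal(new, bv):
            bv = new
            break
        bv = new
    return DecisionMap(
        data=idm.grid.expand(bv), stage=STAGE_REFINED, grid=idm.grid, block_values=bv
    )


def gaussian_smooth(
    idm: DecisionMap, smoother: GaussianSmoother | None = None
) -> DecisionMap:
    """Smooth a decision map into the final decision map (FDM).

    The cubic window makes the 3D Gaussian separable, so the windowed sum
    and its normalization factor are both computed with three 1D passes;
    zero-padding the data and normalizing by the same-window sum of ones
    reproduces boundary truncation with W recomputed over surviving voxels.
    """
    smoother = smoother or GaussianSmoother()
    taps = smoother.kernel1d()
    num = np.asarray(idm.data, dtype=np.float64)
    den = np.ones_like(num)
    for axis in range(3):
        num = correlate1d(num, taps, axis=axis, mode="constant", cval=0.0)
        den = correlate1d(den, taps, axis=axis, mode="constant", cval=0.0)
    fdm = np.clip(num / den, 0.0, 1.0)
    return DecisionMap(data=fdm, stage=STAGE_FDM, grid=idm.grid, block_values=None)
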